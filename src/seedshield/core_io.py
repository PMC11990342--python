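"""Fixture loading, run configuration and deterministic report writing.

The quantitative inputs of the study are five small printed tables shipped
with the package: the 2^3 formulation design with its pLD50 responses, the
per-biofilm desorption parameters (D, K, F), the film physical constants
(thickness etc.), the species-by-sex mortality contingency counts, and the
docking binding affinities. Display scalings used in the printed desorption
table (x10^6, x10^3, x10^5 column headers) are undone on load, so in-memory
values are always in base units: mm, day, g, cm^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .association import ContingencyTable2x2
from .factorial_doe import FactorialDesign

__all__ = ["StudyFixtures", "RunConfig", "FixtureError", "load_fixtures", "write_report"]

_TABLE4_SCALES = {
    "D_x1e6_mm2_per_day": ("D", 1e-6),
    "K_x1e3_per_day": ("K", 1e-3),
    "F_x1e5_g_per_day_per_cm2": ("F", 1e-5),
}


class FixtureError(ValueError):
    """A fixture file is malformed or violates a table invariant."""


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration echoed into every output artifact.

    Units policy is fixed package-wide (time in days, length in mm, mass in
    g, area in cm^2) and recorded for provenance rather than configurability.
    """

    seed: int = 0
    outdir: Path = Path("seedshield-out")
    report_formats: tuple[str, ...] = ("json", "csv")
    units: dict = field(
        default_factory=lambda: {"time": "day", "length": "mm", "mass": "g", "area": "cm^2"}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "outdir", Path(self.outdir))
        unknown = set(self.report_formats) - {"json", "csv"}
        if unknown:
            raise ValueError(f"unsupported report formats: {sorted(unknown)}")


@dataclass(frozen=True)
class StudyFixtures:
    """Validated in-memory bundle of the study's printed tables.

    table1: design + responses (biofilm, coded A/B/C, pLD50_SL, pLD50_BP).
    table4: desorption parameters in base units (D mm^2/day, K 1/day,
    F g/day/cm^2). table6: film constants; thickness_mm is the load-bearing
    one, the rest travel as opaque metadata with uncertainties. table7: 2x2
    species-by-sex mortality counts. table9: docking affinities (kcal/mol).
    """

    table1: pd.DataFrame
    table4: pd.DataFrame
    table6: dict
    table7: ContingencyTable2x2
    table9: pd.DataFrame

    @property
    def film_thickness_mm(self) -> float:
        return float(self.table6["thickness_mm"]["value"])

    def design(self) -> FactorialDesign:
        """The formulation design as a fit-ready :class:`FactorialDesign`."""
        return FactorialDesign(runs=self.table1.copy())


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise FixtureError(f"cannot parse {name} fixture at {path}: {exc}") from exc


def load_fixtures(path: str | Path | None = None) -> StudyFixtures:
    """Load and validate the printed-table fixtures.

    With ``path=None`` the bundled defaults are used; otherwise ``path`` is a
    directory holding the same five files (table1_design.csv,
    table4_desorption.csv, table6_film.json, table7_contingency.csv,
    table9_docking.csv).
    """
    if path is None:
        base = Path(str(resources.files("seedshield").joinpath("data")))
    else:
        base = Path(path)
        if not base.is_dir():
            raise FixtureError(f"fixture directory {base} does not exist")

    table1 = _read_csv(base / "table1_design.csv", "design")
    required1 = {"biofilm", "A", "B", "C", "pLD50_SL", "pLD50_BP"}
    if not required1.issubset(table1.columns):
        raise FixtureError(
            f"design fixture missing columns {sorted(required1 - set(table1.columns))}"
        )
    if len(table1) != 8:
        raise FixtureError(f"design fixture must have exactly 8 rows, got {len(table1)}")
    try:
        FactorialDesign(runs=table1.copy())
    except ValueError as exc:
        raise FixtureError(f"design fixture invalid: {exc}") from exc

    raw4 = _read_csv(base / "table4_desorption.csv", "desorption")
    missing4 = set(_TABLE4_SCALES) - set(raw4.columns)
    if "biofilm" not in raw4.columns or missing4:
        raise FixtureError(f"desorption fixture missing columns {sorted(missing4)}")
    table4 = pd.DataFrame({"biofilm": raw4["biofilm"]})
    for col, (name, scale) in _TABLE4_SCALES.items():
        vals = raw4[col].to_numpy(dtype=float) * scale
        if np.any(vals <= 0):
            bad = raw4["biofilm"][vals <= 0].tolist()
            raise FixtureError(f"non-positive {name} for biofilm(s) {bad}")
        table4[name] = vals

    with open(base / "table6_film.json") as fh:
        table6 = json.load(fh)
    if "thickness_mm" not in table6 or table6["thickness_mm"]["value"] <= 0:
        raise FixtureError("film fixture must state a positive thickness_mm")

    t7 = _read_csv(base / "table7_contingency.csv", "contingency")
    if not {"species", "male", "female"}.issubset(t7.columns) or len(t7) != 2:
        raise FixtureError("contingency fixture must have 2 rows: species, male, female")
    counts = t7[["male", "female"]].to_numpy()
    if not np.issubdtype(counts.dtype, np.integer) or np.any(counts < 0):
        raise FixtureError("contingency counts must be non-negative integers")
    table7 = ContingencyTable2x2(counts=counts, row_labels=tuple(t7["species"]))

    table9 = _read_csv(base / "table9_docking.csv", "docking")
    if not {"target", "affinity_kcal_per_mol"}.issubset(table9.columns):
        raise FixtureError("docking fixture must have columns target, affinity_kcal_per_mol")

    return StudyFixtures(table1=table1, table4=table4, table6=table6,
                         table7=table7, table9=table9)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {
            "columns": list(obj.columns),
            "index": [str(i) for i in obj.index],
            "data": _jsonable(obj.to_numpy().tolist()),
        }
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_report(results: dict, config: RunConfig, stage: str) -> list[Path]:
    """Write stage results as deterministic JSON (and CSVs for DataFrames).

    The JSON carries the seed, the config echo and the stage name; reruns
    with identical inputs produce byte-identical files. An empty result set
    is an error, never an empty report.
    """
    if not results:
        raise ValueError("refusing to write an empty report")
    outdir = config.outdir
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    written: list[Path] = []
    if "csv" in config.report_formats:
        for key, value in results.items():
            if isinstance(value, pd.DataFrame):
                p = outdir / f"{stage}_{key}.csv"
                keep_index = not isinstance(value.index, pd.RangeIndex)
                value.to_csv(p, index=keep_index, lineterminator="\n")
                written.append(p)
    if "json" in config.report_formats:
        payload = {
            "stage": stage,
            "seed": config.seed,
            "config": {
                "units": config.units,
                "report_formats": list(config.report_formats),
            },
            "results": _jsonable(results),
        }
        p = outdir / f"{stage}_report.json"
        with open(p, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
    return written
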