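"""Dose–mortality bioassay reduction: Abbott correction and pLD50.

Treated mortality is corrected for background control mortality with the
Abbott formula, CM% = (MOI - MOC) / (100 - MOC) * 100, and the median lethal
dose is read off by piecewise-linear interpolation of corrected mortality
against the natural log of dose: pLD50 = ln(LD50) at the first upward
crossing of the 50% line. No parametric tolerance model is fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseAssay",
    "Ld50Result",
    "AssayRangeError",
    "corrected_mortality",
    "pld50",
    "pld50_from_simulation",
]


class AssayRangeError(ValueError):
    """Corrected mortality never crosses 50% inside the tested dose range."""


@dataclass
class DoseResponseAssay:
    """Counts from one dose–mortality experiment.

    ``exposed`` and ``dead`` have shape (n_doses, n_replicates); the control
    arrays have shape (n_replicates,). Doses must be strictly positive and
    sorted ascending; dead counts can never exceed exposed counts.
    """

    doses: np.ndarray
    exposed: np.ndarray
    dead: np.ndarray
    control_exposed: np.ndarray
    control_dead: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.exposed = np.atleast_2d(np.asarray(self.exposed, dtype=int))
        self.dead = np.atleast_2d(np.asarray(self.dead, dtype=int))
        self.control_exposed = np.atleast_1d(np.asarray(self.control_exposed, dtype=int))
        self.control_dead = np.atleast_1d(np.asarray(self.control_dead, dtype=int))
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any(np.diff(self.doses) < 0):
            raise ValueError("doses must be sorted ascending")
        if self.exposed.shape != self.dead.shape:
            raise ValueError("exposed and dead must have matching shapes")
        if self.exposed.shape[0] != self.doses.size:
            raise ValueError("first axis of exposed/dead must match doses")
        if np.any(self.dead > self.exposed) or np.any(self.control_dead > self.control_exposed):
            raise ValueError("dead counts cannot exceed exposed counts")
        if np.any(self.dead < 0) or np.any(self.exposed < 1):
            raise ValueError("counts must be non-negative with >= 1 exposed")

    @property
    def n_replicates(self) -> int:
        return self.exposed.shape[1]

    def control_mortality_pct(self) -> float:
        """Control mortality in %, pooled over replicates."""
        return 100.0 * self.control_dead.sum() / self.control_exposed.sum()

    def to_frame(self) -> pd.DataFrame:
        """Long-format table `dose, replicate, exposed, dead, is_control`."""
        rows = []
        for i, d in enumerate(self.doses):
            for r in range(self.n_replicates):
                rows.append((d, r, self.exposed[i, r], self.dead[i, r], False))
        for r, (ne, nd) in enumerate(zip(self.control_exposed, self.control_dead)):
            rows.append((0.0, r, ne, nd, True))
        return pd.DataFrame(rows, columns=["dose", "replicate", "exposed", "dead", "is_control"])


@dataclass(frozen=True)
class Ld50Result:
    """LD50 estimate with the interpolation bracket that produced it."""

    ld50: float
    pld50: float
    bracket: tuple[float, float]  # dose pair (or equal doses on an exact hit)
    cm_table: pd.DataFrame  # columns: dose, moi_pct, cm_pct, flags


def corrected_mortality(moi: float, moc: float) -> tuple[float, list[str]]:
    """Abbott-corrected mortality CM% = (MOI - MOC)/(100 - MOC) * 100.

    Returns the corrected percentage clamped to [0, 100] together with any
    flags ("negative-corrected" when controls out-died the treatment).
    """
    if not (0 <= moi <= 100):
        raise ValueError(f"MOI must be in [0, 100], got {moi}")
    if not (0 <= moc < 100):
        raise ValueError(
            f"MOC must be in [0, 100); got {moc}"
            + (" (control fully dead, assay invalid)" if moc == 100 else "")
        )
    cm = (moi - moc) / (100.0 - moc) * 100.0
    flags = []
    if cm < 0:
        flags.append("negative-corrected")
        cm = 0.0
    return min(cm, 100.0), flags


def pld50(assay: DoseResponseAssay) -> Ld50Result:
    """pLD50 = ln(LD50) from linear interpolation of CM% on ln(dose).

    Per-replicate mortalities are Abbott-corrected against the pooled control
    mortality and averaged per dose; the 50% line is located at the first
    upward crossing walking doses in ascending order, with an exact 50% hit
    resolved to the lower (first) such dose.
    """
    if assay.doses.size < 2:
        raise ValueError("need at least 2 doses for interpolation")
    moc = assay.control_mortality_pct()
    cm_mean = np.empty(assay.doses.size)
    moi_mean = np.empty(assay.doses.size)
    all_flags: list[str] = []
    for i in range(assay.doses.size):
        moi_r = 100.0 * assay.dead[i] / assay.exposed[i]
        cms = []
        for moi in moi_r:
            cm, fl = corrected_mortality(float(moi), moc)
            cms.append(cm)
            all_flags.extend(fl)
        cm_mean[i] = float(np.mean(cms))
        moi_mean[i] = float(np.mean(moi_r))
    table = pd.DataFrame(
        {"dose": assay.doses, "moi_pct": moi_mean, "cm_pct": cm_mean}
    )
    table.attrs["flags"] = sorted(set(all_flags))

    logd = np.log(assay.doses)
    for i, cm in enumerate(cm_mean):
        if cm == 50.0:
            p = float(logd[i])
            return Ld50Result(math.exp(p), p, (float(assay.doses[i]),) * 2, table)
        if i and cm_mean[i - 1] < 50.0 < cm:
            x0, x1 = logd[i - 1], logd[i]
            y0, y1 = cm_mean[i - 1], cm
            p = float(x0 + (50.0 - y0) * (x1 - x0) / (y1 - y0))
            return Ld50Result(
                math.exp(p), p, (float(assay.doses[i - 1]), float(assay.doses[i])), table
            )
    raise AssayRangeError(
        "corrected mortality never crosses 50% within the dose range "
        f"(CM spans {cm_mean.min():.1f}-{cm_mean.max():.1f}%); not extrapolating"
    )


def pld50_from_simulation(spec, reps: int, seed: int | None = None) -> dict:
    """Distribution of pLD50 estimates over seeded simulated assays.

    Runs ``synthetic_data.simulate_bioassay`` ``reps`` times on substreams of
    ``seed`` (default: the spec's own seed) and summarises the estimates.
    """
    from . import synthetic_data

    if reps < 1:
        raise ValueError("reps must be >= 1")
    master = spec.seed if seed is None else seed
    estimates = np.empty(reps)
    for r in range(reps):
        sub = synthetic_data.replace_seed(spec, synthetic_data.derive_seed(master, f"assay-{r}"))
        estimates[r] = pld50(synthetic_data.simulate_bioassay(sub)).pld50
    return {
        "reps": reps,
        "mean_pld50": float(estimates.mean()),
        "sd_pld50": float(estimates.std(ddof=1)) if reps > 1 else 0.0,
        "se_pld50": float(estimates.std(ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0,
        "estimates": estimates,
    }
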