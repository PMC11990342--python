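"""Seeded generators emulating each wet-lab input of the pipeline.

Every generator is a pure function of its spec (including the seed): a
desorption mass-loss series following the first-term Fickian law with
optional noise, a quantal dose–mortality assay with a logistic tolerance
curve in ln(dose), 2^3 factorial responses from a stated coefficient vector
plus Gaussian noise, and species-by-sex mortality counts with binomial
deaths. Substreams derived from one master seed keep the stages independent
but jointly reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np

from .bioassay import DoseResponseAssay
from .factorial_doe import FactorialDesign, _model_row
from .association import ContingencyTable2x2
from .fick_release import DesorptionCurve, SlabFilm, mass_fraction

__all__ = [
    "DesorptionSimSpec",
    "BioassaySimSpec",
    "FactorialSimSpec",
    "ContingencySimSpec",
    "derive_seed",
    "replace_seed",
    "simulate_desorption",
    "simulate_bioassay",
    "simulate_factorial",
    "simulate_contingency",
]

logger = logging.getLogger(__name__)

#: Smallest retained fraction kept after noise clipping (fractions must stay
#: positive for the log-linear fit).
_FRACTION_FLOOR = 1e-12


def derive_seed(master: int, label: str) -> int:
    """Derive a per-stage substream seed (< 2^31) from a master seed."""
    return (zlib.crc32(f"{master}:{label}".encode()) ^ master) % (2**31 - 1)


def replace_seed(spec, seed: int):
    """Copy of a simulation spec with only the seed replaced."""
    return dataclasses.replace(spec, seed=seed)


@dataclass(frozen=True)
class DesorptionSimSpec:
    """Mass-loss series spec: true diffusivity, film thickness, time grid.

    ``noise`` is one of "none", "additive" or "multiplicative"; sigma is the
    Gaussian scale (absolute for additive, relative for multiplicative).
    Default noise reflects a gravimetric series whose relative error is
    roughly constant: multiplicative, sigma = 0.02.
    """

    D_true: float                     # mm^2 / day
    e: float = 0.12                   # mm
    times: tuple = tuple(np.linspace(50.0, 2000.0, 20))
    noise: str = "multiplicative"
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_true <= 0 or self.e <= 0:
            raise ValueError("D_true and e must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.noise not in ("none", "additive", "multiplicative"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing with >= 2 points")
        if t[0] < 0:
            raise ValueError("times must be non-negative")


@dataclass(frozen=True)
class BioassaySimSpec:
    """Quantal assay spec: logistic tolerance curve in ln(dose).

    Mortality probability at dose d is
    control + (1 - control) / (1 + exp(-slope (ln d - ln LD50_true)));
    slope = inf gives a step tolerance at LD50_true. Defaults mirror the
    bench protocol: 10 insects per dose, triplicate, zero-ish control
    mortality.
    """

    ld50_true: float = 1.0
    slope: float = 3.0
    doses: tuple = tuple(np.geomspace(0.1, 10.0, 7))
    n_per_dose: int = 10
    replicates: int = 3
    control_mortality: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ld50_true <= 0:
            raise ValueError("ld50_true must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive (use math.inf for a step)")
        d = np.asarray(self.doses, dtype=float)
        if np.any(d <= 0):
            raise ValueError("doses must be strictly positive")
        if self.n_per_dose < 1 or self.replicates < 1:
            raise ValueError("n_per_dose and replicates must be >= 1")
        if not 0 <= self.control_mortality <= 1:
            raise ValueError("control_mortality must be in [0, 1]")

    def mortality_probability(self, dose) -> np.ndarray:
        """True (uncorrected) mortality probability at each dose."""
        logd = np.log(np.asarray(dose, dtype=float))
        shift = logd - math.log(self.ld50_true)
        if math.isinf(self.slope):
            base = np.where(shift >= 0, 1.0, 0.0)
        else:
            base = 1.0 / (1.0 + np.exp(-self.slope * shift))
        return self.control_mortality + (1 - self.control_mortality) * base


@dataclass(frozen=True)
class FactorialSimSpec:
    """2^3 factorial responses from a stated 8-coefficient model + noise.

    ``coefficients`` are (mu0, muA, muB, muC, muAB, muAC, muBC, muABC).
    """

    coefficients: tuple
    sigma: float = 0.02
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.coefficients) != 8:
            raise ValueError("need exactly 8 coefficients (full third-order model)")
        if self.sigma < 0 or self.replicates < 1:
            raise ValueError("sigma must be >= 0 and replicates >= 1")


@dataclass(frozen=True)
class ContingencySimSpec:
    """Species-by-sex mortality counts.

    The sex split of each species' exposed cohort is deterministic
    (round(total * male_proportion), matching a designed 50/50 release);
    deaths within each sex are binomial with the stated probabilities.
    """

    exposed: tuple = (100, 100)
    male_proportion: tuple = (0.5, 0.5)
    mortality: tuple = ((0.5, 0.45), (0.5, 0.45))   # rows species, cols M/F
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.exposed) != 2 or len(self.male_proportion) != 2:
            raise ValueError("two species expected")
        if any(n < 1 for n in self.exposed):
            raise ValueError("exposed totals must be >= 1")
        probs = [p for row in self.mortality for p in row] + list(self.male_proportion)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("proportions/probabilities must be in [0, 1]")


def simulate_desorption(spec: DesorptionSimSpec) -> DesorptionCurve:
    """Generate a retained-fraction series from the first-term Fickian law.

    With ``noise="none"`` the curve satisfies the generating law exactly;
    noisy values are clipped back into (0, 1] and clip events are logged and
    counted in the curve metadata.
    """
    t = np.asarray(spec.times, dtype=float)
    film = SlabFilm(e=spec.e)
    f = mass_fraction(t, spec.D_true, film, mode="first-term")
    clipped = 0
    if spec.noise != "none" and spec.sigma > 0:
        rng = np.random.default_rng(spec.seed)
        eps = rng.normal(0.0, spec.sigma, size=f.shape)
        f = f + eps if spec.noise == "additive" else f * (1.0 + eps)
        out = np.clip(f, _FRACTION_FLOOR, 1.0)
        clipped = int(np.sum(out != f))
        if clipped:
            logger.info("desorption simulation clipped %d of %d points into (0, 1]",
                        clipped, f.size)
        f = out
    return DesorptionCurve(
        times=t,
        fractions=np.asarray(f),
        meta={
            "D_true": spec.D_true, "e": spec.e, "noise": spec.noise,
            "sigma": spec.sigma, "seed": spec.seed, "n_clipped": clipped,
        },
    )


def simulate_bioassay(spec: BioassaySimSpec) -> DoseResponseAssay:
    """Draw binomial dead counts for treated doses and untreated controls."""
    rng = np.random.default_rng(spec.seed)
    doses = np.sort(np.asarray(spec.doses, dtype=float))
    p = spec.mortality_probability(doses)
    exposed = np.full((doses.size, spec.replicates), spec.n_per_dose, dtype=int)
    dead = rng.binomial(spec.n_per_dose, p[:, None], size=exposed.shape)
    control_exposed = np.full(spec.replicates, spec.n_per_dose, dtype=int)
    control_dead = rng.binomial(spec.n_per_dose, spec.control_mortality,
                                size=spec.replicates)
    return DoseResponseAssay(
        doses=doses, exposed=exposed, dead=dead,
        control_exposed=control_exposed, control_dead=control_dead,
        meta={"ld50_true": spec.ld50_true, "slope": spec.slope, "seed": spec.seed},
    )


def simulate_factorial(spec: FactorialSimSpec, response: str = "response") -> FactorialDesign:
    """Generate coded 2^3 responses: model value + N(0, sigma^2) noise."""
    rng = np.random.default_rng(spec.seed)
    corners = [(a, b, c) for c in (-1, 1) for b in (-1, 1) for a in (-1, 1)]
    mu = np.asarray(spec.coefficients, dtype=float)
    rows = []
    for rep in range(spec.replicates):
        for a, b, c in corners:
            y = float(_model_row(a, b, c) @ mu) + rng.normal(0.0, spec.sigma)
            rows.append({"A": a, "B": b, "C": c, "replicate": rep, response: y})
    import pandas as pd

    return FactorialDesign(runs=pd.DataFrame(rows))


def simulate_contingency(spec: ContingencySimSpec) -> ContingencyTable2x2:
    """Draw the 2x2 species-by-sex table of mortality counts."""
    rng = np.random.default_rng(spec.seed)
    counts = np.zeros((2, 2), dtype=int)
    for s in range(2):
        n_male = int(round(spec.exposed[s] * spec.male_proportion[s]))
        n_female = spec.exposed[s] - n_male
        counts[s, 0] = rng.binomial(n_male, spec.mortality[s][0]) if n_male else 0
        counts[s, 1] = rng.binomial(n_female, spec.mortality[s][1]) if n_female else 0
    return ContingencyTable2x2(counts=counts)
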