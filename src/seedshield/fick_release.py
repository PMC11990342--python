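"""One-dimensional Fickian desorption from a thin slab film.

The active compound is initially distributed uniformly through a flat film of
thickness ``e`` and leaves through one face, where its concentration is held
at zero. Under Fick's second law with constant diffusivity ``D`` the retained
mass fraction decays as a sum of exponentials; once release is under way a
single first-order term dominates,

    Mt/M0 = exp(-D * pi^2 * t / e^2) = exp(-K * t),

so a straight-line fit of ln(Mt/M0) against time yields ``D`` from the slope,
the first-order release constant ``K = pi^2 D / e^2``, and the initial areal
flux ``F = (M0/S) * K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SlabFilm",
    "DesorptionCurve",
    "DiffusionFit",
    "FitError",
    "mass_fraction",
    "fit_diffusivity",
    "evaporation_constant",
    "initial_flux",
    "concentration_profile",
]

#: Default window (open interval bounds on the retained fraction) for the
#: log-linear slope fit: very early points carry series-truncation error,
#: very late points carry the largest relative measurement noise.
DEFAULT_WINDOW = (0.01, 0.99)


class FitError(ValueError):
    """Raised when a desorption curve cannot support a diffusivity fit."""


@dataclass(frozen=True)
class SlabFilm:
    """Geometry and loading of one biofilm sheet.

    Parameters
    ----------
    e
        Film thickness in mm.
    S
        Release surface area in cm^2 (needed only for flux).
    M0
        Initial mass of active compound in g (needed only for flux).
    C0
        Initial (uniform) concentration, arbitrary units.
    C_sat
        Saturation concentration of the surrounding medium; 0 for perfect
        sink conditions.
    """

    e: float
    S: float | None = None
    M0: float | None = None
    C0: float = 1.0
    C_sat: float = 0.0

    def __post_init__(self) -> None:
        if self.e <= 0:
            raise ValueError(f"film thickness must be positive, got e={self.e}")
        if self.S is not None and self.S <= 0:
            raise ValueError(f"surface area must be positive, got S={self.S}")
        if self.M0 is not None and self.M0 < 0:
            raise ValueError(f"initial mass must be non-negative, got M0={self.M0}")


@dataclass
class DesorptionCurve:
    """Retained mass fraction Mt/M0 sampled on a strictly increasing time grid.

    ``times`` are in days; ``fractions`` are dimensionless in (0, 1].
    ``meta`` records provenance (e.g. simulation parameters, clip counts).
    """

    times: np.ndarray
    fractions: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.fractions.shape:
            raise ValueError("times and fractions must be 1-D arrays of equal length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.fractions <= 0) or np.any(self.fractions > 1):
            raise ValueError("fractions must lie in (0, 1]")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class DiffusionFit:
    """Result of the log-linear diffusivity fit.

    ``K`` and ``F`` are recomputed from ``D`` (and the film), never stored
    independently, so the consistency K = pi^2 D / e^2 holds by construction.
    """

    D: float | None
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    window: tuple[float, float]
    film: SlabFilm
    flags: tuple[str, ...] = ()

    @property
    def success(self) -> bool:
        return self.D is not None

    @property
    def K(self) -> float | None:
        if self.D is None:
            return None
        return evaporation_constant(self.D, self.film.e)

    @property
    def F(self) -> float | None:
        if self.D is None or self.film.M0 is None or self.film.S is None:
            return None
        return initial_flux(self.K, self.film)

    def as_dict(self) -> dict:
        return {
            "D_mm2_per_day": self.D,
            "K_per_day": self.K,
            "F_g_per_day_per_cm2": self.F,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "window": list(self.window),
            "flags": list(self.flags),
        }


def _first_term_fraction(t: np.ndarray, D: float, e: float) -> np.ndarray:
    return np.exp(-D * math.pi**2 * t / e**2)


def mass_fraction(
    t,
    D: float,
    film: SlabFilm,
    mode: str = "first-term",
    n_terms: int = 200,
):
    """Retained mass fraction Mt/M0 at time ``t`` (days).

    Parameters
    ----------
    t
        Time in days, scalar or array, t >= 0.
    D
        Diffusivity in mm^2/day, > 0.
    film
        Film geometry (only the thickness is used).
    mode
        ``"first-term"`` -- the single-exponential law exp(-D pi^2 t / e^2).
        ``"series"`` -- partial sum over odd modes with decay exponents
        D (2m+1)^2 pi^2 t / e^2 and amplitudes 1/(2m+1)^2, scaled so the
        leading term coincides with the first-term law (hence the truncated
        sum slightly exceeds 1 at t=0 and converges onto the first-term law
        once release is under way).
        ``"textbook"`` -- the classical one-face-sealed slab solution,
        (8/pi^2) sum exp(-D (2m+1)^2 pi^2 t / (4 e^2)) / (2m+1)^2, provided
        for comparison only.
    n_terms
        Number of series terms (series/textbook modes), >= 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if D <= 0:
        raise ValueError(f"diffusivity must be positive, got D={D}")
    if mode == "first-term":
        out = _first_term_fraction(t, D, film.e)
        return out.item() if out.ndim == 0 else out
    if n_terms < 1:
        raise ValueError(f"n_terms must be >= 1, got {n_terms}")
    m = np.arange(n_terms)
    odd = 2 * m + 1
    if mode == "series":
        rates = D * odd**2 * math.pi**2 / film.e**2
        amps = 1.0 / odd**2
    elif mode == "textbook":
        rates = D * odd**2 * math.pi**2 / (4 * film.e**2)
        amps = (8 / math.pi**2) / odd**2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = np.einsum("m,...m->...", amps, np.exp(-np.multiply.outer(t, rates)))
    return out.item() if np.ndim(out) == 0 else out


def evaporation_constant(D: float, e: float) -> float:
    """First-order release (evaporation) constant K = pi^2 D / e^2, per day."""
    if D <= 0:
        raise ValueError(f"diffusivity must be positive, got D={D}")
    if e <= 0:
        raise ValueError(f"thickness must be positive, got e={e}")
    return math.pi**2 * D / e**2


def initial_flux(K: float, film: SlabFilm) -> float:
    """Initial desorption flux F = (M0/S) * K, in g/day/cm^2.

    This is |dM/dt| / S at t -> 0 under the first-term law M(t) = M0 exp(-Kt);
    the outgoing flux is reported positive.
    """
    if K <= 0:
        raise ValueError(f"release constant must be positive, got K={K}")
    if film.M0 is None or film.S is None:
        raise ValueError("film must define M0 and S to compute a flux")
    return film.M0 / film.S * K


def fit_diffusivity(
    curve: DesorptionCurve,
    film: SlabFilm,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> DiffusionFit:
    """Estimate D from the slope of ln(Mt/M0) against t.

    Points with fraction inside the open-below, closed-above window
    ``(window[0], window[1]]`` enter an ordinary least-squares line with free
    intercept; D = -slope * e^2 / pi^2. A non-negative slope is a flagged
    failure (``D is None``), never a silent negative diffusivity.
    """
    lo, hi = window
    mask = (curve.fractions > lo) & (curve.fractions <= hi)
    t = curve.times[mask]
    f = curve.fractions[mask]
    if t.size < 3:
        raise FitError(
            f"need >= 3 points inside window ({lo}, {hi}], got {t.size}; "
            "widen the window or sample more of the release"
        )
    logf = np.log(f)
    slope, intercept = np.polyfit(t, logf, 1)
    resid = logf - (slope * t + intercept)
    sst = np.sum((logf - logf.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0

    flags: list[str] = []
    if slope >= 0:
        # distinguish a genuinely flat series (slope is float noise on a
        # constant log-fraction) from one that actually rises
        flat = np.allclose(logf, logf[0], rtol=0, atol=1e-12)
        flags.append("no desorption detected" if flat else "rising curve")
        return DiffusionFit(
            D=None, slope=float(slope), intercept=float(intercept),
            r_squared=float(r2), n_points=int(t.size), window=(lo, hi),
            film=film, flags=tuple(flags),
        )
    D = -slope * film.e**2 / math.pi**2
    # exp(-Kt) > 0.5 marks the regime where the dropped higher series terms
    # are largest relative to the first.
    if np.any(np.exp(slope * t) > 0.5):
        flags.append("first-term-regime includes early points (fraction > 0.5)")
    return DiffusionFit(
        D=float(D), slope=float(slope), intercept=float(intercept),
        r_squared=float(r2), n_points=int(t.size), window=(lo, hi),
        film=film, flags=tuple(flags),
    )


def concentration_profile(
    y,
    t: float,
    D: float,
    film: SlabFilm,
    n_terms: int = 200,
):
    """Concentration C(y, t) across the film by separation of variables.

    The uniform initial condition C(y,0) = C0 is expanded over the odd sine
    modes sin((2m+1) pi y / e) (Fourier coefficients 4/((2m+1) pi)), each
    decaying as exp(-D (2m+1)^2 pi^2 t / e^2), so the desorbing face y = e
    satisfies C(e, t) = 0 for all t. The amplitude is scaled by (C0 - C_sat).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > film.e):
        raise ValueError(f"position must lie within [0, {film.e}] mm")
    if t < 0:
        raise ValueError("time must be non-negative")
    if n_terms < 1:
        raise ValueError(f"n_terms must be >= 1, got {n_terms}")
    m = np.arange(n_terms)
    odd = 2 * m + 1
    coeff = 4.0 / (odd * math.pi) * np.exp(-D * odd**2 * math.pi**2 * t / film.e**2)
    modes = np.sin(np.multiply.outer(y, odd * math.pi / film.e))
    out = (film.C0 - film.C_sat) * np.einsum("m,...m->...", coeff, modes)
    return out.item() if np.ndim(out) == 0 else out
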