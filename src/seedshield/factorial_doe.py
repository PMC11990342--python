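"""Two-level full-factorial (2^3) formulation model.

The response (here pLD50 of a formulation) is modelled as

    y = mu0 + sum_i mu_i X_i + sum_{i<j} mu_ij X_i X_j + mu_ABC X_A X_B X_C

on coded factor levels X in {-1, +1}. On the orthogonal 2^3 design each
coefficient is half the difference of response means between the +1 and -1
levels of its contrast column — identical to the least-squares solution —
and with 8 runs and a single replicate the 8-term model is saturated
(zero residual degrees of freedom), so error-based diagnostics are reported
as explicit "undefined" flags rather than numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "FACTORS",
    "TERMS",
    "FactorialDesign",
    "FactorialFit",
    "fit",
    "summary_stats",
    "predict",
    "contour_grid",
]

FACTORS = ("A", "B", "C")
TERMS = ("I", "A", "B", "C", "AB", "AC", "BC", "ABC")

#: Decoding of coded levels to physical concentrations (% w/v).
DEFAULT_DECODING = {
    "A": {-1: 1.0, 1: 2.0},    # collagen
    "B": {-1: 1.0, 1: 2.0},    # chitosan
    "C": {-1: 0.1, 1: 0.5},    # calothrixin A
}


def _model_row(a: float, b: float, c: float) -> np.ndarray:
    return np.array([1.0, a, b, c, a * b, a * c, b * c, a * b * c])


@dataclass
class FactorialDesign:
    """Coded 2^3 design with one or more response columns.

    ``runs`` is a DataFrame with columns A, B, C in {-1, +1} plus responses;
    an optional ``replicate`` column marks repeated measurements of the same
    corner. The full design (every +/-1 combination exactly once per
    replicate) is validated on construction.
    """

    runs: pd.DataFrame
    decoding: dict = field(default_factory=lambda: dict(DEFAULT_DECODING))

    def __post_init__(self) -> None:
        missing = [f for f in FACTORS if f not in self.runs.columns]
        if missing:
            raise ValueError(f"design is missing factor columns {missing}")
        coded = self.runs[list(FACTORS)].to_numpy(dtype=float)
        if not np.all(np.isin(coded, (-1.0, 1.0))):
            raise ValueError("factor levels must be coded -1/+1")
        corners = {tuple(int(v) for v in row) for row in coded}
        expected = {(a, b, c) for a in (-1, 1) for b in (-1, 1) for c in (-1, 1)}
        if corners != expected:
            absent = sorted(expected - corners)
            raise ValueError(f"not a full 2^3 design; missing runs at {absent}")
        counts = self.runs.groupby(list(FACTORS)).size()
        if counts.nunique() != 1:
            raise ValueError("unbalanced design: unequal replication across corners")

    @property
    def n_replicates(self) -> int:
        return len(self.runs) // 8

    @property
    def response_columns(self) -> list[str]:
        drop = set(FACTORS) | {"replicate", "run_id", "biofilm"}
        return [c for c in self.runs.columns if c not in drop]

    def model_matrix(self) -> np.ndarray:
        coded = self.runs[list(FACTORS)].to_numpy(dtype=float)
        return np.stack([_model_row(*row) for row in coded])

    def decode(self, factor: str, coded_level: float) -> float:
        """Physical concentration (% w/v) for a coded level of one factor."""
        return float(np.interp(coded_level, [-1, 1],
                               [self.decoding[factor][-1], self.decoding[factor][1]]))


@dataclass
class FactorialFit:
    """Least-squares fit of the full 8-term model to one response."""

    design: FactorialDesign
    response: str
    coefficients: dict  # term -> float, full precision
    fitted: np.ndarray
    residuals: np.ndarray
    y: np.ndarray

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in TERMS])

    def rounded_coefficients(self, ndigits: int = 2) -> dict:
        """Coefficients rounded half-away-from-zero, for table display."""
        q = Decimal(1).scaleb(-ndigits)
        return {
            t: float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))
            for t, v in self.coefficients.items()
        }

    @property
    def residual_df(self) -> int:
        return self.y.size - len(TERMS)


def fit(design: FactorialDesign, response: str) -> FactorialFit:
    """Estimate all 8 model coefficients by orthogonal contrasts.

    Each coefficient is X_col . y / n on the orthogonal model matrix, which
    equals the ordinary least-squares solution; replicated designs simply
    average over replicates.
    """
    if response not in design.runs.columns:
        raise KeyError(f"response column {response!r} not in design")
    X = design.model_matrix()
    y = design.runs[response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"response {response!r} contains non-finite values")
    beta = X.T @ y / len(y)  # orthogonality: X'X = n I
    fitted = X @ beta
    return FactorialFit(
        design=design,
        response=response,
        coefficients=dict(zip(TERMS, map(float, beta))),
        fitted=fitted,
        residuals=y - fitted,
        y=y,
    )


def predict(fit_: FactorialFit, point) -> float:
    """Evaluate the fitted polynomial at a coded point (A, B, C) in [-1,1]^3.

    Points outside the coded cube raise an extrapolation warning but are
    still evaluated.
    """
    a, b, c = (float(v) for v in point)
    if max(abs(a), abs(b), abs(c)) > 1:
        warnings.warn(
            f"coded point ({a}, {b}, {c}) lies outside [-1, 1]^3; extrapolating",
            stacklevel=2,
        )
    return float(_model_row(a, b, c) @ fit_.coef_vector)


def summary_stats(fit_: FactorialFit) -> dict:
    """Model summary in the style of factorial-design software output.

    mean: response mean. sd: root mean square error of the model. cv_pct:
    100*sd/mean. r_squared: 1 - SSE/SST; adjusted and predicted (PRESS,
    leave-one-out) variants; adequate_precision: predicted-response range
    over its average standard error. With zero residual degrees of freedom
    (saturated model) the error-based entries carry the flag string
    "undefined (saturated model)" instead of a number.
    """
    y, yhat = fit_.y, fit_.fitted
    n, p = y.size, len(TERMS)
    dfe = n - p
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    out: dict = {"mean": float(y.mean()), "n": n, "residual_df": dfe}
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    out["r_squared"] = r2

    undefined = "undefined (saturated model)"
    if dfe > 0:
        mse = sse / dfe
        sd = float(np.sqrt(mse))
        out["sd"] = sd
        out["cv_pct"] = 100.0 * sd / out["mean"]
        out["adj_r_squared"] = 1.0 - (sse / dfe) / (sst / (n - 1))
        ssr = float(np.sum((yhat - y.mean()) ** 2))
        f_stat = (ssr / (p - 1)) / mse if mse > 0 else np.inf
        out["f_value"] = f_stat
        from scipy import stats

        out["p_value"] = float(stats.f.sf(f_stat, p - 1, dfe)) if np.isfinite(f_stat) else 0.0
        out["adequate_precision"] = float(
            (yhat.max() - yhat.min()) / np.sqrt(p * mse / n)
        ) if mse > 0 else np.inf
    else:
        for key in ("sd", "cv_pct", "adj_r_squared", "f_value", "p_value",
                    "adequate_precision"):
            out[key] = undefined

    # PRESS by explicit leave-one-out refits; only defined when every
    # left-out point is still predictable (all leverages < 1).
    X = fit_.design.model_matrix()
    H_diag = np.einsum("ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X)
    if np.any(H_diag >= 1 - 1e-10):
        out["pred_r_squared"] = undefined
    else:
        press = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            beta_i, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            press += (y[i] - X[i] @ beta_i) ** 2
        out["press"] = float(press)
        out["pred_r_squared"] = 1.0 - press / sst if sst > 0 else 1.0
    return out


def contour_grid(
    fit_: FactorialFit,
    pair: tuple[str, str] = ("A", "C"),
    fixed_level: float = -1.0,
    resolution: int = 21,
) -> pd.DataFrame:
    """Predicted-response grid over the coded square of one factor pair.

    Returns a long-format DataFrame (x, y, response) with the remaining
    factor held at ``fixed_level``. Used to tabulate the contour maps of the
    formulation response surface.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    fx, fy = pair
    if fx not in FACTORS or fy not in FACTORS or fx == fy:
        raise ValueError(f"pair must be two distinct factors among {FACTORS}, got {pair}")
    (other,) = set(FACTORS) - {fx, fy}
    grid = np.linspace(-1.0, 1.0, resolution)
    rows = []
    for gy in grid:
        for gx in grid:
            point = {fx: gx, fy: gy, other: fixed_level}
            rows.append((gx, gy, predict(fit_, (point["A"], point["B"], point["C"]))))
    df = pd.DataFrame(rows, columns=[fx, fy, fit_.response])
    df.attrs["fixed"] = {other: fixed_level}
    return df
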