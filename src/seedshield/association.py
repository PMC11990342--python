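"""Association analyses linking desorption kinetics to insecticidal activity.

Three views of association are provided: the Pearson correlation matrix of
the per-biofilm variables (D, K, F, pLD50 per species), a principal-component
analysis of the same correlation matrix, and a battery of contingency-table
coefficients (chi-square with and without Yates continuity correction, Phi,
contingency coefficient, Cramer's V, Tschuprow's T, Goodman-Kruskal lambda,
Cohen's kappa, Yule's Q and Y) for the species-by-sex mortality table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VARIABLES",
    "ContingencyTable2x2",
    "AssociationBundle",
    "PCAResult",
    "variable_matrix",
    "correlation_matrix",
    "pca",
    "chi2_independence",
    "association_coefficients",
]

VARIABLES = ("D", "K", "F", "pLD50_SL", "pLD50_BP")


@dataclass
class ContingencyTable2x2:
    """2x2 mortality counts, rows = species, columns = sex (Male, Female)."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("Sitona lineatus", "Bruchus pisorum")
    col_labels: tuple[str, str] = ("Male", "Female")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2):
            raise ValueError(f"expected a 2x2 table, got shape {self.counts.shape}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(int)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("table is empty (grand total 0)")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray           # descending
    loadings: pd.DataFrame            # variables x components
    scores: pd.DataFrame              # observations x components
    explained_variance_ratio: np.ndarray


@dataclass(frozen=True)
class AssociationBundle:
    """Full coefficient battery for one 2x2 table, at full precision.

    ``goodman_kruskal_lambda`` is the asymmetric lambda predicting the column
    variable (sex) from the row variable (species); both asymmetric variants
    and the symmetric one are also exposed. ``rounded()`` gives the 3-decimal
    display form.
    """

    chi2: float
    p_value: float
    chi2_yates: float
    p_value_yates: float
    df: int
    phi: float
    contingency_coefficient: float
    cramers_v: float
    tschuprow_t: float
    goodman_kruskal_lambda: float
    lambda_col_given_row: float
    lambda_row_given_col: float
    lambda_symmetric: float
    cohen_kappa: float
    yule_q: float | None
    yule_y: float | None
    flags: tuple[str, ...] = ()

    def rounded(self, ndigits: int = 3) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = round(v, ndigits) if isinstance(v, float) else v
        return out


def variable_matrix(fixtures) -> pd.DataFrame:
    """Assemble the per-biofilm variable matrix (D, K, F, pLD50_SL, pLD50_BP).

    Joins the desorption parameters and factorial responses of a
    ``StudyFixtures`` bundle on the biofilm identifier; kinetic quantities
    stay in base units (mm^2/day, 1/day, g/day/cm^2).
    """
    t4 = fixtures.table4.set_index("biofilm")
    t1 = fixtures.table1.set_index("biofilm")
    df = pd.DataFrame(
        {
            "D": t4["D"],
            "K": t4["K"],
            "F": t4["F"],
            "pLD50_SL": t1["pLD50_SL"],
            "pLD50_BP": t1["pLD50_BP"],
        }
    )
    if df.isna().any().any():
        raise ValueError("biofilm identifiers of the two tables do not align")
    return df


def _validate_matrix(data: pd.DataFrame) -> np.ndarray:
    X = data.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError(f"need >= 3 observations, got {X.shape[0]}")
    sd = X.std(axis=0, ddof=1)
    zero = [c for c, s in zip(data.columns, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance variable(s): {zero}")
    return X


def correlation_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Pearson product-moment correlation matrix (symmetric, unit diagonal)."""
    _validate_matrix(data)
    r = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    # enforce exact symmetry / unit diagonal against rounding drift
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=data.columns, columns=data.columns)


def pca(data: pd.DataFrame) -> PCAResult:
    """PCA as eigendecomposition of the Pearson correlation matrix.

    Variables are standardised with the sample (n-1) convention; eigenvalues
    are returned descending (their sum equals the number of variables) and
    each loading vector is oriented so its largest-magnitude entry is
    positive. Scores are the standardised data projected on the loadings.
    """
    X = _validate_matrix(data)
    R = correlation_matrix(data).to_numpy()
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    comps = [f"PC{i+1}" for i in range(len(eigval))]
    return PCAResult(
        eigenvalues=eigval,
        loadings=pd.DataFrame(eigvec, index=data.columns, columns=comps),
        scores=pd.DataFrame(Z @ eigvec, index=data.index, columns=comps),
        explained_variance_ratio=eigval / eigval.sum(),
    )


def chi2_independence(table: ContingencyTable2x2, yates: bool = False):
    """Pearson chi-square test of independence on a 2x2 table.

    Expected counts are row_total * col_total / N. The Yates variant squares
    max(|O - E| - 0.5, 0) in place of (O - E). Returns (chi2, df, p).
    """
    O = table.counts.astype(float)
    rows = O.sum(axis=1)
    cols = O.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal total; chi-square undefined")
    E = np.outer(rows, cols) / table.n
    dev = np.abs(O - E)
    if yates:
        dev = np.clip(dev - 0.5, 0.0, None)
    chi2 = float(np.sum(dev**2 / E))
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _lambda_given(counts: np.ndarray, axis: int) -> float:
    # lambda predicting the variable along `axis` from the other variable
    n = counts.sum()
    within = counts.max(axis=axis).sum()
    marginal = counts.sum(axis=1 - axis).max()
    if n == marginal:
        return 0.0
    return float((within - marginal) / (n - marginal))


def association_coefficients(table: ContingencyTable2x2) -> AssociationBundle:
    """Compute the full association-coefficient battery for a 2x2 table."""
    O = table.counts.astype(float)
    n = table.n
    r, c = O.shape
    chi2, df, p = chi2_independence(table, yates=False)
    chi2_y, _, p_y = chi2_independence(table, yates=True)

    phi = math.sqrt(chi2 / n)
    C = math.sqrt(chi2 / (chi2 + n))
    v = math.sqrt(chi2 / (n * (min(r, c) - 1)))
    t = math.sqrt(chi2 / (n * math.sqrt((r - 1) * (c - 1))))

    lam_col = _lambda_given(O, axis=1)
    lam_row = _lambda_given(O, axis=0)
    num = (O.max(axis=1).sum() - O.sum(axis=0).max()) + (O.max(axis=0).sum() - O.sum(axis=1).max())
    den = (n - O.sum(axis=0).max()) + (n - O.sum(axis=1).max())
    lam_sym = float(num / den) if den else 0.0

    # kappa treats the square table as an agreement table (descriptive only)
    p_o = np.trace(O) / n
    p_e = float(np.sum(O.sum(axis=1) * O.sum(axis=0)) / n**2)
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else 0.0

    a, b = O[0]
    cc, d = O[1]
    flags: list[str] = []
    if a * d + b * cc == 0:
        q = y = None
        flags.append("yule-undefined (ad + bc = 0)")
    else:
        q = float((a * d - b * cc) / (a * d + b * cc))
        y = float(
            (math.sqrt(a * d) - math.sqrt(b * cc)) / (math.sqrt(a * d) + math.sqrt(b * cc))
        )

    return AssociationBundle(
        chi2=chi2, p_value=p, chi2_yates=chi2_y, p_value_yates=p_y, df=df,
        phi=phi, contingency_coefficient=C, cramers_v=v, tschuprow_t=t,
        goodman_kruskal_lambda=lam_col,
        lambda_col_given_row=lam_col, lambda_row_given_col=lam_row,
        lambda_symmetric=lam_sym,
        cohen_kappa=float(kappa), yule_q=q, yule_y=y, flags=tuple(flags),
    )
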