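"""Craniometric morphospace: correlation-matrix PCA with adequacy tests.

Principal components analysis of a measurements table is computed on the
Pearson correlation matrix, so every variable enters standardized and
the eigenvalues sum to the number of variables p.  Sampling adequacy is
summarized by the Kaiser-Meyer-Olkin index (from anti-image partial
correlations; values of 0.7-0.8 are conventionally acceptable) and by
Bartlett's test of sphericity,

    chi2 = -(n - 1 - (2p + 5)/6) * ln det R,   df = p(p - 1)/2,

which rejects when the correlation matrix is distinguishable from the
identity.  Coefficients of variation (100 * SD/mean) and per-group
confidence ellipses on PC score planes support the descriptive side of
the analysis.

Missing data are handled by complete-case deletion by default, with
per-variable mean imputation as the alternative policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CRANIO_VARIABLES",
    "PCAResult",
    "AdequacyStats",
    "GroupEllipse",
    "correlation_pca",
    "bartlett_sphericity",
    "kmo",
    "adequacy",
    "coefficient_of_variation",
    "group_ellipses",
    "cumulative_variance_pct",
]

#: Default craniometric variable set (23 vault and browridge measurements):
#: chords between standard landmarks, vault-thickness sites, and the
#: supraorbital torus dimensions.
CRANIO_VARIABLES = (
    "g-op",                 # maximum cranial length
    "eu-eu",                # maximum cranial breadth
    "ft-ft",                # minimum frontal breadth
    "co-co",                # maximum frontal breadth
    "torus_breadth",        # supraorbital torus breadth
    "po-br",                # porion-bregma height
    "fmt-fmt",              # bifrontomalare temporale breadth
    "postorbital_breadth",
    "ast-ast",              # biasterionic breadth
    "lambda-inion",
    "lambda-asterion",
    "inion-asterion",
    "thickness_lambda",
    "thickness_inion",
    "thickness_int_occ_protuberance",
    "thickness_asterion",
    "thickness_bregma",
    "sottm",                # supraorbital torus thickness at midorbit
    "torus_highest_point",
    "parietal_bregma",
    "parietal_lambda",
    "parietal_eminence",
    "parietal_asterion",
)

_P_FLOOR = 1e-300  # reporting floor for p-values


@dataclass
class PCAResult:
    """Correlation-matrix PCA output.

    Loadings are unit eigenvectors (variables x components), scores the
    standardized data projected on them, variance percentages 100*lambda/p.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_pct: np.ndarray
    cum_variance_pct: np.ndarray
    groups: pd.Series | None = None


@dataclass
class AdequacyStats:
    """KMO sampling adequacy and Bartlett sphericity results."""

    kmo_overall: float
    kmo_per_variable: pd.Series
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


@dataclass
class GroupEllipse:
    """Confidence ellipse of one group on a 2-D score plane."""

    group: str
    center: np.ndarray
    axes: np.ndarray          # columns = unit principal directions
    radii: np.ndarray         # chi-square-scaled semi-axis lengths
    degenerate: bool


def _numeric_matrix(
    table: pd.DataFrame, group_col: str | None, missing: str
) -> tuple[pd.DataFrame, pd.Series | None]:
    if group_col is not None and group_col in table.columns:
        groups = table[group_col]
        data = table.drop(columns=[group_col])
    else:
        groups = None
        data = table
    data = data.apply(pd.to_numeric)
    if missing == "complete-case":
        data = data.dropna(axis=0, how="any")
    elif missing == "mean-impute":
        data = data.fillna(data.mean())
    else:
        raise ValueError(
            f"missing policy must be 'complete-case' or 'mean-impute', got {missing!r}"
        )
    if groups is not None:
        groups = groups.loc[data.index]
    return data, groups


def _correlation(data: pd.DataFrame) -> np.ndarray:
    sd = data.std(ddof=1)
    constant = sd[~(sd > 0)].index.tolist()
    if constant:
        raise ValueError(f"constant variable(s): {constant}")
    return np.corrcoef(data.to_numpy(dtype=float), rowvar=False)


def correlation_pca(
    table: pd.DataFrame,
    group_col: str | None = "group",
    missing: str = "complete-case",
) -> PCAResult:
    """PCA on the correlation matrix of a measurements table.

    Components are ordered by decreasing eigenvalue; each component's
    sign is fixed so that its largest-magnitude loading is positive.
    Scores are the z-standardized data times the eigenvectors.
    """
    data, groups = _numeric_matrix(table, group_col, missing)
    n, p = data.shape
    if n < 3:
        raise ValueError(f"need at least 3 complete individuals, have {n}")
    R = _correlation(data)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    for j in range(p):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    X = data.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    comp_names = [f"PC{j + 1}" for j in range(p)]
    variance = 100.0 * eigval / p
    return PCAResult(
        eigenvalues=eigval,
        loadings=pd.DataFrame(eigvec, index=data.columns, columns=comp_names),
        scores=pd.DataFrame(Z @ eigvec, index=data.index, columns=comp_names),
        variance_pct=variance,
        cum_variance_pct=np.cumsum(variance),
        groups=groups,
    )


def cumulative_variance_pct(eigenvalues, p: int, n_components: int | None = None):
    """Percent of total variance carried by the leading components.

    For correlation-matrix PCA the total variance equals the number of
    variables p, so the cumulative share of the first k components is
    100 * sum(lambda_1..lambda_k) / p.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if n_components is not None:
        ev = ev[:n_components]
    return float(100.0 * ev.sum() / p)


def bartlett_sphericity(
    table: pd.DataFrame,
    group_col: str | None = "group",
    missing: str = "complete-case",
) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    Returns (chi2, df, p) with chi2 = -(n-1-(2p+5)/6) ln det R and
    df = p(p-1)/2.
    """
    data, _ = _numeric_matrix(table, group_col, missing)
    n, p = data.shape
    R = _correlation(data)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular correlation matrix")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = max(float(stats.chi2.sf(chi2, df)), _P_FLOOR)
    return float(chi2), int(df), pval


def kmo(
    table: pd.DataFrame,
    group_col: str | None = "group",
    missing: str = "complete-case",
) -> tuple[float, pd.Series]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Anti-image partial correlations q_ij are read off the inverse
    correlation matrix; KMO = sum r^2 / (sum r^2 + sum q^2) over
    off-diagonal elements, overall and per variable.
    """
    data, _ = _numeric_matrix(table, group_col, missing)
    R = _correlation(data)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        raise ValueError("singular correlation matrix") from None
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    Q = -Rinv / d  # partial correlations, up to the diagonal
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = R**2
    q2 = Q**2
    overall = float(r2[off].sum() / (r2[off].sum() + q2[off].sum()))
    per_num = (r2 * off).sum(axis=1)
    per_den = per_num + (q2 * off).sum(axis=1)
    per_variable = pd.Series(per_num / per_den, index=data.columns, name="kmo")
    return overall, per_variable


def adequacy(
    table: pd.DataFrame,
    group_col: str | None = "group",
    missing: str = "complete-case",
) -> AdequacyStats:
    """KMO and Bartlett sphericity in one sweep."""
    overall, per_var = kmo(table, group_col, missing)
    chi2, df, p = bartlett_sphericity(table, group_col, missing)
    return AdequacyStats(
        kmo_overall=overall,
        kmo_per_variable=per_var,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=p,
    )


def coefficient_of_variation(table: pd.DataFrame, variable: str) -> float:
    """Coefficient of variation, 100 * sample SD (n-1 denominator) / mean."""
    x = pd.to_numeric(table[variable]).dropna()
    if len(x) < 2:
        raise ValueError(f"need at least 2 observations of {variable!r}")
    mean = x.mean()
    if mean == 0:
        raise ValueError(f"mean of {variable!r} is zero; CV undefined")
    return float(100.0 * x.std(ddof=1) / mean)


def group_ellipses(
    scores: pd.DataFrame,
    groups: pd.Series,
    components: tuple[str, str] = ("PC1", "PC2"),
    confidence: float = 0.95,
) -> dict[str, GroupEllipse]:
    """Per-group confidence ellipses on a 2-D plane of PC scores.

    Semi-axes are the covariance eigenvectors scaled by
    sqrt(lambda * chi2_2(confidence)).  Groups with fewer than 3 members
    are skipped with a warning; collinear groups are flagged degenerate.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    scale = stats.chi2.ppf(confidence, df=2)
    out: dict[str, GroupEllipse] = {}
    for gname, idx in scores.groupby(groups).groups.items():
        pts = scores.loc[idx, list(components)].to_numpy(dtype=float)
        if len(pts) < 3:
            warnings.warn(
                f"group {gname!r} has fewer than 3 members; ellipse skipped",
                stacklevel=2,
            )
            continue
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        eigval, eigvec = np.linalg.eigh(cov)
        eigval = eigval[::-1]
        eigvec = eigvec[:, ::-1]
        degenerate = bool(eigval[-1] <= 1e-12 * max(eigval[0], 1.0))
        out[str(gname)] = GroupEllipse(
            group=str(gname),
            center=center,
            axes=eigvec,
            radii=np.sqrt(np.clip(eigval, 0.0, None) * scale),
            degenerate=degenerate,
        )
    return out
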