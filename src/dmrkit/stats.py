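"""Region-level methylation statistics: centering, PCA, covariate screens."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


def center_by_region(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract each region's mean across samples (missing values are
    imputed to the region mean, i.e. 0 after centering)."""
    row_mean = table.mean(axis=1, skipna=True)
    centered = table.sub(row_mean, axis=0)
    return centered.fillna(0.0)


def principal_components(
    centered_table: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Sample scores from an SVD of the sample x region centered matrix.

    Returns ``(scores, variance_explained, loadings)``; the scores frame
    is samples x components. Each component is oriented so that its
    largest-magnitude region loading is positive, which fixes the sign
    ambiguity of the decomposition.
    """
    if centered_table.shape[1] < 2 or centered_table.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 regions")
    X = centered_table.to_numpy(float).T  # samples x regions
    X = X - X.mean(axis=0, keepdims=True)  # column-center over samples for PCA proper
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = n_components or min(X.shape)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for comp in range(len(S)):
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    scores = U * S
    total_var = (X**2).sum()
    var_explained = (S**2) / total_var if total_var > 0 else np.zeros_like(S)
    frame = pd.DataFrame(
        scores,
        index=centered_table.columns,
        columns=[f"PC{i + 1}" for i in range(len(S))],
    )
    return frame, var_explained, Vt


def _single_association(values: np.ndarray, covariate: pd.Series):
    """(statistic, p) for one response vector against one covariate."""
    ok = ~(np.isnan(values) | covariate.isna().to_numpy())
    y = values[ok]
    x = covariate[ok]
    if len(y) < 3:
        return np.nan, np.nan
    if pd.api.types.is_numeric_dtype(x):
        xv = x.to_numpy(float)
        if np.allclose(xv, xv[0]):
            return np.nan, np.nan
        res = sps.linregress(xv, y)
        return res.slope, res.pvalue
    groups = [y[(x == level).to_numpy()] for level in pd.unique(x)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2 or all(len(g) < 2 for g in groups):
        return np.nan, np.nan
    stat, p = sps.f_oneway(*groups)
    return stat, p


def covariate_association(
    table_or_pcs: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    covariates: list[str],
    correction: str = "bonferroni",
    min_present: float = 0.8,
) -> pd.DataFrame:
    """Screen each region (or PC) against each covariate.

    Continuous/ordinal covariates use a simple linear-regression slope
    test; categorical covariates a one-way ANOVA. The Bonferroni
    adjustment multiplies each p by the number of regions tested for that
    covariate (capped at 1). Covariates observed in fewer than
    ``min_present`` of the samples are skipped with a warning; constant
    covariates yield NA.

    ``table_or_pcs`` is regions x samples (or a samples x PCs frame, which
    is transposed automatically when its columns look like PCs).
    """
    table = table_or_pcs
    if all(str(c).startswith("PC") for c in table.columns) and len(table.columns):
        table = table.T  # samples x PCs supplied
    sheet = sample_sheet.set_index("sample").loc[list(table.columns)]
    rows = []
    for cov in covariates:
        if cov not in sheet.columns:
            logger.warning("covariate %r not in sample sheet; skipped", cov)
            continue
        col = sheet[cov]
        if col.notna().mean() < min_present:
            logger.warning("covariate %r present in < %.0f%% of samples; skipped", cov, 100 * min_present)
            continue
        m = len(table)
        for region, values in table.iterrows():
            stat, p = _single_association(values.to_numpy(float), col)
            if np.isnan(p):
                logger.warning("covariate %r vs %r: not testable (constant?)", cov, region)
            p_adj = min(1.0, p * m) if correction == "bonferroni" and not np.isnan(p) else p
            rows.append(
                {"feature": region, "covariate": cov, "statistic": stat, "p": p, "p_adj": p_adj}
            )
    return pd.DataFrame(rows, columns=["feature", "covariate", "statistic", "p", "p_adj"])
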