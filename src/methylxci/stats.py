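"""Statistical machinery: scaled PCA, PC-PR2, per-CpG models, rank tests.

All multi-test families use Benjamini-Hochberg FDR adjustment; family
membership is whatever a single function call computes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "PCPR2Result",
    "pca_scaled",
    "pc_association",
    "pcpr2",
    "cpg_linear_model",
    "group_compare",
    "bh_fdr",
    "wilcoxon_rank_sum",
    "significance_stars",
]

FDR_ALPHA = 0.05
CONDITION_NUMBER_LIMIT = 1e8


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when both groups have <= 12
    observations and there are no ties across groups; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(x) <= 12 and len(y) <= 12 and not has_ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def significance_stars(fdr: float) -> str:
    """Map an FDR value to the conventional star annotation."""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if fdr < threshold:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Principal components of a CpG-scaled beta matrix.

    ``scores`` are samples x components, ``loadings`` CpGs x components
    (orthonormal), ``variance_fraction`` per-component fractions of the
    total variance, and ``standardized_scores`` the scores scaled to
    unit variance per component for cross-dataset comparability. Sign
    convention: the largest-magnitude loading of each component is
    positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    standardized_scores: pd.DataFrame
    n_zero_variance_dropped: int = 0
    n_imputed: int = 0


def _scale_rows(beta: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Impute missing values by the CpG mean, then centre and scale rows."""
    vals = beta.to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        row_means = np.nanmean(vals, axis=1, keepdims=True)
        vals = np.where(np.isnan(vals), row_means, vals)
        logger.info("pca: imputed %d missing values by CpG mean", n_missing)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("pca: dropped %d zero-variance CpGs", n_dropped)
    vals = vals[keep]
    scaled = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(scaled, index=beta.index[keep], columns=beta.columns), n_dropped, n_missing


def pca_scaled(beta: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA on centred-and-scaled beta values (samples as observations).

    Each CpG row is centred and scaled to unit variance first (missing
    values imputed by the CpG mean; zero-variance CpGs dropped with a
    count). Decomposition is a dense SVD, so results are reproducible
    given fixed input; components requested beyond the data rank are
    truncated.
    """
    if beta.shape[1] < 2:
        raise ValueError("PCA requires >= 2 samples")
    scaled, n_dropped, n_imputed = _scale_rows(beta)
    X = scaled.to_numpy().T  # samples x CpGs; columns already centred
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # rank truncation: drop numerically-zero singular values
    tol = S[0] * max(X.shape) * np.finfo(float).eps if len(S) else 0.0
    rank = int((S > tol).sum())
    k = rank if n_components is None else min(n_components, rank)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]

    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0

    scores = U * S
    var = S**2
    total_var = (X**2).sum()
    cols = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=beta.columns, columns=cols)
    loadings_df = pd.DataFrame(Vt.T, index=scaled.index, columns=cols)
    std_scores = scores_df / scores_df.std(axis=0, ddof=1)
    return PCAResult(
        scores=scores_df,
        loadings=loadings_df,
        variance_fraction=var / total_var,
        standardized_scores=std_scores,
        n_zero_variance_dropped=n_dropped,
        n_imputed=n_imputed,
    )


# ---------------------------------------------------------------------------
# PC ~ covariate association


def _design_columns(samples: pd.DataFrame, variable: str) -> pd.DataFrame | None:
    """Expand one covariate to design columns; None when constant."""
    col = samples[variable]
    if col.dtype.kind in "biufc":
        if col.nunique(dropna=True) < 2:
            return None
        return pd.DataFrame({variable: col.astype(float)})
    levels = col.astype(str)
    if levels.nunique() < 2:
        return None
    return pd.get_dummies(levels, prefix=variable, drop_first=True, dtype=float)


def _ols_r2_p(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """R-squared and F-test p for y ~ [1, X] (complete cases assumed)."""
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0, 1.0
    r2 = 1.0 - rss / tss
    df_model, df_resid = p, n - p - 1
    if df_resid <= 0 or rss <= 0:
        return r2, 0.0 if r2 > 0.999999 else 1.0
    f = (r2 / df_model) / ((1 - r2) / df_resid) if r2 < 1 else np.inf
    return r2, float(sps.f.sf(f, df_model, df_resid))


def pc_association(
    pca: PCAResult,
    samples: pd.DataFrame,
    variables: list[str],
    n_components: int = 10,
) -> pd.DataFrame:
    """Associate each PC with each sample variable by a simple linear model.

    Per (PC, variable) pair a model ``PC ~ variable`` is fit (categorical
    variables one-hot encoded with k-1 indicators, R-squared is the
    model R-squared); BH FDR is applied across the full PC x variable
    family; significance at FDR < 0.05. Constant variables are skipped
    with a log note.
    """
    missing = [v for v in variables if v not in samples.columns]
    if missing:
        raise ValueError(f"variables not in sample sheet: {missing}")
    k = min(n_components, pca.scores.shape[1])
    rows = []
    for variable in variables:
        X_df = _design_columns(samples.loc[pca.scores.index], variable)
        if X_df is None:
            logger.info("pc_association: skipping constant variable %s", variable)
            continue
        ok = X_df.notna().all(axis=1).to_numpy()
        X = X_df.to_numpy(dtype=float)[ok]
        for j in range(k):
            y = pca.scores.iloc[:, j].to_numpy()[ok]
            r2, p = _ols_r2_p(y, X)
            rows.append(
                {
                    "component": j + 1,
                    "variable": variable,
                    "r_squared": r2,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
        out["significant"] = out["fdr"] < FDR_ALPHA
    return out


# ---------------------------------------------------------------------------
# PC-PR2


@dataclass
class PCPR2Result:
    """Eigenvalue-weighted partial-R2 attribution of data variance.

    ``partial_r2_pct`` holds, per covariate, the percentage of the
    captured multivariate variance attributable to that covariate.
    """

    covariates: list[str]
    partial_r2_pct: pd.Series
    n_components_used: int
    variance_captured: float


def _expand_covariates(
    covariates: pd.DataFrame,
) -> tuple[np.ndarray, dict[str, list[int]], list[str]]:
    """One-hot expand a covariate frame; returns matrix, groups, column names."""
    blocks, groups, names, start = [], {}, [], 0
    for name in covariates.columns:
        X_df = _design_columns(covariates, name)
        if X_df is None:
            raise ValueError(f"covariate {name} is constant")
        blocks.append(X_df.to_numpy(dtype=float))
        groups[name] = list(range(start, start + X_df.shape[1]))
        names.extend(X_df.columns)
        start += X_df.shape[1]
    return np.hstack(blocks), groups, names


def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.cond(np.column_stack([np.ones(len(X)), X])) <= CONDITION_NUMBER_LIMIT:
        return
    corr = np.corrcoef(X, rowvar=False)
    worst, pair = 0.0, (names[0], names[-1])
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > worst:
                worst, pair = abs(corr[i, j]), (names[i], names[j])
    raise ValueError(
        f"collinear covariates (condition number above {CONDITION_NUMBER_LIMIT:g}): "
        f"{pair[0]} and {pair[1]}"
    )


def pcpr2(
    beta: pd.DataFrame,
    covariates: pd.DataFrame,
    variance_threshold: float = 0.9,
) -> PCPR2Result:
    """Partition multivariate beta-value variance among covariates (PC-PR2).

    The CpG-scaled data are decomposed by PCA and the smallest number
    of leading components whose cumulative variance fraction reaches
    ``variance_threshold`` is kept. For each kept component, the score
    is regressed on all covariates (full model) and on all covariates
    minus each one in turn (reduced models); the per-component partial
    R2 of a covariate is (RSS_reduced - RSS_full) / RSS_reduced. The
    overall statistic per covariate is the eigenvalue-weighted mean of
    its per-component partial R2 values, reported in percent.
    """
    if covariates.shape[1] < 2:
        raise ValueError("pcpr2 requires >= 2 covariates")
    if covariates.isna().any().any():
        raise ValueError("pcpr2 requires complete covariate rows")
    covariates = covariates.loc[beta.columns]

    pca = pca_scaled(beta)
    cum = np.cumsum(pca.variance_fraction)
    q = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    q = min(q, len(cum))
    eigenvalues = pca.variance_fraction[:q]
    scores = pca.scores.to_numpy()[:, :q]

    X, groups, expanded_names = _expand_covariates(covariates)
    names = list(covariates.columns)
    _check_collinearity(X, expanded_names)

    n = X.shape[0]
    full_design = np.column_stack([np.ones(n), X])

    def rss(design: np.ndarray, y: np.ndarray) -> float:
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ coef
        return float(r @ r)

    partial = np.zeros((q, len(names)))
    for j in range(q):
        y = scores[:, j]
        rss_full = rss(full_design, y)
        for c, name in enumerate(names):
            keep = [i for i in range(X.shape[1]) if i not in groups[name]]
            reduced = np.column_stack([np.ones(n), X[:, keep]]) if keep else np.ones((n, 1))
            rss_red = rss(reduced, y)
            partial[j, c] = (rss_red - rss_full) / rss_red if rss_red > 0 else 0.0

    weights = eigenvalues / eigenvalues.sum()
    overall = 100.0 * (weights @ partial)
    return PCPR2Result(
        covariates=names,
        partial_r2_pct=pd.Series(overall, index=names),
        n_components_used=q,
        variance_captured=float(cum[q - 1]),
    )


# ---------------------------------------------------------------------------
# Per-CpG linear models


def _build_design(samples: pd.DataFrame, predictor: str, adjustment: list[str] | None) -> pd.DataFrame:
    cols = [predictor] + list(adjustment or [])
    blocks = []
    for name in cols:
        if name not in samples.columns:
            raise ValueError(f"covariate {name} not in sample sheet")
        X_df = _design_columns(samples, name)
        if X_df is None:
            raise ValueError(f"covariate {name} is constant")
        blocks.append(X_df)
    design = pd.concat(blocks, axis=1)
    design.insert(0, "(intercept)", 1.0)
    return design


def _check_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        aliased = [design.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def cpg_linear_model(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    predictor: str = "gestational_age",
    adjustment: list[str] | None = None,
    effect_threshold: float = 0.03,
) -> pd.DataFrame:
    """Per-CpG OLS of beta on a continuous predictor with optional adjustment.

    The slope is in beta units per predictor unit (e.g. per week of
    gestational age). Two-sided p-values come from the t statistic; BH
    FDR is applied across CpGs; a CpG is ``significant`` only when both
    FDR < 0.05 and |slope| >= ``effect_threshold`` — the joint
    statistical and effect-size gate. CpGs with missing beta values use
    complete cases.
    """
    samples = samples.loc[beta.columns]
    if samples[predictor].nunique(dropna=True) < 3:
        raise ValueError(f"predictor {predictor} needs >= 3 distinct values")
    design = _build_design(samples, predictor, adjustment)
    _check_rank(design)
    X = design.to_numpy(dtype=float)
    slope_idx = list(design.columns).index(predictor)
    Y = beta.to_numpy(dtype=float)

    def fit_block(Xb: np.ndarray, Yb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised OLS over rows of Yb; returns (slopes, p-values)."""
        n, p = Xb.shape
        xtx_inv = np.linalg.inv(Xb.T @ Xb)
        B = xtx_inv @ Xb.T @ Yb.T  # p x n_cpgs
        resid = Yb.T - Xb @ B
        df = n - p
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(sigma2 * xtx_inv[slope_idx, slope_idx])
        slopes = B[slope_idx]
        slopes[np.abs(slopes) < 1e-12] = 0.0  # constant beta: exact zero slope
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, slopes / se, 0.0)
        pvals = 2 * sps.t.sf(np.abs(t), df)
        return slopes, pvals

    complete = ~np.isnan(Y).any(axis=1)
    slopes = np.full(len(Y), np.nan)
    pvals = np.full(len(Y), np.nan)
    if complete.any():
        slopes[complete], pvals[complete] = fit_block(X, Y[complete])
    for i in np.where(~complete)[0]:
        ok = ~np.isnan(Y[i])
        if ok.sum() <= X.shape[1]:
            continue  # not enough complete cases; left NaN
        s, p = fit_block(X[ok], Y[i : i + 1, ok])
        slopes[i], pvals[i] = s[0], p[0]

    fdr = np.full(len(Y), np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        fdr[ok] = bh_fdr(pvals[ok])
    out = pd.DataFrame(
        {
            "slope": slopes,
            "p_value": pvals,
            "fdr": fdr,
        },
        index=beta.index.rename("cpg_id"),
    )
    out["significant"] = (out["fdr"] < FDR_ALPHA) & (out["slope"].abs() >= effect_threshold)
    return out


# ---------------------------------------------------------------------------
# Group comparisons


def group_compare(
    values: pd.Series,
    groups: pd.Series,
    reference_group: str,
) -> pd.DataFrame:
    """Wilcoxon rank-sum tests of a reference group against all others.

    Returns one row per comparison with p-value, BH FDR across the
    family, and star annotations (FDR < 0.05/0.01/0.001/0.0001). Groups
    with fewer than 2 samples are skipped with a log note.
    """
    groups = groups.loc[values.index]
    ref = values[groups == reference_group].dropna().to_numpy()
    if len(ref) == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    rows = []
    for g in sorted(set(groups.dropna()) - {reference_group}):
        other = values[groups == g].dropna().to_numpy()
        if len(other) < 2 or len(ref) < 2:
            logger.info("group_compare: skipping %s (<2 samples)", g)
            continue
        rows.append(
            {
                "reference": reference_group,
                "group": g,
                "n_reference": len(ref),
                "n_group": len(other),
                "p_value": wilcoxon_rank_sum(ref, other),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
        out["stars"] = [significance_stars(f) for f in out["fdr"]]
    return out
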