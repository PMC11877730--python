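"""XCI status calling from allele balance and the DNAme-XCI battery.

Allele-specific expression in XX samples measures, per gene, the
fraction of expression from the major allele ("allele balance", folded
to [0.5, 1]). Genes silenced on the inactive X (subject to XCI) show
monoallelic expression (balance >= 0.8) in most informative samples;
escape genes show biallelic expression. This module calls the
escape / variable escape / subject categories from a gene x sample
balance matrix, and quantifies how well promoter methylation summaries
track those calls via a Pearson correlation battery with the filter
variants used in practice (dropping genes methylated in XY samples,
restricting to CpG-island promoters).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from methylxci.stats import bh_fdr, wilcoxon_rank_sum

__all__ = [
    "XCIThresholds",
    "call_xci",
    "correlate_dname_xci",
    "correlation_battery",
    "compare_categories",
    "cross_tissue_concordance",
    "ConcordanceResult",
]

CATEGORIES = ("escape", "variable", "subject")

METRIC_COLUMNS = {
    "mean_XX": "beta_mean_XX",
    "median_XX": "beta_median_XX",
    "delta_beta": "delta_beta",
}
OUTCOME_COLUMNS = ("proportion_subject", "median_balance")

XY_HIGH_BETA = 0.1  # promoter counts as methylated in XY above this


@dataclass(frozen=True)
class XCIThresholds:
    """Allele-balance thresholds for category calling.

    A sample is "subject-like" when its folded balance is >=
    ``subject_balance``. A gene is subject when the proportion of
    subject-like informative samples exceeds ``subject_prop`` and the
    median balance is >= ``subject_median``; escape when the proportion
    is below ``escape_prop`` and the median is <= ``escape_median``;
    variable otherwise.
    """

    subject_balance: float = 0.8
    subject_prop: float = 0.7
    subject_median: float = 0.8
    escape_prop: float = 0.3
    escape_median: float = 0.75
    min_informative: int = 5


def call_xci(
    ab: pd.DataFrame,
    thresholds: XCIThresholds = XCIThresholds(),
) -> pd.DataFrame:
    """Call per-gene XCI status from a folded allele-balance matrix.

    ``ab`` is genes x samples with values in [0.5, 1]; NaN marks an
    uninformative sample. Returns a DataFrame indexed by gene with
    n_informative, proportion_subject, median_balance and category;
    genes with fewer informative samples than
    ``thresholds.min_informative`` are reported with category
    ``uncalled`` (their metrics are still computed when any sample is
    informative).
    """
    if ab.shape[0] == 0:
        return pd.DataFrame(
            columns=["n_informative", "proportion_subject", "median_balance", "category"]
        )
    vals = ab.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    n_inf = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        prop = np.where(
            n_inf > 0,
            np.nansum(vals >= thresholds.subject_balance, axis=1) / np.maximum(n_inf, 1),
            np.nan,
        )
        med = np.nanmedian(np.where(finite, vals, np.nan), axis=1)

    category = np.full(ab.shape[0], "variable", dtype=object)
    subject = (prop > thresholds.subject_prop) & (med >= thresholds.subject_median)
    escape = (prop < thresholds.escape_prop) & (med <= thresholds.escape_median)
    category[subject] = "subject"
    category[escape] = "escape"
    category[n_inf < thresholds.min_informative] = "uncalled"

    return pd.DataFrame(
        {
            "n_informative": n_inf,
            "proportion_subject": prop,
            "median_balance": med,
            "category": category,
        },
        index=ab.index.rename("gene_id"),
    )


def _apply_filter(merged: pd.DataFrame, filter_spec: str) -> pd.DataFrame:
    if filter_spec in ("exclude_xy_high", "both"):
        merged = merged[merged["beta_mean_XY"] <= XY_HIGH_BETA]
    if filter_spec in ("cgi_only", "both"):
        merged = merged[merged["cgi_class"].isin(["HC", "IC"])]
    if filter_spec not in ("all", "exclude_xy_high", "cgi_only", "both"):
        raise ValueError(f"unknown filter_spec: {filter_spec}")
    return merged


def correlate_dname_xci(
    summaries: pd.DataFrame,
    calls: pd.DataFrame,
    filter_spec: str = "all",
    metric: str = "delta_beta",
    outcome: str = "proportion_subject",
) -> dict:
    """Pearson correlation of a DNAme summary with an XCI outcome.

    ``summaries`` is a region summary table with a ``gene_id`` column
    (one promoter per gene); ``calls`` is the output of
    :func:`call_xci`. Genes present in both inputs survive the chosen
    filter; requires >= 3 genes and a non-constant outcome.
    """
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric: {metric}")
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"unknown outcome: {outcome}")
    called = calls[calls["category"] != "uncalled"]
    merged = summaries.merge(
        called.reset_index()[["gene_id", "proportion_subject", "median_balance"]],
        on="gene_id",
        how="inner",
    )
    merged = _apply_filter(merged, filter_spec)
    x = merged[METRIC_COLUMNS[metric]].to_numpy(dtype=float)
    y = merged[outcome].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(
            f"fewer than 3 genes survive filter {filter_spec!r} "
            f"(metric={metric}, outcome={outcome})"
        )
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return {
            "filter_label": filter_spec,
            "metric": metric,
            "outcome": outcome,
            "n_genes": len(x),
            "pearson_r": np.nan,
            "p_value": np.nan,
        }
    r, p = sps.pearsonr(x, y)
    return {
        "filter_label": filter_spec,
        "metric": metric,
        "outcome": outcome,
        "n_genes": len(x),
        "pearson_r": float(r),
        "p_value": float(p),
    }


def correlation_battery(
    summaries: pd.DataFrame,
    calls: pd.DataFrame,
    filters: tuple[str, ...] = ("all", "exclude_xy_high", "cgi_only", "both"),
    metrics: tuple[str, ...] = ("mean_XX", "median_XX", "delta_beta"),
    outcomes: tuple[str, ...] = ("proportion_subject", "median_balance"),
) -> pd.DataFrame:
    """Run the full correlation battery with one BH-FDR family.

    Every requested filter x metric x outcome combination is computed
    and the FDR adjustment is applied across all of them jointly (one
    family per invocation); the family is recorded in the output.
    """
    rows = []
    for flt, metric, outcome in itertools.product(filters, metrics, outcomes):
        rows.append(correlate_dname_xci(summaries, calls, flt, metric, outcome))
    out = pd.DataFrame(rows)
    fdr = np.full(len(out), np.nan)
    ok = out["p_value"].notna().to_numpy()
    if ok.any():
        fdr[ok] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
    out["fdr"] = fdr
    out["fdr_family"] = "battery"
    return out


def compare_categories(
    summaries: pd.DataFrame,
    calls: pd.DataFrame,
) -> dict:
    """Compare promoter methylation between XCI categories.

    Returns a dict with ``pairwise``: Wilcoxon rank-sum tests of
    delta_beta between every category pair (BH FDR across the three
    pairs); ``within_category``: XX-vs-XY mean comparisons inside each
    category (their own BH family); and ``category_means``: per
    category mean delta_beta / XX / XY with gene counts. Pairs with a
    category holding fewer than 2 genes are skipped with a note.
    """
    called = calls[calls["category"] != "uncalled"]
    merged = summaries.merge(
        called.reset_index()[["gene_id", "category"]], on="gene_id", how="inner"
    )
    groups = {
        c: merged.loc[merged["category"] == c, "delta_beta"].dropna().to_numpy()
        for c in CATEGORIES
    }

    pair_rows, skipped = [], []
    for a, b in itertools.combinations(CATEGORIES, 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            skipped.append(f"{a} vs {b}: a category has <2 genes")
            continue
        p = wilcoxon_rank_sum(groups[a], groups[b])
        pair_rows.append({"group_a": a, "group_b": b, "p_value": p})
    pairwise = pd.DataFrame(pair_rows)
    if len(pairwise):
        pairwise["fdr"] = bh_fdr(pairwise["p_value"].to_numpy())

    within_rows = []
    for c in CATEGORIES:
        sub = merged[merged["category"] == c]
        xx = sub["beta_mean_XX"].dropna().to_numpy()
        xy = sub["beta_mean_XY"].dropna().to_numpy()
        if len(xx) < 2 or len(xy) < 2:
            skipped.append(f"XX vs XY within {c}: <2 genes")
            continue
        within_rows.append(
            {"category": c, "p_value": wilcoxon_rank_sum(xx, xy), "n_genes": len(sub)}
        )
    within = pd.DataFrame(within_rows)
    if len(within):
        within["fdr"] = bh_fdr(within["p_value"].to_numpy())

    means = (
        merged.groupby("category")[["delta_beta", "beta_mean_XX", "beta_mean_XY"]]
        .mean()
        .join(merged.groupby("category").size().rename("n_genes"))
    )
    return {
        "pairwise": pairwise,
        "within_category": within,
        "category_means": means,
        "skipped": skipped,
    }


@dataclass
class ConcordanceResult:
    """Cross-tissue XCI concordance: 3x3 table and discordance lists."""

    table: pd.DataFrame  # rows: categories in tissue A, columns: tissue B
    chi2_p: float  # chi-square on 2x3 counts-by-tissue marginals
    fully_discordant: list[str]  # escape/subject flips
    discordant: list[str]  # any category change


def cross_tissue_concordance(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> ConcordanceResult:
    """Compare per-gene XCI categories between two tissues.

    Builds the 3x3 cross-classification over genes called in both
    tissues, lists fully discordant genes (escape in one tissue,
    subject in the other), and tests whether the marginal category
    counts differ between tissues with a chi-square on the 2x3
    counts-by-tissue table.
    """
    a = calls_a.loc[calls_a["category"] != "uncalled", "category"]
    b = calls_b.loc[calls_b["category"] != "uncalled", "category"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no genes called in both tissues")
    a, b = a.loc[shared], b.loc[shared]

    table = pd.crosstab(a, b).reindex(
        index=list(CATEGORIES), columns=list(CATEGORIES), fill_value=0
    )
    counts = np.array(
        [[int((a == c).sum()) for c in CATEGORIES], [int((b == c).sum()) for c in CATEGORIES]]
    )
    nonzero = counts.sum(axis=0) > 0
    chi2_p = float(sps.chi2_contingency(counts[:, nonzero]).pvalue)

    fully = sorted(
        g
        for g in shared
        if {a.loc[g], b.loc[g]} == {"escape", "subject"}
    )
    disc = sorted(g for g in shared if a.loc[g] != b.loc[g])
    return ConcordanceResult(table, chi2_p, fully, disc)
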