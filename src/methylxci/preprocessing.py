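"""Probe QC, sex inference, and region-level per-sex methylation summaries.

Beta matrices are pandas DataFrames with probe ids as the index and
sample ids as columns; sample sheets are DataFrames indexed by
sample_id with a ``reported_sex`` (or inferred ``sex``) column holding
``XX`` / ``XY``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from methylxci.annotation import CpGAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeQC",
    "RegionDef",
    "RegionSummaryResult",
    "filter_probes",
    "infer_sex",
    "regions_from_annotations",
    "region_mean_beta",
    "stratified_mean_beta",
]

DETECTION_P_THRESHOLD = 0.01
MIN_BEAD_COUNT = 3
DEFAULT_FAIL_FRACTION = 0.05


@dataclass
class ProbeQC:
    """Per-probe, per-sample QC companion to a beta matrix.

    ``missing`` defaults to the NA pattern of the beta matrix when not
    supplied at construction.
    """

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame
    missing: pd.DataFrame | None = None

    def aligned_to(self, beta: pd.DataFrame) -> "ProbeQC":
        for name, df in (("detection_p", self.detection_p), ("bead_count", self.bead_count)):
            if df.shape != beta.shape:
                raise ValueError(f"QC matrix {name} shape {df.shape} != beta {beta.shape}")
        det = self.detection_p.reindex(index=beta.index, columns=beta.columns)
        beads = self.bead_count.reindex(index=beta.index, columns=beta.columns)
        if det.isna().to_numpy().any() or beads.isna().to_numpy().any():
            raise ValueError("QC matrices are not aligned to the beta matrix")
        missing = self.missing if self.missing is not None else beta.isna()
        missing = missing.reindex(index=beta.index, columns=beta.columns).fillna(True)
        return ProbeQC(det, beads, missing)


def filter_probes(
    beta: pd.DataFrame,
    qc: ProbeQC,
    mask_list: set[str] | frozenset[str] = frozenset(),
    mappable: set[str] | None = None,
    frac_threshold: float = DEFAULT_FAIL_FRACTION,
) -> list[str]:
    """Return the probe ids retained after QC filtering, in input order.

    A probe is dropped iff the fraction of samples in which it fails QC
    (detection p > 0.01, bead count < 3, or a missing beta value)
    strictly exceeds ``frac_threshold``, or it appears in ``mask_list``
    (polymorphic / cross-hybridising probes), or ``mappable`` is given
    and the probe is not in it (failed genome mapping).
    """
    if beta.shape[1] == 0:
        raise ValueError("beta matrix has no samples")
    qc = qc.aligned_to(beta)
    fails = (
        (qc.detection_p.to_numpy() > DETECTION_P_THRESHOLD)
        | (qc.bead_count.to_numpy() < MIN_BEAD_COUNT)
        | qc.missing.to_numpy()
    )
    fail_frac = fails.mean(axis=1)
    keep = fail_frac <= frac_threshold
    retained = []
    for i, probe in enumerate(beta.index):
        if not keep[i]:
            continue
        if probe in mask_list:
            continue
        if mappable is not None and probe not in mappable:
            continue
        retained.append(probe)
    logger.info("filter_probes: retained %d / %d probes", len(retained), beta.shape[0])
    return retained


def infer_sex(
    intensities: pd.DataFrame,
    reported_sex: pd.Series | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Infer sample sex from median X / Y probe intensities.

    ``intensities`` holds per-sample columns ``median_x``, ``median_y``
    and ``median_auto`` (all positive). X and Y intensities are
    normalised by the autosomal median, samples are partitioned by
    2-means on (x_norm, y_norm) with a fixed seed, and the cluster with
    the higher mean y_norm is labelled XY. When the clusters are
    degenerate (their y_norm centres nearly coincide — e.g. a
    single-sex cohort) the routine falls back to a fixed threshold
    (y_norm > 0.5 => XY) with a warning. Returns a DataFrame with
    ``x_norm``, ``y_norm``, ``inferred_sex`` and, when a reported sex
    is supplied, a ``mismatch`` flag.
    """
    required = {"median_x", "median_y", "median_auto"}
    if not required.issubset(intensities.columns):
        raise ValueError(f"intensities must have columns {sorted(required)}")
    if (intensities[list(required)] <= 0).any().any():
        raise ValueError("intensities must be positive")

    x_norm = intensities["median_x"] / intensities["median_auto"]
    y_norm = intensities["median_y"] / intensities["median_auto"]
    pts = np.column_stack([x_norm.to_numpy(), y_norm.to_numpy()])

    degenerate = len(pts) < 2
    if not degenerate:
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pts)
        centre_y = km.cluster_centers_[:, 1]
        # well-separated sexes differ by ~1 in y_norm; treat < 0.2 as one sex
        if abs(centre_y[0] - centre_y[1]) < 0.2:
            degenerate = True

    if degenerate:
        warnings.warn(
            "sex clusters degenerate; falling back to fixed threshold y_norm > 0.5",
            stacklevel=2,
        )
        inferred = np.where(y_norm.to_numpy() > 0.5, "XY", "XX")
    else:
        xy_cluster = int(np.argmax(centre_y))
        inferred = np.where(km.labels_ == xy_cluster, "XY", "XX")

    out = pd.DataFrame(
        {"x_norm": x_norm, "y_norm": y_norm, "inferred_sex": inferred},
        index=intensities.index,
    )
    if reported_sex is not None:
        rep = reported_sex.reindex(intensities.index)
        out["reported_sex"] = rep
        out["mismatch"] = (rep.notna()) & (rep != "unknown") & (rep != out["inferred_sex"])
    return out


@dataclass(frozen=True)
class RegionDef:
    """A named region mapping to the CpGs it contains."""

    region_id: str
    gene_id: str
    region_kind: str  # promoter | gene_body | enhancer | tss_window | custom
    cpg_ids: tuple[str, ...]
    cgi_class: str = "none"


def regions_from_annotations(
    annotations: Sequence[CpGAnnotation], kind: str
) -> list[RegionDef]:
    """Build gene-keyed region definitions from CpG annotations.

    ``kind`` is one of ``promoter``, ``gene_body``, ``enhancer`` or
    ``tss_window``. Multi-gene memberships expand to one region per
    gene. For promoters, the region's CGI class is the dominant class
    of its CpGs (HC beats IC beats none).
    """
    attr = {"promoter": "promoter_genes", "gene_body": "body_genes", "enhancer": "enhancer_genes"}
    if kind in attr:
        by_gene: dict[str, list[CpGAnnotation]] = {}
        for a in annotations:
            for g in getattr(a, attr[kind]):
                by_gene.setdefault(g, []).append(a)
        regions = []
        for gene, cpgs in sorted(by_gene.items()):
            classes = {c.cgi_class for c in cpgs}
            cgi = "HC" if "HC" in classes else ("IC" if "IC" in classes else "none")
            regions.append(
                RegionDef(
                    region_id=f"{kind}:{gene}",
                    gene_id=gene,
                    region_kind=kind,
                    cpg_ids=tuple(c.cpg_id for c in cpgs),
                    cgi_class=cgi,
                )
            )
        return regions
    if kind == "tss_window":
        regions = []
        for window in ("TSS200", "TSS200_1500"):
            cpgs = tuple(a.cpg_id for a in annotations if a.tss_window == window)
            if cpgs:
                regions.append(RegionDef(window, "", "tss_window", cpgs))
        return regions
    raise ValueError(f"unknown region kind: {kind}")


@dataclass
class RegionSummaryResult:
    """Region-level methylation summaries.

    ``summary`` has one row per region with columns region_id, gene_id,
    region_kind, cgi_class, n_cpgs, beta_mean_XX, beta_mean_XY and
    delta_beta (XX minus XY, of per-sample means averaged within sex);
    ``sample_means`` / ``sample_medians`` are region x sample matrices.
    """

    summary: pd.DataFrame
    sample_means: pd.DataFrame
    sample_medians: pd.DataFrame


def _sex_groups(samples: pd.DataFrame) -> tuple[list[str], list[str]]:
    col = "sex" if "sex" in samples.columns else "reported_sex"
    xx = samples.index[samples[col] == "XX"].tolist()
    xy = samples.index[samples[col] == "XY"].tolist()
    return xx, xy


def region_mean_beta(
    beta: pd.DataFrame,
    regions: Sequence[RegionDef],
    samples: pd.DataFrame,
) -> RegionSummaryResult:
    """Summarise methylation per region, per sample, and per sex.

    Per-sample means/medians ignore missing beta values; the group mean
    for each sex is the unweighted mean of per-sample means. Regions
    covering zero retained CpGs are omitted (a log line reports the
    count). A sex group with no samples yields NaN group mean and NaN
    delta_beta.
    """
    xx, xy = _sex_groups(samples)
    present = set(beta.index)
    rows, mean_rows, median_rows, kept = [], [], [], []
    n_empty = 0
    for region in regions:
        cpgs = [c for c in region.cpg_ids if c in present]
        if not cpgs:
            n_empty += 1
            continue
        block = beta.loc[cpgs]
        means = block.mean(axis=0, skipna=True)
        medians = block.median(axis=0, skipna=True)
        mean_xx = means[xx].mean() if xx else np.nan
        mean_xy = means[xy].mean() if xy else np.nan
        rows.append(
            {
                "region_id": region.region_id,
                "gene_id": region.gene_id,
                "region_kind": region.region_kind,
                "cgi_class": region.cgi_class,
                "n_cpgs": len(cpgs),
                "beta_mean_XX": mean_xx,
                "beta_mean_XY": mean_xy,
                "beta_median_XX": medians[xx].median() if xx else np.nan,
                "beta_median_XY": medians[xy].median() if xy else np.nan,
                "delta_beta": mean_xx - mean_xy,
            }
        )
        mean_rows.append(means)
        median_rows.append(medians)
        kept.append(region.region_id)
    if n_empty:
        logger.info("region_mean_beta: %d regions with no covered CpGs omitted", n_empty)
    summary = pd.DataFrame(rows)
    sample_means = pd.DataFrame(mean_rows, index=kept, columns=beta.columns)
    sample_medians = pd.DataFrame(median_rows, index=kept, columns=beta.columns)
    return RegionSummaryResult(summary, sample_means, sample_medians)


def stratified_mean_beta(
    beta: pd.DataFrame,
    annotations: Sequence[CpGAnnotation],
    chrom_x: str = "chrX",
) -> pd.DataFrame:
    """Per-sample mean beta in PMD x repeat strata, split by chromosome class.

    Within each chromosome class (autosomal vs chrX) every CpG falls in
    exactly one of the four cells of {PMD, non-PMD} x {repetitive
    (LINE-1 or SINE), non-repetitive}. Returns a long DataFrame with
    columns sample_id, chrom_class, pmd, repetitive, n_cpgs, mean_beta;
    empty strata yield NaN with a warning.
    """
    by_cpg = {a.cpg_id: a for a in annotations}
    strata: dict[tuple[str, bool, bool], list[str]] = {}
    for probe in beta.index:
        a = by_cpg.get(probe)
        if a is None:
            continue
        chrom_class = "chrX" if a.chrom == chrom_x else "autosomal"
        strata.setdefault(
            (chrom_class, a.in_pmd, a.in_line1 or a.in_sine), []
        ).append(probe)

    rows = []
    for chrom_class in ("autosomal", "chrX"):
        for pmd in (True, False):
            for rep in (True, False):
                cpgs = strata.get((chrom_class, pmd, rep), [])
                if not cpgs:
                    warnings.warn(
                        f"empty stratum ({chrom_class}, pmd={pmd}, repetitive={rep})",
                        stacklevel=2,
                    )
                    means = pd.Series(np.nan, index=beta.columns)
                else:
                    means = beta.loc[cpgs].mean(axis=0, skipna=True)
                for sample, m in means.items():
                    rows.append(
                        {
                            "sample_id": sample,
                            "chrom_class": chrom_class,
                            "pmd": pmd,
                            "repetitive": rep,
                            "n_cpgs": len(cpgs),
                            "mean_beta": m,
                        }
                    )
    return pd.DataFrame(rows)
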