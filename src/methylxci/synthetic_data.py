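"""Synthetic methylome + metadata + allele-balance generator.

Emulates the statistical structure of X-chromosome methylation-array
studies of placenta: XX beta values are the average of active-X (Xa)
and inactive-X (Xi) allele states while XY samples carry only an Xa;
X-linked beta distributions are trimodal (modes near 0, 0.5 and 1);
partially methylated domains (PMDs) depress methylation; bulk samples
are mixtures of six cell types with per-cell-type offsets; and
allele-balance matrices encode per-gene XCI categories.

The coupling between Xi promoter methylation and XCI status is the key
dial: in ``somatic`` mode genes subject to XCI carry high Xi promoter
methylation and escape genes low (the canonical somatic-tissue
relationship), while in ``placenta`` mode Xi promoter methylation is
low regardless of XCI category (the placental decoupling), shifted
down further by a configurable depletion. ``custom`` mode blends the
two with weight ``coupling_rho``.

All randomness flows through named, independently seeded streams so
one component can be varied holding the others fixed; a
:class:`GroundTruth` object records the generative state for
parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from methylxci import annotation as ann
from methylxci.io import CELL_TYPES

__all__ = ["SimConfig", "GroundTruth", "SimResult", "simulate_study", "export_fixture"]

_STREAMS = {"genes": 1, "methylation": 2, "cells": 3, "metadata": 4, "allele_balance": 5, "noise": 6}

# trimodal intergenic modes: unmethylated, allele-intermediate, methylated
_MODE_PARAMS = ((2.0, 30.0), (50.0, 50.0), (30.0, 2.0))


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic methylome study.

    Defaults describe a term-placenta-like study: 200 X-linked genes
    with escape / variable / subject fractions (0.10, 0.20, 0.70),
    30 samples per sex, array-scale noise (sd 0.05 on the beta scale),
    trophoblast-dominated cell composition, and gestational ages
    spanning 8-42 weeks with no methylation-gestation trend (the null
    observed in placenta).
    """

    seed: int = 0
    n_genes: int = 200
    n_cpgs_per_promoter: int = 3
    n_cpgs_per_body: int = 2
    n_intergenic_cpgs: int = 300
    n_autosomal_cpgs: int = 200
    n_samples_per_sex: int = 30
    tissue: str = "placenta"
    cohort: str = "SIM"
    xci_fractions: tuple[float, float, float] = (0.10, 0.20, 0.70)  # escape, variable, subject
    coupling_mode: str = "placenta"  # somatic | placenta | custom
    coupling_rho: float = 1.0  # custom mode: 1 -> somatic, 0 -> placenta
    xa_promoter_beta_params: tuple[float, float] = (2.0, 30.0)
    xi_subject_beta_params: tuple[float, float] = (30.0, 8.0)
    xi_escape_beta_params: tuple[float, float] = (2.0, 30.0)
    placenta_xi_depletion: float = 0.05
    body_beta_params: tuple[float, float] = (10.0, 4.0)
    intergenic_mode_probs: tuple[float, float, float] = (0.4, 0.2, 0.4)
    pmd_fraction: float = 0.3
    pmd_hypomethylation: float = 0.15
    noise_sd: float = 0.05
    cell_dirichlet: tuple[float, ...] = (0.3, 1.2, 4.8, 6.6, 11.4, 35.4)
    cell_offset_sd: float = 0.02
    ga_range_weeks: tuple[float, float] = (8.0, 42.0)
    ga_effect: float = 0.0  # beta change per week; 0 = the placental null
    ab_subject_params: tuple[float, float] = (8.0, 1.0)  # folded: 0.5 + 0.5*Beta
    ab_escape_params: tuple[float, float] = (1.2, 6.0)
    variable_propensity_range: tuple[float, float] = (0.3, 0.7)
    informative_rate: float = 0.85
    cgi_fraction: float = 0.85  # promoters overlapping an HC CpG island
    with_enhancers: bool = True

    def validate(self) -> None:
        if abs(sum(self.xci_fractions) - 1.0) > 1e-9 or any(
            f < 0 or f > 1 for f in self.xci_fractions
        ):
            raise ValueError("xci_fractions must lie in [0,1] and sum to 1")
        if abs(sum(self.intergenic_mode_probs) - 1.0) > 1e-9:
            raise ValueError("intergenic_mode_probs must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.coupling_mode not in ("somatic", "placenta", "custom"):
            raise ValueError(f"unknown coupling_mode: {self.coupling_mode}")
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must lie in [0, 1]")
        if not 0.0 <= self.placenta_xi_depletion <= 1.0:
            raise ValueError("placenta_xi_depletion must lie in [0, 1]")
        if not 0.0 < self.informative_rate <= 1.0:
            raise ValueError("informative_rate must lie in (0, 1]")
        if len(self.cell_dirichlet) != len(CELL_TYPES):
            raise ValueError(f"cell_dirichlet needs {len(CELL_TYPES)} concentrations")
        lo, hi = self.variable_propensity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("variable_propensity_range must be ordered within [0, 1]")


@dataclass
class GroundTruth:
    """True generative state exported alongside a simulated study."""

    genes: pd.DataFrame  # gene_id, category, propensity, xa_mean, xi_mean
    cpgs: pd.DataFrame  # cpg_id, chrom, pos (0-based), kind, gene_id, in_pmd
    samples: pd.DataFrame  # sex, gestational_age, true cell proportions
    coupling_mode: str
    seed: int


@dataclass
class SimResult:
    beta: pd.DataFrame
    samples: pd.DataFrame
    annotations: list[ann.CpGAnnotation]
    allele_balance: pd.DataFrame
    ground_truth: GroundTruth
    tracks: ann.AnnotationTracks
    tss: list[ann.TSSRecord]
    manifest: list[tuple[str, str, int]]  # cpg_id, chrom, 1-based pos


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


def _beta_draw(rng: np.random.Generator, params: tuple[float, float], size) -> np.ndarray:
    """Beta draw with degenerate endpoints: (0, b) -> 0, (a, 0) -> 1."""
    a, b = params
    shape = () if size is None else size
    if a == 0:
        return np.zeros(shape)
    if b == 0:
        return np.ones(shape)
    return rng.beta(a, b, size=size)


def _layout(config: SimConfig):
    """Deterministic genomic layout on chrX (plus autosomal filler).

    Gene g has a + strand TSS at 100000 + 10000*g, a promoter-like
    element spanning [TSS-150, TSS+50), promoter CpGs inside it (within
    the TSS200 band), a gene body [TSS, TSS+5000) with body CpGs, an
    optional HC CpG island over the promoter, and an optional proximal
    enhancer-like element 1.5 kb downstream with one CpG. Intergenic
    CpGs follow at 500 bp spacing; the trailing ``pmd_fraction`` of
    them sits inside a single PMD block, and recurring offsets place
    some inside LINE-1 / SINE repeat intervals.
    """
    rng = _rng(config, "genes")
    tss, pls, pels, bodies, cgis = [], [], [], [], []
    rows = []  # manifest + truth rows: cpg_id, chrom, pos0, kind, gene
    for g in range(config.n_genes):
        gene = f"GENE{g:04d}"
        t = 100_000 + 10_000 * g
        tss.append(ann.TSSRecord(gene, "chrX", t, "+"))
        pls.append(ann.GenomicInterval("chrX", t - 150, t + 50))
        bodies.append((ann.GenomicInterval("chrX", t, t + 5_000), gene))
        if rng.random() < config.cgi_fraction:
            cgis.append(ann.CGIRecord(ann.GenomicInterval("chrX", t - 300, t + 300), 600, 0.60, 0.80))
        for j in range(config.n_cpgs_per_promoter):
            pos = t - 140 + 30 * j  # inside the PLS and the TSS200 band
            rows.append((f"cgX_p{g:04d}_{j}", "chrX", pos, "promoter", gene))
        for j in range(config.n_cpgs_per_body):
            rows.append((f"cgX_b{g:04d}_{j}", "chrX", t + 1_000 + 2_000 * j, "body", gene))
        if config.with_enhancers:
            pels.append(ann.GenomicInterval("chrX", t + 1_450, t + 1_650))
            rows.append((f"cgX_e{g:04d}", "chrX", t + 1_500, "enhancer", gene))

    base = 100_000 + 10_000 * config.n_genes + 50_000
    line1, sine = [], []
    n_pmd = int(round(config.pmd_fraction * config.n_intergenic_cpgs))
    for i in range(config.n_intergenic_cpgs):
        pos = base + 500 * i
        rows.append((f"cgX_i{i:05d}", "chrX", pos, "intergenic", ""))
        if i % 7 == 3:
            line1.append(ann.GenomicInterval("chrX", pos - 100, pos + 200))
        elif i % 7 == 5:
            sine.append(ann.GenomicInterval("chrX", pos - 50, pos + 100))
    pmds = []
    if n_pmd > 0:
        pmd_start = base + 500 * (config.n_intergenic_cpgs - n_pmd)
        pmds.append(ann.GenomicInterval("chrX", pmd_start - 100, base + 500 * config.n_intergenic_cpgs))

    n_auto_pmd = int(round(config.pmd_fraction * config.n_autosomal_cpgs))
    for i in range(config.n_autosomal_cpgs):
        pos = 10_000 + 500 * i
        rows.append((f"cgA_i{i:05d}", "chr7", pos, "autosomal", ""))
        if i % 7 == 3:
            line1.append(ann.GenomicInterval("chr7", pos - 100, pos + 200))
        elif i % 7 == 5:
            sine.append(ann.GenomicInterval("chr7", pos - 50, pos + 100))
    if n_auto_pmd > 0:
        start = 10_000 + 500 * (config.n_autosomal_cpgs - n_auto_pmd)
        pmds.append(ann.GenomicInterval("chr7", start - 100, 10_000 + 500 * config.n_autosomal_cpgs))

    tracks = ann.AnnotationTracks(
        promoters=ann.assign_promoters(pls, tss),
        enhancers=ann.assign_enhancers(pels, tss) if pels else [],
        bodies=bodies,
        cgis=cgis,
        pmds=pmds,
        line1=line1,
        sine=sine,
    )
    return rows, tracks, tss, pls, pels


def _prop_subject_propensity(config: SimConfig, category: str, pi: float) -> float:
    """Expected per-sample probability of a subject-like balance (>= 0.8)."""
    # folded balance b = 0.5 + 0.5 * Beta(a, b); b >= 0.8 <=> Beta >= 0.6
    p_sub = float(sps.beta.sf(0.6, *config.ab_subject_params))
    p_esc = float(sps.beta.sf(0.6, *config.ab_escape_params))
    if category == "subject":
        return p_sub
    if category == "escape":
        return p_esc
    return pi * p_sub + (1 - pi) * p_esc


def simulate_study(config: SimConfig) -> SimResult:
    """Generate a complete synthetic study.

    Per gene, an XCI category is drawn from ``xci_fractions``; promoter
    CpGs get an Xa state from a low Beta and an Xi state set by the
    coupling mode. XY beta is built from the Xa state alone, XX beta is
    the (Xa + Xi) / 2 allele mixture. PMD CpGs are shifted down, per
    cell type offsets are applied on the beta scale before Dirichlet
    mixing, a gestational-age trend (when configured) is added, and
    truncated-Gaussian noise (clip to [0, 1]) finishes the measurement
    model. Allele balances for XX samples are drawn from
    category-specific folded-Beta laws, with variable-escape genes
    mixing the subject and escape laws by a per-gene propensity.
    """
    config.validate()
    rows, tracks, tss, _, _ = _layout(config)
    manifest = [(cpg_id, chrom, pos + 1) for cpg_id, chrom, pos, _, _ in rows]
    annotations = ann.annotate_cpgs(manifest, tracks, tss)
    ann_by_id = {a.cpg_id: a for a in annotations}

    gene_rng = _rng(config, "genes")
    meth_rng = _rng(config, "methylation")
    cell_rng = _rng(config, "cells")
    meta_rng = _rng(config, "metadata")
    ab_rng = _rng(config, "allele_balance")
    noise_rng = _rng(config, "noise")

    genes = [f"GENE{g:04d}" for g in range(config.n_genes)]
    categories = gene_rng.choice(
        ["escape", "variable", "subject"], size=config.n_genes, p=list(config.xci_fractions)
    )
    lo, hi = config.variable_propensity_range
    pi_g = gene_rng.uniform(lo, hi, size=config.n_genes)

    # --- allele states per CpG ------------------------------------------------
    n_cpgs = len(rows)
    m_a = np.empty(n_cpgs)
    m_i = np.empty(n_cpgs)
    gene_index = {g: i for i, g in enumerate(genes)}
    xi_gene_mean_acc: dict[str, list[float]] = {g: [] for g in genes}
    xa_gene_mean_acc: dict[str, list[float]] = {g: [] for g in genes}

    def xi_somatic(category: str, pi: float, size: int) -> np.ndarray:
        if category == "subject":
            return _beta_draw(meth_rng, config.xi_subject_beta_params, size)
        if category == "escape":
            return _beta_draw(meth_rng, config.xi_escape_beta_params, size)
        high = _beta_draw(meth_rng, config.xi_subject_beta_params, size)
        low = _beta_draw(meth_rng, config.xi_escape_beta_params, size)
        return pi * high + (1 - pi) * low

    def xi_placenta(size: int) -> np.ndarray:
        low = _beta_draw(meth_rng, config.xi_escape_beta_params, size)
        return np.clip(low - config.placenta_xi_depletion, 0.0, 1.0)

    for k, (cpg_id, chrom, pos, kind, gene) in enumerate(rows):
        if kind == "promoter":
            gi = gene_index[gene]
            m_a[k] = _beta_draw(meth_rng, config.xa_promoter_beta_params, None)
            som = xi_somatic(categories[gi], pi_g[gi], 1)[0]
            pla = xi_placenta(1)[0]
            if config.coupling_mode == "somatic":
                m_i[k] = som
            elif config.coupling_mode == "placenta":
                m_i[k] = pla
            else:
                m_i[k] = config.coupling_rho * som + (1 - config.coupling_rho) * pla
            xa_gene_mean_acc[gene].append(m_a[k])
            xi_gene_mean_acc[gene].append(m_i[k])
        elif kind in ("body", "enhancer"):
            m_a[k] = _beta_draw(meth_rng, config.body_beta_params, None)
            m_i[k] = m_a[k]
        else:  # intergenic / autosomal: trimodal
            mode = meth_rng.choice(3, p=list(config.intergenic_mode_probs))
            m_a[k] = _beta_draw(meth_rng, _MODE_PARAMS[mode], None)
            if kind == "intergenic" and config.coupling_mode != "somatic":
                # placental Xi depletion extends beyond promoters
                shift = config.placenta_xi_depletion if config.coupling_mode == "placenta" else (
                    (1 - config.coupling_rho) * config.placenta_xi_depletion
                )
                m_i[k] = np.clip(
                    _beta_draw(meth_rng, _MODE_PARAMS[mode], None) - shift, 0.0, 1.0
                )
            else:
                m_i[k] = _beta_draw(meth_rng, _MODE_PARAMS[mode], None)

    in_pmd = np.array([ann_by_id[cpg_id].in_pmd for cpg_id, *_ in rows])
    m_a = np.where(in_pmd, np.clip(m_a - config.pmd_hypomethylation, 0, 1), m_a)
    m_i = np.where(in_pmd, np.clip(m_i - config.pmd_hypomethylation, 0, 1), m_i)

    # --- samples --------------------------------------------------------------
    n = config.n_samples_per_sex
    sample_ids = [f"XX{i:03d}" for i in range(n)] + [f"XY{i:03d}" for i in range(n)]
    sexes = np.array(["XX"] * n + ["XY"] * n)
    ga = meta_rng.uniform(*config.ga_range_weeks, size=2 * n)
    cells = meta_rng.dirichlet(config.cell_dirichlet, size=2 * n)
    ancestry = meta_rng.dirichlet((2.0, 2.0, 6.0), size=2 * n)
    bw_z = meta_rng.normal(0.0, 1.0, size=2 * n)

    samples = pd.DataFrame(
        {
            "reported_sex": sexes,
            "sex": sexes,
            "tissue": config.tissue,
            "gestational_age": ga,
            "cohort": config.cohort,
            **{f"prop_{ct}": cells[:, i] for i, ct in enumerate(CELL_TYPES)},
            "ancestry_1": ancestry[:, 0],
            "ancestry_2": ancestry[:, 1],
            "ancestry_3": ancestry[:, 2],
            "birthweight_z": bw_z,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- measurement model ----------------------------------------------------
    base_xx = (m_a + m_i) / 2.0
    base_xy = m_a.copy()
    base = np.where(sexes[None, :] == "XX", base_xx[:, None], base_xy[:, None])

    if config.ga_effect != 0.0:
        ga_centered = ga - ga.mean()
        base = base + config.ga_effect * ga_centered[None, :]

    if config.cell_offset_sd > 0:
        offsets = cell_rng.normal(0.0, config.cell_offset_sd, size=(n_cpgs, len(CELL_TYPES)))
        per_type = np.clip(base[:, :, None] + offsets[:, None, :], 0.0, 1.0)
        beta_vals = np.einsum("csk,sk->cs", per_type, cells)
    else:
        beta_vals = np.clip(base, 0.0, 1.0)

    if config.noise_sd > 0:
        beta_vals = beta_vals + noise_rng.normal(0.0, config.noise_sd, size=beta_vals.shape)
    beta_vals = np.clip(beta_vals, 0.0, 1.0)
    beta = pd.DataFrame(beta_vals, index=[r[0] for r in rows], columns=sample_ids)
    beta.index.name = "cpg_id"

    # --- allele balance (XX samples) -------------------------------------------
    xx_ids = sample_ids[:n]
    ab_vals = np.full((config.n_genes, n), np.nan)
    for gi, gene in enumerate(genes):
        cat = categories[gi]
        subject_like = (
            np.ones(n, dtype=bool)
            if cat == "subject"
            else np.zeros(n, dtype=bool)
            if cat == "escape"
            else ab_rng.random(n) < pi_g[gi]
        )
        draws_sub = 0.5 + 0.5 * _beta_draw(ab_rng, config.ab_subject_params, n)
        draws_esc = 0.5 + 0.5 * _beta_draw(ab_rng, config.ab_escape_params, n)
        balances = np.where(subject_like, draws_sub, draws_esc)
        informative = ab_rng.random(n) < config.informative_rate
        ab_vals[gi, informative] = balances[informative]
    allele_balance = pd.DataFrame(ab_vals, index=pd.Index(genes, name="gene_id"), columns=xx_ids)

    gene_truth = pd.DataFrame(
        {
            "gene_id": genes,
            "category": categories,
            "propensity": [
                _prop_subject_propensity(config, categories[i], pi_g[i])
                for i in range(config.n_genes)
            ],
            "variable_pi": pi_g,
            "xa_mean": [float(np.mean(xa_gene_mean_acc[g])) if xa_gene_mean_acc[g] else np.nan for g in genes],
            "xi_mean": [float(np.mean(xi_gene_mean_acc[g])) if xi_gene_mean_acc[g] else np.nan for g in genes],
        }
    )
    cpg_truth = pd.DataFrame(
        {
            "cpg_id": [r[0] for r in rows],
            "chrom": [r[1] for r in rows],
            "pos": [r[2] for r in rows],
            "kind": [r[3] for r in rows],
            "gene_id": [r[4] for r in rows],
            "in_pmd": in_pmd,
        }
    )
    truth = GroundTruth(
        genes=gene_truth,
        cpgs=cpg_truth,
        samples=samples[["sex", "gestational_age"] + [f"prop_{ct}" for ct in CELL_TYPES]].copy(),
        coupling_mode=config.coupling_mode,
        seed=config.seed,
    )
    return SimResult(
        beta=beta,
        samples=samples,
        annotations=annotations,
        allele_balance=allele_balance,
        ground_truth=truth,
        tracks=tracks,
        tss=tss,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# fixture export


def _write_bed(path: Path, intervals) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _write_named_bed(path: Path, pairs) -> None:
    with open(path, "w") as fh:
        for iv, name in pairs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def export_fixture(config: SimConfig, outdir: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write a simulated study to disk in the pipeline's input formats.

    Emits the beta matrix, all-pass QC matrices, sample sheet,
    annotation tracks (PLS / pELS / gene bodies / CGI / PMD / repeats),
    the TSS table, the probe manifest, the allele-balance matrix and a
    ground-truth JSON. Re-running with the same config is
    byte-identical. Refuses to write into an existing non-empty
    directory unless ``overwrite`` is set.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty (pass overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    sim = simulate_study(config)
    paths: dict[str, Path] = {}

    def reg(name: str, filename: str) -> Path:
        paths[name] = outdir / filename
        return paths[name]

    sim.beta.to_csv(reg("beta", "beta.tsv"), sep="\t", float_format="%.6f")
    det = pd.DataFrame(0.0, index=sim.beta.index, columns=sim.beta.columns)
    det.to_csv(reg("detection_p", "detection_p.tsv"), sep="\t", float_format="%.2f")
    beads = pd.DataFrame(10, index=sim.beta.index, columns=sim.beta.columns)
    beads.to_csv(reg("bead_count", "bead_count.tsv"), sep="\t")
    sim.samples.reset_index().to_csv(reg("sample_sheet", "sample_sheet.csv"), index=False, float_format="%.6f")

    with open(reg("manifest", "manifest.tsv"), "w") as fh:
        fh.write("cpg_id\tchrom\tpos\n")
        for cpg_id, chrom, pos1 in sim.manifest:
            fh.write(f"{cpg_id}\t{chrom}\t{pos1}\n")

    _, tracks, tss, pls, pels = _layout(config)
    _write_bed(reg("pls", "pls.bed"), pls)
    if pels:
        _write_bed(reg("pels", "pels.bed"), pels)
    _write_named_bed(reg("gene_bodies", "gene_bodies.bed"), tracks.bodies)
    with open(reg("cgi", "cgi.bed"), "w") as fh:
        for c in tracks.cgis:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.length_bp}\t{c.gc_fraction:.4f}\t{c.obs_exp_ratio:.4f}\n"
            )
    _write_bed(reg("pmd", "pmd.bed"), tracks.pmds)
    _write_bed(reg("line1", "line1.bed"), tracks.line1)
    _write_bed(reg("sine", "sine.bed"), tracks.sine)
    with open(reg("tss", "tss.tsv"), "w") as fh:
        fh.write("gene_id\tchrom\tpos\tstrand\n")
        for t in tss:
            fh.write(f"{t.gene_id}\t{t.chrom}\t{t.pos}\t{t.strand}\n")

    sim.allele_balance.to_csv(reg("allele_balance", "allele_balance.tsv"), sep="\t", float_format="%.6f")

    truth = {
        "coupling_mode": sim.ground_truth.coupling_mode,
        "seed": sim.ground_truth.seed,
        "config": dataclasses.asdict(config),
        "genes": sim.ground_truth.genes.to_dict(orient="records"),
        "samples": sim.ground_truth.samples.reset_index().to_dict(orient="records"),
    }
    with open(reg("ground_truth", "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1, default=float)
    with open(reg("config", "config.json"), "w") as fh:
        json.dump(dataclasses.asdict(config), fh, sort_keys=True, indent=1)
    return paths


def config_hash(config: SimConfig) -> str:
    """Stable short hash of a configuration, for output provenance lines."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
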