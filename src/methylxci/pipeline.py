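"""Command-line orchestration of the analysis stages.

Stages run in a fixed order (annotate -> qc -> summarize -> xci ->
stats -> windows), each re-runnable from its on-disk inputs. Every
output table carries '#'-prefixed header lines with the package
version, a config hash and the seed; a JSON run manifest records all
thresholds used and the CpG / gene counts at each filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from methylxci import annotation as ann
from methylxci import io as mio
from methylxci import preprocessing as prep
from methylxci import stats as mstats
from methylxci import xci as mxci

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "select_differential_windows", "run_pipeline", "cli"]

WINDOW_DELTA_THRESHOLD = 0.20
WINDOW_WIDTH = 100


@dataclass
class RunConfig:
    """Paths, thresholds and toggles for a pipeline run."""

    beta: str
    sample_sheet: str
    manifest: str
    tss: str
    outdir: str
    detection_p: str | None = None
    bead_count: str | None = None
    pls: str | None = None
    pels: str | None = None
    gene_bodies: str | None = None
    cgi: str | None = None
    pmd: str | None = None
    line1: str | None = None
    sine: str | None = None
    allele_balance: str | None = None
    mask_list: str | None = None  # one probe id per line
    seed: int = 0
    frac_threshold: float = 0.05
    effect_threshold: float = 0.03
    min_informative: int = 5
    window_delta_threshold: float = WINDOW_DELTA_THRESHOLD
    chrom_x: str = "chrX"
    ga_adjustment: list[str] = field(default_factory=lambda: ["ancestry_1", "ancestry_2"])
    pcpr2_covariates: list[str] = field(default_factory=lambda: ["gestational_age", "prop_syncytiotrophoblast"])
    pc_variables: list[str] = field(
        default_factory=lambda: [
            "gestational_age",
            "birthweight_z",
            "cohort",
            "prop_nrbc",
            "prop_hofbauer",
            "prop_endothelial",
            "prop_stromal",
            "prop_cytotrophoblast",
            "prop_syncytiotrophoblast",
            "ancestry_1",
            "ancestry_2",
            "ancestry_3",
        ]
    )
    tissue_group_a: str | None = None  # "somatic" side of the window export
    tissue_group_b: str | None = None  # "placenta" side
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def validate(self) -> None:
        for name in ("beta", "sample_sheet", "manifest", "tss"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")
        for name in (
            "detection_p", "bead_count", "pls", "pels", "gene_bodies", "cgi",
            "pmd", "line1", "sine", "allele_balance", "mask_list",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")
        if not (0 <= self.frac_threshold <= 1):
            raise ValueError("frac_threshold must lie in [0, 1]")
        if self.effect_threshold < 0:
            raise ValueError("effect_threshold must be nonnegative")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(config: RunConfig) -> list[str]:
    from methylxci import __version__

    return [
        f"methylxci {__version__}",
        f"config_hash {config.hash()}",
        f"seed {config.seed}",
    ]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.8g")


def _read_manifest(path: str | Path) -> list[tuple[str, str, int]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [(str(r.cpg_id), str(r.chrom), int(r.pos)) for r in df.itertuples(index=False)]


def _load_tracks(config: RunConfig) -> tuple[ann.AnnotationTracks, list[ann.TSSRecord]]:
    tss = ann.read_tss_table(config.tss)
    promoters = ann.assign_promoters(ann.read_bed(config.pls), tss) if config.pls else []
    enhancers = ann.assign_enhancers(ann.read_bed(config.pels), tss) if config.pels else []
    tracks = ann.AnnotationTracks(
        promoters=promoters,
        enhancers=enhancers,
        bodies=ann.read_named_bed(config.gene_bodies) if config.gene_bodies else [],
        cgis=ann.read_cgi_bed(config.cgi) if config.cgi else [],
        pmds=ann.read_bed(config.pmd) if config.pmd else [],
        line1=ann.read_bed(config.line1) if config.line1 else [],
        sine=ann.read_bed(config.sine) if config.sine else [],
    )
    return tracks, tss


# ---------------------------------------------------------------------------
# stages


def stage_annotate(config: RunConfig, outdir: Path) -> pd.DataFrame:
    manifest = _read_manifest(config.manifest)
    tracks, tss = _load_tracks(config)
    annotations = ann.annotate_cpgs(manifest, tracks, tss)
    table = ann.annotations_to_frame(annotations)
    _write_table(table, outdir / "annotation.tsv", config)
    return table


def stage_qc(config: RunConfig, outdir: Path) -> pd.DataFrame:
    beta = mio.read_beta_matrix(config.beta)
    if config.detection_p and config.bead_count:
        qc = prep.ProbeQC(
            detection_p=mio.read_matrix_tsv(config.detection_p),
            bead_count=mio.read_matrix_tsv(config.bead_count),
        )
        mask: set[str] = set()
        if config.mask_list:
            mask = {line.strip() for line in open(config.mask_list) if line.strip()}
        retained = prep.filter_probes(beta, qc, mask_list=mask, frac_threshold=config.frac_threshold)
        beta = beta.loc[retained]
    mio.write_matrix_tsv(beta, outdir / "beta_filtered.tsv", _header_lines(config))
    return beta


def stage_summarize(
    config: RunConfig, outdir: Path, beta: pd.DataFrame, ann_table: pd.DataFrame, samples: pd.DataFrame
) -> prep.RegionSummaryResult:
    annotations = ann.annotations_from_frame(ann_table)
    regions = []
    for kind in ("promoter", "gene_body", "enhancer", "tss_window"):
        regions.extend(prep.regions_from_annotations(annotations, kind))
    result = prep.region_mean_beta(beta, regions, samples)
    _write_table(result.summary, outdir / "region_summary.tsv", config)
    _write_table(result.sample_means.rename_axis("region_id"), outdir / "region_sample_means.tsv", config, index=True)
    strat = prep.stratified_mean_beta(beta, annotations, chrom_x=config.chrom_x)
    _write_table(strat, outdir / "stratified_means.tsv", config)
    return result


def stage_xci(config: RunConfig, outdir: Path, summary: pd.DataFrame) -> None:
    if not config.allele_balance:
        logger.info("xci stage skipped: no allele-balance matrix configured")
        return
    ab = mio.read_allele_balance(config.allele_balance)
    thresholds = mxci.XCIThresholds(min_informative=config.min_informative)
    calls = mxci.call_xci(ab, thresholds)
    _write_table(calls.reset_index(), outdir / "xci_calls.tsv", config)
    promoters = summary[summary["region_kind"] == "promoter"]
    if len(promoters) >= 3:
        battery = mxci.correlation_battery(promoters, calls)
        _write_table(battery, outdir / "xci_correlation_battery.tsv", config)
        comp = mxci.compare_categories(promoters, calls)
        if len(comp["pairwise"]):
            _write_table(comp["pairwise"], outdir / "xci_category_tests.tsv", config)
        _write_table(comp["category_means"].reset_index(), outdir / "xci_category_means.tsv", config)
    with open(outdir / "xci_thresholds.json", "w") as fh:
        json.dump(dataclasses.asdict(thresholds), fh, sort_keys=True, indent=1)


def stage_stats(
    config: RunConfig, outdir: Path, beta: pd.DataFrame, ann_table: pd.DataFrame, samples: pd.DataFrame
) -> None:
    x_cpgs = ann_table.loc[ann_table["chrom"] == config.chrom_x, "cpg_id"]
    beta_x = beta.loc[beta.index.intersection(x_cpgs)]
    for sex in ("XX", "XY"):
        sel = samples.index[samples["reported_sex"] == sex]
        sel = [s for s in sel if s in beta.columns]
        if len(sel) < 3:
            logger.info("stats stage: skipping %s (n=%d < 3)", sex, len(sel))
            continue
        sub = beta_x[sel]
        pca = mstats.pca_scaled(sub)
        _write_table(
            pca.standardized_scores.rename_axis("sample_id"),
            outdir / f"pca_scores_{sex}.tsv",
            config,
            index=True,
        )
        assoc = mstats.pc_association(pca, samples.loc[sel], config.pc_variables)
        if len(assoc):
            _write_table(assoc, outdir / f"pc_association_{sex}.tsv", config)
        covs = samples.loc[sel, config.pcpr2_covariates]
        nonconstant = [c for c in covs.columns if covs[c].nunique(dropna=True) > 1]
        if len(nonconstant) >= 2 and covs[nonconstant].notna().all().all():
            r = mstats.pcpr2(sub, covs[nonconstant])
            _write_table(
                r.partial_r2_pct.rename("partial_r2_pct").rename_axis("covariate").reset_index(),
                outdir / f"pcpr2_{sex}.tsv",
                config,
            )
        else:
            logger.info("stats stage: pcpr2 skipped for %s (constant/missing covariates)", sex)
        if samples.loc[sel, "gestational_age"].nunique() >= 3:
            model = mstats.cpg_linear_model(
                sub,
                samples.loc[sel],
                predictor="gestational_age",
                adjustment=config.ga_adjustment,
                effect_threshold=config.effect_threshold,
            )
            _write_table(model.reset_index(), outdir / f"ga_model_{sex}.tsv", config)


def select_differential_windows(
    delta: pd.DataFrame,
    threshold: float = WINDOW_DELTA_THRESHOLD,
    width: int = WINDOW_WIDTH,
    genome=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit fixed-width windows around CpGs with a large group difference.

    ``delta`` has columns cpg_id, chrom, pos (0-based) and delta_beta
    (group A minus group B means). CpGs with delta_beta strictly above
    ``threshold`` yield a window of total ``width`` bp centred on the
    CpG ([pos - width/2, pos + width/2)), clipped to 0 at the
    chromosome start with a flag. Returns (windows, background) where
    the background covers every processed CpG, for external motif
    enrichment tools. When ``genome`` (a pyfaidx.Fasta-like mapping) is
    given, windows gain an upper-case ``sequence`` column and an
    ``has_n`` flag.
    """
    half = width // 2
    rows = []
    for r in delta.itertuples(index=False):
        if not np.isfinite(r.delta_beta) or r.delta_beta <= threshold:
            continue
        start = r.pos - half
        clipped = start < 0
        rows.append(
            {
                "chrom": r.chrom,
                "start": max(start, 0),
                "end": r.pos + half,
                "cpg_id": r.cpg_id,
                "delta_beta": r.delta_beta,
                "clipped": clipped,
            }
        )
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "cpg_id", "delta_beta", "clipped"])
    background = pd.DataFrame(
        {
            "chrom": delta["chrom"],
            "start": (delta["pos"] - half).clip(lower=0),
            "end": delta["pos"] + half,
            "cpg_id": delta["cpg_id"],
        }
    )
    if genome is not None and len(windows):
        seqs = [str(genome[c][s:e]).upper() for c, s, e in zip(windows["chrom"], windows["start"], windows["end"])]
        windows["sequence"] = seqs
        windows["has_n"] = ["N" in s for s in seqs]
    return windows, background


def stage_windows(
    config: RunConfig, outdir: Path, beta: pd.DataFrame, ann_table: pd.DataFrame, samples: pd.DataFrame
) -> None:
    if not (config.tissue_group_a and config.tissue_group_b):
        logger.info("windows stage skipped: tissue groups not configured")
        return
    a = samples.index[samples["tissue"] == config.tissue_group_a]
    b = samples.index[samples["tissue"] == config.tissue_group_b]
    a = [s for s in a if s in beta.columns]
    b = [s for s in b if s in beta.columns]
    if not a or not b:
        logger.info("windows stage skipped: empty tissue group")
        return
    pos = ann_table.set_index("cpg_id")
    shared = beta.index.intersection(pos.index)
    delta = pd.DataFrame(
        {
            "cpg_id": shared,
            "chrom": pos.loc[shared, "chrom"].to_numpy(),
            "pos": pos.loc[shared, "pos"].to_numpy(),
            "delta_beta": (beta.loc[shared, a].mean(axis=1) - beta.loc[shared, b].mean(axis=1)).to_numpy(),
        }
    )
    windows, background = select_differential_windows(delta, threshold=config.window_delta_threshold)
    _write_table(windows, outdir / "differential_windows.bed.tsv", config)
    _write_table(background, outdir / "background_windows.bed.tsv", config)


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages in order; returns the output directory.

    Any stage error aborts with the failing stage named. The run
    manifest (JSON) lists every threshold used and the CpG / gene
    counts after each filter.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage = "annotate"
    try:
        ann_table = stage_annotate(config, outdir)
        counts["cpgs_annotated"] = len(ann_table)
        stage = "qc"
        beta = stage_qc(config, outdir)
        counts["probes_retained"] = beta.shape[0]
        samples = mio.read_sample_sheet(config.sample_sheet)
        samples = samples.loc[[s for s in samples.index if s in beta.columns]]
        counts["samples"] = len(samples)
        stage = "summarize"
        summaries = stage_summarize(config, outdir, beta, ann_table, samples)
        counts["regions_summarized"] = len(summaries.summary)
        stage = "xci"
        stage_xci(config, outdir, summaries.summary)
        stage = "stats"
        stage_stats(config, outdir, beta, ann_table, samples)
        stage = "windows"
        stage_windows(config, outdir, beta, ann_table, samples)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "counts": counts,
        "thresholds": {
            "detection_p": prep.DETECTION_P_THRESHOLD,
            "min_bead_count": prep.MIN_BEAD_COUNT,
            "frac_threshold": config.frac_threshold,
            "effect_threshold": config.effect_threshold,
            "min_informative": config.min_informative,
            "window_delta_threshold": config.window_delta_threshold,
            "xy_high_beta": mxci.XY_HIGH_BETA,
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return outdir


# ---------------------------------------------------------------------------
# CLI


@click.group()
def cli() -> None:
    """X-chromosome methylation / XCI analysis pipeline."""


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None, help="SimConfig JSON")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--outdir", type=click.Path(), required=True)
@click.option("--overwrite", is_flag=True)
def simulate(config_path, seed, outdir, overwrite):
    """Generate a synthetic study fixture on disk."""
    from methylxci.synthetic_data import SimConfig, export_fixture

    if config_path:
        with open(config_path) as fh:
            payload = json.load(fh)
        payload.setdefault("seed", seed)
        payload = {k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()}
        sim_config = SimConfig(**payload)
    else:
        sim_config = SimConfig(seed=seed)
    paths = export_fixture(sim_config, outdir, overwrite=overwrite)
    click.echo(f"wrote {len(paths)} files to {outdir}")


def _run_stages(config_path: str, stages: list[str]) -> None:
    config = RunConfig.from_json(config_path)
    if stages == ["all"]:
        run_pipeline(config)
        return
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann_table = beta = samples = summary = None

    def need_ann():
        nonlocal ann_table
        if ann_table is None:
            path = outdir / "annotation.tsv"
            ann_table = pd.read_csv(path, sep="\t", comment="#") if path.exists() else stage_annotate(config, outdir)
        return ann_table

    def need_beta():
        nonlocal beta
        if beta is None:
            path = outdir / "beta_filtered.tsv"
            beta = mio.read_beta_matrix(path) if path.exists() else stage_qc(config, outdir)
        return beta

    def need_samples():
        nonlocal samples
        if samples is None:
            samples = mio.read_sample_sheet(config.sample_sheet)
            samples = samples.loc[[s for s in samples.index if s in need_beta().columns]]
        return samples

    for stage in stages:
        if stage == "annotate":
            ann_table = stage_annotate(config, outdir)
        elif stage == "qc":
            beta = stage_qc(config, outdir)
        elif stage == "summarize":
            summary = stage_summarize(config, outdir, need_beta(), need_ann(), need_samples())
        elif stage == "xci":
            if summary is None:
                path = outdir / "region_summary.tsv"
                if path.exists():
                    stage_xci(config, outdir, pd.read_csv(path, sep="\t", comment="#"))
                    continue
                summary = stage_summarize(config, outdir, need_beta(), need_ann(), need_samples())
            stage_xci(config, outdir, summary.summary)
        elif stage == "stats":
            stage_stats(config, outdir, need_beta(), need_ann(), need_samples())
        elif stage == "windows":
            stage_windows(config, outdir, need_beta(), need_ann(), need_samples())
        else:
            raise click.ClickException(f"unknown stage {stage}")


def _stage_command(name: str, help_text: str):
    @cli.command(name=name, help=help_text)
    @click.option("--config", "config_path", type=click.Path(exists=True), required=True, help="RunConfig JSON")
    def _cmd(config_path):
        _run_stages(config_path, [name])

    return _cmd


_stage_command("annotate", "Annotate manifest CpGs with genomic context.")
_stage_command("qc", "Filter probes by detection p / bead count / missingness.")
_stage_command("summarize", "Region-level and stratified methylation summaries.")
_stage_command("xci", "XCI calls and the DNAme-XCI correlation battery.")
_stage_command("stats", "PCA, PC associations, PC-PR2 and gestational-age models.")
_stage_command("windows", "Export differential-methylation windows for motif tools.")


@cli.command(name="run-all")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True, help="RunConfig JSON")
def run_all(config_path):
    """Run every stage in order with a run manifest."""
    outdir = run_pipeline(RunConfig.from_json(config_path))
    click.echo(f"pipeline outputs in {outdir}")


if __name__ == "__main__":
    cli()
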