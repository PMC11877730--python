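"""Genomic annotation of array CpGs.

Assigns every CpG its functional context: ENCODE promoter-like (PLS)
and proximal enhancer-like (pELS) elements linked to genes via
transcription start sites (TSS), gene bodies, strand-aware TSS windows
(TSS200 / TSS200-1500), CpG-island density class (high / intermediate
density by the Weber length / GC / observed-expected criteria),
partially methylated domains (PMDs), and LINE-1 / SINE repeats.

All internal coordinates are 0-based half-open. BED input is taken
verbatim; array manifests are 1-based and shifted by -1 on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "TSSRecord",
    "CGIRecord",
    "CpGAnnotation",
    "AnnotationTracks",
    "read_bed",
    "read_named_bed",
    "read_cgi_bed",
    "read_tss_table",
    "assign_promoters",
    "assign_enhancers",
    "classify_cgi",
    "tss_window_label",
    "annotate_cpgs",
]

# ENCODE pairing distances (bp)
PROMOTER_TSS_WINDOW = 200
ENHANCER_TSS_WINDOW = 2000

# strand-aware upstream bands relative to the TSS (bp)
TSS200_BAND = (1, 200)
TSS1500_BAND = (201, 1500)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site (0-based position) with strand."""

    gene_id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("TSS position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class CGIRecord:
    """A CpG island with the sequence statistics used for density classing."""

    interval: GenomicInterval
    length_bp: int
    gc_fraction: float
    obs_exp_ratio: float
    density_class: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "density_class",
            classify_cgi(self.length_bp, self.gc_fraction, self.obs_exp_ratio),
        )


@dataclass
class CpGAnnotation:
    """Per-CpG functional context flags and linked gene ids."""

    cpg_id: str
    chrom: str
    pos: int  # 0-based
    promoter_genes: set[str] = field(default_factory=set)
    enhancer_genes: set[str] = field(default_factory=set)
    body_genes: set[str] = field(default_factory=set)
    tss_window: str = "none"  # TSS200 | TSS200_1500 | none
    cgi_class: str = "none"  # HC | IC | none
    in_pmd: bool = False
    in_line1: bool = False
    in_sine: bool = False


@dataclass
class AnnotationTracks:
    """The input tracks consumed by :func:`annotate_cpgs`.

    ``promoters`` and ``enhancers`` are (element interval, gene_id)
    pairs as produced by :func:`assign_promoters` /
    :func:`assign_enhancers`; ``bodies`` are (gene-body interval,
    gene_id) pairs.
    """

    promoters: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    enhancers: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    bodies: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    cgis: list[CGIRecord] = field(default_factory=list)
    pmds: list[GenomicInterval] = field(default_factory=list)
    line1: list[GenomicInterval] = field(default_factory=list)
    sine: list[GenomicInterval] = field(default_factory=list)


class BedParseError(ValueError):
    """Raised on a malformed BED line; message names the line number."""


def _parse_bed_line(line: str, lineno: int, path: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
    return fields


def _bed_interval(fields: list[str], lineno: int, path: str) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
    try:
        return GenomicInterval(fields[0], start, end, strand)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: {exc}") from exc


def _iter_bed(path: str | Path):
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, _parse_bed_line(line, lineno, str(path))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a >=3 column BED file into intervals, preserving input order."""
    return [_bed_interval(f, n, str(path)) for n, f in _iter_bed(path)]


def read_named_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read a BED file whose 4th column carries a name (e.g. a gene id)."""
    out = []
    for lineno, fields in _iter_bed(path):
        if len(fields) < 4:
            raise BedParseError(f"{path}:{lineno}: named BED needs >=4 columns")
        out.append((_bed_interval(fields, lineno, str(path)), fields[3]))
    return out


def read_cgi_bed(path: str | Path) -> list[CGIRecord]:
    """Read a CpG-island BED carrying length / GC fraction / obs-exp ratio.

    Columns 4-6 hold the island length in bp, GC fraction in [0,1] and
    the observed/expected CpG ratio; when absent, the length is taken
    from the coordinates and GC / obs-exp must be supplied elsewhere.
    """
    out = []
    for lineno, fields in _iter_bed(path):
        iv = _bed_interval(fields, lineno, str(path))
        if len(fields) >= 6:
            try:
                length = int(fields[3])
                gc = float(fields[4])
                ratio = float(fields[5])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: CGI columns 4-6 must be numeric"
                ) from exc
        else:
            raise BedParseError(
                f"{path}:{lineno}: CGI BED requires length/GC/obs-exp in columns 4-6"
            )
        out.append(CGIRecord(iv, length, gc, ratio))
    return out


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a TSV of TSS records: gene_id, chrom, pos (0-based), strand."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:1] == ["gene_id"]:
                continue
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            out.append(TSSRecord(fields[0], fields[1], int(fields[2]), fields[3]))
    return out


def _overlaps_closed_window(iv: GenomicInterval, lo: int, hi: int) -> bool:
    # interval [start, end) vs closed window [lo, hi]
    return iv.start <= hi and iv.end > lo


def assign_promoters(
    pls: Sequence[GenomicInterval], tss: Sequence[TSSRecord]
) -> list[tuple[GenomicInterval, str]]:
    """Pair promoter-like elements with genes whose TSS lies within 200 bp.

    A (PLS, gene) pair is emitted iff the PLS interval overlaps the
    closed window [TSS - 200, TSS + 200] on the same chromosome. One
    element may pair with many genes and vice versa; output is
    deduplicated and sorted for determinism.
    """
    by_chrom: dict[str, list[TSSRecord]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    pairs: set[tuple[GenomicInterval, str]] = set()
    for iv in pls:
        for t in by_chrom.get(iv.chrom, ()):
            if _overlaps_closed_window(
                iv, t.pos - PROMOTER_TSS_WINDOW, t.pos + PROMOTER_TSS_WINDOW
            ):
                pairs.add((iv, t.gene_id))
    return sorted(pairs, key=lambda p: (p[0].chrom, p[0].start, p[0].end, p[1]))


def assign_enhancers(
    pels: Sequence[GenomicInterval], tss: Sequence[TSSRecord]
) -> list[tuple[GenomicInterval, str]]:
    """Pair enhancer-like elements with genes whose TSS is within 2 kb.

    A (pELS, gene) pair is emitted iff the TSS position lies in
    [pels.start - 2000, pels.end + 2000) — half-open on the right for
    determinism at the boundary.
    """
    by_chrom: dict[str, list[TSSRecord]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    pairs: set[tuple[GenomicInterval, str]] = set()
    for iv in pels:
        for t in by_chrom.get(iv.chrom, ()):
            if iv.start - ENHANCER_TSS_WINDOW <= t.pos < iv.end + ENHANCER_TSS_WINDOW:
                pairs.add((iv, t.gene_id))
    return sorted(pairs, key=lambda p: (p[0].chrom, p[0].start, p[0].end, p[1]))


def classify_cgi(length_bp: int, gc_fraction: float, obs_exp_ratio: float) -> str:
    """Classify a CpG island by density: ``HC``, ``IC`` or ``none``.

    High-density (HC): length > 500 bp, GC > 0.55 and observed/expected
    CpG ratio > 0.75. Intermediate-density (IC): length > 200 bp,
    GC > 0.50 and obs/exp > 0.48. All comparisons strict; HC is tested
    first (every HC island also satisfies the IC clauses).
    """
    if length_bp < 0:
        raise ValueError("length_bp must be nonnegative")
    if length_bp > 500 and gc_fraction > 0.55 and obs_exp_ratio > 0.75:
        return "HC"
    if length_bp > 200 and gc_fraction > 0.50 and obs_exp_ratio > 0.48:
        return "IC"
    return "none"


def _upstream_distance(cpg_pos: int, t: TSSRecord) -> int:
    """Distance from a CpG to the TSS, positive when upstream of it."""
    return t.pos - cpg_pos if t.strand == "+" else cpg_pos - t.pos


def tss_window_label(
    cpg_pos: int, tss: Sequence[TSSRecord], chrom: str | None = None
) -> str:
    """Label a CpG by its strand-aware upstream TSS band.

    TSS200 covers the 200 bp immediately upstream of a TSS (for a +
    strand TSS at t, positions [t-200, t); mirrored for - strand);
    TSS200-1500 covers the band from 1500 to 200 bp upstream. A CpG in
    the TSS200 of any gene is labelled TSS200 (the closer band wins);
    otherwise TSS200_1500 if in that band of any gene; else ``none``.
    """
    label = "none"
    for t in tss:
        if chrom is not None and t.chrom != chrom:
            continue
        d = _upstream_distance(cpg_pos, t)
        if TSS200_BAND[0] <= d <= TSS200_BAND[1]:
            return "TSS200"
        if TSS1500_BAND[0] <= d <= TSS1500_BAND[1]:
            label = "TSS200_1500"
    return label


def _tree(intervals: Iterable[tuple[GenomicInterval, object]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
    return trees


def _hits(trees: dict[str, IntervalTree], chrom: str, pos: int) -> list:
    tree = trees.get(chrom)
    if tree is None:
        return []
    return [h.data for h in tree.at(pos)]


def annotate_cpgs(
    manifest: Sequence[tuple[str, str, int]],
    tracks: AnnotationTracks,
    tss: Sequence[TSSRecord],
) -> list[CpGAnnotation]:
    """Annotate every manifest CpG with its full genomic context.

    ``manifest`` rows are (cpg_id, chrom, 1-based position) following
    the array-manifest convention; positions are shifted to 0-based
    internally. Membership is point-in-interval on the half-open
    convention. Every manifest CpG yields exactly one record; a CpG on
    a chromosome absent from all tracks gets an all-empty context.
    """
    seen: set[str] = set()
    for cpg_id, _, _ in manifest:
        if cpg_id in seen:
            raise ValueError(f"duplicate cpg_id in manifest: {cpg_id}")
        seen.add(cpg_id)

    prom_trees = _tree(tracks.promoters)
    enh_trees = _tree(tracks.enhancers)
    body_trees = _tree(tracks.bodies)
    cgi_trees = _tree((c.interval, c) for c in tracks.cgis)
    pmd_trees = _tree((iv, True) for iv in tracks.pmds)
    line1_trees = _tree((iv, True) for iv in tracks.line1)
    sine_trees = _tree((iv, True) for iv in tracks.sine)
    tss_by_chrom: dict[str, list[TSSRecord]] = {}
    for t in tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t)

    records = []
    for cpg_id, chrom, pos1 in manifest:
        pos = pos1 - 1
        cgi_hits = _hits(cgi_trees, chrom, pos)
        cgi_class = "none"
        for c in cgi_hits:
            if c.density_class == "HC":
                cgi_class = "HC"
                break
            if c.density_class == "IC":
                cgi_class = "IC"
        records.append(
            CpGAnnotation(
                cpg_id=cpg_id,
                chrom=chrom,
                pos=pos,
                promoter_genes=set(_hits(prom_trees, chrom, pos)),
                enhancer_genes=set(_hits(enh_trees, chrom, pos)),
                body_genes=set(_hits(body_trees, chrom, pos)),
                tss_window=tss_window_label(pos, tss_by_chrom.get(chrom, ())),
                cgi_class=cgi_class,
                in_pmd=bool(_hits(pmd_trees, chrom, pos)),
                in_line1=bool(_hits(line1_trees, chrom, pos)),
                in_sine=bool(_hits(sine_trees, chrom, pos)),
            )
        )
    return records


def annotations_to_frame(annotations: Sequence[CpGAnnotation]):
    """Flatten annotation records to a DataFrame (sets joined with ';')."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cpg_id": [a.cpg_id for a in annotations],
            "chrom": [a.chrom for a in annotations],
            "pos": [a.pos for a in annotations],
            "promoter_genes": [";".join(sorted(a.promoter_genes)) for a in annotations],
            "enhancer_genes": [";".join(sorted(a.enhancer_genes)) for a in annotations],
            "body_genes": [";".join(sorted(a.body_genes)) for a in annotations],
            "tss_window": [a.tss_window for a in annotations],
            "cgi_class": [a.cgi_class for a in annotations],
            "in_pmd": [a.in_pmd for a in annotations],
            "in_line1": [a.in_line1 for a in annotations],
            "in_sine": [a.in_sine for a in annotations],
        }
    )


def annotations_from_frame(df) -> list[CpGAnnotation]:
    """Rebuild annotation records from a flattened annotation table."""

    def split(s: object) -> set[str]:
        if s is None or (isinstance(s, float)) or not str(s) or str(s) == "nan":
            return set()
        return set(str(s).split(";"))

    return [
        CpGAnnotation(
            cpg_id=str(row.cpg_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            promoter_genes=split(row.promoter_genes),
            enhancer_genes=split(row.enhancer_genes),
            body_genes=split(row.body_genes),
            tss_window=str(row.tss_window),
            cgi_class=str(row.cgi_class),
            in_pmd=bool(row.in_pmd),
            in_line1=bool(row.in_line1),
            in_sine=bool(row.in_sine),
        )
        for row in df.itertuples(index=False)
    ]
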