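"""Readers and writers for the tabular formats used across the package.

Beta-value and QC matrices are TSV with probes as rows and a header row
of sample ids; sample sheets are CSV keyed by ``sample_id``; allele
balance matrices are TSV with genes as rows. Output tables may carry
'#'-prefixed metadata header lines, which all readers skip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "reported_sex",
    "tissue",
    "gestational_age",
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
    "birthweight_z",
]

CELL_TYPES = [
    "nrbc",
    "hofbauer",
    "endothelial",
    "stromal",
    "cytotrophoblast",
    "syncytiotrophoblast",
]


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probes/genes x samples TSV matrix (index in column 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a beta matrix and validate that values lie in [0, 1]."""
    beta = read_matrix_tsv(path)
    vals = beta.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise ValueError(f"{path}: beta values outside [0, 1]")
    if beta.index.duplicated().any():
        raise ValueError(f"{path}: duplicate probe ids")
    if beta.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return beta.astype(float)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a CSV sample sheet indexed by sample_id; validates proportions.

    Cell-type proportions, when all present for a sample, must each lie
    in [0, 1] and sum to 1 within 0.05; ancestry coordinates must sum
    to 1 within 0.01.
    """
    df = pd.read_csv(path, comment="#")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: sample sheet requires a sample_id column")
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    prop_cols = [f"prop_{ct}" for ct in CELL_TYPES if f"prop_{ct}" in df.columns]
    if len(prop_cols) == len(CELL_TYPES):
        props = df[prop_cols].astype(float)
        complete = props.notna().all(axis=1)
        if ((props[complete] < 0) | (props[complete] > 1)).any().any():
            raise ValueError(f"{path}: cell proportions outside [0, 1]")
        sums = props[complete].sum(axis=1)
        if ((sums < 0.95) | (sums > 1.05)).any():
            bad = sums[(sums < 0.95) | (sums > 1.05)].index.tolist()
            raise ValueError(f"{path}: cell proportions do not sum to 1: {bad}")
    anc_cols = [c for c in ("ancestry_1", "ancestry_2", "ancestry_3") if c in df.columns]
    if len(anc_cols) == 3:
        anc = df[anc_cols].astype(float)
        complete = anc.notna().all(axis=1)
        sums = anc[complete].sum(axis=1)
        if ((sums - 1.0).abs() > 0.01 + 1e-9).any():
            raise ValueError(f"{path}: ancestry coordinates do not sum to 1")
    return df


def read_allele_balance(path: str | Path, fold: bool = True) -> pd.DataFrame:
    """Read a gene x sample allele-balance TSV.

    Balances are folded to ``max(b, 1-b)`` on ingest so matrices on the
    raw [0, 1] scale are accepted; thresholds downstream are stated on
    the folded (skew) scale [0.5, 1].
    """
    ab = read_matrix_tsv(path).astype(float)
    vals = ab.to_numpy()
    finite = vals[np.isfinite(vals)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise ValueError(f"{path}: allele balances outside [0, 1]")
    if fold:
        ab = fold_allele_balance(ab)
    return ab


def fold_allele_balance(ab: pd.DataFrame) -> pd.DataFrame:
    """Fold allele balances to the major-allele scale max(b, 1-b)."""
    return ab.where(ab.isna(), np.maximum(ab, 1.0 - ab))
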