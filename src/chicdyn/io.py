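"""Reading and writing the plain-text formats the pipeline exchanges.

Counts travel as Matrix Market (.mtx) with TSV row/column registries,
regions as BED (0-based half-open), cut tables and cell metadata as TSV,
configuration as YAML.  Everything written here round-trips exactly,
including empty rows and missing metadata entries.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .quantify import CountMatrix, CutTable, RegionSet

BED_COLUMNS = ["chrom", "start", "end", "id"]


def read_regions_bed(path: str) -> RegionSet:
    """Read a BED file (chrom, start, end[, name]) into a RegionSet.

    Input order is preserved; a missing name column gets ``chrom:start-end``
    identifiers.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns, got {df.shape[1]}")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = BED_COLUMNS[: df.shape[1]]
    if "id" not in df.columns:
        df["id"] = [f"{c}:{s}-{e}" for c, s, e in zip(df.chrom, df.start, df.end)]
    return RegionSet(df)


def write_regions_bed(regions: RegionSet, path: str) -> None:
    regions.df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_cut_table(path: str) -> CutTable:
    """Read a cut table TSV with columns chrom, pos, cell, count (header optional)."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = str(first.iloc[0, 0]).lower() in ("chrom", "#chrom", "chr")
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        dtype={0: str},
    )
    if df.shape[1] < 4:
        raise ValueError(f"{path}: cut table needs 4 columns (chrom, pos, cell, count)")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "pos", "cell", "count"]
    return CutTable(df)


def write_cut_table(cuts: CutTable, path: str) -> None:
    cuts.df.to_csv(path, sep="\t", index=False)


def write_count_matrix(mat: CountMatrix, prefix: str) -> list[str]:
    """Write counts as ``prefix.mtx`` plus region/cell registries.

    Returns the list of files written.
    """
    mtx = f"{prefix}.mtx"
    rows = f"{prefix}.regions.tsv"
    cols = f"{prefix}.cells.tsv"
    scipy.io.mmwrite(mtx, sp.coo_matrix(mat.Y))
    mat.regions.df[BED_COLUMNS].to_csv(rows, sep="\t", index=False)
    pd.Series(mat.cells, name="cell").to_csv(cols, sep="\t", index=False)
    return [mtx, rows, cols]


def read_count_matrix(prefix: str) -> CountMatrix:
    Y = sp.csr_matrix(scipy.io.mmread(f"{prefix}.mtx")).astype(np.int64)
    regions = RegionSet(pd.read_csv(f"{prefix}.regions.tsv", sep="\t", dtype={"chrom": str}))
    cells = pd.read_csv(f"{prefix}.cells.tsv", sep="\t")["cell"].astype(str).tolist()
    return CountMatrix(regions=regions, cells=cells, Y=Y)


def read_cell_metadata(path: str) -> pd.DataFrame:
    """Cell metadata TSV; first column is the cell id, NA entries preserved."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def write_cell_metadata(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=True)


def read_chrom_sizes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    return dict(zip(df.chrom, df["size"].astype(int)))


def read_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg if cfg is not None else {}


def write_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
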