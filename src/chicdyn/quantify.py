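"""Quantification and QC of single-cell cut counts.

Turns per-cell genomic cut-site tables into region x cell count matrices
over 50 kb bins, TSS windows or supplied peak sets, and computes the QC
metrics used to judge single-cell chromatin profiling data: per-cell total
cuts, fraction of cuts in peaks (FRiP), the Gini coefficient of the count
distribution, and signal enrichment over a uniform-genome expectation.
Also calls bins above the background mode of the summed-count histogram
and forms per-group pseudobulk profiles.

All genomic coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import gaussian_kde


class RegionSet:
    """An ordered set of genomic regions (chrom, start, end, id).

    Coordinates are 0-based half-open; ids must be unique.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True).copy()
        required = {"chrom", "start", "end", "id"}
        if not required.issubset(df.columns):
            missing = required - set(df.columns)
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        df["id"] = df["id"].astype(str)
        if (df.start < 0).any():
            raise ValueError("region starts must be >= 0")
        if (df.start >= df.end).any():
            raise ValueError("regions must satisfy start < end")
        if df.id.duplicated().any():
            dup = df.id[df.id.duplicated()].iloc[0]
            raise ValueError(f"duplicate region id: {dup!r}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionSet) and self.df[
            ["chrom", "start", "end", "id"]
        ].equals(other.df[["chrom", "start", "end", "id"]])

    @property
    def ids(self) -> np.ndarray:
        return self.df.id.to_numpy()

    @property
    def widths(self) -> np.ndarray:
        return (self.df.end - self.df.start).to_numpy()

    def total_bp(self) -> int:
        """Total covered bp (overlaps counted once per region)."""
        return int(self.widths.sum())

    def has_overlaps(self) -> bool:
        for _, grp in self.df.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g.start.to_numpy()[1:] < g.end.to_numpy()[:-1]).any():
                return True
        return False


@dataclass
class CutTable:
    """Deduplicated cut events: one row per (chrom, pos, cell) with multiplicity."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["cell"] = df["cell"].astype(str)
        df["count"] = df["count"].astype(np.int64)
        if (df["pos"] < 0).any():
            raise ValueError("cut positions must be >= 0")
        if (df["count"] < 1).any():
            raise ValueError("cut counts must be >= 1")
        if (df["cell"] == "").any():
            raise ValueError("cell ids must be nonempty")
        self.df = df

    @property
    def total_events(self) -> int:
        return int(self.df["count"].sum())

    @property
    def cells(self) -> list[str]:
        return pd.unique(self.df["cell"]).tolist()


@dataclass
class CountMatrix:
    """Sparse region x cell integer count matrix with aligned registries."""

    regions: RegionSet
    cells: list[str]
    Y: sp.spmatrix

    def __post_init__(self):
        self.Y = sp.csr_matrix(self.Y)
        if self.Y.shape != (len(self.regions), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.Y.shape} does not match registries "
                f"({len(self.regions)} regions, {len(self.cells)} cells)"
            )
        if self.Y.nnz and self.Y.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        self.cells = [str(c) for c in self.cells]

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape

    def __repr__(self) -> str:
        return (f"CountMatrix({len(self.regions)} regions x "
                f"{len(self.cells)} cells, nnz={self.Y.nnz})")

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.Y.sum(axis=0)).ravel()

    def region_totals(self) -> np.ndarray:
        return np.asarray(self.Y.sum(axis=1)).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.Y.todense())

    def subset_regions(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            regions=RegionSet(self.regions.df.iloc[idx]),
            cells=list(self.cells),
            Y=self.Y[idx, :],
        )

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            regions=self.regions,
            cells=[self.cells[i] for i in idx],
            Y=self.Y[:, idx],
        )


@dataclass
class QCReport:
    """Per-cell QC table plus matrix-level summary metrics."""

    per_cell: pd.DataFrame  # index cell; columns total_cuts, frip (opt), pass, reason
    gini_coefficient: float | None = None
    signal_enrichment: float | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_pass(self) -> int:
        return int(self.per_cell["pass"].sum())

    @property
    def n_fail(self) -> int:
        return int((~self.per_cell["pass"]).sum())


# ---------------------------------------------------------------------------
# region construction


def make_bins(chrom_sizes: dict[str, int], width: int = 50_000) -> RegionSet:
    """Tile each chromosome with fixed-width bins (default 50 kb).

    The last bin of each chromosome is truncated at the chromosome end.
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    if not chrom_sizes:
        raise ValueError("empty genome: no chromosomes given")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size < 1:
            raise ValueError(f"chromosome {chrom} has nonpositive size {size}")
        starts = np.arange(0, size, width, dtype=np.int64)
        ends = np.minimum(starts + width, size)
        for s, e in zip(starts, ends):
            rows.append((str(chrom), s, e, f"{chrom}:{s}-{e}"))
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "id"]))


def make_tss_windows(tss_table: pd.DataFrame, halfwidth: int = 5_000,
                     chrom_sizes: dict[str, int] | None = None) -> RegionSet:
    """Windows of ±halfwidth bp around TSSs (default ±5 kb), clipped at chromosome bounds.

    ``tss_table`` needs columns chrom, tss, strand, gene.  Duplicate gene names
    are disambiguated with a numeric suffix.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    required = {"chrom", "tss", "strand", "gene"}
    if not required.issubset(tss_table.columns):
        raise ValueError(f"TSS table missing columns: {sorted(required - set(tss_table.columns))}")
    bad = ~tss_table["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"malformed strand value: {tss_table['strand'][bad].iloc[0]!r}")
    starts = np.maximum(tss_table["tss"].to_numpy(np.int64) - halfwidth, 0)
    ends = tss_table["tss"].to_numpy(np.int64) + halfwidth
    if chrom_sizes is not None:
        limits = tss_table["chrom"].astype(str).map(chrom_sizes).to_numpy()
        ends = np.minimum(ends, limits)
    ids = _dedupe(tss_table["gene"].astype(str).tolist())
    return RegionSet(pd.DataFrame({
        "chrom": tss_table["chrom"].astype(str).to_numpy(),
        "start": starts,
        "end": ends,
        "id": ids,
    }))


def _dedupe(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


# ---------------------------------------------------------------------------
# counting


def _region_index_per_chrom(regions: RegionSet):
    """chrom -> (starts, ends, region_row_indices), starts sorted."""
    index = {}
    for chrom, grp in regions.df.groupby("chrom", sort=False):
        order = np.argsort(grp.start.to_numpy(), kind="stable")
        index[chrom] = (
            grp.start.to_numpy()[order],
            grp.end.to_numpy()[order],
            grp.index.to_numpy()[order],
        )
    return index


def count_cuts(cuts: CutTable, regions: RegionSet, cells: list[str] | None = None,
               overlap_policy: str = "reject") -> CountMatrix:
    """Assign cuts to regions (start <= pos < end) and build the count matrix.

    With ``overlap_policy="reject"`` (default) overlapping regions raise; with
    ``"count_in_all"`` a cut is counted once per overlapping region.  Cuts on
    chromosomes absent from the region set are dropped with a warning.
    """
    if overlap_policy not in ("reject", "count_in_all"):
        raise ValueError(f"unknown overlap policy {overlap_policy!r}")
    overlapping = regions.has_overlaps()
    if overlapping and overlap_policy == "reject":
        raise ValueError("regions overlap; pass overlap_policy='count_in_all' to allow")

    if cells is None:
        cells = sorted(cuts.df["cell"].unique())
    cell_idx = {c: i for i, c in enumerate(cells)}
    unknown_cells = set(cuts.df["cell"]) - set(cells)
    if unknown_cells:
        raise ValueError(f"cut table contains cells not in registry: {sorted(unknown_cells)[:3]}")

    index = _region_index_per_chrom(regions)
    rows, cols, vals = [], [], []
    dropped = 0
    for chrom, grp in cuts.df.groupby("chrom", sort=False):
        if chrom not in index:
            dropped += int(grp["count"].sum())
            continue
        starts, ends, ridx = index[chrom]
        pos = grp["pos"].to_numpy()
        ccol = grp["cell"].map(cell_idx).to_numpy()
        cnt = grp["count"].to_numpy()
        if not overlapping:
            j = np.searchsorted(starts, pos, side="right") - 1
            ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
            rows.append(ridx[j[ok]])
            cols.append(ccol[ok])
            vals.append(cnt[ok])
        else:
            order = np.argsort(pos, kind="stable")
            pos_s, ccol_s, cnt_s = pos[order], ccol[order], cnt[order]
            for s, e, r in zip(starts, ends, ridx):
                lo = np.searchsorted(pos_s, s, side="left")
                hi = np.searchsorted(pos_s, e, side="left")
                if hi > lo:
                    rows.append(np.full(hi - lo, r))
                    cols.append(ccol_s[lo:hi])
                    vals.append(cnt_s[lo:hi])
    if dropped:
        warnings.warn(f"dropped {dropped} cut events on chromosomes absent from region set")
    if rows:
        Y = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(regions), len(cells)),
            dtype=np.int64,
        )
    else:
        Y = sp.coo_matrix((len(regions), len(cells)), dtype=np.int64)
    return CountMatrix(regions=regions, cells=list(cells), Y=Y)


# ---------------------------------------------------------------------------
# QC metrics


def fraction_in_peaks(cuts: CutTable, peaks: RegionSet, per_cell: bool = False):
    """Fraction of cut events falling inside the peak set (FRiP).

    Returns a scalar, or a per-cell Series when ``per_cell=True``.  Cells (or
    tables) with zero events give NaN with a warning.
    """
    index = _region_index_per_chrom(peaks)
    df = cuts.df
    in_peak = np.zeros(len(df), dtype=bool)
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in index:
            continue
        starts, ends, _ = index[chrom]
        pos = grp["pos"].to_numpy()
        # a position is in a peak iff some start <= pos < end; peaks may overlap,
        # membership (not multiplicity) is what FRiP counts
        j = np.searchsorted(starts, pos, side="right")
        hit = np.zeros(len(pos), dtype=bool)
        # check all peaks starting at or before pos whose end exceeds pos
        running_max_end = np.maximum.accumulate(ends)
        ok = j > 0
        hit[ok] = pos[ok] < running_max_end[j[ok] - 1]
        in_peak[grp.index.to_numpy()] = hit
    cnt = df["count"].to_numpy()
    if per_cell:
        tab = pd.DataFrame({"cell": df["cell"], "inp": cnt * in_peak, "tot": cnt})
        agg = tab.groupby("cell", sort=True).sum()
        zero = agg["tot"] == 0
        if zero.any():
            warnings.warn("cells with zero cut events: FRiP undefined")
        with np.errstate(invalid="ignore"):
            return (agg["inp"] / agg["tot"]).rename("frip")
    total = cnt.sum()
    if total == 0:
        warnings.warn("no cut events: FRiP undefined")
        return float("nan")
    return float((cnt * in_peak).sum() / total)


def gini(counts: np.ndarray) -> float:
    """Gini coefficient of a nonnegative count vector, in [0, 1).

    Computed with the sorted-cumulative formula, equal to the mean absolute
    pairwise difference divided by twice the mean.  An all-zero vector returns
    0 by convention (perfect equality), with a warning.
    """
    x = np.asarray(counts, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("gini needs at least one value")
    if (x < 0).any():
        raise ValueError("gini is defined for nonnegative values")
    total = x.sum()
    if total == 0:
        warnings.warn("all-zero vector: Gini defined as 0")
        return 0.0
    xs = np.sort(x)
    n = x.size
    # G = sum_i (2i - n - 1) x_(i) / (n * sum x)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


def signal_enrichment(cuts: CutTable, marked: RegionSet, genome_size: int) -> float:
    """FRiP over the genomic fraction covered by the marked regions.

    1.0 means cuts are distributed as uniformly over the genome as the marked
    regions; >1 means enrichment inside them.
    """
    covered = marked.total_bp()
    if not (0 < covered <= genome_size):
        raise ValueError(f"covered bp {covered} must be in (0, genome_size={genome_size}]")
    frip = fraction_in_peaks(cuts, marked)
    if np.isnan(frip):
        warnings.warn("no cut events: signal enrichment undefined")
        return float("nan")
    return float(frip / (covered / genome_size))


def filter_cells(mat: CountMatrix, min_cuts: int = 0,
                 min_frip: float | None = None,
                 frip: pd.Series | None = None) -> tuple[CountMatrix, QCReport]:
    """Drop cells with too few total cuts (and optionally too low FRiP).

    Returns the filtered matrix and a QC report listing, per cell, the totals
    and the reason for removal.
    """
    if min_cuts < 0:
        raise ValueError("min_cuts must be >= 0")
    totals = mat.cell_totals()
    passing = totals >= min_cuts
    reason = np.where(passing, "", "low_cuts")
    frip_col = None
    if min_frip is not None:
        if frip is None:
            raise ValueError("min_frip given but no per-cell FRiP values supplied")
        frip_col = frip.reindex(mat.cells).to_numpy()
        low = ~(frip_col >= min_frip)  # NaN fails
        reason = np.where(passing & low, "low_frip", reason)
        passing = passing & ~low
    per_cell = pd.DataFrame(
        {"total_cuts": totals, "pass": passing, "reason": reason},
        index=pd.Index(mat.cells, name="cell"),
    )
    if frip_col is not None:
        per_cell.insert(1, "frip", frip_col)
    if not passing.any():
        raise ValueError(
            f"all {len(mat.cells)} cells removed (min_cuts={min_cuts}, min_frip={min_frip}); "
            f"max total was {totals.max() if totals.size else 0}"
        )
    report = QCReport(per_cell=per_cell, params={"min_cuts": min_cuts, "min_frip": min_frip})
    return mat.subset_cells(passing), report


def bins_above_background(mat: CountMatrix, manual_cutoff: float | None = None,
                          bw_method: float | str = "scott") -> np.ndarray:
    """Mask of bins whose summed (over cells) counts exceed background.

    The distribution of per-bin log10 summed counts in this assay is bimodal:
    a low background mode and a high signal mode.  The threshold is placed at
    the minimum-density valley between the two largest modes of a Gaussian KDE
    of log10 counts, or at ``manual_cutoff`` (log10 counts) when given.  If no
    valley exists all bins are kept with a warning.
    """
    if len(mat.regions) < 2:
        raise ValueError("need at least 2 bins")
    sums = mat.region_totals().astype(float)
    if manual_cutoff is not None:
        return np.log10(np.maximum(sums, 1e-300)) > manual_cutoff
    pos = sums[sums > 0]
    if pos.size < 2 or np.allclose(pos, pos[0]):
        warnings.warn("degenerate bin-sum distribution: no valley found, keeping all bins")
        return np.ones(len(sums), dtype=bool)
    logs = np.log10(pos)
    try:
        kde = gaussian_kde(logs, bw_method=bw_method)
    except np.linalg.LinAlgError:
        warnings.warn("KDE failed on bin sums: keeping all bins")
        return np.ones(len(sums), dtype=bool)
    grid = np.linspace(logs.min(), logs.max(), 512)
    dens = kde(grid)
    # local maxima / minima on the grid
    up = np.r_[True, dens[1:] > dens[:-1]]
    down = np.r_[dens[:-1] > dens[1:], True]
    peaks = np.flatnonzero(up & down)
    if peaks.size < 2:
        warnings.warn("bin-sum density is unimodal: no background valley, keeping all bins")
        return np.ones(len(sums), dtype=bool)
    top2 = peaks[np.argsort(dens[peaks])][-2:]
    lo, hi = sorted(top2)
    valley = grid[lo + np.argmin(dens[lo:hi + 1])]
    return np.log10(np.maximum(sums, 1e-300)) > valley


def pseudobulk(mat: CountMatrix, labels: pd.Series | dict) -> pd.DataFrame:
    """Sum counts per label group: group x region DataFrame; totals conserved."""
    lab = pd.Series(labels)
    missing = [c for c in mat.cells if c not in lab.index]
    if missing:
        raise ValueError(f"cells without labels: {missing[:3]}")
    lab = lab.reindex(mat.cells)
    groups = sorted(lab.unique())
    out = np.zeros((len(groups), len(mat.regions)), dtype=np.int64)
    Y = mat.Y.tocsc()
    for gi, g in enumerate(groups):
        idx = np.flatnonzero((lab == g).to_numpy())
        out[gi] = np.asarray(Y[:, idx].sum(axis=1)).ravel()
    return pd.DataFrame(out, index=pd.Index(groups, name="group"), columns=mat.regions.ids)
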