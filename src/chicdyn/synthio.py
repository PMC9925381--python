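"""Synthetic single-cell cut-count data with known ground truth.

Emulates the statistical structure of sort-assisted single-cell chromatin
profiling data: per-cell counts are multinomial draws from a cell-type
profile over genomic regions, with log-normal sequencing depth, a planted
set of "dynamic" regions carrying per-type fold changes, optional per-plate
batch shifts in log-profile space, double-incubated cells drawn from a
w-weighted mixture of two mark-specific profiles, region x motif designs
with planted activities, and FACS marker triples along a differentiation
trajectory with an exact count of masked entries.

All randomness flows from one integer seed; each operation draws from its
own substream (seeded ``numpy`` Philox generators keyed by seed and an
operation tag), so outputs are bit-reproducible and independent across ops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .quantify import CountMatrix, RegionSet, make_bins

_OP_TAGS = {
    "profiles": 1,
    "cells": 2,
    "double": 3,
    "motif": 4,
    "facs": 5,
    "batch": 6,
}


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=(int(seed) << 8) | _OP_TAGS[op]))


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    depth_median / depth_sigma define the log-normal law of per-cell total
    cuts (median ~3e3 mirrors an active histone mark at single-cell depth).
    fold_spec gives, per cell type, the multiplicative enrichment applied to
    that type's planted dynamic regions before renormalization.
    """

    n_region: int = 1000
    n_type: int = 3
    n_cell_per_type: int | Sequence[int] = 100
    depth_median: float = 3e3
    depth_sigma: float = 0.35
    frac_dynamic: float = 0.1
    fold_spec: Sequence[float] | None = None  # length n_type; type 0 is the reference
    batch_spec: dict[str, float] | None = None  # plate -> additive log-profile shift scale
    n_plate: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_region < 1 or self.n_type < 1:
            raise ValueError("n_region and n_type must be >= 1")
        if not 0 <= self.frac_dynamic <= 1:
            raise ValueError("frac_dynamic must be in [0, 1]")
        self.n_cells = (
            [int(self.n_cell_per_type)] * self.n_type
            if np.isscalar(self.n_cell_per_type)
            else [int(n) for n in self.n_cell_per_type]
        )
        if len(self.n_cells) != self.n_type:
            raise ValueError("n_cell_per_type length must equal n_type")
        if any(n < 0 for n in self.n_cells):
            raise ValueError("cell counts must be >= 0")
        if self.fold_spec is None:
            self.fold_spec = [1.0] + [4.0] * (self.n_type - 1)
        if len(self.fold_spec) != self.n_type:
            raise ValueError(
                f"fold_spec length {len(self.fold_spec)} must equal n_type {self.n_type}"
            )
        if any(f <= 0 for f in self.fold_spec):
            raise ValueError("folds must be > 0")
        if self.depth_median <= 0 or self.depth_sigma < 0:
            raise ValueError("depth law parameters must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    type_profiles: np.ndarray = None  # n_type x n_region, rows sum to 1
    type_names: list[str] = field(default_factory=list)
    cell_labels: pd.Series | None = None
    cell_plates: pd.Series | None = None
    dynamic_mask: np.ndarray | None = None  # per-region bool
    true_log2_fold: np.ndarray | None = None  # n_type x n_region vs type 0
    pair_labels: pd.DataFrame | None = None  # per double cell: c, l, w_true
    motif_activity_true: np.ndarray | None = None
    facs_truth: pd.DataFrame | None = None


def _check_profiles(P: np.ndarray):
    if (P < 0).any():
        raise ValueError("profiles must be nonnegative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("profiles must sum to 1")


def simulate_profiles(cfg: SimConfig) -> GroundTruth:
    """Build per-type multinomial profiles with planted fold changes.

    A shared baseline profile (moderately heavy-tailed, so bins differ in
    coverage as real 50 kb bins do) is perturbed multiplicatively at the
    planted dynamic regions per type, then renormalized.  Type 0 is the
    reference and keeps the baseline everywhere.
    """
    rng = _rng(cfg.seed, "profiles")
    base = rng.gamma(shape=2.0, scale=1.0, size=cfg.n_region) + 1e-3
    base /= base.sum()
    n_dyn = int(round(cfg.frac_dynamic * cfg.n_region))
    dynamic = np.zeros(cfg.n_region, dtype=bool)
    dynamic[rng.choice(cfg.n_region, size=n_dyn, replace=False)] = True

    P = np.tile(base, (cfg.n_type, 1))
    # split planted regions round-robin across non-reference types so each
    # type has its own enriched set
    dyn_idx = np.flatnonzero(dynamic)
    owner = np.full(cfg.n_region, -1)
    if cfg.n_type > 1 and dyn_idx.size:
        owner[dyn_idx] = 1 + (np.arange(dyn_idx.size) % (cfg.n_type - 1))
    for t in range(1, cfg.n_type):
        mask = owner == t
        P[t, mask] *= cfg.fold_spec[t]
        P[t] /= P[t].sum()
    _check_profiles(P)

    with np.errstate(divide="ignore"):
        l2f = np.log2(P / P[0])
    return GroundTruth(
        type_profiles=P,
        type_names=[f"type{t}" for t in range(cfg.n_type)],
        dynamic_mask=dynamic,
        true_log2_fold=l2f,
    )


def simulate_cells(truth: GroundTruth, cfg: SimConfig) -> tuple[CountMatrix, pd.Series]:
    """Draw per-cell multinomial counts at log-normal depth; adds labels/plates to truth.

    When cfg.batch_spec is given, each plate adds its own Gaussian shift in
    log-profile space (scale per plate) before renormalization, emulating a
    plate-level technical effect on the sampling profile.
    """
    if truth.type_profiles is None:
        raise ValueError("profiles not simulated yet")
    rng = _rng(cfg.seed, "cells")
    regions = make_bins({"chrSim": cfg.n_region * 50_000}, 50_000)
    labels, plates, cols = [], [], []
    mu = np.log(cfg.depth_median)
    plate_shift = {}
    if cfg.batch_spec:
        brng = _rng(cfg.seed, "batch")
        for plate, scale in cfg.batch_spec.items():
            plate_shift[plate] = brng.normal(0.0, scale, size=cfg.n_region)
    plate_names = list(cfg.batch_spec) if cfg.batch_spec else [f"plate{i}" for i in range(cfg.n_plate)]

    for t, n in enumerate(cfg.n_cells):
        for j in range(n):
            plate = plate_names[(t * 131 + j) % len(plate_names)]
            prof = truth.type_profiles[t]
            if plate in plate_shift:
                prof = prof * np.exp(plate_shift[plate])
                prof = prof / prof.sum()
            depth = max(1, int(round(np.exp(rng.normal(mu, cfg.depth_sigma)))))
            cols.append(rng.multinomial(depth, prof))
            labels.append(truth.type_names[t])
            plates.append(plate)
    if not cols:
        raise ValueError("no cells simulated")
    Y = sp.csr_matrix(np.asarray(cols, dtype=np.int64).T)
    cells = [f"{plates[i]}:w{i:04d}" for i in range(len(cols))]
    truth.cell_labels = pd.Series(labels, index=cells, name="celltype")
    truth.cell_plates = pd.Series(plates, index=cells, name="plate")
    mat = CountMatrix(regions=RegionSet(regions.df), cells=cells, Y=Y)
    return mat, truth.cell_labels


def simulate_double_cells(p_profiles: np.ndarray, q_profiles: np.ndarray,
                          pairing: list[tuple[int, int]], w: float | Sequence[float],
                          depth: int, seed: int = 0) -> tuple[CountMatrix, pd.DataFrame]:
    """Cells whose counts mix an active-mark and a repressive-mark profile.

    Each cell i with pair (c, l) draws Multinomial(depth, w*p_c + (1-w)*q_l).
    Returns counts over a generic region registry plus the truth table.
    """
    p = np.atleast_2d(np.asarray(p_profiles, dtype=float))
    q = np.atleast_2d(np.asarray(q_profiles, dtype=float))
    if p.shape[1] != q.shape[1]:
        raise ValueError("p and q must share a region registry")
    ws = np.broadcast_to(np.asarray(w, dtype=float), (len(pairing),)).copy()
    if ((ws < 0) | (ws > 1)).any():
        raise ValueError("w must be in [0, 1]")
    rng = _rng(seed, "double")
    cols, rows = [], []
    for i, ((c, l), wi) in enumerate(zip(pairing, ws)):
        mix = wi * p[c] + (1 - wi) * q[l]
        mix = mix / mix.sum()
        cols.append(rng.multinomial(depth, mix))
        rows.append((f"dbl{i:04d}", c, l, wi))
    labels = pd.DataFrame(rows, columns=["cell", "c", "l", "w_true"]).set_index("cell")
    regions = make_bins({"chrSim": p.shape[1] * 50_000}, 50_000)
    mat = CountMatrix(
        regions=regions,
        cells=labels.index.tolist(),
        Y=sp.csr_matrix(np.asarray(cols, dtype=np.int64).T),
    )
    return mat, labels


def simulate_motif_design(n_region: int, n_motif: int, n_cell: int,
                          n_active: int = 3, activity_scale: float = 1.0,
                          noise_sd: float = 0.1, site_rate: float = 1.0,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse Poisson motif site counts N, planted activities A, and signal Y = N·A + noise.

    The first ``n_active`` motifs get cell-structured activities (smoothly
    varying across cells, scale ``activity_scale``); the remaining motifs are
    exact nulls (all-zero rows of A).  Returns (N [region x motif],
    Y [region x cell], A [motif x cell]).
    """
    if min(n_region, n_motif, n_cell) < 1:
        raise ValueError("dimensions must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_active > n_motif:
        raise ValueError("n_active cannot exceed n_motif")
    rng = _rng(seed, "motif")
    N = rng.poisson(site_rate, size=(n_region, n_motif)).astype(float)
    # guarantee no all-zero motif column (a site somewhere per motif)
    empty = np.flatnonzero(N.sum(axis=0) == 0)
    if empty.size:
        N[rng.integers(0, n_region, size=empty.size), empty] += 1
    A = np.zeros((n_motif, n_cell))
    t = np.linspace(0, 1, n_cell)
    for m in range(n_active):
        phase = rng.uniform(0, 2 * np.pi)
        A[m] = activity_scale * np.sin(2 * np.pi * (m + 1) * t / 2 + phase)
    Y = N @ A
    if noise_sd > 0:
        Y = Y + rng.normal(0.0, noise_sd, size=Y.shape)
    return N, Y, A


def simulate_facs_trajectory(n_cell: int,
                             trajectory_spec: Callable[[np.ndarray], np.ndarray] | None = None,
                             missing_frac: float = 0.0, noise_sd: float = 0.0,
                             seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FACS (Sca1, cKit, Lin) marker levels along pseudotime t in [0, 1].

    ``trajectory_spec(t)`` returns an (n, 3) array of marker means; the
    default mimics stem-to-mature differentiation: Sca1 decreasing, cKit
    rising then falling, Lin increasing.  Exactly
    ``round(missing_frac * n_cell)`` cells have one marker masked (NaN),
    chosen by seeded permutation, so the masked count is deterministic.
    Returns (observed table with NaNs, truth table).
    """
    if not 0 <= missing_frac < 1:
        raise ValueError("missing_frac must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed, "facs")
    t = np.sort(rng.uniform(0, 1, size=n_cell))
    if trajectory_spec is None:
        def trajectory_spec(tt):
            return np.column_stack([
                1000.0 * (1 - tt),            # Sca1 high in stem cells
                800.0 * np.sin(np.pi * tt) + 100.0,  # cKit peaks mid-trajectory
                900.0 * tt + 50.0,            # Lin rises with maturity
            ])
    M = np.asarray(trajectory_spec(t), dtype=float)
    if M.shape != (n_cell, 3):
        raise ValueError("trajectory_spec must return an (n_cell, 3) array")
    obs = M + rng.normal(0.0, noise_sd, size=M.shape) if noise_sd > 0 else M.copy()
    cells = [f"facs{i:04d}" for i in range(n_cell)]
    truth = pd.DataFrame(M, index=cells, columns=["Sca1", "cKit", "Lin"])
    truth["t_true"] = t
    table = pd.DataFrame(obs, index=cells, columns=["Sca1", "cKit", "Lin"])
    n_mask = int(round(missing_frac * n_cell))
    if n_mask:
        which = rng.permutation(n_cell)[:n_mask]
        marker = rng.integers(0, 3, size=n_mask)
        for i, m in zip(which, marker):
            table.iat[i, m] = np.nan
    return table, truth
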