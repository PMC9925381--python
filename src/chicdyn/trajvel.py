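"""Differentiation trajectories and chromatin velocity.

Covers four steps of the trajectory analysis: (1) completing FACS marker
triples (Sca1, cKit, Lin) when one of the three is missing, by averaging
the ten nearest neighbors in a latent cell embedding; (2) projecting
marker triples onto the stem → progenitor → mature ternary simplex;
(3) assigning a pseudotime in [0, 1] to trajectory cells from two selected
principal components (rank-transformed projection on the leading axis of
that 2-PC subspace, oriented so the designated start population sits
early); and (4) chromatin velocity: a trajectory-specific cubic B-spline of
the per-region signal along pseudotime, differentiated by the forward step
to t + 0.01 (backward at the right boundary), then projected onto the PCA
as 2-D arrows per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

MARKERS = ["Sca1", "cKit", "Lin"]
DEFAULT_DELTA = 0.01


def impute_missing_marker(facs: pd.DataFrame, latent: np.ndarray, k: int = 10
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing FACS entries with the mean of the k nearest complete cells.

    Each cell may miss at most one of the three markers.  Neighbors are
    searched (Euclidean, in the latent embedding) among cells where the
    missing marker was measured.  Returns the completed table and a boolean
    imputation-flag table.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not set(MARKERS).issubset(facs.columns):
        raise ValueError(f"FACS table needs columns {MARKERS}")
    X = np.asarray(latent, dtype=float)
    if X.shape[0] != len(facs):
        raise ValueError("latent embedding must have one row per cell")
    missing = facs[MARKERS].isna()
    if (missing.sum(axis=1) > 1).any():
        raise ValueError("cells may miss at most one marker")
    out = facs.copy()
    flags = missing.copy()
    for m in MARKERS:
        miss = missing[m].to_numpy()
        if not miss.any():
            continue
        have = ~miss
        n_have = int(have.sum())
        if n_have == 0:
            raise ValueError(f"no cells with {m} measured: cannot impute")
        kk = k
        if n_have < k:
            warnings.warn(f"only {n_have} cells carry {m}: using all of them")
            kk = n_have
        nn = NearestNeighbors(n_neighbors=kk).fit(X[have])
        _, idx = nn.kneighbors(X[miss])
        values = facs.loc[have, m].to_numpy()[idx].mean(axis=1)
        out.loc[miss, m] = values
    return out, flags


def ternary_coords(sca1, ckit, lin) -> np.ndarray:
    """Normalize marker triples onto the simplex; rows sum to 1."""
    M = np.column_stack([np.asarray(sca1, dtype=float),
                         np.asarray(ckit, dtype=float),
                         np.asarray(lin, dtype=float)])
    if (M < 0).any():
        raise ValueError("marker levels must be nonnegative")
    s = M.sum(axis=1)
    if (s == 0).any():
        raise ValueError("all-zero marker triple: ternary coordinates undefined")
    return M / s[:, None]


def pseudotime_from_pcs(scores: np.ndarray, pcs: tuple[int, int],
                        trajectory_cells: np.ndarray,
                        start_labels: pd.Series | np.ndarray | None = None,
                        start_type: str | None = None) -> np.ndarray:
    """Pseudotime in [0, 1] for the trajectory cells from two selected PCs.

    The trajectory cells' coordinates in the chosen 2-PC subspace are
    projected on that subspace's leading principal axis and rank-transformed
    to [0, 1]; orientation is flipped if the mean pseudotime of the start
    population exceeds 0.5.
    """
    idx = np.asarray(trajectory_cells)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("empty trajectory cell set")
    sub = np.asarray(scores, dtype=float)[idx][:, list(pcs)]
    axis = PCA(n_components=1, svd_solver="full").fit_transform(sub).ravel()
    ranks = pd.Series(axis).rank(method="average").to_numpy() - 1
    t = ranks / max(len(ranks) - 1, 1)
    if start_labels is not None:
        if start_type is None:
            raise ValueError("start_type required with start_labels")
        lab = np.asarray(start_labels)[idx] if len(np.asarray(start_labels)) != idx.size \
            else np.asarray(start_labels)
        starters = lab == start_type
        if not starters.any():
            raise ValueError(f"start type {start_type!r} absent from trajectory")
        if t[starters].mean() > 0.5:
            t = 1.0 - t
    return t


@dataclass
class TrajectoryFrame:
    """Per-cell trajectory bookkeeping: markers, ternary coords, pseudotime."""

    cells: list[str]
    pseudotime: np.ndarray
    markers: pd.DataFrame | None = None
    imputed_flags: pd.DataFrame | None = None
    ternary: np.ndarray | None = None
    trajectory_id: str = "trajectory"

    def __post_init__(self):
        t = np.asarray(self.pseudotime, dtype=float)
        if ((t < 0) | (t > 1)).any():
            raise ValueError("pseudotime must lie in [0, 1]")
        self.pseudotime = t


@dataclass
class SplineFit:
    """Least-squares cubic B-spline of one region's signal along pseudotime."""

    spline: BSpline
    df: int
    knots: np.ndarray

    def predict(self, t) -> np.ndarray:
        return self.spline(np.clip(np.asarray(t, dtype=float), 0.0, 1.0))


def fit_trajectory_spline(signal: np.ndarray, t: np.ndarray, df: int = 6) -> SplineFit:
    """Fit a clamped cubic B-spline with ``df`` basis functions on [0, 1].

    Interior knots sit at pseudotime quantiles; df < 4 (a bare cubic) is
    rejected, and the fit needs at least df + 2 cells and non-degenerate t.
    """
    if df < 4:
        raise ValueError("df must be >= 4 for a cubic spline")
    y = np.asarray(signal, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape:
        raise ValueError("signal and pseudotime must align")
    if len(t) < df + 2:
        raise ValueError(f"need at least df + 2 = {df + 2} cells")
    if np.allclose(t, t[0]):
        raise ValueError("degenerate pseudotime: all values equal")
    n_interior = df - 4
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(t, qs)
    else:
        interior = np.array([])
    knots = np.r_[np.zeros(4), interior, np.ones(4)]
    B = BSpline.design_matrix(np.clip(t, 0, 1), knots, 3).toarray()
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    return SplineFit(spline=BSpline(knots, coef, 3), df=df, knots=knots)


def chromatin_velocity(fit: SplineFit, t: np.ndarray, delta: float = DEFAULT_DELTA) -> np.ndarray:
    """Finite-difference derivative (pred(t + delta) - pred(t)) / delta per cell.

    Cells within delta of the trajectory end use the backward difference.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    t = np.asarray(t, dtype=float)
    forward = t + delta <= 1.0
    v = np.empty_like(t)
    v[forward] = (fit.predict(t[forward] + delta) - fit.predict(t[forward])) / delta
    back = ~forward
    v[back] = (fit.predict(t[back]) - fit.predict(t[back] - delta)) / delta
    return v


@dataclass
class VelocityField:
    """Per-region spline fits, per-cell velocities, and 2-D PCA arrows."""

    velocities: np.ndarray       # region x cell
    splines: list[SplineFit] = field(repr=False, default=None)
    arrows: np.ndarray | None = None
    delta: float = DEFAULT_DELTA
    region_ids: np.ndarray | None = None
    cells: list[str] | None = None


def velocity_field(signal: np.ndarray, t: np.ndarray, df: int = 6,
                   delta: float = DEFAULT_DELTA, region_ids=None, cells=None) -> VelocityField:
    """Spline-fit every region's signal along pseudotime and differentiate."""
    S = np.atleast_2d(np.asarray(signal, dtype=float))
    splines = [fit_trajectory_spline(S[g], t, df=df) for g in range(S.shape[0])]
    V = np.vstack([chromatin_velocity(f, t, delta=delta) for f in splines])
    return VelocityField(velocities=V, splines=splines, delta=delta,
                         region_ids=region_ids, cells=cells)


def project_velocity(velocities: np.ndarray, loadings: np.ndarray,
                     pcs: tuple[int, int] | None = (0, 1)) -> np.ndarray:
    """Project region x cell velocities onto PCA loadings: cell x PC arrows.

    Velocities are differences of signal, so the PCA centering cancels and
    the arrow is simply loadings' @ velocity.
    """
    V = np.atleast_2d(np.asarray(velocities, dtype=float))
    L = np.asarray(loadings, dtype=float)
    if L.shape[0] != V.shape[0]:
        raise ValueError("velocity and loading region registries differ")
    if pcs is not None:
        L = L[:, list(pcs)]
    return (L.T @ V).T
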