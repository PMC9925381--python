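"""Deconvolution of double-incubated cells by multinomial mixture models.

A cell stained for two histone marks (active H3K4me1 + heterochromatic
H3K9me3) yields cuts drawn from a weighted mixture of two mark-specific
multinomial profiles:

    y | c, l, w ~ Multinomial(N, w * p_c + (1 - w) * q_l)

with p_c the relative cut frequencies of active-mark cell type c, q_l those
of repressive-mark lineage l, and w the fraction of cuts contributed by the
active mark.  Single-incubated reference data provide pseudocounted p and q
vectors; for each double cell every (c, l) pair is scored by its profile
log-likelihood at the per-pair maximum-likelihood w (or a fixed w), and the
best pair is reported with a softmax posterior over pairs.

The log-likelihood is concave in w, so a golden-section search finds the
maximizer reliably.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_INVPHI = (math.sqrt(5) - 1) / 2


@dataclass
class MixtureReference:
    """Pseudocounted per-cluster probability vectors on a shared feature registry."""

    feature_ids: np.ndarray
    p: pd.DataFrame     # active-mark clusters x features, rows sum to 1
    q: pd.DataFrame     # repressive-mark clusters x features
    pseudocount: float = 1.0

    def __post_init__(self):
        for name, tab in (("p", self.p), ("q", self.q)):
            arr = tab.to_numpy()
            if (arr <= 0).any():
                raise ValueError(f"{name} profiles must be strictly positive (pseudocounted)")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"{name} profiles must sum to 1")
            if tab.shape[1] != len(self.feature_ids):
                raise ValueError(f"{name} profiles do not match the feature registry")


@dataclass
class PairAssignment:
    """Per-cell best (cell type, lineage) pair, w estimate and pair posterior."""

    best: pd.DataFrame            # index cell: c, l, w_hat, loglik, n_reads, flat_w, tied
    loglik: dict[str, pd.DataFrame]   # cell -> pair table (c x l) of log-likelihoods
    posterior: dict[str, pd.DataFrame]
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        return "\n".join([
            f"Mixture deconvolution: {len(self.best)} cells, "
            f"{self.params.get('n_active')} active x {self.params.get('n_repressive')} repressive clusters",
            f"median w-hat: {self.best['w_hat'].median():.3f}",
            f"w mode: {self.params.get('w_mode')}",
        ])


def build_reference(active_pseudobulk: pd.DataFrame, repressive_pseudobulk: pd.DataFrame,
                    feature_ids=None, pseudocount: float = 1.0) -> MixtureReference:
    """Normalize pseudocounted cluster pseudobulks into mixture profiles.

    Both pseudobulks are cluster x feature count tables on the same feature
    registry (typically active-mark marker regions plus repressive-mark
    cluster-specific bins).
    """
    if not active_pseudobulk.columns.equals(repressive_pseudobulk.columns):
        raise ValueError("pseudobulks must share a feature registry")
    if len(active_pseudobulk) == 0 or len(repressive_pseudobulk) == 0:
        raise ValueError("empty cluster set in reference pseudobulk")
    feats = np.asarray(feature_ids if feature_ids is not None else active_pseudobulk.columns)

    def _norm(tab: pd.DataFrame) -> pd.DataFrame:
        arr = tab.to_numpy(dtype=float) + pseudocount
        if (arr.sum(axis=1) <= 0).any():
            raise ValueError("cluster with zero total counts and zero pseudocount")
        return pd.DataFrame(arr / arr.sum(axis=1, keepdims=True),
                            index=tab.index, columns=tab.columns)

    return MixtureReference(feature_ids=feats, p=_norm(active_pseudobulk),
                            q=_norm(repressive_pseudobulk), pseudocount=pseudocount)


def pair_loglik(y: np.ndarray, p: np.ndarray, q: np.ndarray, w: float) -> float:
    """sum_i y_i log(w p_i + (1-w) q_i); multinomial coefficient omitted."""
    if not 0 <= w <= 1:
        raise ValueError("w must be in [0, 1]")
    y = np.asarray(y, dtype=float)
    mix = w * np.asarray(p, dtype=float) + (1 - w) * np.asarray(q, dtype=float)
    nz = y > 0
    if (mix[nz] <= 0).any():
        warnings.warn("observed counts where both profiles are zero: -inf likelihood")
        return float("-inf")
    return float((y[nz] * np.log(mix[nz])).sum())


def fit_w(y: np.ndarray, p: np.ndarray, q: np.ndarray,
          tol: float = 1e-4) -> tuple[float, float, bool]:
    """Maximize the concave profile likelihood over w in [0, 1] by golden section.

    Returns (w_hat, max log-likelihood, flat_flag); a flat likelihood
    (p = q on the support of y) gives w = 0.5 with the flag set.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    nz = y > 0
    yz, pz, qz = y[nz], p[nz], q[nz]

    def nll(w):
        mix = w * pz + (1 - w) * qz
        if (mix <= 0).any():
            return float("inf")
        return -float((yz * np.log(mix)).sum())

    if yz.size == 0 or np.allclose(pz, qz):
        ll = -nll(0.5) if yz.size else 0.0
        return 0.5, ll, True

    a, b = 0.0, 1.0
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = nll(c), nll(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = nll(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = nll(d)
    w_hat = (a + b) / 2
    # concave ll: also check the boundary values, the maximizer may sit at 0 or 1
    cand = [(nll(w), w) for w in (0.0, w_hat, 1.0)]
    f_best, w_best = min(cand)
    return float(w_best), float(-f_best), False


class MixtureDeconvolver:
    """Score every (cell type, lineage) pair for each double-incubated cell.

    Parameters
    ----------
    ref : MixtureReference
    w_mode : "free" (per-cell, per-pair profile MLE) or a float in [0, 1]
        fixing w globally (one mixing chemistry for the whole plate).
    """

    def __init__(self, ref: MixtureReference, w_mode="free"):
        self.ref = ref
        if w_mode != "free":
            w_mode = float(w_mode)
            if not 0 <= w_mode <= 1:
                raise ValueError("fixed w must be in [0, 1]")
        self.w_mode = w_mode

    def fit(self, Y, cells: list[str] | None = None) -> PairAssignment:
        """Assign each column of the feature x cell count matrix to its best pair."""
        if hasattr(Y, "dense"):
            cells = list(Y.cells) if cells is None else cells
            Y = Y.dense()
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != len(self.ref.feature_ids):
            raise ValueError("count matrix does not match the reference feature registry")
        if cells is None:
            cells = [f"cell{i}" for i in range(Y.shape[1])]

        cs = list(self.ref.p.index)
        ls = list(self.ref.q.index)
        P = self.ref.p.to_numpy()
        Q = self.ref.q.to_numpy()
        rows, ll_tabs, post_tabs = [], {}, {}
        for j, cell in enumerate(cells):
            y = Y[:, j]
            ll = np.empty((len(cs), len(ls)))
            wh = np.empty_like(ll)
            flat = np.zeros_like(ll, dtype=bool)
            for a, c in enumerate(cs):
                for b, l in enumerate(ls):
                    if self.w_mode == "free":
                        wab, lab, fl = fit_w(y, P[a], Q[b])
                    else:
                        wab, fl = self.w_mode, False
                        lab = pair_loglik(y, P[a], Q[b], wab)
                    ll[a, b], wh[a, b], flat[a, b] = lab, wab, fl
            shifted = ll - ll.max()
            post = np.exp(shifted)
            post /= post.sum()
            flatidx = np.flatnonzero(np.isclose(ll.ravel(), ll.max()))
            tied = flatidx.size > 1
            best_flat = flatidx[0]      # lexicographic (row-major) tie-break
            a, b = np.unravel_index(best_flat, ll.shape)
            if tied:
                warnings.warn(f"cell {cell}: tied pair likelihoods, lexicographic tie-break")
            rows.append((cell, cs[a], ls[b], wh[a, b], ll[a, b], y.sum(),
                         bool(flat[a, b]), tied))
            ll_tabs[cell] = pd.DataFrame(ll, index=cs, columns=ls)
            post_tabs[cell] = pd.DataFrame(post, index=cs, columns=ls)
        best = pd.DataFrame(rows, columns=["cell", "c", "l", "w_hat", "loglik",
                                           "n_reads", "flat_w", "tied"]).set_index("cell")
        return PairAssignment(best=best, loglik=ll_tabs, posterior=post_tabs,
                              params={"w_mode": self.w_mode, "n_active": len(cs),
                                      "n_repressive": len(ls)})


def assign_pair(Y, ref: MixtureReference, w_mode="free", cells=None) -> PairAssignment:
    """Convenience wrapper: ``MixtureDeconvolver(ref, w_mode).fit(Y)``."""
    return MixtureDeconvolver(ref, w_mode=w_mode).fit(Y, cells=cells)
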