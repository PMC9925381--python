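"""Reference-based probabilistic cell typing with multinomial likelihoods.

A labeled reference (for example FACS-sorted populations) is pooled into
per-type pseudocounted probability vectors over genomic regions.  A query
cell's counts are assumed multinomial given its type, so

    log P(type | y)  ∝  log prior(type) + sum_i y_i log p_type,i

softmax-normalized in log space with max-subtraction, which keeps the
computation stable up to depths of 1e7 and beyond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TypingReference:
    """Per-type probability vectors (rows strictly positive, sum to 1)."""

    profiles: pd.DataFrame      # type x region
    n_cells: pd.Series          # source cells per type
    pseudocount: float = 1.0

    def __post_init__(self):
        arr = self.profiles.to_numpy()
        if (arr <= 0).any():
            raise ValueError("reference profiles must be strictly positive (pseudocounted)")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("reference profiles must sum to 1")

    @property
    def types(self) -> list[str]:
        return self.profiles.index.tolist()


@dataclass
class TypingResult:
    """Posterior type probabilities and argmax labels for the query cells."""

    posterior: pd.DataFrame     # cell x type, rows sum to 1
    labels: pd.Series
    flags: pd.Series            # zero-count cells get a uniform posterior
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        counts = self.labels.value_counts().sort_index()
        return "Cell typing: " + ", ".join(f"{t}={n}" for t, n in counts.items())


def build_typing_reference(mat, labels: pd.Series, pseudocount: float = 1.0) -> TypingReference:
    """Pool labeled reference counts per type, add pseudocount, normalize."""
    lab = pd.Series(labels)
    if hasattr(mat, "dense"):
        lab = lab.reindex(mat.cells)
        if lab.isna().any():
            raise ValueError("every reference cell must be labeled")
        Y = mat.dense()
        region_ids = mat.regions.ids
    else:
        Y = np.atleast_2d(np.asarray(mat, dtype=float))
        region_ids = np.array([f"r{i}" for i in range(Y.shape[0])])
        if len(lab) != Y.shape[1]:
            raise ValueError("labels must match the number of cells")
    types = sorted(lab.unique())
    rows, ncell = [], []
    for t in types:
        idx = np.flatnonzero((lab == t).to_numpy())
        if idx.size == 0:
            raise ValueError(f"type {t!r} has zero reference cells")
        pooled = Y[:, idx].sum(axis=1) + pseudocount
        rows.append(pooled / pooled.sum())
        ncell.append(idx.size)
    profiles = pd.DataFrame(rows, index=pd.Index(types, name="type"), columns=region_ids)
    return TypingReference(profiles=profiles,
                           n_cells=pd.Series(ncell, index=types), pseudocount=pseudocount)


class MultinomialTyper:
    """Classifier scoring query cells against a :class:`TypingReference`."""

    def __init__(self, ref: TypingReference, prior=None):
        self.ref = ref
        k = len(ref.types)
        if prior is None:
            prior = np.full(k, 1.0 / k)
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (k,) or (prior < 0).any() or prior.sum() <= 0:
            raise ValueError("prior must be a nonnegative vector over the reference types")
        self.log_prior = np.log(prior / prior.sum())

    def fit(self, mat, cells: list[str] | None = None) -> TypingResult:
        """Posterior over types for every column of the region x cell matrix."""
        if hasattr(mat, "dense"):
            if not np.array_equal(mat.regions.ids, self.ref.profiles.columns.to_numpy()):
                raise ValueError("query and reference region registries differ")
            cells = list(mat.cells) if cells is None else cells
            Y = mat.dense()
        else:
            Y = np.atleast_2d(np.asarray(mat, dtype=float))
            if cells is None:
                cells = [f"cell{i}" for i in range(Y.shape[1])]
        logp = np.log(self.ref.profiles.to_numpy())         # type x region
        scores = logp @ Y + self.log_prior[:, None]          # type x cell
        scores -= scores.max(axis=0, keepdims=True)
        post = np.exp(scores)
        post /= post.sum(axis=0, keepdims=True)
        zero = Y.sum(axis=0) == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} cells with zero counts: uniform posterior")
            post[:, zero] = 1.0 / len(self.ref.types)
        posterior = pd.DataFrame(post.T, index=pd.Index(cells, name="cell"),
                                 columns=self.ref.types)
        labels = posterior.idxmax(axis=1).rename("celltype")
        return TypingResult(posterior=posterior, labels=labels,
                            flags=pd.Series(zero, index=cells, name="zero_counts"),
                            params={"pseudocount": self.ref.pseudocount})


def classify_cells(mat, ref: TypingReference, prior=None, cells=None) -> TypingResult:
    """Convenience wrapper: ``MultinomialTyper(ref, prior).fit(mat)``."""
    return MultinomialTyper(ref, prior=prior).fit(mat, cells=cells)
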