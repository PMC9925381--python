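"""Multinomial topic-model dimensionality reduction of cut counts.

Region x cell counts are modelled as a hierarchical multinomial (LDA):
topics are distributions over regions, cells are mixtures over topics —
a discrete analogue of probabilistic PCA.  The reconstruction
phi' theta' gives per-cell smoothed multinomial probabilities; its natural
log is the "imputed signal" consumed by motif-activity inference and
chromatin velocity.  Batch (plate) effects are removed in the latent space
by a cell-type-specific linear model that leaves cluster means untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, LatentDirichletAllocation

from .quantify import CountMatrix


@dataclass
class TopicFit:
    """Fitted topic model: row-stochastic doc-topic and topic-term matrices."""

    n_topic: int
    doc_topic: np.ndarray       # cell x K, rows sum to 1
    topic_term: np.ndarray      # K x region, rows sum to 1
    cells: list[str]
    region_ids: np.ndarray
    log_likelihood: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not np.allclose(self.doc_topic.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("doc_topic rows must sum to 1")
        if not np.allclose(self.topic_term.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("topic_term rows must sum to 1")
        if not np.all(np.isfinite(self.log_likelihood)):
            raise ValueError("log-likelihood trace must be finite")

    def summary(self) -> str:
        lines = [
            f"Topic model: K={self.n_topic}, {len(self.cells)} cells, "
            f"{self.topic_term.shape[1]} regions",
            f"final variational bound: {self.log_likelihood[-1]:.2f}" if self.log_likelihood else "",
            "top regions per topic:",
        ]
        for k in range(self.n_topic):
            top = np.argsort(self.topic_term[k])[::-1][:5]
            lines.append(f"  topic {k}: " + ", ".join(self.region_ids[top]))
        return "\n".join(x for x in lines if x)


@dataclass
class ImputedSignal:
    """Per-cell log reconstructed multinomial probabilities (natural log)."""

    values: np.ndarray          # region x cell
    region_ids: np.ndarray
    cells: list[str]
    batch_corrected: bool = False

    @property
    def shape(self):
        return self.values.shape


class TopicModel:
    """LDA over a region x cell count matrix.

    Parameters
    ----------
    mat : CountMatrix
        Counts; every cell must have at least one cut (filter first).
    n_topic : int
        Number of topics K.  The fits used for imputation typically set K
        near the number of expected cell states.
    alpha, beta : float, optional
        Symmetric Dirichlet priors on cell-topic and topic-region weights;
        defaults 1/K and 0.1 (weak priors, in the range the variational
        fitter accepts).
    """

    def __init__(self, mat: CountMatrix, n_topic: int,
                 alpha: float | None = None, beta: float = 0.1):
        if n_topic < 1:
            raise ValueError("n_topic must be >= 1")
        totals = mat.cell_totals()
        if (totals == 0).any():
            bad = [mat.cells[i] for i in np.flatnonzero(totals == 0)[:3]]
            raise ValueError(
                f"cells with zero total cuts (e.g. {bad}): run quantify.filter_cells first"
            )
        self.mat = mat
        self.n_topic = int(n_topic)
        self.alpha = 1.0 / n_topic if alpha is None else float(alpha)
        self.beta = float(beta)

    def fit(self, n_iter: int = 200, seed: int = 0) -> TopicFit:
        """Variational-Bayes fit; deterministic for a fixed seed."""
        X = self.mat.Y.T.tocsr()  # cells x regions, sklearn document orientation
        lda = LatentDirichletAllocation(
            n_components=self.n_topic,
            doc_topic_prior=self.alpha,
            topic_word_prior=self.beta,
            max_iter=n_iter,
            learning_method="batch",
            random_state=int(seed),
            evaluate_every=-1,
        )
        theta = lda.fit_transform(X)
        theta = theta / theta.sum(axis=1, keepdims=True)
        phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
        return TopicFit(
            n_topic=self.n_topic,
            doc_topic=theta,
            topic_term=phi,
            cells=list(self.mat.cells),
            region_ids=self.mat.regions.ids,
            log_likelihood=[float(lda.score(X))],
            seed=int(seed),
        )


def fit_topics(mat: CountMatrix, K: int, alpha: float | None = None,
               beta: float = 0.1, n_iter: int = 200, seed: int = 0) -> TopicFit:
    """Convenience wrapper: ``TopicModel(mat, K, ...).fit(...)``."""
    return TopicModel(mat, K, alpha=alpha, beta=beta).fit(n_iter=n_iter, seed=seed)


def impute_signal(fit: TopicFit) -> ImputedSignal:
    """Natural-log reconstructed probabilities, region x cell; exp-columns sum to 1."""
    probs = fit.topic_term.T @ fit.doc_topic.T  # region x cell
    return ImputedSignal(
        values=np.log(np.maximum(probs, 1e-300)),
        region_ids=fit.region_ids,
        cells=list(fit.cells),
    )


def correct_batch(values: np.ndarray, batch: pd.Series | np.ndarray,
                  cluster: pd.Series | np.ndarray,
                  cells: list[str] | None = None) -> np.ndarray:
    """Remove per-batch shifts within each cluster; cluster means are preserved.

    ``values`` is cell x dim (latent coordinates or signal transposed).  The
    model is value ~ cluster + cluster:batch by least squares per dimension;
    the batch terms (per-(cluster, batch) mean deviations from the cluster
    mean, which is the weighted sum-to-zero OLS solution) are subtracted.
    A cluster observed in a single batch has nothing identifiable to remove
    and is skipped with a warning.
    """
    V = np.asarray(values, dtype=float)
    b = np.asarray(batch.reindex(cells) if isinstance(batch, pd.Series) and cells is not None else batch)
    c = np.asarray(cluster.reindex(cells) if isinstance(cluster, pd.Series) and cells is not None else cluster)
    if len(b) != V.shape[0] or len(c) != V.shape[0]:
        raise ValueError("batch/cluster labels must match the number of rows")
    out = V.copy()
    for cl in pd.unique(c):
        idx = np.flatnonzero(c == cl)
        batches = pd.unique(b[idx])
        if len(batches) < 2:
            warnings.warn(f"cluster {cl!r} confined to one batch: skipping its batch term")
            continue
        cluster_mean = V[idx].mean(axis=0)
        for bt in batches:
            sub = idx[b[idx] == bt]
            out[sub] -= V[sub].mean(axis=0) - cluster_mean
    return out


def latent_log_odds(fit: TopicFit, eps: float = 1e-8) -> np.ndarray:
    """Cell x K log-odds transform of doc-topic weights, the default batch-correction space."""
    th = np.clip(fit.doc_topic, eps, 1 - eps)
    return np.log(th / (1 - th))


def cluster_cells(latent: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Seeded k-means labels on the latent coordinates."""
    X = np.asarray(latent, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("latent coordinates must be finite")
    if X.shape[0] < k:
        raise ValueError(f"cannot form {k} clusters from {X.shape[0]} cells")
    if np.allclose(X, X[0]):
        return np.zeros(X.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    return km.fit_predict(X)


@dataclass
class PCAProjection:
    scores: np.ndarray        # cell x PC
    loadings: np.ndarray      # region x PC
    variance_fraction: np.ndarray
    region_means: np.ndarray  # per-region centering used
    region_ids: np.ndarray
    cells: list[str]


def project_pca(signal: ImputedSignal, region_mask: np.ndarray | None = None,
                n_components: int | None = None) -> PCAProjection:
    """Region-centered PCA of the imputed signal (optionally restricted to dynamic bins)."""
    V = signal.values
    ids = signal.region_ids
    if region_mask is not None:
        V = V[np.asarray(region_mask)] if np.asarray(region_mask).dtype == bool else V[region_mask]
        ids = ids[np.asarray(region_mask)]
    if V.shape[0] < 2 or V.shape[1] < 2:
        raise ValueError("PCA needs at least 2 regions and 2 cells")
    X = V.T  # cells x regions
    if np.allclose(X, X[0]):
        raise ValueError("constant signal matrix: PCA undefined")
    n_components = min(X.shape) - 1 if n_components is None else n_components
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAProjection(
        scores=scores,
        loadings=pca.components_.T,
        variance_fraction=pca.explained_variance_ratio_,
        region_means=pca.mean_,
        region_ids=ids,
        cells=list(signal.cells),
    )
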