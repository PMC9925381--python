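"""Differential histone-mark analysis by Poisson deviance tests.

Per genomic region, counts across cells are modelled as Poisson with a
per-cell exposure offset (log total cuts, so sequencing depth cannot
masquerade as biology).  A null model with one shared rate is compared to a
full model with one rate per cell type; twice the log-likelihood-ratio is
the deviance difference, chi-square distributed with (#types - 1) degrees
of freedom under the null.  Because both models are purely categorical the
maximum-likelihood rates have closed forms (per-group count sums over
exposure sums), which this module uses; the estimates and deviances are
identical to an iterative GLM fit.

Downstream utilities: Benjamini-Hochberg q-values, mark-specific dynamic
calls (q < 1e-50 for the active marks and H3K27me3, q < 1e-9 for H3K9me3),
log2 fold changes against a reference population (HSPCs in the study
design), fate-independence classification of dynamic bins, and selection
of the most-depleted regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

DEFAULT_Q_THRESHOLDS = {
    "H3K4me1": 1e-50,
    "H3K4me3": 1e-50,
    "H3K27me3": 1e-50,
    "H3K9me3": 1e-9,
}


@dataclass
class DiffResult:
    """Per-region deviance test results and per-type log2 fold changes."""

    table: pd.DataFrame          # index region id; deviance_null, deviance_full, deviance_diff, df, pvalue, qvalue, dynamic
    log2_fold: pd.DataFrame      # region x type (reference column all zeros)
    reference: str
    types: list[str]
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        n = len(self.table)
        ndyn = int(self.table["dynamic"].sum()) if "dynamic" in self.table else 0
        lines = [
            f"Poisson deviance test: {n} regions, types {self.types} (reference {self.reference})",
            f"median deviance difference: {self.table['deviance_diff'].median():.3g}",
            f"regions with q < 0.05: {(self.table['qvalue'] < 0.05).sum()}",
        ]
        if "dynamic" in self.table:
            lines.append(f"dynamic regions at mark threshold: {ndyn}")
        return "\n".join(lines)


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """2 * sum[y log(y/mu) - (y - mu)] along the last axis, 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return 2.0 * (term - (y - mu)).sum(axis=-1)


class PoissonDiffModel:
    """Null-versus-full Poisson comparison for every region of a count matrix.

    Parameters
    ----------
    Y : array or CountMatrix-like, region x cell counts
    celltype : per-cell labels
    offset : per-cell log exposure; defaults to log of the cell's total cuts
    reference : label whose rate the fold changes are measured against
    """

    def __init__(self, Y, celltype, offset: np.ndarray | None = None,
                 reference: str | None = None, region_ids=None):
        if hasattr(Y, "dense"):  # CountMatrix
            region_ids = Y.regions.ids if region_ids is None else region_ids
            celltype = (celltype.reindex(Y.cells)
                        if isinstance(celltype, pd.Series) else celltype)
            Y = Y.dense()
        self.Y = np.atleast_2d(np.asarray(Y, dtype=float))
        self.labels = np.asarray(celltype)
        if self.labels.shape[0] != self.Y.shape[1]:
            raise ValueError("celltype labels must match the number of cells")
        counts = pd.Series(self.labels).value_counts()
        empty = counts[counts == 0]
        if len(empty):
            warnings.warn(f"dropping empty cell types: {list(empty.index)}")
        self.types = sorted(counts.index.tolist())
        self.reference = self.types[0] if reference is None else str(reference)
        if self.reference not in self.types:
            raise ValueError(f"reference type {self.reference!r} not present")
        if offset is None:
            totals = self.Y.sum(axis=0)
            if (totals <= 0).any():
                raise ValueError("cells with zero totals: filter before testing")
            offset = np.log(totals)
        self.offset = np.asarray(offset, dtype=float)
        if not np.all(np.isfinite(self.offset)):
            raise ValueError("offsets must be finite")
        self.region_ids = (np.asarray(region_ids) if region_ids is not None
                           else np.array([f"r{i}" for i in range(self.Y.shape[0])]))

    def fit(self) -> DiffResult:
        """Closed-form MLE rates, deviances and chi-square p-values per region."""
        Y, labels = self.Y, self.labels
        expo = np.exp(self.offset)                     # per-cell exposure
        total_expo = expo.sum()
        row_tot = Y.sum(axis=1)

        # null: one rate; mu_c = rate * exposure_c
        null_rate = row_tot / total_expo
        mu_null = null_rate[:, None] * expo[None, :]
        dev_null = _poisson_deviance(Y, np.maximum(mu_null, 1e-300))

        # full: one rate per cell type
        mu_full = np.empty_like(Y)
        type_rates = {}
        for t in self.types:
            idx = np.flatnonzero(labels == t)
            rate_t = Y[:, idx].sum(axis=1) / expo[idx].sum()
            type_rates[t] = rate_t
            mu_full[:, idx] = rate_t[:, None] * expo[None, idx]
        dev_full = _poisson_deviance(Y, np.maximum(mu_full, 1e-300))

        df = len(self.types) - 1
        diff = np.maximum(dev_null - dev_full, 0.0)    # nesting; clip numerical dust
        if df > 0:
            pvals = chi2.sf(diff, df)
        else:
            pvals = np.ones_like(diff)
        all_zero = row_tot == 0
        pvals = np.where(all_zero, 1.0, pvals)

        ref_rate = type_rates[self.reference]
        l2f = {}
        with np.errstate(divide="ignore", invalid="ignore"):
            for t in self.types:
                f = np.log2(type_rates[t]) - np.log2(ref_rate)
                l2f[t] = np.where(all_zero, 0.0, f)
        l2f[self.reference] = np.zeros(Y.shape[0])

        table = pd.DataFrame(
            {
                "deviance_null": dev_null,
                "deviance_full": dev_full,
                "deviance_diff": diff,
                "df": df,
                "pvalue": pvals,
                "qvalue": adjust_q(pvals),
            },
            index=pd.Index(self.region_ids, name="region"),
        )
        log2_fold = pd.DataFrame(l2f, index=table.index)[self.types]
        return DiffResult(table=table, log2_fold=log2_fold,
                          reference=self.reference, types=self.types,
                          params={"n_cell": Y.shape[1], "df": df})


def fit_region_glm(Y, celltype, offset=None, reference=None, region_ids=None) -> DiffResult:
    """Convenience wrapper: ``PoissonDiffModel(...).fit()``."""
    return PoissonDiffModel(Y, celltype, offset=offset, reference=reference,
                            region_ids=region_ids).fit()


def adjust_q(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_dynamic(res: DiffResult, mark: str,
                 q_thresholds: dict[str, float] | None = None) -> np.ndarray:
    """Flag regions with q below the mark-specific threshold; stored on the result."""
    thresholds = DEFAULT_Q_THRESHOLDS if q_thresholds is None else q_thresholds
    if mark not in thresholds:
        raise KeyError(f"unknown mark {mark!r}; known: {sorted(thresholds)}")
    thr = thresholds[mark]
    if not 0 < thr <= 1:
        raise ValueError("q threshold must be in (0, 1]")
    flags = res.table["qvalue"].to_numpy() < thr
    res.table["dynamic"] = flags
    res.params["mark"] = mark
    res.params["q_threshold"] = thr
    return flags


def fold_change_vs_reference(pseudobulk: pd.DataFrame, reference: str,
                             pseudo: float = 0.0) -> pd.DataFrame:
    """log2 of depth-normalized pseudobulk rate ratios vs the reference group.

    ``pseudobulk`` is group x region counts.  This is the simple ratio
    estimator; at high counts it agrees with the GLM coefficients of
    :class:`PoissonDiffModel` (same MLE under categorical design).
    """
    if reference not in pseudobulk.index:
        raise ValueError(f"reference group {reference!r} absent from pseudobulk")
    depth = pseudobulk.sum(axis=1).astype(float)
    rates = (pseudobulk.astype(float).add(pseudo)).div(depth, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        l2f = np.log2(rates) - np.log2(rates.loc[reference])
    return l2f.T  # region x group


def classify_fate_independent(res: DiffResult, min_effect: float = 0.0) -> pd.DataFrame:
    """Fraction of changing bins per (type, direction) that change in every type.

    A region "changes" in non-reference type t with direction d (gain/loss)
    iff it is dynamic and sign(log2FC_t) = d with |log2FC_t| > min_effect.
    It is fate-independent for direction d iff it changes in ALL
    non-reference types with that direction.  The returned table gives, per
    (type, direction), n_changing, n_fate_independent and their ratio
    (NaN with a warning when nothing changes).
    """
    if "dynamic" not in res.table:
        raise ValueError("run call_dynamic first")
    others = [t for t in res.types if t != res.reference]
    if not others:
        raise ValueError("no non-reference types")
    dyn = res.table["dynamic"].to_numpy()
    rows = []
    per_region = {}
    for d, name in ((1, "gain"), (-1, "loss")):
        change = {}
        for t in others:
            f = res.log2_fold[t].to_numpy()
            change[t] = dyn & (np.sign(f) == d) & (np.abs(f) > min_effect)
        shared = np.logical_and.reduce([change[t] for t in others])
        per_region[name] = shared
        for t in others:
            n_change = int(change[t].sum())
            n_shared = int((change[t] & shared).sum())
            frac = n_shared / n_change if n_change else float("nan")
            rows.append((t, name, n_change, n_shared, frac))
    out = pd.DataFrame(rows, columns=["celltype", "direction", "n_changing",
                                      "n_fate_independent", "fraction"])
    if out["n_changing"].sum() == 0:
        warnings.warn("no dynamic regions: fate-independent fractions undefined")
    region_class = pd.DataFrame(per_region, index=res.table.index)
    out.attrs["per_region"] = region_class
    return out


def select_top_depleted(folds: pd.Series, k: int = 150) -> list[str]:
    """Ids of the k most-depleted regions (most negative log2FC), ties by id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    s = pd.Series(folds)
    if k > len(s):
        warnings.warn(f"k={k} exceeds {len(s)} regions: returning all")
        k = len(s)
    order = s.to_frame("fold").reset_index()
    order.columns = ["id", "fold"]
    order = order.sort_values(["fold", "id"], kind="stable")
    return order["id"].head(k).tolist()
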