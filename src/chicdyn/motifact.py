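"""Single-cell TF motif activity inference (MARA-style ridge regression).

The batch-corrected log-imputed signal Y[g, c] in region g and cell c is
modelled as a linear combination of motif site counts:

    Y[g, c] = sum_m N[g, m] * A[m, c] + eps,   eps ~ Gaussian

where N is the region x motif site-count design and A[m, c] the activity of
motif m in cell c.  A is estimated by ridge regression with one L2 penalty
shared across cells (so activities are comparable between cells), the
penalty chosen by an 80/20 cross-validation split over regions.  Motif
significance is a z-score — the root-mean-square over cells of the
activity-to-standard-error ratio — thresholded at 0.7 by default.

The signal is centered per region across cells before the fit (activities
then express deviation from the average cell, instead of every motif
absorbing the mean profile) and design columns are standardized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_Z_THRESHOLD = 0.7


@dataclass
class MotifDesign:
    """Nonnegative region x motif site counts with aligned registries."""

    N: np.ndarray
    motif_names: list[str]
    region_ids: np.ndarray

    def __post_init__(self):
        self.N = np.asarray(self.N, dtype=float)
        if (self.N < 0).any():
            raise ValueError("site counts must be nonnegative")
        if self.N.shape != (len(self.region_ids), len(self.motif_names)):
            raise ValueError("design shape does not match registries")
        keep = self.N.sum(axis=0) > 0
        if not keep.all():
            dropped = [m for m, k in zip(self.motif_names, keep) if not k]
            warnings.warn(f"dropping all-zero motif columns: {dropped}")
            self.N = self.N[:, keep]
            self.motif_names = [m for m, k in zip(self.motif_names, keep) if k]


@dataclass
class ActivityFit:
    """Estimated activities, the selected penalty, and significance scores."""

    activities: pd.DataFrame     # motif x cell
    lam: float
    cv_errors: pd.Series         # lambda -> mean held-out MSE
    residual_variance: np.ndarray  # per cell
    standard_errors: pd.DataFrame  # motif x cell
    zscores: pd.Series = field(default=None)
    significant: pd.Series = field(default=None)
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        sig = self.significant[self.significant].index.tolist() if self.significant is not None else []
        return "\n".join([
            f"Motif activities: {self.activities.shape[0]} motifs x {self.activities.shape[1]} cells",
            f"selected ridge penalty lambda = {self.lam:.4g}",
            f"significant motifs (z > {self.params.get('z_threshold', DEFAULT_Z_THRESHOLD)}): {sig}",
        ])


def ridge_solve(N: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Solve (N'N + lam I) A = N'Y for all columns of Y at once."""
    G = N.T @ N + lam * np.eye(N.shape[1])
    return np.linalg.solve(G, N.T @ Y)


def default_lambda_grid(N: np.ndarray, n: int = 13) -> np.ndarray:
    """Log-spaced grid 1e-3..1e3 times the mean diagonal of N'N."""
    scale = float(np.mean(np.einsum("ij,ij->j", N, N)))
    return scale * np.logspace(-3, 3, n)


class MotifActivityModel:
    """Ridge model of imputed signal on motif site counts.

    Parameters
    ----------
    signal : array (region x cell) or ImputedSignal
    design : MotifDesign
    center_signal, standardize_design : bool
        Preprocessing toggles; both on by default (see module docstring).
    """

    def __init__(self, signal, design: MotifDesign,
                 center_signal: bool = True, standardize_design: bool = True):
        if hasattr(signal, "values") and hasattr(signal, "region_ids"):
            if len(signal.region_ids) != len(design.region_ids) or \
                    not np.array_equal(np.asarray(signal.region_ids), np.asarray(design.region_ids)):
                raise ValueError("signal and design region registries differ")
            self.cells = list(signal.cells)
            Y = np.asarray(signal.values, dtype=float)
        else:
            Y = np.atleast_2d(np.asarray(signal, dtype=float))
            self.cells = [f"cell{i}" for i in range(Y.shape[1])]
        if Y.shape[0] != design.N.shape[0]:
            raise ValueError("signal and design disagree on the number of regions")
        self.design = design
        self.Y_raw = Y
        self.center_signal = center_signal
        self.standardize_design = standardize_design

    def _prepare(self):
        Y = self.Y_raw
        if self.center_signal:
            Y = Y - Y.mean(axis=1, keepdims=True)
        N = self.design.N
        if self.standardize_design:
            sd = N.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
            N = (N - N.mean(axis=0)) / sd if self.center_signal else N / sd
        return N, Y

    def fit(self, lambda_grid: np.ndarray | None = None,
            cv_fraction: float = 0.8, seed: int = 0,
            z_threshold: float = DEFAULT_Z_THRESHOLD) -> ActivityFit:
        """Select lambda by an 80/20 region split, then solve on all regions."""
        N, Y = self._prepare()
        G, M = N.shape
        if lambda_grid is None:
            lambda_grid = default_lambda_grid(self.design.N)
        lambda_grid = np.asarray(lambda_grid, dtype=float)
        if lambda_grid.size == 0:
            raise ValueError("empty lambda grid")
        if (lambda_grid == 0).any() and np.linalg.matrix_rank(N) < M:
            warnings.warn("singular design: dropping lambda = 0 from the grid")
            lambda_grid = lambda_grid[lambda_grid > 0]

        rng = np.random.default_rng(int(seed))
        perm = rng.permutation(G)
        n_train = max(1, int(round(cv_fraction * G)))
        train, test = perm[:n_train], perm[n_train:]
        cv = {}
        for lam in lambda_grid:
            A = ridge_solve(N[train], Y[train], lam)
            if test.size:
                resid = Y[test] - N[test] @ A
                cv[float(lam)] = float(np.mean(resid ** 2))
            else:
                cv[float(lam)] = float("nan")
        cv_s = pd.Series(cv).sort_index()
        lam = float(cv_s.idxmin()) if np.isfinite(list(cv.values())).any() else float(lambda_grid[0])

        A = ridge_solve(N, Y, lam)
        resid = Y - N @ A
        dof = max(G - M, 1)
        sigma2 = (resid ** 2).sum(axis=0) / dof     # per cell
        # ridge sandwich: Var(A_.c) = sigma2_c * (N'N+lam I)^-1 N'N (N'N+lam I)^-1
        Ginv = np.linalg.inv(N.T @ N + lam * np.eye(M))
        H = Ginv @ (N.T @ N) @ Ginv
        se = np.sqrt(np.maximum(np.outer(np.diag(H), sigma2), 1e-24))

        motif_idx = pd.Index(self.design.motif_names, name="motif")
        fit = ActivityFit(
            activities=pd.DataFrame(A, index=motif_idx, columns=self.cells),
            lam=lam,
            cv_errors=cv_s,
            residual_variance=sigma2,
            standard_errors=pd.DataFrame(se, index=motif_idx, columns=self.cells),
            params={"seed": int(seed), "cv_fraction": cv_fraction,
                    "z_threshold": z_threshold,
                    "center_signal": self.center_signal,
                    "standardize_design": self.standardize_design},
        )
        fit.zscores, fit.significant = motif_zscores(fit, threshold=z_threshold)
        return fit


def fit_activities(signal, design: MotifDesign, lambda_grid=None,
                   cv_fraction: float = 0.8, seed: int = 0, **kw) -> ActivityFit:
    """Convenience wrapper: ``MotifActivityModel(signal, design).fit(...)``."""
    return MotifActivityModel(signal, design).fit(
        lambda_grid=lambda_grid, cv_fraction=cv_fraction, seed=seed, **kw)


def motif_zscores(fit: ActivityFit, threshold: float = DEFAULT_Z_THRESHOLD):
    """Per-motif z = RMS over cells of activity / standard error; significant iff z > threshold."""
    if (fit.residual_variance <= 0).any():
        warnings.warn("zero residual variance in some cells: flooring standard errors")
    ratio = fit.activities.to_numpy() / fit.standard_errors.to_numpy()
    z = pd.Series(np.sqrt(np.mean(ratio ** 2, axis=1)), index=fit.activities.index,
                  name="zscore")
    return z, (z > threshold).rename("significant")
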