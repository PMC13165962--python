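"""L1-sparse spectrogram pre-selection.

Flattened, per-column standardized log-Mel spectrograms (rows = clips,
columns = the 80 x T_fixed time-frequency cells in row-major, frequency-major
order) are regressed on the 0/1 class code with the lasso,

    beta_hat = argmin_beta  (1/2n) ||y - X beta||_2^2 + lambda ||beta||_1,

the penalty weight chosen by patient-grouped cross-validation over a
log-spaced grid below lambda_max = max|X^T y| / n. Cells with nonzero
coefficients are kept; the keep pattern is reshaped back to the (80, T_fixed)
grid and applied as a mask before the network, with dropped cells set to the
clip mean (the neutral value on a standardized log-energy scale). In the
orthonormal-design case the solution coordinates reduce to the
soft-threshold closed form, which serves as this module's oracle.

The mask is always fit on training rows only and reapplied unchanged to
held-out data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import GroupKFold, KFold

from .features import LogMelSpec, standardize_spec

T_FIXED = 501  # frames on the fixed flattening grid (5 s at 10 ms hop)
N_MELS = 80


@dataclass
class LassoDesign:
    X: np.ndarray                 # (n, p) standardized
    y: np.ndarray                 # (n,) 0/1
    means: np.ndarray
    scales: np.ndarray
    constant_cols: np.ndarray     # boolean flags
    frame_grid: Tuple[int, int] = (N_MELS, T_FIXED)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class LassoSolution:
    beta_hat: np.ndarray
    lambda_: float
    lambda_path: np.ndarray
    cv_error_curve: np.ndarray
    residual: np.ndarray
    frame_grid: Tuple[int, int]


@dataclass
class FeatureMask:
    keep: np.ndarray              # boolean (n_mels, T_fixed)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


# ---------------------------------------------------------------------------

def pad_or_crop(values: np.ndarray, t_fixed: int = T_FIXED) -> np.ndarray:
    """Fix the frame count: right-pad short matrices with the clip mean,
    center-crop long ones."""
    F, T = values.shape
    if T == t_fixed:
        return values
    if T < t_fixed:
        pad = np.full((F, t_fixed - T), values.mean())
        return np.concatenate([values, pad], axis=1)
    start = (T - t_fixed) // 2
    return values[:, start:start + t_fixed]


def flatten_specs(specs: Sequence[LogMelSpec], t_fixed: int = T_FIXED) -> np.ndarray:
    """Row-major (frequency-major) flattening of fixed-grid spectrograms."""
    return np.stack([pad_or_crop(s.values, t_fixed).ravel(order="C")
                     for s in specs])


def standardize_features(raw: np.ndarray, y: np.ndarray,
                         frame_grid: Tuple[int, int] = (N_MELS, T_FIXED),
                         ) -> LassoDesign:
    """Per-column zero-mean/unit-variance standardization; constant columns
    get scale 1 and are flagged. Returns the design plus stored statistics."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    means = raw.mean(axis=0)
    scales = raw.std(axis=0)
    constant = scales < 1e-12
    scales = np.where(constant, 1.0, scales)
    X = (raw - means) / scales
    X[:, constant] = 0.0
    return LassoDesign(X=X, y=np.asarray(y, dtype=np.float64), means=means,
                       scales=scales, constant_cols=constant,
                       frame_grid=frame_grid)


def apply_standardization(raw: np.ndarray, design: LassoDesign) -> np.ndarray:
    """Re-apply *training* column statistics to held-out rows."""
    X = (np.asarray(raw, dtype=np.float64) - design.means) / design.scales
    X[:, design.constant_cols] = 0.0
    return X


def soft_threshold(beta_ols: float, lambda_: float) -> float:
    """Closed-form lasso coordinate for an orthonormal design:
    sign(b) * max(|b| - lambda, 0)."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be nonnegative")
    return float(np.sign(beta_ols) * max(abs(beta_ols) - lambda_, 0.0))


def lambda_grid_for(design: LassoDesign, n_lambdas: int = 100,
                    eps: float = 1e-3) -> np.ndarray:
    """Log-spaced grid from lambda_max (null-model threshold) down to
    eps*lambda_max."""
    lam_max = float(np.max(np.abs(design.X.T @ design.y)) / design.n)
    return np.logspace(np.log10(lam_max), np.log10(eps * lam_max), n_lambdas)


def fit_lasso_cv(design: LassoDesign, lambda_grid: np.ndarray | None = None,
                 cv_folds: int = 5, seed: int = 0,
                 groups: Sequence | None = None,
                 max_iter: int = 5000, tol: float = 1e-5) -> LassoSolution:
    """Choose lambda by CV squared error over the grid, refit on all rows.

    ``groups`` (e.g. patient ids) makes the internal CV leakage-free by
    keeping each group's rows in one fold.

    The response is centered before fitting (equivalent to an intercept at
    the class prevalence): the standardized columns have zero mean, so
    without centering no coefficient could absorb the 0/1 offset and the
    CV would compare models against a mis-specified baseline. Coefficient
    estimates are unchanged by the centering.
    """
    if len(np.unique(design.y)) < 2:
        raise ValueError("degenerate one-class response")
    y = design.y - design.y.mean()
    if design.n < cv_folds or cv_folds < 2:
        raise ValueError("need n >= cv_folds >= 2")
    if lambda_grid is None:
        lambda_grid = lambda_grid_for(design)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=np.float64))[::-1]
    if groups is not None:
        groups = np.asarray(groups)
        n_groups = len(np.unique(groups))
        splitter = GroupKFold(n_splits=min(cv_folds, n_groups))
        cv_iter = list(splitter.split(design.X, y, groups))
    else:
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        cv_iter = list(splitter.split(design.X, y))
    model = LassoCV(alphas=lambda_grid, fit_intercept=False, cv=cv_iter,
                    max_iter=max_iter, tol=tol)
    model.fit(design.X, y)
    # mse_path_ rows follow model.alphas_ (descending)
    order = np.argsort(model.alphas_)[::-1]
    cv_curve = model.mse_path_.mean(axis=1)[order]
    beta = model.coef_.astype(np.float64)
    return LassoSolution(beta_hat=beta, lambda_=float(model.alpha_),
                         lambda_path=model.alphas_[order],
                         cv_error_curve=cv_curve,
                         residual=design.y - design.y.mean() - design.X @ beta,
                         frame_grid=design.frame_grid)


def fit_lasso(design: LassoDesign, lambda_: float,
              max_iter: int = 50000, tol: float = 1e-10) -> np.ndarray:
    """Single lasso fit at a fixed penalty (Eq-form objective, no intercept)."""
    model = Lasso(alpha=lambda_, fit_intercept=False, max_iter=max_iter, tol=tol)
    model.fit(design.X, design.y)
    return model.coef_.astype(np.float64)


def mask_from_coefficients(solution: LassoSolution,
                           frame_grid: Tuple[int, int] | None = None) -> FeatureMask:
    grid = frame_grid or solution.frame_grid
    p = grid[0] * grid[1]
    if solution.beta_hat.shape[0] != p:
        raise ValueError(f"coefficient length {solution.beta_hat.shape[0]} "
                         f"does not match grid {grid}")
    keep = (solution.beta_hat != 0).reshape(grid, order="C")
    return FeatureMask(keep=keep)


def apply_mask(values: np.ndarray, mask: FeatureMask) -> np.ndarray:
    """Keep selected cells; set dropped cells to the clip mean (neutral on a
    standardized log-energy scale). Input must be on the fixed grid."""
    if values.shape != mask.keep.shape:
        raise ValueError(f"shape mismatch: {values.shape} vs {mask.keep.shape}")
    out = np.where(mask.keep, values, values.mean())
    return out


# ---------------------------------------------------------------------------
# end-to-end selector used by the training pipeline
# ---------------------------------------------------------------------------

class SpectrogramSelector:
    """Fit-on-train / apply-everywhere wrapper: per-clip standardization,
    fixed-grid alignment, lasso mask fitting, and mask application."""

    def __init__(self, t_fixed: int = T_FIXED, n_lambdas: int = 100,
                 cv_folds: int = 5, seed: int = 0, enabled: bool = True,
                 max_iter: int = 5000, tol: float = 1e-4):
        self.t_fixed = t_fixed
        self.n_lambdas = n_lambdas
        self.cv_folds = cv_folds
        self.seed = seed
        self.enabled = enabled
        self.max_iter = max_iter
        self.tol = tol
        self.mask: FeatureMask | None = None
        self.solution: LassoSolution | None = None

    def _clip_matrix(self, spec: LogMelSpec) -> np.ndarray:
        return pad_or_crop(standardize_spec(spec.values), self.t_fixed)

    def fit(self, specs: Sequence[LogMelSpec], labels: Sequence[int],
            patient_ids: Sequence[str] | None = None) -> "SpectrogramSelector":
        if not self.enabled:
            self.mask = FeatureMask(np.ones((N_MELS, self.t_fixed), dtype=bool))
            return self
        raw = np.stack([self._clip_matrix(s).ravel(order="C") for s in specs])
        design = standardize_features(raw, np.asarray(labels, dtype=float),
                                      frame_grid=(N_MELS, self.t_fixed))
        grid = lambda_grid_for(design, self.n_lambdas)
        self.solution = fit_lasso_cv(design, grid, cv_folds=self.cv_folds,
                                     seed=self.seed, groups=patient_ids,
                                     max_iter=self.max_iter, tol=self.tol)
        self.mask = mask_from_coefficients(self.solution)
        if self.mask.n_kept == 0:
            # fully-shrunk solution would blank the input; keep everything
            self.mask = FeatureMask(np.ones((N_MELS, self.t_fixed), dtype=bool))
        return self

    def transform(self, spec: LogMelSpec) -> np.ndarray:
        """Standardized, grid-aligned, masked (n_mels, t_fixed) matrix."""
        if self.mask is None:
            raise RuntimeError("selector not fitted")
        return apply_mask(self._clip_matrix(spec), self.mask)

    def save_mask(self, path: str) -> str:
        """Persist the mask (compressed boolean array + JSON sidecar with
        the selected penalty, kept-cell count, grid and flattening order)."""
        import json

        if self.mask is None:
            raise RuntimeError("selector not fitted")
        np.savez_compressed(path, keep=self.mask.keep)
        npz = path if path.endswith(".npz") else path + ".npz"
        meta = {"lambda": self.solution.lambda_ if self.solution else None,
                "n_kept": self.mask.n_kept,
                "grid": list(self.mask.keep.shape),
                "flattening": "row-major, frequency-major"}
        with open(npz + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)
        return npz


def load_mask(path: str) -> FeatureMask:
    with np.load(path) as data:
        return FeatureMask(keep=data["keep"].astype(bool))
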