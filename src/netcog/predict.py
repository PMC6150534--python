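"""Cross-validated select-average-regress prediction of cognition from
vertex-wise morphometry.

Within each training fold of a repeated k-fold split the workflow is:
robust-scale every vertex (median/IQR from training rows only), test each
scaled vertex's simple linear relationship with the ability score, keep
vertices with two-sided p <= alpha, average the selected vertices per
participant, and fit a one-coefficient linear regression of ability on that
average.  Held-out participants are scaled and averaged with the training
fold's statistics and predicted from the training model.  Per-participant
predictions are averaged over all test-fold occurrences, per selection
threshold and then across thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError
from .surface import ScaleParams, SurfaceDataset, apply_scale, robust_scale

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS = (0.05, 0.01, 0.001, 0.0005, 0.0001)


@dataclass
class CVPlan:
    """Repeated k-fold plan: k folds, n_iterations independent random
    partitions, selection p-thresholds stored strictly decreasing."""

    k: int = 5
    n_iterations: int = 100
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    seed: int = 0

    def __post_init__(self):
        self.alphas = tuple(float(a) for a in self.alphas)
        if self.k < 2:
            raise ConfigurationError("k: must be >= 2")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations: must be >= 1")
        if any(not 0 < a <= 1 for a in self.alphas):
            raise ConfigurationError("alphas: must be in (0, 1]")
        if list(self.alphas) != sorted(self.alphas, reverse=True):
            raise ConfigurationError("alphas: must be strictly decreasing")


@dataclass
class AverageModel:
    """One trained fold model: the selected-vertex mask, the intercept/slope
    of ability on the mean of selected scaled vertices, and the training
    fold's scaling parameters."""

    mask: np.ndarray  # boolean over vertices
    intercept: float
    slope: float
    scale_params: ScaleParams | None = None


@dataclass
class PredictionSet:
    """Aggregated cross-validated predictions.

    ``predictions``: DataFrame with one row per participant, one column per
    alpha (NaN where a participant never received a prediction at that
    threshold) and an ``average`` column (mean over non-missing per-alpha
    predictions).  ``empty_fraction``: per alpha, the fraction of training
    folds in which no vertex survived selection.  ``fold_slopes``: long-format
    record of every trained fold's slope.
    """

    predictions: pd.DataFrame
    empty_fraction: dict[float, float]
    fold_slopes: pd.DataFrame
    plan: CVPlan


def univariate_select(X_scaled, y, alpha: float) -> np.ndarray:
    """Boolean mask of vertices whose simple-regression two-sided p <= alpha.

    The per-vertex test is the Pearson-correlation t-test with n-2 degrees of
    freedom, computed vectorized across columns.  Zero-variance columns are
    never selected.
    """
    X = np.asarray(X_scaled, float)
    y = np.asarray(y, float)
    n = len(y)
    if n <= 3:
        raise InsufficientDataError("univariate selection needs n > 3")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    ok = denom > 0
    r = np.zeros(X.shape[1])
    r[ok] = (Xc.T @ yc)[ok] / denom[ok]
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[~ok] = 1.0
    return p <= alpha


def fit_average_model(X_scaled, mask, y) -> AverageModel:
    """OLS of ability on the per-participant mean of masked scaled vertices."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise InsufficientDataError("empty vertex mask")
    x = np.asarray(X_scaled, float)[:, mask].mean(axis=1)
    y = np.asarray(y, float)
    vx = np.var(x)
    if vx == 0:
        slope = 0.0
    else:
        slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
    intercept = float(y.mean() - slope * x.mean())
    return AverageModel(mask=mask, intercept=intercept, slope=slope)


def predict_from_model(model: AverageModel, X_new_raw) -> np.ndarray:
    """Predict new participants: scale with the model's own training-fold
    parameters, average the masked vertices, apply the linear model."""
    X = np.asarray(X_new_raw, float)
    if model.scale_params is not None:
        X = apply_scale(model.scale_params, X)
    x = X[:, model.mask].mean(axis=1)
    return model.intercept + model.slope * x


def repeated_cv_predict(ds: SurfaceDataset, y, plan: CVPlan) -> PredictionSet:
    """Run the full repeated k-fold workflow on one network's matrix.

    Iteration i draws its partition from a sub-seed derived from
    ``(plan.seed, i)``, so increasing ``n_iterations`` never changes earlier
    iterations.  Scaling, selection and fitting only ever see training rows.
    Folds in which no vertex survives a threshold contribute no predictions
    at that threshold and are tallied in ``empty_fraction``.
    """
    y = np.asarray(y, float)
    keep = np.isfinite(y)
    if not keep.all():
        logger.warning("excluding %d participants with missing ability", int((~keep).sum()))
    X_all = ds.values[keep]
    ids = ds.participant_ids[keep]
    y = y[keep]
    n = len(y)
    alphas = plan.alphas
    A = len(alphas)

    pred_sum = np.zeros((n, A))
    pred_cnt = np.zeros((n, A), dtype=int)
    empty = np.zeros(A, dtype=int)
    slopes: list[tuple[int, int, float, float, int]] = []
    total_folds = plan.n_iterations * plan.k

    for it in range(plan.n_iterations):
        rng = np.random.default_rng([plan.seed, it])
        folds = np.array_split(rng.permutation(n), plan.k)
        for fold_i, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx, assume_unique=False)
            params, X_tr = robust_scale(X_all[train_idx])
            X_te = apply_scale(params, X_all[test_idx])
            y_tr = y[train_idx]
            for a_i, alpha in enumerate(alphas):
                mask = univariate_select(X_tr, y_tr, alpha)
                if not mask.any():
                    empty[a_i] += 1
                    continue
                model = fit_average_model(X_tr, mask, y_tr)
                preds = model.intercept + model.slope * X_te[:, mask].mean(axis=1)
                pred_sum[test_idx, a_i] += preds
                pred_cnt[test_idx, a_i] += 1
                slopes.append((it, fold_i, alpha, model.slope, int(mask.sum())))

    per_alpha = np.where(pred_cnt > 0, pred_sum / np.maximum(pred_cnt, 1), np.nan)
    finite = np.isfinite(per_alpha)
    n_avail = finite.sum(axis=1)
    average = np.where(
        n_avail > 0,
        np.where(finite, per_alpha, 0.0).sum(axis=1) / np.maximum(n_avail, 1),
        np.nan,
    )

    pred_df = pd.DataFrame(per_alpha, columns=[f"alpha_{a:g}" for a in alphas])
    pred_df.insert(0, "id", ids)
    pred_df["average"] = average
    return PredictionSet(
        predictions=pred_df,
        empty_fraction={a: empty[i] / total_folds for i, a in enumerate(alphas)},
        fold_slopes=pd.DataFrame(
            slopes, columns=["iteration", "fold", "alpha", "slope", "n_selected"]
        ),
        plan=plan,
    )
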