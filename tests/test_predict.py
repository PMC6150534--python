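"""Select-average-regress cross-validated prediction workflow."""

import numpy as np
import pytest
from scipy import stats

from netcog import (
    CVPlan,
    compute_composites,
    fit_average_model,
    repeated_cv_predict,
    simulate_cohort,
    subset_network,
    univariate_select,
)
from netcog.errors import ConfigurationError, InsufficientDataError
from netcog.surface import SurfaceDataset
from conftest import planted_net7_coupling, small_config


def make_ds(X, labels=None):
    n, v = X.shape
    return SurfaceDataset(
        values=X,
        measure="thickness",
        participant_ids=np.array([f"p{i}" for i in range(n)]),
        vertex_ids=np.array([f"v{j}" for j in range(v)]),
        labels=np.ones(v, int) if labels is None else np.asarray(labels),
    )


# --- univariate selection -------------------------------------------------


def test_selection_matches_brute_force_oracle():
    """Mask identical to per-vertex pearsonr p-values computed one at a time."""
    rng = np.random.default_rng(12)
    X = rng.standard_normal((20, 50))
    y = rng.standard_normal(20)
    for alpha in (0.5, 0.05, 0.01):
        mask = univariate_select(X, y, alpha)
        oracle = np.array(
            [stats.pearsonr(X[:, j], y).pvalue <= alpha for j in range(50)]
        )
        assert np.array_equal(mask, oracle)


def test_perfect_predictor_always_selected():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((30, 5))
    y = X[:, 2].copy()
    for alpha in (0.05, 0.0001):
        assert univariate_select(X, y, alpha)[2]


def test_selection_type_one_calibration():
    """Under a permuted target, about alpha * V vertices are selected."""
    rng = np.random.default_rng(7)
    counts = []
    for _ in range(50):
        X = rng.standard_normal((40, 200))
        y = rng.standard_normal(40)
        counts.append(univariate_select(X, y, 0.05).sum())
    assert 6 < np.mean(counts) < 14  # expectation 10


def test_selection_needs_enough_rows():
    with pytest.raises(InsufficientDataError):
        univariate_select(np.zeros((3, 4)), np.zeros(3), 0.05)


# --- averaged linear model ------------------------------------------------


def test_fit_identity_when_target_is_masked_mean():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((25, 10))
    mask = np.zeros(10, bool)
    mask[[1, 4, 7]] = True
    y = X[:, mask].mean(axis=1)
    m = fit_average_model(X, mask, y)
    assert m.slope == pytest.approx(1.0)
    assert m.intercept == pytest.approx(0.0, abs=1e-12)


def test_single_vertex_mask_reduces_to_simple_regression():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((10, 3))
    y = rng.standard_normal(10)
    mask = np.array([False, True, False])
    m = fit_average_model(X, mask, y)
    slope, intercept = np.polyfit(X[:, 1], y, 1)
    assert m.slope == pytest.approx(slope)
    assert m.intercept == pytest.approx(intercept)


def test_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((10, 6))
    mask = np.ones(6, bool)
    y = rng.standard_normal(10)
    m = fit_average_model(X, mask, y)
    A = np.column_stack([np.ones(10), X.mean(axis=1)])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    assert m.intercept == pytest.approx(beta[0])
    assert m.slope == pytest.approx(beta[1])


# --- repeated CV ----------------------------------------------------------


def test_cvplan_validation():
    with pytest.raises(ConfigurationError):
        CVPlan(k=1)
    with pytest.raises(ConfigurationError):
        CVPlan(alphas=(0.01, 0.05))  # not decreasing


def test_recoverable_signal_noise_free():
    rng = np.random.default_rng(21)
    latent = rng.standard_normal(60)
    X = latent[:, None] + 0.3 * rng.standard_normal((60, 40))
    y = latent  # every vertex is a noisy copy of the target's driver
    ds = make_ds(X)
    pset = repeated_cv_predict(ds, y, CVPlan(k=5, n_iterations=5, alphas=(0.05,), seed=2))
    pred = pset.predictions["average"].to_numpy()
    assert np.corrcoef(pred, y)[0, 1] > 0.95


def test_null_target_predictions_center_on_zero():
    rng = np.random.default_rng(4)
    rs = []
    for rep in range(20):
        X = rng.standard_normal((50, 80))
        y = rng.standard_normal(50)
        pset = repeated_cv_predict(
            make_ds(X), y, CVPlan(k=5, n_iterations=3, alphas=(0.05, 0.01), seed=rep)
        )
        pred = pset.predictions["average"].to_numpy()
        ok = np.isfinite(pred)
        rs.append(np.corrcoef(pred[ok], y[ok])[0, 1])
    assert abs(np.mean(rs)) < 0.1


def test_planted_network_has_top_predictive_r():
    """With coupling only in the default-mode network, that network wins the
    single-network comparison in >= 90% of replicates."""
    wins = 0
    n_rep = 20
    for rep in range(n_rep):
        cfg = small_config(network_coupling=planted_net7_coupling(), seed=900 + rep)
        co = simulate_cohort(cfg)
        tab, _, _ = compute_composites(co.participants)
        y = tab["executive_function"].to_numpy()
        plan = CVPlan(k=5, n_iterations=3, alphas=(0.05, 0.01), seed=rep)
        rs = {}
        for net in range(1, 8):
            pset = repeated_cv_predict(subset_network(co.thickness, net), y, plan)
            pred = pset.predictions["average"].to_numpy()
            ok = np.isfinite(pred)
            rs[net] = np.corrcoef(pred[ok], y[ok])[0, 1] if ok.sum() > 3 else -np.inf
        if max(rs, key=rs.get) == 7:
            wins += 1
    assert wins >= 0.9 * n_rep


def test_leakage_guard_fold_model_ignores_its_test_rows():
    """Replacing one fold's test rows with constants leaves that fold's
    fitted slope unchanged (the model never sees its test rows)."""
    rng = np.random.default_rng(13)
    X = rng.standard_normal((40, 30))
    y = rng.standard_normal(40)
    plan = CVPlan(k=5, n_iterations=1, alphas=(0.5,), seed=77)
    base = repeated_cv_predict(make_ds(X), y, plan)

    # reconstruct iteration 0's partition exactly as the implementation does
    folds = np.array_split(np.random.default_rng([plan.seed, 0]).permutation(40), plan.k)
    test0 = folds[0]
    X2 = X.copy()
    X2[test0] = 123.456
    mod = repeated_cv_predict(make_ds(X2), y, plan)

    s_base = base.fold_slopes.query("fold == 0")["slope"].to_numpy()
    s_mod = mod.fold_slopes.query("fold == 0")["slope"].to_numpy()
    assert np.array_equal(s_base, s_mod)
    # the corruption is not a no-op: other folds (which train on those rows)
    # do change
    o_base = base.fold_slopes.query("fold != 0")["slope"].to_numpy()
    o_mod = mod.fold_slopes.query("fold != 0")["slope"].to_numpy()
    assert not np.array_equal(o_base, o_mod)


def test_alpha_one_reduces_to_mean_regression():
    """With alpha = 1 every vertex is selected and the workflow equals CV
    regression on the scaled network mean (independent reimplementation)."""
    from netcog.surface import apply_scale, robust_scale

    rng = np.random.default_rng(3)
    X = rng.standard_normal((30, 12))
    y = rng.standard_normal(30)
    plan = CVPlan(k=3, n_iterations=2, alphas=(1.0,), seed=9)
    pset = repeated_cv_predict(make_ds(X), y, plan)

    pred_sum = np.zeros(30)
    cnt = np.zeros(30)
    for it in range(2):
        folds = np.array_split(np.random.default_rng([9, it]).permutation(30), 3)
        for te in folds:
            tr = np.setdiff1d(np.arange(30), te)
            params, Xtr = robust_scale(X[tr])
            xm = Xtr.mean(axis=1)
            b = np.polyfit(xm, y[tr], 1)
            xte = apply_scale(params, X[te]).mean(axis=1)
            pred_sum[te] += b[0] * xte + b[1]
            cnt[te] += 1
    assert np.allclose(pset.predictions["average"].to_numpy(), pred_sum / cnt)
    assert pset.empty_fraction[1.0] == 0.0


def test_each_participant_predicted_once_per_iteration():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((23, 8))
    y = rng.standard_normal(23)
    plan = CVPlan(k=5, n_iterations=4, alphas=(1.0,), seed=0)
    pset = repeated_cv_predict(make_ds(X), y, plan)
    # with alpha=1 every fold fits a model, so every participant is
    # predicted exactly n_iterations times
    assert pset.fold_slopes.shape[0] == plan.k * plan.n_iterations
    assert np.isfinite(pset.predictions["alpha_1"].to_numpy()).all()


def test_missing_ability_rows_are_excluded():
    rng = np.random.default_rng(10)
    X = rng.standard_normal((20, 6))
    y = rng.standard_normal(20)
    y[3] = np.nan
    pset = repeated_cv_predict(make_ds(X), y, CVPlan(k=4, n_iterations=1, alphas=(1.0,), seed=1))
    assert len(pset.predictions) == 19
    assert "p3" not in set(pset.predictions["id"])
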