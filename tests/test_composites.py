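"""Winsorization, PCA/varimax, and composite construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netcog import (
    REFERENCE_LOADINGS,
    TASK_BATTERY,
    TASK_NAMES,
    build_composites,
    compute_composites,
    default_config,
    pca_varimax,
    prepare_task_matrix,
    simulate_cohort,
    winsorize,
)
from netcog.errors import DegenerateInputError, InsufficientDataError
from conftest import small_config

EXECUTIVE_TASKS = {
    "flanker_rt",
    "trail_b_time",
    "spatial_wm_acc",
    "n_back_acc",
    "dot_comparison_rt",
    "digit_symbol",
}
MEMORY_TASKS = set(TASK_NAMES) - EXECUTIVE_TASKS


# --- winsorize ------------------------------------------------------------


def test_winsorize_no_outliers_unchanged():
    v = np.array([-2.9, -1.0, 0.0, 1.0, 2.9])  # max |z| < 3 by construction
    out, count = winsorize(v * v.std(ddof=1))
    assert count == 0


def test_winsorize_hand_arithmetic():
    # [0,0,0,0,0,100]: mean 16.6667, SD(ddof=1) 40.8248; at k=1.5 the
    # boundary is 16.6667 + 1.5*40.8248 = 77.9039 and only 100 is replaced.
    v = np.array([0.0, 0, 0, 0, 0, 100])
    out, count = winsorize(v, k_sd=1.5)
    assert count == 1
    assert out[-1] == pytest.approx(np.mean(v) + 1.5 * np.std(v, ddof=1))
    assert np.all(out[:-1] == 0)
    # at k=3 a single outlier among 6 values cannot exceed 3 SD of its own
    # sample, so nothing is replaced
    out3, count3 = winsorize(v, k_sd=3.0)
    assert count3 == 0 and np.array_equal(out3, v)


def test_winsorize_constant_and_short_inputs():
    out, count = winsorize(np.full(10, 7.0))
    assert count == 0 and np.all(out == 7.0)
    with pytest.raises(InsufficientDataError):
        winsorize(np.array([1.0, 2.0]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=40),
    st.floats(0.5, 4.0),
)
def test_winsorize_properties(values, k):
    """Range bounded by mean +/- k*SD of the input; rank order preserved up
    to boundary ties."""
    v = np.asarray(values)
    out, count = winsorize(v, k_sd=k)
    mu, sd = v.mean(), v.std(ddof=1)
    if sd > 0:
        assert out.min() >= mu - k * sd - 1e-6 * max(1, abs(mu))
        assert out.max() <= mu + k * sd + 1e-6 * max(1, abs(mu))
    order = np.argsort(v, kind="stable")
    assert np.all(np.diff(out[order]) >= -1e-12 * max(1.0, sd))
    if count == 0:
        assert np.array_equal(out, v)


# --- pca_varimax ----------------------------------------------------------


def _varimax_oracle(L, tol=1e-8, max_iter=2000):
    """Independent varimax: classic Lawley-Maxwell SVD iteration."""
    p, k = L.shape
    T = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = L @ T
        U, s, Vt = np.linalg.svd(L.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p))
        T = U @ Vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    return L @ T


def test_two_orthogonal_blocks_load_cleanly():
    rng = np.random.default_rng(0)
    f = rng.standard_normal((300, 2))
    X = np.column_stack([np.tile(f[:, 0], (6, 1)).T, np.tile(f[:, 1], (5, 1)).T])
    sol = pca_varimax(X)
    assert np.array_equal(sol.assignment, np.array([0] * 6 + [1] * 5))
    on = np.abs(sol.loadings[np.arange(11), sol.assignment])
    off = np.abs(sol.loadings[np.arange(11), 1 - sol.assignment])
    assert np.all(on > 0.99)
    assert np.all(off < 0.01)


def test_loading_recovery_against_population_oracle():
    """At n=5000 with orthogonal factors the sample PCA/varimax solution
    matches the population correlation matrix's own solution within 0.05."""
    cfg = small_config(n_participants=5000, latent_factor_correlation=0.0, seed=55)
    co = simulate_cohort(cfg)
    M, _ = prepare_task_matrix(co.participants)
    sol = pca_varimax(M)

    # population R implied by the generative model (unit task variances)
    L = cfg.task_loading_matrix
    noise = cfg.resolved_task_noise_sd()
    R = L @ L.T + np.diag(noise**2)
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1][:2]
    L_pop = eigvec[:, order] * np.sqrt(eigval[order])
    L_pop = _varimax_oracle(L_pop)
    # align sign/order to the sample solution's convention
    ss = (L_pop**2).sum(axis=0)
    L_pop = L_pop[:, np.argsort(ss)[::-1]]
    for j in range(2):
        i = int(np.argmax(np.abs(L_pop[:, j])))
        if L_pop[i, j] < 0:
            L_pop[:, j] = -L_pop[:, j]

    assert np.abs(sol.loadings - L_pop).max() < 0.05
    # the block structure of the generating loadings is recovered exactly
    assert np.array_equal(sol.assignment, np.argmax(np.abs(REFERENCE_LOADINGS), axis=1))


def test_rotation_is_orthogonal():
    """Varimax preserves communalities: L_rot L_rot' == L_unrot L_unrot'."""
    cfg = small_config(seed=8)
    co = simulate_cohort(cfg)
    M, _ = prepare_task_matrix(co.participants)
    sol = pca_varimax(M)
    R = np.corrcoef(M, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1][:2]
    L0 = eigvec[:, order] * np.sqrt(eigval[order])
    assert np.abs(sol.loadings @ sol.loadings.T - L0 @ L0.T).max() < 1e-8


def test_direction_handling_gives_positive_loadings():
    """After reversing lower-is-better tasks every task's dominant loading is
    positive, as in the printed two-component solution."""
    co = simulate_cohort(default_config(seed=33))
    M, _ = prepare_task_matrix(co.participants)
    sol = pca_varimax(M)
    assert np.all(sol.loadings[np.arange(11), sol.assignment] > 0)


def test_rank_deficient_matrix_raises():
    x = np.linspace(0, 1, 50)
    with pytest.raises(DegenerateInputError):
        pca_varimax(np.tile(x, (11, 1)).T)


# --- build_composites -----------------------------------------------------


def test_composites_match_independent_mean_of_z(default_cohort):
    """Composites equal an independently coded mean-of-z-scores, r = 1."""
    tab, sol, _ = compute_composites(default_cohort.participants)
    M, _ = prepare_task_matrix(default_cohort.participants)
    Z = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    name_to_idx = {n: i for i, n in enumerate(sol.task_names)}
    for col, members in (
        ("executive_function", EXECUTIVE_TASKS),
        ("episodic_memory", MEMORY_TASKS),
    ):
        idx = [name_to_idx[n] for n in members]
        oracle = Z[:, idx].mean(axis=1)
        assert np.corrcoef(oracle, tab[col])[0, 1] > 1 - 1e-12
        assert abs(tab[col].mean()) < 1e-12


def test_expected_component_membership(default_cohort):
    tab, sol, _ = compute_composites(default_cohort.participants)
    blocks = {frozenset(sol.members(0)), frozenset(sol.members(1))}
    assert blocks == {frozenset(EXECUTIVE_TASKS), frozenset(MEMORY_TASKS)}


def test_single_task_component_equals_its_zscore():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((100, 11))
    sol = pca_varimax(X)
    sol.assignment = np.array([0] + [1] * 10)
    ef, mem = build_composites(X, sol)
    z = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std(ddof=1)
    assert np.allclose(ef, z)


def test_empty_component_raises():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((50, 11))
    sol = pca_varimax(X)
    sol.assignment = np.zeros(11, dtype=int)
    with pytest.raises(DegenerateInputError):
        build_composites(X, sol)


def test_composites_invariant_to_affine_task_rescaling(default_cohort):
    tab1, _, _ = compute_composites(default_cohort.participants)
    scaled = default_cohort.participants.copy()
    scaled["digit_symbol"] = scaled["digit_symbol"] * 12.5 + 100
    scaled["cvlt_free_recall"] = scaled["cvlt_free_recall"] * 0.3 - 2
    tab2, _, _ = compute_composites(scaled)
    assert np.allclose(tab1["executive_function"], tab2["executive_function"])
    assert np.allclose(tab1["episodic_memory"], tab2["episodic_memory"])
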