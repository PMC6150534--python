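"""Bootstrap inference and difference-of-coefficients mediation.

``partial_correlation`` residualizes both variables on the covariates and
correlates the residuals.  ``bootstrap_estimate`` is a case (pairs) bootstrap:
participant rows are resampled jointly and the statistic — including any
residualization or standardization it contains — is recomputed per resample.
Significance is the one-sided proportion of draws at or below zero, matching
an alternative of a positive effect; percentile intervals are reported at
both 95% (2.5/97.5) and 90% (5/95) coverage.

``mediation_effect`` fits two least-squares models for an outcome: (1) on age
and covariates, (2) on age, a brain-based mediator, and covariates.  The
mediation effect is the drop in the age coefficient between the two models,
which for linear models equals the product of the age->mediator and
mediator->outcome paths.  Age is negated before fitting so that effects
consistent with age-related decline carry a positive sign, and age, mediator
and outcome are standardized so coefficients are on a correlation-like scale
(binary covariates such as sex are left as coded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InstabilityError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    point: float
    draws: np.ndarray
    ci_low: float
    ci_high: float
    ci90_low: float
    ci90_high: float
    p_boot: float
    B: int
    seed: int | None


@dataclass
class MediationEstimate:
    total_effect: float  # age coefficient, model without mediator
    direct_effect: float  # age coefficient, model with mediator
    mediation_effect: float  # total - direct
    covariate_names: tuple[str, ...]
    age_negated: bool
    bootstrap: BootstrapResult | None = None


def _design(covariates, n):
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _residualize(v, Q):
    beta, *_ = np.linalg.lstsq(Q, v, rcond=None)
    return v - Q @ beta


def partial_correlation(x, y, covariates=None) -> float:
    """Pearson correlation of x and y after removing covariates by least
    squares.  With no covariates this is the plain Pearson r."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    Q = _design(covariates, n)
    if n <= Q.shape[1] + 3:
        raise InsufficientDataError("too few observations for partial correlation")
    if np.linalg.matrix_rank(Q) < Q.shape[1]:
        raise DegenerateInputError("collinear covariates")
    rx = _residualize(x, Q)
    ry = _residualize(y, Q)
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if sx < 1e-12 * max(1.0, np.abs(x).max()) or sy < 1e-12 * max(1.0, np.abs(y).max()):
        raise DegenerateInputError("a variable is (nearly) explained by the covariates")
    return float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))


def bootstrap_estimate(statistic_fn, data, B: int = 5000, seed=None) -> BootstrapResult:
    """Case bootstrap of an arbitrary row-wise statistic.

    ``data`` is a 2-D array whose rows are participants; ``statistic_fn``
    receives a with-replacement row resample (and the full sample for the
    point estimate).  Resamples on which the statistic raises are dropped;
    more than 1% failures raises :class:`InstabilityError`.
    """
    data = np.asarray(data, float)
    n = data.shape[0]
    point = float(statistic_fn(data))
    rng = np.random.default_rng(seed)
    draws = np.empty(B)
    failures = 0
    kept = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            draws[kept] = statistic_fn(data[idx])
            kept += 1
        except Exception:
            failures += 1
    if failures > 0.01 * B:
        raise InstabilityError(f"statistic failed on {failures}/{B} resamples")
    draws = draws[:kept]
    lo, hi = np.percentile(draws, [2.5, 97.5])
    lo90, hi90 = np.percentile(draws, [5, 95])
    return BootstrapResult(
        point=point,
        draws=draws,
        ci_low=float(lo),
        ci_high=float(hi),
        ci90_low=float(lo90),
        ci90_high=float(hi90),
        p_boot=float(np.mean(draws <= 0)),
        B=B,
        seed=seed,
    )


def _zscore(v):
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def _mediation_point(age, mediator, outcome, covariates, negate_age):
    n = len(age)
    a = _zscore(-age if negate_age else age)
    m = _zscore(mediator)
    yv = _zscore(outcome)
    C = _design(covariates, n)
    X1 = np.column_stack([C, a])
    X2 = np.column_stack([C, a, m])
    if np.linalg.matrix_rank(X2) < X2.shape[1]:
        raise DegenerateInputError("mediator is collinear with age/covariates")
    b1, *_ = np.linalg.lstsq(X1, yv, rcond=None)
    b2, *_ = np.linalg.lstsq(X2, yv, rcond=None)
    total = float(b1[-1])
    direct = float(b2[-2])
    return total, direct, total - direct


def mediation_effect(
    age,
    mediator,
    outcome,
    covariates=None,
    B: int = 5000,
    seed=None,
    negate_age: bool = True,
    covariate_names: tuple[str, ...] = (),
) -> MediationEstimate:
    """Difference-of-coefficients mediation of the age-cognition relation,
    with a case-bootstrap distribution of the mediation effect."""
    age = np.asarray(age, float)
    mediator = np.asarray(mediator, float)
    outcome = np.asarray(outcome, float)
    total, direct, med = _mediation_point(age, mediator, outcome, covariates, negate_age)

    n = len(age)
    if covariates is None:
        data = np.column_stack([age, mediator, outcome])
        n_cov = 0
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        data = np.column_stack([age, mediator, outcome, C])
        n_cov = C.shape[1]

    def stat(rows):
        cov = rows[:, 3 : 3 + n_cov] if n_cov else None
        return _mediation_point(rows[:, 0], rows[:, 1], rows[:, 2], cov, negate_age)[2]

    boot = bootstrap_estimate(stat, data, B=B, seed=seed) if B else None
    return MediationEstimate(
        total_effect=total,
        direct_effect=direct,
        mediation_effect=med,
        covariate_names=tuple(covariate_names),
        age_negated=negate_age,
        bootstrap=boot,
    )
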