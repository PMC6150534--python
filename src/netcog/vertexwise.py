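"""Vertex-wise bootstrap-ratio (BSR) maps and network enrichment testing.

For every vertex the statistic of interest — the sex-adjusted partial
correlation of its morphometry with a cognitive ability, or the mediation
effect of its morphometry on the age-ability relation — is recomputed over B
case-bootstrap resamples.  One shared set of B resample index vectors is used
for all vertices, so maps are coherent across the cortex and the computation
vectorizes.  The BSR of a vertex is the mean of its bootstrap draws divided
by their standard deviation (ddof=1) and is thresholded like a z statistic.

Network enrichment: count suprathreshold vertices per functional network,
then build a null by permuting vertex BSRs across all labeled vertices
(equivalently, permuting the network labels) and recounting; the permutation
p is the proportion of null counts at or above the empirical count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .surface import SurfaceDataset

logger = logging.getLogger(__name__)

DEFAULT_BSR_THRESHOLDS = (1.96, 2.58, 3.3, 3.9)


@dataclass
class BSRMap:
    bsr: np.ndarray  # (V,), NaN where flagged
    flags: np.ndarray  # (V,) bool, True = undefined (zero-variance / degenerate)
    kind: str  # 'correlation' | 'mediation'
    measure: str | None
    ability: str | None
    B: int
    seed: int | None


@dataclass
class NetworkCountTable:
    """Suprathreshold vertex counts per network (rows, codes 1-7) and BSR
    threshold (columns), with optional permutation-null summaries."""

    counts: pd.DataFrame
    thresholds: tuple[float, ...]
    sign: str
    null_mean: pd.DataFrame | None = None
    p_ge: pd.DataFrame | None = None  # enrichment: perm count >= empirical
    p_le: pd.DataFrame | None = None  # depletion: perm count <= empirical
    n_perm: int | None = None
    seed: int | None = None

    @property
    def whole_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)


def _design(covariates, n):
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _residualize_cols(M, Q):
    beta, *_ = np.linalg.lstsq(Q, M, rcond=None)
    return M - Q @ beta


def _partial_corr_cols(X, y, Q):
    """Columnwise partial correlation of X's columns with y given design Q."""
    Rx = _residualize_cols(X, Q)
    ry = _residualize_cols(y, Q)
    sx = np.sqrt((Rx**2).sum(axis=0))
    sy = np.sqrt(ry @ ry)
    out = np.full(X.shape[1], np.nan)
    ok = (sx > 1e-12) & (sy > 1e-12)
    out[ok] = np.clip((Rx.T @ ry)[ok] / (sx[ok] * sy), -1.0, 1.0)
    return out


def _mediation_cols(X, age, y, covariates):
    """Columnwise difference-of-coefficients mediation effect, computed via
    the equivalent product of the age->vertex and vertex->outcome|age paths
    on standardized age/vertex/outcome."""
    n = len(y)
    a = (-age - (-age).mean()) / (-age).std(ddof=1)
    yv = (y - y.mean()) / y.std(ddof=1)
    sd = X.std(axis=0, ddof=1)
    ok = sd > 1e-12
    M = np.full_like(X, np.nan)
    M[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]

    C = _design(covariates, n)
    Q_b = np.column_stack([C, a])  # for the mediator->outcome|age path
    Rm = _residualize_cols(np.where(ok, M, 0.0), Q_b)
    ry = _residualize_cols(yv, Q_b)
    denom = (Rm**2).sum(axis=0)
    b_path = np.full(X.shape[1], np.nan)
    good = ok & (denom > 1e-12)
    b_path[good] = (Rm.T @ ry)[good] / denom[good]

    ra = _residualize_cols(a, C)  # age residual for the age->mediator path
    Rm2 = _residualize_cols(np.where(ok, M, 0.0), C)
    da = ra @ ra
    a_path = np.full(X.shape[1], np.nan)
    a_path[good] = (Rm2.T @ ra)[good] / da
    return a_path * b_path


def vertex_bootstrap_ratios(
    ds: SurfaceDataset,
    target,
    covariates=None,
    B: int = 500,
    seed=None,
    kind: str = "correlation",
    ability_name: str | None = None,
) -> BSRMap:
    """Bootstrap-ratio map for one measure/ability combination.

    ``target`` is the ability vector for ``kind='correlation'`` or an
    ``(age, ability)`` pair for ``kind='mediation'``.  Vertices with zero
    variance, or whose bootstrap draws are degenerate (zero spread), are
    flagged undefined and excluded from downstream counts.
    """
    if B < 100:
        raise ConfigurationError("B: bootstrap ratio maps need B >= 100")
    if kind not in ("correlation", "mediation"):
        raise ConfigurationError(f"kind: unknown statistic kind '{kind}'")
    X = np.asarray(ds.values, float)
    n, V = X.shape
    if kind == "mediation":
        age, y = (np.asarray(t, float) for t in target)
    else:
        age, y = None, np.asarray(target, float)
    C = None if covariates is None else np.asarray(covariates, float)
    if C is not None and C.ndim == 1:
        C = C[:, None]

    var0 = X.var(axis=0) > 1e-24
    rng = np.random.default_rng(seed)
    draws = np.empty((B, V))
    for b in range(B):
        idx = rng.integers(0, n, size=n)  # shared across vertices within draw
        Xb = X[idx]
        Cb = None if C is None else C[idx]
        if kind == "correlation":
            draws[b] = _partial_corr_cols(Xb, y[idx], _design(Cb, n))
        else:
            draws[b] = _mediation_cols(Xb, age[idx], y[idx], Cb)

    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    # sd <= 1e-12 treats numerically-degenerate draws (e.g. a vertex that is
    # an exact copy of the target: every draw == 1 up to rounding) as undefined
    flags = ~var0 | ~np.isfinite(mean) | ~np.isfinite(sd) | (sd <= 1e-12)
    bsr = np.full(V, np.nan)
    bsr[~flags] = mean[~flags] / sd[~flags]
    logger.info(
        "BSR map (%s): %d vertices, %d flagged undefined, B=%d", kind, V, int(flags.sum()), B
    )
    return BSRMap(
        bsr=bsr,
        flags=flags,
        kind=kind,
        measure=ds.measure,
        ability=ability_name,
        B=B,
        seed=seed,
    )


def _supra_masks(values, thresholds, sign):
    if sign == "positive":
        return [values >= t for t in thresholds]
    if sign == "absolute":
        return [np.abs(values) >= t for t in thresholds]
    raise ConfigurationError(f"sign: must be 'positive' or 'absolute', got '{sign}'")


def count_suprathreshold(
    bsr_map: BSRMap,
    labels,
    thresholds=DEFAULT_BSR_THRESHOLDS,
    sign: str = "positive",
) -> NetworkCountTable:
    """Count unflagged labeled vertices exceeding each BSR threshold, per
    network.  ``sign='positive'`` counts BSR >= t; ``'absolute'`` counts
    |BSR| >= t."""
    labels = np.asarray(labels, int)
    eligible = (labels > 0) & ~bsr_map.flags
    vals = bsr_map.bsr[eligible]
    labs = labels[eligible]
    counts = np.zeros((7, len(thresholds)), dtype=int)
    for j, mask in enumerate(_supra_masks(vals, thresholds, sign)):
        counts[:, j] = np.bincount(labs[mask], minlength=8)[1:8]
    df = pd.DataFrame(counts, index=pd.RangeIndex(1, 8, name="network"), columns=list(thresholds))
    return NetworkCountTable(counts=df, thresholds=tuple(thresholds), sign=sign)


def permutation_network_test(
    bsr_map: BSRMap,
    labels,
    thresholds=DEFAULT_BSR_THRESHOLDS,
    n_perm: int = 2000,
    seed=None,
    sign: str = "positive",
    mode: str = "labels",
) -> NetworkCountTable:
    """Shuffled-BSR network enrichment test.

    Each permutation reassigns BSR values to labeled vertices at random
    (``mode='labels'`` permutes the label vector, ``mode='values'`` permutes
    the BSR vector; the two are distributionally identical) and recounts
    suprathreshold vertices per network.  Reports the null mean count, the
    enrichment p (proportion of permutations with count >= empirical, so a
    plain proportion with resolution 1/n_perm) and the depletion p
    (proportion <= empirical) for below-chance claims.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm: permutation test needs n_perm >= 100")
    if mode not in ("labels", "values"):
        raise ConfigurationError(f"mode: must be 'labels' or 'values', got '{mode}'")
    base = count_suprathreshold(bsr_map, labels, thresholds, sign)
    emp = base.counts.to_numpy()

    labels = np.asarray(labels, int)
    eligible = (labels > 0) & ~bsr_map.flags
    vals = bsr_map.bsr[eligible]
    labs = labels[eligible]
    masks = _supra_masks(vals, thresholds, sign)

    T = len(thresholds)
    sums = np.zeros((7, T))
    ge = np.zeros((7, T), dtype=int)
    le = np.zeros((7, T), dtype=int)
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = rng.permutation(len(vals))
        if mode == "labels":
            labs_p = labs[perm]
            per_t = [np.bincount(labs_p[m], minlength=8)[1:8] for m in masks]
        else:
            vals_p = vals[perm]
            per_t = [
                np.bincount(labs[m], minlength=8)[1:8]
                for m in _supra_masks(vals_p, thresholds, sign)
            ]
        c = np.column_stack(per_t)
        sums += c
        ge += c >= emp
        le += c <= emp

    idx = base.counts.index
    cols = base.counts.columns
    if float(ge.min() / n_perm) == 0.0:
        logger.info("permutation p of 0 reported; resolution limit is %.2g", 1 / n_perm)
    return NetworkCountTable(
        counts=base.counts,
        thresholds=tuple(thresholds),
        sign=sign,
        null_mean=pd.DataFrame(sums / n_perm, index=idx, columns=cols),
        p_ge=pd.DataFrame(ge / n_perm, index=idx, columns=cols),
        p_le=pd.DataFrame(le / n_perm, index=idx, columns=cols),
        n_perm=n_perm,
        seed=seed,
    )
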