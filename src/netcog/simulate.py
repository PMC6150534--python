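"""Synthetic cohorts with the statistical structure of an older-adult
morphometry-and-cognition study.

The generative model:

* age ~ truncated normal on a configured range;
* two correlated latent cognitive factors (executive function, episodic
  memory), each with a configured correlation with standardized age;
* 11 task scores = loading-matrix image of the factors plus independent noise,
  mapped onto each task's conventional raw scale (reaction-time style tasks
  are emitted lower-is-better, matching how the battery is scored downstream);
* vertex-wise cortical thickness (mm) and surface area (mm^2) matrices over a
  1-D vertex array partitioned into 7 functional-network blocks plus an
  unlabeled block, with network-specific linear couplings to the factors and
  to age, additive (thickness) / multiplicative (area) sex effects, a shared
  participant-level global component, and spatially smoothed vertex noise
  (moving average over a vertex-index neighborhood).

Couplings are expressed on a correlation-like scale: vertex signals are built
from unit-variance standardized components, so a planted coupling of c yields
a population vertex-factor correlation of approximately c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, stats

from .composites import REFERENCE_LOADINGS, TASK_BATTERY
from .errors import ConfigurationError
from .surface import SurfaceDataset

logger = logging.getLogger(__name__)

#: Local (within-participant) coefficient of variation of vertex surface area.
LOCAL_AREA_CV = 0.15

#: Loading of every thickness vertex on a shared participant-level global
#: component (inter-vertex correlation ~= its square), emulating globally
#: correlated cortical thickness.
GLOBAL_THICKNESS_LOADING = 0.5


@dataclass
class NetworkCoupling:
    """Per-network effect sizes (correlation scale), rows ordered network 1-7.

    ``thickness_factor``: (7, 2) coupling of vertex thickness to the two
    latent factors; ``thickness_age``: (7,) coupling to standardized age;
    ``area_factor``: (7, 2) coupling of vertex area to the factors.
    """

    thickness_factor: np.ndarray
    thickness_age: np.ndarray
    area_factor: np.ndarray

    def __post_init__(self):
        self.thickness_factor = np.asarray(self.thickness_factor, float).reshape(7, 2)
        self.thickness_age = np.asarray(self.thickness_age, float).reshape(7)
        self.area_factor = np.asarray(self.area_factor, float).reshape(7, 2)

    @classmethod
    def zero(cls) -> "NetworkCoupling":
        return cls(np.zeros((7, 2)), np.zeros(7), np.zeros((7, 2)))


@dataclass
class SimulationConfig:
    n_participants: int = 165
    n_vertices: int = 2000
    #: vertex counts indexed by network code 0..7 (0 = unlabeled/medial wall)
    network_sizes: np.ndarray = field(
        default_factory=lambda: np.array([100, 304, 304, 228, 228, 152, 304, 380])
    )
    age_mean: float = 69.5
    age_sd: float = 6.58
    age_range: tuple[float, float] = (60.0, 89.0)
    female_fraction: float = 105 / 165
    latent_factor_correlation: float = 0.35
    age_effect_per_factor: tuple[float, float] = (-0.30, -0.36)
    task_loading_matrix: np.ndarray = field(default_factory=lambda: REFERENCE_LOADINGS.copy())
    task_noise_sd: np.ndarray | None = None  # derived from loadings when None
    thickness_mean: float = 2.39
    thickness_sd: float = 0.12
    area_total_mean: float = 157614.2
    area_total_sd: float = 15775.83
    network_coupling: NetworkCoupling = field(default_factory=NetworkCoupling.zero)
    #: loading of every thickness vertex on a shared participant-level global
    #: component (inter-vertex correlation ~= its square); emulates globally
    #: correlated cortical thickness
    global_component: float = GLOBAL_THICKNESS_LOADING
    spatial_smoothness: int = 5  # moving-average half-width in vertices
    sex_effects: tuple[float, float] = (0.065, 0.90)  # (thickness shift mm, area scale)
    seed: int = 20180921

    def __post_init__(self):
        self.network_sizes = np.asarray(self.network_sizes, int)
        self.task_loading_matrix = np.asarray(self.task_loading_matrix, float)
        if self.task_noise_sd is not None:
            self.task_noise_sd = np.asarray(self.task_noise_sd, float)

    def resolved_task_noise_sd(self) -> np.ndarray:
        """Default per-task noise SD: tops the latent task variance up to 1 so
        generating loadings behave as correlations of standardized tasks."""
        if self.task_noise_sd is not None:
            return self.task_noise_sd
        L = self.task_loading_matrix
        rho = self.latent_factor_correlation
        implied = L[:, 0] ** 2 + L[:, 1] ** 2 + 2 * rho * L[:, 0] * L[:, 1]
        return np.sqrt(np.clip(1.0 - implied, 0.05, None))

    def validate(self) -> None:
        def bad(fieldname, why):
            raise ConfigurationError(f"{fieldname}: {why}")

        if self.n_participants < 2:
            bad("n_participants", "must be >= 2")
        if self.network_sizes.shape != (8,) or np.any(self.network_sizes < 0):
            bad("network_sizes", "must be 8 non-negative counts (unlabeled + 7 networks)")
        if int(self.network_sizes.sum()) != self.n_vertices:
            bad(
                "network_sizes",
                f"sum {int(self.network_sizes.sum())} != n_vertices {self.n_vertices}",
            )
        for name in ("age_sd", "thickness_sd", "area_total_sd"):
            if getattr(self, name) <= 0:
                bad(name, "must be > 0")
        lo, hi = self.age_range
        if not (lo < hi and lo <= self.age_mean <= hi):
            bad("age_range", "must contain age_mean")
        if not 0 <= self.female_fraction <= 1:
            bad("female_fraction", "must be in [0, 1]")
        if self.task_loading_matrix.shape != (11, 2):
            bad("task_loading_matrix", "must be 11x2")
        if not np.all(np.isfinite(self.task_loading_matrix)):
            bad("task_loading_matrix", "must be finite")
        noise = self.resolved_task_noise_sd()
        if noise.shape != (11,) or np.any(noise <= 0):
            bad("task_noise_sd", "must be 11 positive SDs")
        if not -1 < self.latent_factor_correlation < 1:
            bad("latent_factor_correlation", "must be in (-1, 1)")
        if self.spatial_smoothness < 0:
            bad("spatial_smoothness", "must be >= 0")
        if not 0 <= self.global_component < 1:
            bad("global_component", "must be in [0, 1)")
        if np.min(np.linalg.eigvalsh(self._factor_conditional_cov())) < -1e-10:
            bad(
                "latent_factor_correlation",
                "incompatible with age_effect_per_factor (conditional covariance "
                "not positive semi-definite)",
            )

    def _factor_conditional_cov(self) -> np.ndarray:
        r1, r2 = self.age_effect_per_factor
        rho = self.latent_factor_correlation
        return np.array([[1 - r1**2, rho - r1 * r2], [rho - r1 * r2, 1 - r2**2]])

    def joint_latent_cov(self) -> np.ndarray:
        """Covariance of (factor1, factor2, standardized age)."""
        r1, r2 = self.age_effect_per_factor
        rho = self.latent_factor_correlation
        return np.array([[1, rho, r1], [rho, 1, r2], [r1, r2, 1]])


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame
    thickness: SurfaceDataset
    area: SurfaceDataset
    latent_truth: np.ndarray  # (n, 2) factor scores
    planted_effects: NetworkCoupling


def default_config(**overrides) -> SimulationConfig:
    """Study-condition defaults: n=165 older adults aged 60-89 (mean 69.5,
    SD 6.58, 105 female), 2,000 vertices partitioned proportionally to the
    7-network parcellation, global mean thickness 2.39 mm (SD 0.12), total
    surface area 157,614 mm^2 (SD 15,776).

    With no planted couplings the default cohort is a structural null:
    morphometry is unrelated to cognition and age beyond sex effects.
    """
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


def realistic_coupling() -> NetworkCoupling:
    """A plausible effect pattern: thickness of every network weakly coupled
    to both abilities with somatomotor, salience and default-mode elevated,
    uniform negative thickness-age coupling, area uncoupled."""
    tf = np.array(
        [
            [0.12, 0.10],  # visual
            [0.22, 0.18],  # somatomotor
            [0.12, 0.10],  # dorsal attention
            [0.25, 0.08],  # salience
            [0.15, 0.12],  # limbic
            [0.15, 0.12],  # control
            [0.25, 0.20],  # default mode
        ]
    )
    return NetworkCoupling(tf, np.full(7, -0.20), np.zeros((7, 2)))


def _truncnorm_params(target_mean, target_sd, lo, hi):
    """Location/scale of the parent normal such that the [lo, hi]-truncated
    distribution has the target mean and SD (the reported sample moments
    describe the truncated population, not the parent)."""
    from scipy.optimize import fsolve

    def moments(params):
        loc, scale = params
        scale = abs(scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return [
            stats.truncnorm.mean(a, b, loc=loc, scale=scale) - target_mean,
            stats.truncnorm.std(a, b, loc=loc, scale=scale) - target_sd,
        ]

    loc, scale = fsolve(moments, [target_mean, target_sd], full_output=False)
    return float(loc), float(abs(scale))


def _block_labels(sizes: np.ndarray) -> np.ndarray:
    """Vertex labels as contiguous blocks: networks 1..7 then unlabeled 0."""
    parts = [np.full(sizes[c], c) for c in range(1, 8)]
    parts.append(np.full(sizes[0], 0))
    return np.concatenate(parts).astype(int)


def _smooth_noise(rng, n, labels, half_width):
    """Spatially correlated vertex noise: iid normals moving-averaged within
    each network block over +/- half_width vertices, rescaled back to unit
    variance."""
    eps = rng.standard_normal((n, len(labels)))
    if half_width <= 0:
        return eps
    w = 2 * half_width + 1
    out = np.empty_like(eps)
    start = 0
    for code in list(range(1, 8)) + [0]:
        size = int(np.sum(labels == code))
        if size == 0:
            continue
        block = eps[:, start : start + size]
        out[:, start : start + size] = (
            ndimage.uniform_filter1d(block, size=w, axis=1, mode="nearest") * np.sqrt(w)
        )
        start += size
    return out


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort under the configured generative model.

    Deterministic under a fixed ``config.seed``: repeated calls return
    bit-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    lo, hi = config.age_range

    loc, scale = _truncnorm_params(config.age_mean, config.age_sd, lo, hi)
    age = stats.truncnorm.rvs(
        (lo - loc) / scale,
        (hi - loc) / scale,
        loc=loc,
        scale=scale,
        size=n,
        random_state=rng,
    )
    z_age = (age - config.age_mean) / config.age_sd
    sex = (rng.random(n) < config.female_fraction).astype(int)  # 1 = female

    # latent factors conditional on age
    r = np.asarray(config.age_effect_per_factor)
    cond_cov = config._factor_conditional_cov()
    eigval, eigvec = np.linalg.eigh(cond_cov)
    chol = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0, None)))
    factors = z_age[:, None] * r[None, :] + rng.standard_normal((n, 2)) @ chol.T

    # task scores on their conventional raw scales
    noise_sd = config.resolved_task_noise_sd()
    latent_tasks = factors @ config.task_loading_matrix.T + rng.standard_normal(
        (n, 11)
    ) * noise_sd[None, :]
    tasks = {}
    for j, task in enumerate(TASK_BATTERY):
        direction = 1.0 if task.higher_is_better else -1.0
        tasks[task.name] = task.typical_mean + task.typical_sd * direction * latent_tasks[:, j]

    labels = _block_labels(config.network_sizes)
    V = config.n_vertices
    coup = config.network_coupling
    female = sex.astype(float)
    Sigma = config.joint_latent_cov()  # order (f1, f2, z_age)

    # --- thickness -------------------------------------------------------
    # Per-vertex signal has unit variance: a shared global component, the
    # network-specific couplings, and smoothed local noise.  The mm scale is
    # then set so the labeled-mean thickness has the configured SD (sex shift
    # contributes its own share of the global-mean variance).
    shift, area_scale = config.sex_effects
    ff = config.female_fraction

    c_thick = np.zeros((V, 3))  # coupling vectors in (f1, f2, z_age) order
    labeled = labels > 0
    c_thick[labeled, 0] = coup.thickness_factor[labels[labeled] - 1, 0]
    c_thick[labeled, 1] = coup.thickness_factor[labels[labeled] - 1, 1]
    c_thick[labeled, 2] = coup.thickness_age[labels[labeled] - 1]

    n_labeled = int(labeled.sum())
    c_g = config.global_component
    g = rng.standard_normal(n)

    var_v = np.einsum("vi,ij,vj->v", c_thick, Sigma, c_thick)
    c_e = np.sqrt(np.clip(1.0 - c_g**2 - var_v, 0.05, None))
    latent3 = np.column_stack([factors, z_age])
    eps = _smooth_noise(rng, n, labels, config.spatial_smoothness)
    signal = c_g * g[:, None] + latent3 @ c_thick.T + c_e[None, :] * eps

    # variance of the labeled-vertex mean of the unit-variance signal
    m_bar = c_thick[labeled].mean(axis=0) if n_labeled else np.zeros(3)
    w = 2 * config.spatial_smoothness + 1
    leak = float(np.mean(c_e[labeled] ** 2)) * min(w, n_labeled) / max(n_labeled, 1)
    var_mean = c_g**2 + float(m_bar @ Sigma @ m_bar) + leak
    sex_var_mm2 = ff * (1 - ff) * shift**2
    global_sd_core = np.sqrt(max(config.thickness_sd**2 - sex_var_mm2, 1e-8))
    vertex_sd = global_sd_core / np.sqrt(var_mean)

    baseline = config.thickness_mean - ff * shift
    thickness_values = baseline + vertex_sd * signal + shift * female[:, None]

    # --- surface area ----------------------------------------------------
    a0 = config.area_total_mean / max(n_labeled, 1)
    norm = ff * area_scale + (1 - ff)
    rel_target = config.area_total_sd / config.area_total_mean
    sex_rel_var = ff * (1 - ff) * ((area_scale - 1) / norm) ** 2
    rel_h = np.sqrt(max(rel_target**2 - sex_rel_var, 1e-6))
    h = rng.standard_normal(n)
    m = np.where(female == 1, area_scale, 1.0) * (1 + rel_h * h) / norm

    c_area = np.zeros((V, 3))
    c_area[labeled, 0] = coup.area_factor[labels[labeled] - 1, 0]
    c_area[labeled, 1] = coup.area_factor[labels[labeled] - 1, 1]
    var_av = np.einsum("vi,ij,vj->v", c_area, Sigma, c_area)
    c_ae = np.sqrt(np.clip(1.0 - var_av, 0.05, None))
    eps_a = _smooth_noise(rng, n, labels, config.spatial_smoothness)
    s_local = latent3 @ c_area.T + c_ae[None, :] * eps_a
    area_values = a0 * m[:, None] * (1 + LOCAL_AREA_CV * s_local)

    ids = np.array([f"p{i + 1:04d}" for i in range(n)])
    vertex_ids = np.array([f"v{j:06d}" for j in range(V)])
    participants = pd.DataFrame({"id": ids, "age": age, "sex": sex, **tasks})

    thickness = SurfaceDataset(thickness_values, "thickness", ids, vertex_ids, labels)
    area = SurfaceDataset(area_values, "area", ids, vertex_ids, labels)
    logger.info(
        "simulated cohort: n=%d, V=%d (labeled %d), seed=%d",
        n,
        V,
        n_labeled,
        config.seed,
    )
    return SyntheticCohort(
        participants=participants,
        thickness=thickness,
        area=area,
        latent_truth=factors,
        planted_effects=coup,
    )


# --- config / cohort serialization ---------------------------------------


def config_to_yaml(config: SimulationConfig, path) -> None:
    d = asdict(config)
    for key in ("network_sizes", "task_loading_matrix", "task_noise_sd"):
        if d[key] is not None:
            d[key] = np.asarray(d[key]).tolist()
    d["network_coupling"] = {
        "thickness_factor": config.network_coupling.thickness_factor.tolist(),
        "thickness_age": config.network_coupling.thickness_age.tolist(),
        "area_factor": config.network_coupling.area_factor.tolist(),
    }
    d["age_range"] = list(config.age_range)
    d["age_effect_per_factor"] = list(config.age_effect_per_factor)
    d["sex_effects"] = list(config.sex_effects)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "network_coupling" in d and isinstance(d["network_coupling"], dict):
        d["network_coupling"] = NetworkCoupling(**d["network_coupling"])
    for key in ("age_range", "age_effect_per_factor", "sex_effects"):
        if key in d:
            d[key] = tuple(d[key])
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg
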