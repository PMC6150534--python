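"""Composite cognitive-ability scores from an 11-task battery.

The battery mixes speeded executive-function tasks and episodic-memory tasks
commonly used in cognitive-aging studies.  Composites are built data-driven:
winsorize each task (one pass at k standard deviations), sign-correct
lower-is-better tasks, run a principal component analysis on the task
correlation matrix, varimax-rotate the first two components, assign each task
to the component on which it loads most strongly, and average the standardized
scores of each component's member tasks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .errors import DegenerateInputError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Task:
    """One behavioral task: its column name, scoring direction, and a typical
    raw scale (mean, SD) for older-adult samples used by the simulator."""

    name: str
    label: str
    higher_is_better: bool
    typical_mean: float
    typical_sd: float


#: The 11-task battery, in canonical order.  Reaction-time / completion-time /
#: error-count tasks are scored lower-is-better.
TASK_BATTERY: tuple[Task, ...] = (
    Task("flanker_rt", "Flanker Incongruent (ms)", False, 844.57, 123.52),
    Task("trail_b_time", "Trail Making Part B (s)", False, 77.67, 24.74),
    Task("spatial_wm_acc", "Spatial Working Memory (accuracy)", True, 0.79, 0.12),
    Task("n_back_acc", "Letter N-Back (2-back accuracy)", True, 0.82, 0.15),
    Task("category_fluency", "Category Fluency (animals+vegetables)", True, 40.75, 8.90),
    Task("face_scene_dprime", "Face-Scene (d')", True, 0.86, 0.59),
    Task("spatial_recon_swaps", "Spatial Reconstruction (swaps)", False, 0.13, 0.07),
    Task("dot_comparison_rt", "Dot Comparison (ms)", False, 2634.02, 688.70),
    Task("digit_symbol", "Digit Symbol Coding", True, 63.06, 12.43),
    Task("cvlt_free_recall", "CVLT Free Recall (delayed)", True, 11.18, 3.38),
    Task("story_recall", "Story Free Recall (delayed)", True, 11.37, 3.32),
)

TASK_NAMES: tuple[str, ...] = tuple(t.name for t in TASK_BATTERY)

#: tasks conventionally carried by the executive-function component; used
#: only to decide which rotated component gets which composite label
EXECUTIVE_REFERENCE = frozenset(
    {"flanker_rt", "trail_b_time", "spatial_wm_acc", "n_back_acc",
     "dot_comparison_rt", "digit_symbol"}
)

#: Reference two-component loading structure for the battery (executive
#: function, episodic memory), on direction-corrected standardized scores.
#: Used as the simulator's default generating loadings.
REFERENCE_LOADINGS = np.array(
    [
        [0.59, 0.04],  # flanker_rt
        [0.71, 0.19],  # trail_b_time
        [0.62, 0.21],  # spatial_wm_acc
        [0.52, 0.14],  # n_back_acc
        [0.27, 0.56],  # category_fluency
        [0.17, 0.58],  # face_scene_dprime
        [0.13, 0.69],  # spatial_recon_swaps
        [0.74, 0.09],  # dot_comparison_rt
        [0.69, 0.31],  # digit_symbol
        [0.22, 0.74],  # cvlt_free_recall
        [0.04, 0.68],  # story_recall
    ]
)


@dataclass
class ComponentSolution:
    """Rotated PCA solution for the task battery.

    ``loadings`` are correlations between tasks and varimax-rotated
    components; ``assignment[i]`` gives the component index (0-based) on which
    task ``i`` has the larger absolute loading; ``variance_explained`` is the
    per-component sum of squared rotated loadings divided by the number of
    tasks.
    """

    loadings: np.ndarray  # (n_tasks, n_components)
    variance_explained: np.ndarray  # (n_components,)
    assignment: np.ndarray  # (n_tasks,) int
    task_names: tuple[str, ...] = TASK_NAMES
    n_retained: int = 2

    def members(self, component: int) -> list[str]:
        return [n for n, a in zip(self.task_names, self.assignment) if a == component]


def winsorize(values, k_sd: float = 3.0):
    """Single-pass winsorization at ``k_sd`` standard deviations.

    Mean and SD (ddof=1) are computed once from the input itself; values with
    |z| > k_sd are replaced by mean ± k_sd*SD.  Returns ``(winsorized, count)``
    where count is the number of replaced values.  A constant vector is
    returned unchanged with count 0.
    """
    v = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(v)) < 3:
        raise InsufficientDataError("winsorize needs at least 3 non-missing values")
    mu = np.nanmean(v)
    sd = np.nanstd(v, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return v.copy(), 0
    lo, hi = mu - k_sd * sd, mu + k_sd * sd
    out = np.clip(v, lo, hi)
    count = int(np.sum((v < lo) | (v > hi)))
    return out, count


def prepare_task_matrix(table: pd.DataFrame, k_sd: float = 3.0):
    """Winsorize each task then sign-correct lower-is-better tasks.

    Returns ``(matrix, outlier_counts)``: an (n, 11) array in battery order in
    which every column is oriented higher-is-better, plus a dict of
    winsorization replacement counts per task.
    """
    cols = []
    counts: dict[str, int] = {}
    for task in TASK_BATTERY:
        if task.name not in table.columns:
            raise KeyError(f"task column '{task.name}' missing from table")
        w, c = winsorize(table[task.name].to_numpy(dtype=float), k_sd)
        counts[task.name] = c
        cols.append(w if task.higher_is_better else -w)
    return np.column_stack(cols), counts


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def pca_varimax(task_matrix, n_components: int = 2) -> ComponentSolution:
    """PCA on the task correlation matrix followed by varimax rotation.

    Kaiser (communality) normalization is applied before rotation and undone
    after; components are reordered by post-rotation variance explained and
    sign-fixed so each component's largest-|loading| task loads positively.
    """
    X = np.asarray(task_matrix, dtype=float)
    n, p = X.shape
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[n_components - 1] < 1e-10 or np.linalg.matrix_rank(R) < n_components:
        raise DegenerateInputError(
            f"task matrix rank < {n_components}; cannot extract components"
        )
    L = eigvec[:, :n_components] * np.sqrt(eigval[:n_components])

    # Kaiser normalization: rotate rows scaled to unit communality.
    h = np.sqrt((L**2).sum(axis=1))
    h_safe = np.where(h > 1e-12, h, 1.0)
    L_rot, _ = rotate_factors(L / h_safe[:, None], "varimax", tol=1e-6, max_tries=1000)
    L_rot = L_rot * h_safe[:, None]

    ss = (L_rot**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    L_rot = L_rot[:, order]
    ss = ss[order]
    for j in range(n_components):
        i_max = int(np.argmax(np.abs(L_rot[:, j])))
        if L_rot[i_max, j] < 0:
            L_rot[:, j] = -L_rot[:, j]

    assignment = np.argmax(np.abs(L_rot), axis=1)
    return ComponentSolution(
        loadings=L_rot,
        variance_explained=ss / p,
        assignment=assignment,
        n_retained=n_components,
    )


def build_composites(task_matrix, solution: ComponentSolution):
    """Average standardized member-task scores per component.

    Each composite is the mean of z-scored tasks assigned to that component,
    so both returned vectors have mean 0 and are oriented higher-is-better.
    Returns one vector per retained component, in component order
    (executive function first, episodic memory second for the default
    battery).
    """
    Z = _zscore(np.asarray(task_matrix, dtype=float))
    out = []
    for j in range(solution.n_retained):
        idx = np.flatnonzero(solution.assignment == j)
        if idx.size == 0:
            raise DegenerateInputError(f"component {j} has no assigned tasks")
        out.append(Z[:, idx].mean(axis=1))
    return tuple(out)


def compute_composites(table: pd.DataFrame, k_sd: float = 3.0):
    """End-to-end composite construction on a participant table.

    Returns ``(table_with_composites, solution, outlier_counts)``.  Adds
    ``executive_function`` and ``episodic_memory`` columns (standardized
    units, higher = better).  Components in the solution are ordered by
    variance explained; the composite labels are assigned by which component
    carries the majority of the battery's executive block, since the
    variance-explained order is not identified across samples.
    """
    M, counts = prepare_task_matrix(table, k_sd)
    solution = pca_varimax(M, n_components=2)
    comps = build_composites(M, solution)
    ef_idx = int(
        len(set(solution.members(0)) & EXECUTIVE_REFERENCE)
        < len(set(solution.members(1)) & EXECUTIVE_REFERENCE)
    )
    out = table.copy()
    out["executive_function"] = comps[ef_idx]
    out["episodic_memory"] = comps[1 - ef_idx]
    logger.info(
        "composites built: variance explained %.3f / %.3f, outliers %s",
        *solution.variance_explained[:2],
        counts,
    )
    return out, solution, counts
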