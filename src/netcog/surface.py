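"""Vertex-wise morphometry container, CSV I/O, network subsetting, robust scaling.

A :class:`SurfaceDataset` holds one morphometric measure (cortical thickness
in mm or vertex surface area in mm^2) as a participants x vertices matrix,
together with a per-vertex label assigning each vertex to one of 7 functional
networks (1=visual, 2=somatomotor, 3=dorsal attention, 4=salience,
5=limbic, 6=control, 7=default mode) or 0 for unlabeled/medial-wall vertices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import EmptyNetworkError, FormatError

logger = logging.getLogger(__name__)

NETWORK_NAMES = {
    1: "visual",
    2: "somatomotor",
    3: "dorsal_attention",
    4: "salience",
    5: "limbic",
    6: "control",
    7: "default_mode",
}

VALID_MEASURES = ("thickness", "area")


@dataclass
class SurfaceDataset:
    """Participants x vertices matrix of one morphometric measure."""

    values: np.ndarray
    measure: str
    participant_ids: np.ndarray
    vertex_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.participant_ids = np.asarray(self.participant_ids)
        self.vertex_ids = np.asarray(self.vertex_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        n, v = self.values.shape
        if self.measure not in VALID_MEASURES:
            raise FormatError(f"unknown measure '{self.measure}'")
        if len(self.participant_ids) != n:
            raise FormatError("participant_ids length does not match row count")
        if len(self.vertex_ids) != v or len(self.labels) != v:
            raise FormatError("vertex_ids/labels length does not match column count")
        if len(set(self.participant_ids.tolist())) != n:
            raise FormatError("participant_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("values matrix contains non-finite entries")
        bad = set(np.unique(self.labels)) - set(range(8))
        if bad:
            raise FormatError(f"unknown network label codes {sorted(bad)}")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    def global_summary(self) -> np.ndarray:
        """Per-participant whole-cortex summary over labeled vertices:
        unweighted mean for thickness, sum for area."""
        labeled = self.labels > 0
        if self.measure == "thickness":
            return self.values[:, labeled].mean(axis=1)
        return self.values[:, labeled].sum(axis=1)


@dataclass
class ScaleParams:
    """Per-vertex robust scaling parameters: median center and IQR scale
    (25th-75th percentile, linear interpolation).  Vertices with zero IQR
    keep scale 1 so they are centered but not rescaled."""

    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        if np.any(self.scale < 0):
            raise FormatError("scale must be non-negative")


def save_surface_matrix(ds: SurfaceDataset, values_path, labels_path=None) -> None:
    """Write the matrix as CSV (first column id, header = vertex ids) and,
    optionally, the labels as a two-column CSV."""
    df = pd.DataFrame(ds.values, columns=ds.vertex_ids)
    df.insert(0, "id", ds.participant_ids)
    # %.17g guarantees float64 round-trips bit-exactly through text
    df.to_csv(values_path, index=False, float_format="%.17g")
    if labels_path is not None:
        pd.DataFrame({"vertex_id": ds.vertex_ids, "network_id": ds.labels}).to_csv(
            labels_path, index=False
        )


def load_surface_matrix(values_path, labels_path, measure: str) -> SurfaceDataset:
    """Load a participants x vertices CSV and its vertex->network label CSV."""
    try:
        # round_trip parsing + %.17g writing make CSV interchange bit-exact
        df = pd.read_csv(values_path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise FormatError(f"{values_path}: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0] != "id":
        raise FormatError(f"{values_path}: expected first column 'id'")
    values = df.iloc[:, 1:].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{values_path}: non-numeric cells in value matrix")
    lab = pd.read_csv(labels_path)
    if list(lab.columns[:2]) != ["vertex_id", "network_id"]:
        raise FormatError(f"{labels_path}: expected columns vertex_id,network_id")
    if len(lab) != values.shape[1]:
        raise FormatError(
            f"{labels_path}: {len(lab)} labels for {values.shape[1]} matrix columns"
        )
    ds = SurfaceDataset(
        values=values,
        measure=measure,
        participant_ids=df["id"].to_numpy(),
        vertex_ids=lab["vertex_id"].to_numpy(),
        labels=lab["network_id"].to_numpy(),
    )
    logger.info(
        "loaded %s matrix: %d participants x %d vertices",
        measure,
        ds.n_participants,
        ds.n_vertices,
    )
    return ds


def subset_network(ds: SurfaceDataset, network) -> SurfaceDataset:
    """Restrict columns to one functional network (code 1-7) or, with
    ``'whole'``, to all labeled vertices (drops code 0)."""
    if network == "whole":
        keep = ds.labels > 0
    else:
        code = int(network)
        if code not in NETWORK_NAMES:
            raise FormatError(f"network code must be 1-7 or 'whole', got {network!r}")
        keep = ds.labels == code
    if not np.any(keep):
        raise EmptyNetworkError(f"no vertices with network {network!r}")
    return replace(
        ds,
        values=ds.values[:, keep],
        vertex_ids=ds.vertex_ids[keep],
        labels=ds.labels[keep],
    )


def robust_scale(train) -> tuple[ScaleParams, np.ndarray]:
    """Fit per-vertex median/IQR on a training matrix and return the scaled
    training matrix.  Accepts a SurfaceDataset or a 2-D array."""
    X = train.values if isinstance(train, SurfaceDataset) else np.asarray(train, float)
    if X.shape[0] < 4:
        raise FormatError("robust scaling needs at least 4 rows")
    center = np.median(X, axis=0)
    q25, q75 = np.percentile(X, [25, 75], axis=0)
    iqr = q75 - q25
    scale = np.where(iqr > 0, iqr, 1.0)
    params = ScaleParams(center=center, scale=scale)
    return params, (X - center) / scale


def apply_scale(params: ScaleParams, matrix) -> np.ndarray:
    """Scale a matrix with previously fitted parameters (train-only statistics)."""
    X = matrix.values if isinstance(matrix, SurfaceDataset) else np.asarray(matrix, float)
    if X.shape[1] != params.center.shape[0]:
        raise FormatError(
            f"matrix has {X.shape[1]} columns but params were fit on "
            f"{params.center.shape[0]}"
        )
    return (X - params.center) / params.scale
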