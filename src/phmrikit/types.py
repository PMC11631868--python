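"""Core in-memory containers shared across the pipeline stages.

The containers are deliberately thin: numpy arrays plus the metadata the
analysis stages need (grids, registries, windows).  Validation happens at
construction so downstream code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Bold4D",
    "AtlasLabels",
    "SubjectTransform",
    "NodeTimeSeries",
    "ConnectivityMatrix",
    "Window",
    "validate_windows",
]

#: inclusive 1-based acquisition index pair, matching scanner-log convention
Window = tuple[int, int]


def validate_windows(baseline: Window, response: Window, n_acquisitions: int) -> None:
    """Check that baseline and response windows are valid and disjoint.

    Windows are 1-based inclusive acquisition index pairs; the baseline must
    lie entirely before the response window.
    """
    for name, (lo, hi) in (("baseline", baseline), ("response", response)):
        if not (1 <= lo <= hi <= n_acquisitions):
            raise ValueError(
                f"{name} window {lo}-{hi} outside acquisitions 1-{n_acquisitions}"
            )
    if baseline[1] >= response[0]:
        raise ValueError(
            f"baseline window {baseline} must end before response window {response}"
        )


def window_slice(window: Window) -> slice:
    """Convert a 1-based inclusive window to a 0-based half-open slice."""
    lo, hi = window
    return slice(lo - 1, hi)


@dataclass
class Bold4D:
    """A single subject's BOLD acquisition: (x, y, z, t) signal array."""

    data: np.ndarray
    tr: float
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD series contain non-finite values")
        if self.tr <= 0:
            raise ValueError("repetition time must be positive")

    @property
    def n_acquisitions(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def duration_seconds(self) -> float:
        return self.n_acquisitions * self.tr


@dataclass
class AtlasLabels:
    """Integer label volume plus a region lookup table.

    Label 0 is background.  ``regions`` has columns ``id``, ``name`` and
    optionally ``hemisphere``; every nonzero label in the volume must appear
    in it.
    """

    labels: np.ndarray
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        required = {"id", "name"}
        if not required.issubset(self.regions.columns):
            raise ValueError(f"region table must have columns {sorted(required)}")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.regions["id"].astype(int))
        missing = present - known
        if missing:
            raise ValueError(f"labels missing from region table: {sorted(missing)}")

    @property
    def region_ids(self) -> list[int]:
        return [int(i) for i in self.regions["id"]]

    def region_name(self, region_id: int) -> str:
        row = self.regions.loc[self.regions["id"] == region_id]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        return str(row["name"].iloc[0])

    def region_size(self, region_id: int) -> int:
        return int(np.count_nonzero(self.labels == region_id))


@dataclass
class SubjectTransform:
    """Affine mapping from a subject grid to the composite/atlas grid.

    Stored as a 4x4 homogeneous matrix acting on voxel coordinates.  The
    inverse is computed once and reused when pulling subject values into the
    composite grid.
    """

    matrix: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform must be a 4x4 homogeneous matrix")
        det = np.linalg.det(self.matrix)
        if abs(det) < 1e-12:
            raise ValueError(
                f"singular transform for subject {self.subject_id!r} (det={det:g})"
            )
        self.inverse = np.linalg.inv(self.matrix)

    @classmethod
    def identity(cls, subject_id: str = "") -> "SubjectTransform":
        return cls(np.eye(4), subject_id)


@dataclass
class NodeTimeSeries:
    """Region-averaged time series: one row per node, one column per frame."""

    data: np.ndarray
    node_ids: list[int]
    node_names: list[str]
    sampling_interval: float
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("node time series must be a 2D (node x time) matrix")
        if len(self.node_ids) != self.data.shape[0]:
            raise ValueError("node registry length does not match matrix rows")
        if not np.isfinite(self.data).all():
            raise ValueError("node series contain non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric node-by-node edge weights with a value-kind tag.

    ``kind`` is one of ``pearson_r``, ``fisher_z`` or ``group_z``.  The
    diagonal carries no self-edge information and is kept at zero.
    """

    values: np.ndarray
    node_ids: list[int]
    kind: str
    qc_flags: dict = field(default_factory=dict)

    _KINDS = ("pearson_r", "fisher_z", "group_z")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if len(self.node_ids) != n:
            raise ValueError("node registry length does not match matrix size")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        off = ~np.eye(n, dtype=bool)
        finite = self.values[off][np.isfinite(self.values[off])]
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric within 1e-12")
        if self.kind == "pearson_r" and finite.size and np.abs(finite).max() > 1 + 1e-12:
            raise ValueError("pearson_r entries must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]
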