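"""Small synthetic label atlases standing in for a full segmented brain atlas."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..types import AtlasLabels

__all__ = ["make_atlas"]


def make_atlas(
    shape: tuple[int, int, int] = (24, 24, 8),
    n_regions: int = 8,
    border: int = 1,
) -> AtlasLabels:
    """Partition a small 3D grid into contiguous labelled regions.

    A ``border``-voxel background rim (label 0) surrounds an interior that is
    split into ``n_regions`` roughly equal slabs along the first axis (and the
    second axis when more slabs are needed than the first axis can hold).
    Region names are ``region_01`` ... with alternating hemisphere tags; the
    construction is fully deterministic.
    """
    if n_regions < 1:
        raise ValueError("need at least one region")
    labels = np.zeros(shape, dtype=np.int32)
    interior = tuple(slice(border, s - border) for s in shape)
    inner_shape = tuple(s - 2 * border for s in shape)
    if min(inner_shape) < 1:
        raise ValueError("grid too small for the requested border")
    nx, ny = inner_shape[0], inner_shape[1]
    # factor n_regions into an (a, b) grid of slabs over the x-y plane
    a = int(np.ceil(np.sqrt(n_regions)))
    while n_regions % a:
        a -= 1
    b = n_regions // a
    if a > nx or b > ny:
        raise ValueError(f"cannot fit {n_regions} regions into interior {inner_shape}")
    x_edges = np.linspace(0, nx, a + 1).astype(int)
    y_edges = np.linspace(0, ny, b + 1).astype(int)
    inner = np.zeros(inner_shape, dtype=np.int32)
    region = 1
    for i in range(a):
        for j in range(b):
            inner[x_edges[i] : x_edges[i + 1], y_edges[j] : y_edges[j + 1], :] = region
            region += 1
    labels[interior] = inner
    table = pd.DataFrame(
        {
            "id": np.arange(1, n_regions + 1),
            "name": [f"region_{i:02d}" for i in range(1, n_regions + 1)],
            "hemisphere": ["L" if i % 2 else "R" for i in range(1, n_regions + 1)],
        }
    )
    return AtlasLabels(labels, table)
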