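"""Shared dense-grid helpers for the texture modules."""

from __future__ import annotations

import numpy as np

#: The 13 unique 3D direction offsets (one per axis/diagonal pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, -1, 1), (1, 1, -1), (1, -1, -1),
)


def dense_label_grid(coords: np.ndarray, labels: np.ndarray):
    """Pack sparse voxel labels into a dense bounding-box grid.

    Returns ``(grid, origin)`` where ``grid`` holds the label at each in-mask
    position and 0 outside the mask (labels must be >= 1), and ``origin`` is
    the minimum coordinate subtracted from ``coords``.
    """
    coords = np.asarray(coords)
    origin = coords.min(axis=0)
    local = coords - origin
    shape = local.max(axis=0) + 1
    grid = np.zeros(shape, dtype=np.int64)
    grid[local[:, 0], local[:, 1], local[:, 2]] = labels
    return grid, origin
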