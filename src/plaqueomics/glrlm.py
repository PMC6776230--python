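"""Gray-level run-length matrices and the 11 classic run statistics.

A run is a maximal segment of collinear, consecutive mask voxels sharing one
gray level; a gap in the mask terminates a run.  Matrices R(i, j) count runs
of gray level i and length j along each of the 13 unique 3D directions.

The 11 statistics (Galloway / Chu / Dasarathy-Holder definitions) are
computed per direction and averaged over the 13 directions, matching the
mean-aggregation convention of the co-occurrence block: 11 features per
discretized image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._grid import DIRECTIONS_13
from .discretize import DiscretizedLesion

__all__ = [
    "GLRLMatrix",
    "GLRLM_STAT_NAMES",
    "build_glrlm",
    "glrlm_statistics",
    "compute_glrlm_block",
    "glrlm_feature_names",
]

GLRLM_STAT_NAMES: tuple[str, ...] = (
    "sre", "lre", "gln", "rln", "rp",
    "lglre", "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle",
)


@dataclass(frozen=True)
class GLRLMatrix:
    """Run counts: ``counts[i-1, j-1]`` = number of runs of level i, length j."""

    counts: np.ndarray
    direction: tuple[int, int, int]
    n_voxels: int


def build_glrlm(dlesion: DiscretizedLesion, offset) -> GLRLMatrix:
    """Run-length matrix for one direction.

    Voxels are grouped into lines of the given direction; within a line,
    consecutive equal labels form a run, and a mask gap (non-consecutive
    positions) closes the current run.
    """
    offset = tuple(int(o) for o in offset)
    if offset not in DIRECTIONS_13:
        raise ValueError(f"offset {offset} is not one of the 13 unique directions")
    coords = np.asarray(dlesion.coords, dtype=np.int64)
    bins = np.asarray(dlesion.bins, dtype=np.int64)
    n = len(bins)
    B = dlesion.n_bins
    o = np.array(offset, dtype=np.int64)
    norm = int(o @ o)
    # Step parameter along a line increases by |o|^2 between consecutive
    # voxels of that line; the line key is constant along the line.
    step = coords @ o
    line_key = coords * norm - step[:, None] * o[None, :]
    order = np.lexsort((step, line_key[:, 2], line_key[:, 1], line_key[:, 0]))
    step_s = step[order]
    bins_s = bins[order]
    key_s = line_key[order]

    same_line = np.all(key_s[1:] == key_s[:-1], axis=1)
    consecutive = step_s[1:] - step_s[:-1] == norm
    same_label = bins_s[1:] == bins_s[:-1]
    # True where voxel k+1 continues the run started at or before voxel k.
    cont = same_line & consecutive & same_label
    starts = np.flatnonzero(np.concatenate(([True], ~cont)))
    ends = np.concatenate((starts[1:], [n]))
    lengths = ends - starts
    levels = bins_s[starts]

    lmax = int(lengths.max()) if n else 1
    mat = np.zeros((B, lmax), dtype=np.int64)
    np.add.at(mat, (levels - 1, lengths - 1), 1)
    return GLRLMatrix(counts=mat, direction=offset, n_voxels=n)


def _single_direction_stats(matrix: GLRLMatrix) -> np.ndarray:
    R = matrix.counts.astype(np.float64)
    nr = R.sum()
    if nr == 0:
        return np.zeros(len(GLRLM_STAT_NAMES))
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    sre = (R / j ** 2).sum() / nr
    lre = (R * j ** 2).sum() / nr
    gln = (R.sum(axis=1) ** 2).sum() / nr
    rln = (R.sum(axis=0) ** 2).sum() / nr
    rp = nr / matrix.n_voxels
    lglre = (R / i ** 2).sum() / nr
    hglre = (R * i ** 2).sum() / nr
    srlgle = (R / (i ** 2 * j ** 2)).sum() / nr
    srhgle = (R * i ** 2 / j ** 2).sum() / nr
    lrlgle = (R * j ** 2 / i ** 2).sum() / nr
    lrhgle = (R * i ** 2 * j ** 2).sum() / nr
    return np.array([sre, lre, gln, rln, rp, lglre, hglre,
                     srlgle, srhgle, lrlgle, lrhgle])


def glrlm_statistics(matrices) -> dict[str, float]:
    """The 11 run statistics, computed per direction and averaged.

    ``matrices`` is the sequence of per-direction matrices (normally 13).
    An empty sequence yields all zeros.
    """
    matrices = list(matrices)
    if not matrices:
        return {name: 0.0 for name in GLRLM_STAT_NAMES}
    stats = np.mean([_single_direction_stats(m) for m in matrices], axis=0)
    return dict(zip(GLRLM_STAT_NAMES, (float(v) for v in stats)))


def compute_glrlm_block(dlesion: DiscretizedLesion) -> dict[str, float]:
    """The 11 direction-averaged run-length features of one discretized image."""
    mats = [build_glrlm(dlesion, direction) for direction in DIRECTIONS_13]
    stats = glrlm_statistics(mats)
    return {f"glrlm_{dlesion.code}_{name}": val for name, val in stats.items()}


def glrlm_feature_names(code: str) -> list[str]:
    return [f"glrlm_{code}_{name}" for name in GLRLM_STAT_NAMES]
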