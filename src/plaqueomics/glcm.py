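"""Gray-level co-occurrence matrices and Haralick-family texture statistics.

A GLCM tabulates how often pairs of gray levels co-occur at a fixed spatial
offset within the segmentation mask.  Matrices are built for the 13 unique 3D
directions at voxel distances 1-3, symmetrized and normalized; pairs with one
endpoint outside the mask are skipped (mask-restricted co-occurrence).

Nineteen statistics are computed per matrix (standard Haralick-family
definitions, log base 2, with 0*log0 := 0), then aggregated over the 13
directions by mean and by range (max - min), per distance:
19 statistics x 2 aggregations x 3 distances = 114 features per discretized
image.  The maximal-correlation coefficient is replaced by maximum
probability for numerical stability on near-degenerate matrices; correlation
and the first informational measure are defined as 0 when their
normalizers vanish (e.g. single-gray-level lesions).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._grid import DIRECTIONS_13, dense_label_grid
from .discretize import DiscretizedLesion

__all__ = [
    "GLCMatrix",
    "GLCM_STAT_NAMES",
    "GLCM_DISTANCES",
    "build_glcm",
    "glcm_statistics",
    "compute_glcm_block",
    "glcm_feature_names",
]

GLCM_DISTANCES: tuple[int, ...] = (1, 2, 3)

GLCM_STAT_NAMES: tuple[str, ...] = (
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
    "max_probability", "autocorrelation", "cluster_shade",
    "cluster_prominence", "dissimilarity", "idn",
)


@dataclass(frozen=True)
class GLCMatrix:
    """Symmetric, normalized B x B co-occurrence probability matrix."""

    probs: np.ndarray
    distance: int
    direction: tuple[int, int, int]
    empty: bool = False


@lru_cache(maxsize=8)
def _index_arrays(n_bins: int):
    i = np.arange(1, n_bins + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    sum_idx = (ii + jj).astype(np.int64).ravel() - 2
    diff_idx = np.abs(ii - jj).astype(np.int64).ravel()
    return i, ii, jj, sum_idx, diff_idx


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def build_glcm(dlesion: DiscretizedLesion, offset, distance: int = 1) -> GLCMatrix:
    """Co-occurrence matrix for one direction and distance.

    Counts ordered gray-level pairs at displacement ``distance * offset``
    over voxel pairs that both lie inside the mask, adds the transpose and
    normalizes to sum 1.  If no pair exists the matrix is all-zero and
    flagged ``empty``.
    """
    offset = tuple(int(o) for o in offset)
    if offset not in DIRECTIONS_13:
        raise ValueError(f"offset {offset} is not one of the 13 unique directions")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    B = dlesion.n_bins
    grid, _ = dense_label_grid(dlesion.coords, dlesion.bins)
    shift = tuple(distance * o for o in offset)

    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, sh in enumerate(shift):
        if sh >= 0:
            src[ax] = slice(0, grid.shape[ax] - sh)
            dst[ax] = slice(sh, grid.shape[ax])
        else:
            src[ax] = slice(-sh, grid.shape[ax])
            dst[ax] = slice(0, grid.shape[ax] + sh)
    a = grid[tuple(src)].ravel()
    b = grid[tuple(dst)].ravel()
    keep = (a > 0) & (b > 0)
    a, b = a[keep], b[keep]
    mat = np.zeros((B, B), dtype=np.float64)
    if len(a) == 0:
        return GLCMatrix(probs=mat, distance=distance, direction=offset, empty=True)
    np.add.at(mat, (a - 1, b - 1), 1.0)
    mat = mat + mat.T
    mat /= mat.sum()
    return GLCMatrix(probs=mat, distance=distance, direction=offset, empty=False)


def glcm_statistics(matrix: GLCMatrix) -> dict[str, float]:
    """The 19 Haralick-family statistics of one normalized GLCM.

    An empty matrix yields all zeros.
    """
    if matrix.empty:
        return {name: 0.0 for name in GLCM_STAT_NAMES}
    p = matrix.probs
    B = p.shape[0]
    i, ii, jj, sum_idx, diff_idx = _index_arrays(B)

    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    # p_{x+y}(k), k = 2..2B and p_{x-y}(k), k = 0..B-1
    ksum = np.arange(2, 2 * B + 1, dtype=np.float64)
    p_sum = np.bincount(sum_idx, weights=p.ravel(), minlength=2 * B - 1)
    kdiff = np.arange(0, B, dtype=np.float64)
    p_diff = np.bincount(diff_idx, weights=p.ravel(), minlength=B)

    asm = float((p ** 2).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    autocorr = float((p * ii * jj).sum())
    correlation = (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 0.0
    variance = sigma2
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float((ksum * p_sum).sum())
    sum_variance = float(((ksum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = float(-_xlog2(p_sum).sum())
    entropy = float(-_xlog2(p).sum())
    diff_mean = float((kdiff * p_diff).sum())
    difference_variance = float(((kdiff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = float(-_xlog2(p_diff).sum())

    hx = float(-_xlog2(px).sum())
    pxpy = np.outer(px, px)
    hxy1 = float(-(p * np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    max_probability = float(p.max())
    cluster_shade = float((p * (ii + jj - 2 * mu) ** 3).sum())
    cluster_prominence = float((p * (ii + jj - 2 * mu) ** 4).sum())
    dissimilarity = float((p * np.abs(ii - jj)).sum())
    idn = float((p / (1.0 + np.abs(ii - jj) / B)).sum())

    values = (asm, contrast, float(correlation), variance, idm, sum_average,
              sum_variance, sum_entropy, entropy, difference_variance,
              difference_entropy, float(imc1), imc2, max_probability,
              autocorr, cluster_shade, cluster_prominence, dissimilarity, idn)
    return dict(zip(GLCM_STAT_NAMES, values))


def compute_glcm_block(dlesion: DiscretizedLesion) -> dict[str, float]:
    """The 114 GLCM features of one discretized image.

    For each distance in {1, 2, 3}: the 19 statistics on each of the 13
    direction matrices, aggregated by mean and by range over directions.
    """
    code = dlesion.code
    out: dict[str, float] = {}
    for d in GLCM_DISTANCES:
        stats = np.empty((len(DIRECTIONS_13), len(GLCM_STAT_NAMES)))
        for k, direction in enumerate(DIRECTIONS_13):
            s = glcm_statistics(build_glcm(dlesion, direction, d))
            stats[k] = [s[name] for name in GLCM_STAT_NAMES]
        means = stats.mean(axis=0)
        ranges = stats.max(axis=0) - stats.min(axis=0)
        for agg, vals in (("mean", means), ("range", ranges)):
            for name, val in zip(GLCM_STAT_NAMES, vals):
                out[f"glcm_{code}_d{d}_{agg}_{name}"] = float(val)
    return out


def glcm_feature_names(code: str) -> list[str]:
    """Feature names of one discretized image's GLCM block, in output order."""
    return [f"glcm_{code}_d{d}_{agg}_{name}"
            for d in GLCM_DISTANCES
            for agg in ("mean", "range")
            for name in GLCM_STAT_NAMES]
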