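"""Surface and fractal-dimension geometry features.

Five quantities describe a voxel set: voxel-face surface area (mm^2), volume
(mm^3), and three fractal dimensions (box-counting, information,
correlation) estimated from the scaling of box occupancy across dyadic box
sizes.  They are computed on the original mask and on every gray-level
sub-mask of each discretized image:
5 + (2 x 16 + 2 x 32 + 2 x 64) x 5 = 1125 features per lesion.

Surface area is the sum of exposed voxel faces (a face is exposed when its
6-neighbor lies outside the set), with per-axis face areas from the
anisotropic spacing.  Fractal dimensions overlay cubic box grids of side
eps in {1, 2, 4, 8, 16} voxels anchored at the bounding-box origin and fit
least-squares slopes of N(eps), I(eps) and C(eps) against log2 box size;
all three are reported with the sign convention that makes them non-negative
for ordinary sets.  A single point, or an empty sub-mask, yields 0.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedLesion
from .io import VoxelLesion

__all__ = [
    "surface_area",
    "fractal_dimensions",
    "compute_geometry_block",
    "geometry_feature_names",
    "BOX_SCALES",
]

BOX_SCALES: tuple[int, ...] = (1, 2, 4, 8, 16)


def surface_area(coords: np.ndarray, spacing_mm) -> float:
    """Total exposed-face area (mm^2) of a voxel set; empty set -> 0."""
    coords = np.asarray(coords, dtype=np.int64)
    if len(coords) == 0:
        return 0.0
    sx, sy, sz = (float(s) for s in spacing_mm)
    face_area = (sy * sz, sx * sz, sx * sy)  # x-, y-, z-normal faces
    origin = coords.min(axis=0)
    local = coords - origin + 1  # pad by one so every neighbor index is valid
    shape = local.max(axis=0) + 2
    grid = np.zeros(shape, dtype=bool)
    grid[local[:, 0], local[:, 1], local[:, 2]] = True
    total = 0.0
    for axis in range(3):
        inside = np.logical_and(grid, np.roll(grid, 1, axis=axis))
        exposed = 2 * grid.sum() - 2 * inside.sum()
        total += face_area[axis] * exposed
    return float(total)


def _box_occupancies(local: np.ndarray, eps: int) -> np.ndarray:
    boxes = local // eps
    dims = boxes.max(axis=0) + 1
    keys = (boxes[:, 0] * dims[1] + boxes[:, 1]) * dims[2] + boxes[:, 2]
    counts = np.bincount(keys)
    counts = counts[counts > 0]
    return counts / len(local)


# least-squares slope weights against log2(1/eps), precomputed for the fixed
# dyadic scales: slope = sum(w * y)
_INV_SIZE = -np.log2(np.asarray(BOX_SCALES, dtype=np.float64))
_SLOPE_W = (_INV_SIZE - _INV_SIZE.mean()) / ((_INV_SIZE - _INV_SIZE.mean()) ** 2).sum()


def fractal_dimensions(coords: np.ndarray) -> tuple[float, float, float]:
    """(box-counting, information, correlation) dimensions of a point set.

    Box grids of side eps in :data:`BOX_SCALES` voxels are anchored at the
    bounding-box origin.  Per scale: N(eps) = occupied boxes,
    I(eps) = -sum p log2 p, C(eps) = log2 sum p^2 with p the box occupancy
    fractions.  Dimensions are least-squares slopes of log2 N and I against
    log2(1/eps), and of C against log2 eps.  Sets yielding fewer than two
    usable scales (e.g. a single point) return zeros.
    """
    coords = np.asarray(coords, dtype=np.int64)
    if len(coords) == 0:
        return (0.0, 0.0, 0.0)
    local = coords - coords.min(axis=0)
    log_n = np.empty(len(BOX_SCALES))
    info = np.empty(len(BOX_SCALES))
    corr = np.empty(len(BOX_SCALES))
    for s, eps in enumerate(BOX_SCALES):
        p = _box_occupancies(local, eps)
        log_n[s] = np.log2(len(p))
        info[s] = -(p * np.log2(p)).sum()
        corr[s] = np.log2((p ** 2).sum())
    box_dim = float(_SLOPE_W @ log_n)
    info_dim = float(_SLOPE_W @ info)
    # C regressed on log2 eps = -log2(1/eps): slope flips sign
    corr_dim = float(-(_SLOPE_W @ corr))
    return (box_dim, info_dim, corr_dim)


def _five(coords: np.ndarray, spacing, total_surface: float | None):
    """surface, (volume | surface ratio), box, info, corr for one voxel set."""
    if len(coords) == 0:
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    surf = surface_area(coords, spacing)
    box, info, corr = fractal_dimensions(coords)
    if total_surface is None:
        sx, sy, sz = (float(s) for s in spacing)
        second = len(coords) * sx * sy * sz  # volume
    else:
        second = surf / total_surface if total_surface > 0 else 0.0
    return (surf, second, box, info, corr)


def compute_geometry_block(lesion: VoxelLesion,
                           dlesions: list[DiscretizedLesion]) -> dict[str, float]:
    """The 1125 geometry features of one lesion.

    Original mask: surface, volume and the three fractal dimensions.  Then,
    for each discretized image and each gray level g in 1..B: surface of the
    g-level sub-mask, its ratio to the total mask surface, and the three
    fractal dimensions of the sub-mask.  Empty gray levels contribute zeros.
    """
    out: dict[str, float] = {}
    surf, vol, box, info, corr = _five(lesion.coords, lesion.spacing_mm, None)
    out["geom_surface"] = surf
    out["geom_volume"] = vol
    out["geom_boxdim"] = box
    out["geom_infodim"] = info
    out["geom_corrdim"] = corr
    for dl in dlesions:
        code = dl.code
        for g in range(1, dl.n_bins + 1):
            sub = dl.coords[dl.bins == g]
            s, ratio, b, i, c = _five(sub, dl.spacing_mm, surf)
            out[f"geom_{code}_g{g:02d}_surface"] = s
            out[f"geom_{code}_g{g:02d}_surfratio"] = ratio
            out[f"geom_{code}_g{g:02d}_boxdim"] = b
            out[f"geom_{code}_g{g:02d}_infodim"] = i
            out[f"geom_{code}_g{g:02d}_corrdim"] = c
    return out


def geometry_feature_names(codes) -> list[str]:
    names = ["geom_surface", "geom_volume", "geom_boxdim", "geom_infodim",
             "geom_corrdim"]
    for code in codes:
        n_bins = int(code[2:])
        for g in range(1, n_bins + 1):
            for stat in ("surface", "surfratio", "boxdim", "infodim", "corrdim"):
                names.append(f"geom_{code}_g{g:02d}_{stat}")
    return names
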