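"""Gray-level discretization of lesion HU values.

Texture and per-level geometry features are computed not on raw Hounsfield
units but on discretized copies of the lesion: voxel values mapped to B gray
levels either by identical HU ranges per bin (equal-width) or identical voxel
counts per bin (equal-probability), at B in {16, 32, 64}.  Each lesion thus
yields six discretized images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VoxelLesion

__all__ = [
    "DiscretizedLesion",
    "discretize_equal_width",
    "discretize_equal_prob",
    "discretize_all",
    "SCHEMES",
]

#: (scheme, B) pairs of the six standard discretizations, in fixed order.
SCHEMES: tuple[tuple[str, int], ...] = (
    ("equal_width", 16), ("equal_width", 32), ("equal_width", 64),
    ("equal_prob", 16), ("equal_prob", 32), ("equal_prob", 64),
)


@dataclass(frozen=True)
class DiscretizedLesion:
    """A lesion's voxels with integer gray-level labels in 1..B.

    ``bins`` is aligned with the parent lesion's ``coords``; ``coords`` and
    ``spacing_mm`` are carried along so texture and geometry modules can run
    from this object alone.
    """

    bins: np.ndarray
    coords: np.ndarray
    spacing_mm: tuple[float, float, float]
    n_bins: int
    scheme: str
    parent: str

    def __post_init__(self) -> None:
        bins = np.asarray(self.bins, dtype=np.int64)
        object.__setattr__(self, "bins", bins)
        if self.scheme not in ("equal_width", "equal_prob"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if len(bins) != len(self.coords):
            raise ValueError("bins and coords length mismatch")
        if len(bins) and (bins.min() < 1 or bins.max() > self.n_bins):
            raise ValueError(f"bin labels outside 1..{self.n_bins}")

    @property
    def code(self) -> str:
        """Short feature-name code, e.g. ``ew16`` or ``ep64``."""
        prefix = "ew" if self.scheme == "equal_width" else "ep"
        return f"{prefix}{self.n_bins}"


def equal_width_labels(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin labels in 1..B for a value array.

    bin(v) = min(B, floor((v - min) / ((max - min) / B)) + 1); a constant
    array maps entirely to bin 1.
    """
    values = np.asarray(values, dtype=np.float64)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.ones(len(values), dtype=np.int64)
    width = (vmax - vmin) / n_bins
    labels = np.floor((values - vmin) / width).astype(np.int64) + 1
    return np.minimum(labels, n_bins)


def equal_prob_labels(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-probability (rank-based) bin labels in 1..B.

    Voxels are sorted by (value, position order) — ties broken by the stable
    input order — and the k-th of n voxels (0-based) receives label
    ``floor(k*B/n) + 1`` capped at B, so bin counts differ by at most one.
    """
    values = np.asarray(values)
    n = len(values)
    if values.min() == values.max():  # single gray level, as in equal-width
        return np.ones(n, dtype=np.int64)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    labels = (ranks * n_bins) // n + 1
    return np.minimum(labels, n_bins)


def _make(lesion: VoxelLesion, labels: np.ndarray, n_bins: int,
          scheme: str) -> DiscretizedLesion:
    return DiscretizedLesion(bins=labels, coords=lesion.coords,
                             spacing_mm=lesion.spacing_mm, n_bins=n_bins,
                             scheme=scheme, parent=lesion.lesion_id)


def discretize_equal_width(lesion: VoxelLesion, n_bins: int) -> DiscretizedLesion:
    """Discretize into ``n_bins`` bins of identical HU range."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    return _make(lesion, equal_width_labels(lesion.values, n_bins), n_bins,
                 "equal_width")


def discretize_equal_prob(lesion: VoxelLesion, n_bins: int) -> DiscretizedLesion:
    """Discretize into ``n_bins`` bins of (near-)identical voxel count."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    return _make(lesion, equal_prob_labels(lesion.values, n_bins), n_bins,
                 "equal_prob")


def discretize_all(lesion: VoxelLesion) -> list[DiscretizedLesion]:
    """The six standard discretized images, in :data:`SCHEMES` order."""
    out = []
    for scheme, n_bins in SCHEMES:
        fn = discretize_equal_width if scheme == "equal_width" else discretize_equal_prob
        out.append(fn(lesion, n_bins))
    return out
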