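"""Synthetic coronary plaque cross-section phantoms.

Generates labeled plaque lesions with the statistical structure the analysis
assumes, so the whole pipeline is testable without patient data.  A lesion
is a short slab (a few 0.6 mm sections) of an annular or crescent-shaped
vessel-wall mask filled with fibrous-tissue Hounsfield units (default
N(90, 25) with a mild smooth in-plane gradient).  Advanced lesions
additionally contain a spatially contiguous low-attenuation core (default
N(20, 15)) occupying a random fraction of the wall; with probability 0.3 the
core is a concentric band, the analog of the napkin-ring sign.

With ``matched_marginal`` set, each early lesion is a random spatial
permutation of an advanced lesion's voxel values, so the two classes have
identical per-lesion HU histograms and differ only in spatial arrangement:
any separation achieved on such a cohort is attributable to texture and
geometry, not to the marginal intensity distribution.

Visual pattern labels follow the generative rule (no core -> homogeneous,
blob core -> heterogeneous, ring core -> napkin-ring) and are flipped to a
random other category with probability ``pattern_label_noise`` to emulate
imperfect visual reading.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import VoxelLesion, write_lesion

__all__ = [
    "PhantomConfig",
    "PhantomLesion",
    "PATTERNS",
    "generate_lesion",
    "generate_cohort",
    "write_cohort",
    "lesion_to_voxels",
]

PATTERNS: tuple[str, ...] = ("homogeneous", "heterogeneous", "napkin-ring")

RING_CORE_PROBABILITY = 0.3
CRESCENT_PROBABILITY = 0.35

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of a synthetic cohort.

    Defaults mirror the analyzed cohort: 445 cross sections at 30% advanced
    prevalence, voxel spacing (0.4, 0.4, 0.6) mm, three-section slabs,
    fibrous tissue around 90 HU and necrotic/lipid core below the 30 HU
    low-attenuation threshold.
    """

    n_lesions: int = 445
    prevalence_advanced: float = 0.30
    spacing_mm: tuple[float, float, float] = (0.4, 0.4, 0.6)
    slab_thickness_vox: int = 3
    wall_radius_range_vox: tuple[int, int] = (5, 10)
    hu_fibrous: tuple[float, float] = (90.0, 25.0)
    hu_core: tuple[float, float] = (20.0, 15.0)
    core_fraction_range: tuple[float, float] = (0.10, 0.40)
    matched_marginal: bool = False
    pattern_label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence_advanced <= 1.0:
            raise ValueError("prevalence_advanced must be in [0, 1]")
        if not 0.0 <= self.pattern_label_noise <= 1.0:
            raise ValueError("pattern_label_noise must be in [0, 1]")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if self.slab_thickness_vox < 1:
            raise ValueError("slab_thickness_vox must be >= 1")
        if self.wall_radius_range_vox[0] < 3:
            raise ValueError("minimum wall radius must be >= 3 voxels")
        lo, hi = self.core_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("core_fraction_range must be ordered fractions")


@dataclass(frozen=True)
class PhantomLesion:
    """One synthetic cross-section lesion with its ground-truth labels."""

    volume: np.ndarray
    mask: np.ndarray
    label_advanced: int
    label_pattern: str
    lesion_id: str
    core_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mask.sum() == 0:
            raise ValueError("mask is empty")
        if self.label_pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.label_pattern!r}")
        _, n_components = ndimage.label(self.mask, structure=_STRUCT_26)
        if n_components != 1:
            raise ValueError("mask must be a single 26-connected component")


def _wall_mask(config: PhantomConfig, rng: np.random.Generator):
    """Annular or crescent wall mask plus in-plane radius/angle maps."""
    r_lo, r_hi = config.wall_radius_range_vox
    r_out = int(rng.integers(r_lo, r_hi + 1))
    r_in = max(1, int(round(r_out * rng.uniform(0.30, 0.55))))
    if r_out - r_in < 2:
        r_in = r_out - 2
    size = 2 * r_out + 3
    center = r_out + 1
    x = np.arange(size) - center
    xx, yy = np.meshgrid(x, x, indexing="ij")
    rr = np.hypot(xx, yy)
    wall2d = (rr <= r_out) & (rr > r_in)
    if rng.random() < CRESCENT_PROBABILITY:
        theta = np.arctan2(yy, xx)
        gap_center = rng.uniform(-np.pi, np.pi)
        gap_half = np.deg2rad(rng.uniform(30.0, 75.0))
        delta = np.angle(np.exp(1j * (theta - gap_center)))
        wall2d &= np.abs(delta) > gap_half
    nz = config.slab_thickness_vox
    mask = np.repeat(wall2d[:, :, None], nz, axis=2)
    return mask, rr, (r_in, r_out)


def _grow_core(mask: np.ndarray, target: int, rng: np.random.Generator):
    """Contiguous blob of ~target voxels grown inside the mask (BFS over
    26-neighbors from a random seed voxel)."""
    coords = np.argwhere(mask)
    seed_voxel = tuple(coords[rng.integers(len(coords))])
    core = np.zeros_like(mask)
    frontier = [seed_voxel]
    core[seed_voxel] = True
    count = 1
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    shape = mask.shape
    while count < target and frontier:
        next_frontier = []
        rng.shuffle(frontier)
        for vox in frontier:
            for dx, dy, dz in offsets:
                nb = (vox[0] + dx, vox[1] + dy, vox[2] + dz)
                if (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                        and 0 <= nb[2] < shape[2]
                        and mask[nb] and not core[nb]):
                    core[nb] = True
                    next_frontier.append(nb)
                    count += 1
                    if count >= target:
                        return core
        frontier = next_frontier
    return core


def _ring_core(mask: np.ndarray, rr: np.ndarray, radii, target: int):
    """Concentric low-attenuation band (napkin-ring analog) of >= target
    voxels, grown radially around the mid-wall radius."""
    r_in, r_out = radii
    r_mid = 0.5 * (r_in + r_out)
    for half_width in np.arange(0.5, r_out - r_in, 0.25):
        band = np.abs(rr - r_mid) <= half_width
        core = mask & band[:, :, None]
        if core.sum() >= target:
            return core
    return mask & (np.abs(rr - r_mid) <= (r_out - r_in))[:, :, None]


def _flip_pattern(pattern: str, noise: float, rng: np.random.Generator) -> str:
    if noise > 0 and rng.random() < noise:
        others = [p for p in PATTERNS if p != pattern]
        return others[int(rng.integers(len(others)))]
    return pattern


def generate_lesion(config: PhantomConfig, advanced: bool,
                    rng: np.random.Generator,
                    lesion_id: str = "lesion") -> PhantomLesion:
    """Generate one synthetic lesion.

    Early lesions are fibrous-only walls; advanced lesions carry a
    contiguous low-HU core (blob or ring).  Under ``matched_marginal``,
    early lesions are spatial permutations of an advanced draw, preserving
    the per-lesion HU multiset exactly.  Degenerate draws (< 10 voxels, or a
    disconnected wall) are regenerated, up to 100 attempts.
    """
    make_core = advanced or config.matched_marginal
    for _ in range(100):
        mask, rr, radii = _wall_mask(config, rng)
        n_vox = int(mask.sum())
        if n_vox < 10:
            continue
        _, n_components = ndimage.label(mask, structure=_STRUCT_26)
        if n_components != 1:
            continue

        mu_f, sd_f = config.hu_fibrous
        values = rng.normal(mu_f, sd_f, size=mask.shape)
        # mild smooth in-plane gradient
        amp = rng.uniform(0.0, 10.0)
        phi = rng.uniform(0.0, 2 * np.pi)
        center = (mask.shape[0] - 1) / 2.0
        xg = np.arange(mask.shape[0]) - center
        grad2d = (np.cos(phi) * xg[:, None] + np.sin(phi) * xg[None, :])
        grad2d *= amp / max(1.0, np.abs(grad2d[mask.any(axis=2)]).max())
        values += grad2d[:, :, None]

        core = np.zeros_like(mask)
        ring = False
        if make_core:
            lo, hi = config.core_fraction_range
            target = max(1, int(round(rng.uniform(lo, hi) * n_vox)))
            ring = bool(rng.random() < RING_CORE_PROBABILITY)
            if ring:
                core = _ring_core(mask, rr, radii, target)
            else:
                core = _grow_core(mask, target, rng)
            mu_c, sd_c = config.hu_core
            values[core] = rng.normal(mu_c, sd_c, size=int(core.sum()))

        volume = np.where(mask, np.rint(values), 0).astype(np.int16)

        if make_core and not advanced:
            # matched-marginal early lesion: permute the advanced draw's
            # values over the mask, destroying spatial structure only.
            flat = volume[mask]
            volume = volume.copy()
            volume[mask] = rng.permutation(flat)
            core = np.zeros_like(mask)
            ring = False

        if not core.any():
            pattern = "homogeneous"
        elif ring:
            pattern = "napkin-ring"
        else:
            pattern = "heterogeneous"
        pattern = _flip_pattern(pattern, config.pattern_label_noise, rng)
        return PhantomLesion(volume=volume, mask=mask.astype(np.uint8),
                             label_advanced=int(advanced),
                             label_pattern=pattern, lesion_id=lesion_id,
                             core_mask=core if core.any() else None)
    raise RuntimeError("failed to generate a valid lesion in 100 attempts")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_cohort(config: PhantomConfig):
    """Generate the full labeled cohort.

    Exactly ``round_half_up(n_lesions * prevalence_advanced)`` lesions are
    advanced (445 x 0.30 -> 134).  Each lesion draws from its own RNG stream
    derived from (seed, lesion index), so cohorts are reproducible and
    order-independent; the advanced/early assignment is a seeded permutation.

    Returns ``(lesions, labels)`` with one labels row per lesion:
    lesion_id, label_advanced, label_pattern.
    """
    n = config.n_lesions
    n_advanced = _round_half_up(n * config.prevalence_advanced)
    assign_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10 ** 9]))
    advanced_flags = np.zeros(n, dtype=bool)
    advanced_flags[assign_rng.permutation(n)[:n_advanced]] = True

    lesions = []
    rows = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        lesion_id = f"lesion_{i:04d}"
        lesion = generate_lesion(config, bool(advanced_flags[i]), rng,
                                 lesion_id=lesion_id)
        lesions.append(lesion)
        rows.append({"lesion_id": lesion_id,
                     "label_advanced": lesion.label_advanced,
                     "label_pattern": lesion.label_pattern})
    labels = pd.DataFrame(rows)
    return lesions, labels


def lesion_to_voxels(lesion: PhantomLesion,
                     spacing_mm=(0.4, 0.4, 0.6)) -> VoxelLesion:
    """In-memory masked-voxel view of a phantom lesion."""
    coords = np.argwhere(lesion.mask == 1)
    values = lesion.volume[coords[:, 0], coords[:, 1], coords[:, 2]].astype(np.int64)
    return VoxelLesion(values=values, coords=coords, spacing_mm=spacing_mm,
                       lesion_id=lesion.lesion_id)


def write_cohort(lesions, labels: pd.DataFrame, out_dir,
                 spacing_mm=(0.4, 0.4, 0.6)) -> None:
    """Write one NRRD image + mask per lesion and the labels CSV."""
    os.makedirs(out_dir, exist_ok=True)
    for lesion in lesions:
        write_lesion(lesion.volume, lesion.mask, spacing_mm,
                     os.path.join(out_dir, f"{lesion.lesion_id}_image.nrrd"),
                     os.path.join(out_dir, f"{lesion.lesion_id}_mask.nrrd"))
    labels.to_csv(os.path.join(out_dir, "labels.csv"), index=False)
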