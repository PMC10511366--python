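"""Shared geometry primitives and the ground-truth container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..image import BinaryMask
from ..tree import CenterlineTree

# Default HU plateaus: air-filled lumen, foam/parenchyma background, and
# soft-tissue-like tube/wall material, matching the contrast of inspiratory
# low-dose chest CT.
HU_LUMEN = -1000.0
HU_BACKGROUND = -850.0
HU_WALL = -50.0

# Default voxel spacing (mm): sub-millimetre in-plane pixels with a slightly
# coarser slice increment, echoing thin-slice low-dose reconstructions.
DEFAULT_SPACING = (0.6, 0.6, 0.7)

SUPERSAMPLE = 3  # per-axis anti-aliasing factor for rasterisation


@dataclass
class GroundTruth:
    """Exact reference for a synthetic volume.

    ``trees`` holds one :class:`CenterlineTree` per connected structure (one
    per tube for a phantom, a single tree for an airway tree).  The diameter
    dicts are parallel to ``trees`` and keyed by branch id.
    """

    lumen_mask: BinaryMask
    wall_mask: BinaryMask
    trees: list[CenterlineTree] = field(default_factory=list)
    lumen_diameters_mm: list[dict[int, float]] = field(default_factory=list)
    total_diameters_mm: list[dict[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any((self.lumen_mask.values > 0) & (self.wall_mask.values > 0)):
            raise ValueError("lumen and wall masks must be disjoint")


@dataclass
class Capsule:
    """A finite cylinder: rounded (capsule) ends by default, flat caps if ``capped``."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float
    capped: bool = False

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.capped:
            a = self.p1 - self.p0
            n = np.linalg.norm(a)
            a = a / n if n > 0 else a
            radial = self.radius * np.sqrt(np.clip(1.0 - a**2, 0.0, 1.0))
            lo = np.minimum(self.p0, self.p1) - radial
            hi = np.maximum(self.p0, self.p1) + radial
        else:
            lo = np.minimum(self.p0, self.p1) - self.radius
            hi = np.maximum(self.p0, self.p1) + self.radius
        return lo, hi

    def distance_sq(self, x, y, z) -> np.ndarray:
        d = self.p1 - self.p0
        length = float(np.linalg.norm(d))
        if length == 0:
            return (x - self.p0[0]) ** 2 + (y - self.p0[1]) ** 2 + (z - self.p0[2]) ** 2
        u = d / length
        dx, dy, dz = x - self.p0[0], y - self.p0[1], z - self.p0[2]
        t_raw = dx * u[0] + dy * u[1] + dz * u[2]
        t = np.clip(t_raw, 0.0, length)
        d2 = (dx - t * u[0]) ** 2 + (dy - t * u[1]) ** 2 + (dz - t * u[2]) ** 2
        if self.capped:
            # outside the axial span counts as outside regardless of radius
            d2 = np.where((t_raw < 0.0) | (t_raw > length), np.inf, d2)
        return d2


@dataclass
class Sphere:
    center: np.ndarray
    radius: float

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, dtype=float)
        return c - self.radius, c + self.radius

    def distance_sq(self, x, y, z) -> np.ndarray:
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 + (z - self.center[2]) ** 2


def rasterize_solids(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    primitives: list[tuple[object, float, float]],
    supersample: int = SUPERSAMPLE,
):
    """Anti-aliased rasterisation of (primitive, lumen_radius, outer_radius) triples.

    Returns per-voxel partial-volume fractions ``(f_lumen, f_solid)`` where
    ``f_solid`` covers lumen plus wall, computed by membership counting on a
    ``supersample``-times finer grid.
    """
    sp = np.asarray(spacing, dtype=float)
    ss = supersample
    ss_shape = tuple(int(n) * ss for n in shape)
    lumen = np.zeros(ss_shape, dtype=bool)
    solid = np.zeros(ss_shape, dtype=bool)
    ss_sp = sp / ss

    def coord(axis: int, i0: int, i1: int) -> np.ndarray:
        idx = np.arange(i0, i1, dtype=float)
        return ((idx + 0.5) / ss - 0.5) * sp[axis]

    for prim, r_l, r_o in primitives:
        lo, hi = prim.bounds()
        i0 = np.maximum(np.floor((lo / sp + 0.5) * ss).astype(int), 0)
        i1 = np.minimum(np.ceil((hi / sp + 0.5) * ss).astype(int) + 1, ss_shape)
        if np.any(i0 >= i1):
            continue
        x = coord(0, i0[0], i1[0])[:, None, None]
        y = coord(1, i0[1], i1[1])[None, :, None]
        z = coord(2, i0[2], i1[2])[None, None, :]
        d2 = prim.distance_sq(x, y, z)
        sl = (slice(i0[0], i1[0]), slice(i0[1], i1[1]), slice(i0[2], i1[2]))
        if r_l > 0:
            lumen[sl] |= d2 <= r_l * r_l
        solid[sl] |= d2 <= r_o * r_o

    def block_mean(a: np.ndarray) -> np.ndarray:
        nx, ny, nz = shape
        return (
            a.reshape(nx, ss, ny, ss, nz, ss)
            .mean(axis=(1, 3, 5))
        )

    return block_mean(lumen), block_mean(solid)


def fractions_to_volume(f_lumen, f_solid, spacing, hu_lumen, hu_wall, hu_background):
    """HU volume from partial-volume fractions (mixture of the three plateaus)."""
    f_wall = np.clip(f_solid - f_lumen, 0.0, 1.0)
    values = (
        hu_lumen * f_lumen
        + hu_wall * f_wall
        + hu_background * (1.0 - np.clip(f_lumen + f_wall, 0.0, 1.0))
    )
    return values


def fractions_to_masks(f_lumen, f_solid, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote binary masks: lumen, wall (solid minus lumen), disjoint."""
    lumen = f_lumen > 0.5
    solid = f_solid > 0.5
    wall = solid & ~lumen
    return lumen.astype(np.uint8), wall.astype(np.uint8)
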