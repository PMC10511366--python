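"""Tube phantoms: air-filled annular tubes embedded in foam.

Emulates the calibration phantoms used to tune airway wall segmentation:
straight tubes of known lumen diameter and wall thickness, rasterised with
partial-volume anti-aliasing so sub-voxel accuracy can be assessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..image import BinaryMask, ImageVolume
from ..tree import Branch, CenterlineTree
from .base import (
    DEFAULT_SPACING,
    HU_BACKGROUND,
    HU_LUMEN,
    HU_WALL,
    Capsule,
    GroundTruth,
    fractions_to_masks,
    fractions_to_volume,
    rasterize_solids,
)

__all__ = ["TubeSpec", "PhantomSpec", "rasterize_tube_phantom", "default_phantom_spec"]


@dataclass
class TubeSpec:
    """One straight tube: air lumen surrounded by a solid wall annulus."""

    lumen_diameter_mm: float
    wall_thickness_mm: float
    length_mm: float
    center_mm: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.lumen_diameter_mm <= 0:
            raise ValueError("lumen diameter must be > 0")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall thickness must be > 0")
        if self.length_mm <= 0:
            raise ValueError("length must be > 0")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("axis must be non-zero")
        self.axis = tuple(a / n)

    @property
    def lumen_radius_mm(self) -> float:
        return 0.5 * self.lumen_diameter_mm

    @property
    def outer_radius_mm(self) -> float:
        return self.lumen_radius_mm + self.wall_thickness_mm

    @property
    def total_diameter_mm(self) -> float:
        return 2.0 * self.outer_radius_mm

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_mm, dtype=float)
        a = np.asarray(self.axis, dtype=float)
        h = 0.5 * self.length_mm
        return c - h * a, c + h * a


@dataclass
class PhantomSpec:
    tubes: list[TubeSpec]
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    hu_lumen: float = HU_LUMEN
    hu_wall: float = HU_WALL
    hu_background: float = HU_BACKGROUND


def default_phantom_spec(
    lumen_diameters_mm=(6.0, 6.0, 5.5, 5.0, 4.5, 4.0, 3.5, 3.0),
    wall_thicknesses_mm=(1.5, 0.9, 1.2, 1.0, 0.8, 0.6, 0.7, 0.5),
    tube_length_mm: float = 15.0,
    cell_mm: float = 18.0,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> PhantomSpec:
    """An 8-tube phantom laid out on a 2x4 grid, tubes along z.

    Lumen diameters span 3-6 mm and wall thicknesses 0.5-1.5 mm, covering the
    calibre range of the first airway generations at screening-CT resolution.
    """
    if len(lumen_diameters_mm) != len(wall_thicknesses_mm):
        raise ValueError("diameter and wall lists must have equal length")
    n = len(lumen_diameters_mm)
    ncols = 4
    nrows = int(np.ceil(n / ncols))
    sp = np.asarray(spacing, dtype=float)
    extent_xy = np.asarray([nrows * cell_mm, ncols * cell_mm])
    z_extent = tube_length_mm + 4.0
    shape = tuple(int(np.ceil(e / s)) for e, s in zip((*extent_xy, z_extent), sp))
    zc = (shape[2] - 1) * sp[2] / 2.0
    tubes = []
    # sub-voxel offset keeps tube centres incommensurate with the voxel grid;
    # grid-aligned centres digitise with a systematic rim deficit
    off = (0.2718, 0.1414)
    for i, (d, t) in enumerate(zip(lumen_diameters_mm, wall_thicknesses_mm)):
        r, c = divmod(i, ncols)
        center = ((r + 0.5) * cell_mm + off[0], (c + 0.5) * cell_mm + off[1], zc)
        tubes.append(
            TubeSpec(
                lumen_diameter_mm=d,
                wall_thickness_mm=t,
                length_mm=tube_length_mm,
                center_mm=center,
            )
        )
    return PhantomSpec(tubes=tubes, shape=shape, spacing=spacing)


def rasterize_tube_phantom(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Rasterise the phantom into an ideal (noise-free) HU volume + ground truth.

    Raises if a tube extends outside the grid or two tubes overlap.
    """
    if not spec.tubes:
        raise ValueError("phantom needs at least one tube")
    sp = np.asarray(spec.spacing, dtype=float)
    shape = np.asarray(spec.shape, dtype=int)
    phys_lo = -0.5 * sp
    phys_hi = (shape - 0.5) * sp

    primitives = []
    for tube in spec.tubes:
        p0, p1 = tube.endpoints()
        # tight cylinder AABB: radial extent per axis is r * sqrt(1 - d_axis^2)
        a = np.asarray(tube.axis, dtype=float)
        radial = tube.outer_radius_mm * np.sqrt(np.clip(1.0 - a**2, 0.0, 1.0))
        lo = np.minimum(p0, p1) - radial
        hi = np.maximum(p0, p1) + radial
        if np.any(lo < phys_lo) or np.any(hi > phys_hi):
            raise ValueError(f"tube at {tube.center_mm} extends outside the grid")
        primitives.append(
            (
                Capsule(p0, p1, tube.outer_radius_mm, capped=True),
                tube.lumen_radius_mm,
                tube.outer_radius_mm,
            )
        )

    # pairwise overlap check on outer envelopes (capsule-capsule distance via
    # dense sampling of one axis against the other's capsule)
    for i in range(len(spec.tubes)):
        for j in range(i + 1, len(spec.tubes)):
            a, b = spec.tubes[i], spec.tubes[j]
            pa0, pa1 = a.endpoints()
            ts = np.linspace(0.0, 1.0, 64)
            pts = pa0[None, :] * (1 - ts[:, None]) + pa1[None, :] * ts[:, None]
            cap = Capsule(*b.endpoints(), 0.0)
            d = np.sqrt(cap.distance_sq(pts[:, 0], pts[:, 1], pts[:, 2]))
            if np.min(d) < a.outer_radius_mm + b.outer_radius_mm:
                raise ValueError(f"tubes {i} and {j} overlap")

    f_lumen, f_solid = rasterize_solids(tuple(shape), tuple(sp), primitives)
    values = fractions_to_volume(
        f_lumen, f_solid, sp, spec.hu_lumen, spec.hu_wall, spec.hu_background
    )
    volume = ImageVolume(values=values, spacing=tuple(sp))
    lumen_arr, wall_arr = fractions_to_masks(f_lumen, f_solid, sp)
    lumen_mask = BinaryMask(values=lumen_arr, spacing=tuple(sp))
    wall_mask = BinaryMask(values=wall_arr, spacing=tuple(sp))

    trees, lum_d, tot_d = [], [], []
    for tube in spec.tubes:
        p0, p1 = tube.endpoints()
        n_pts = max(2, int(np.ceil(tube.length_mm)) + 1)
        pts = np.linspace(p0, p1, n_pts)
        branch = Branch(branch_id=0, points=pts, parent_id=None, generation=0)
        trees.append(CenterlineTree(branches={0: branch}, root_id=0))
        lum_d.append({0: tube.lumen_diameter_mm})
        tot_d.append({0: tube.total_diameter_mm})

    gt = GroundTruth(
        lumen_mask=lumen_mask,
        wall_mask=wall_mask,
        trees=trees,
        lumen_diameters_mm=lum_d,
        total_diameters_mm=tot_d,
    )
    return volume, gt
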