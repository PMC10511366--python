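"""Recursive bifurcating airway trees with exact ground truth.

Geometry follows the symmetric dichotomous-branching (Weibel-type) model: a
root segment (trachea, generation 0) splits at each branch point into two
children whose diameter is the parent diameter times a fixed ratio, whose
length is a fixed multiple of their diameter, and whose directions deviate
from the parent by a branching half-angle.  Successive branching planes are
rotated 90 degrees so the tree fills 3D space.  Optional jitter on angles and
lengths breaks the symmetry; with zero jitter a tree of maximum generation g
has exactly ``2**(g+1) - 1`` branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

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
    Sphere,
    fractions_to_masks,
    fractions_to_volume,
    rasterize_solids,
)

__all__ = ["TreeSpec", "rasterize_airway_tree"]


@dataclass
class TreeSpec:
    root_lumen_diameter_mm: float = 6.0
    wall_fraction: float = 0.35  # wall thickness as a fraction of lumen radius
    diameter_ratio: float = 0.75  # child lumen diameter / parent lumen diameter
    length_diameter_ratio: float = 3.0
    half_angle_deg: float = 35.0
    max_generation: int = 2
    min_lumen_diameter_mm: float = 2.0
    angle_jitter_deg: float = 0.0
    length_jitter_frac: float = 0.0
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    hu_lumen: float = HU_LUMEN
    hu_wall: float = HU_WALL
    hu_background: float = HU_BACKGROUND

    def __post_init__(self) -> None:
        if not (0 < self.diameter_ratio <= 1):
            raise ValueError("diameter ratio must be in (0, 1]")
        if self.max_generation < 0:
            raise ValueError("max generation must be >= 0")
        if self.min_lumen_diameter_mm <= 0:
            raise ValueError("min lumen diameter must be > 0")
        if self.wall_fraction <= 0:
            raise ValueError("wall fraction must be > 0")


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about unit axis."""
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1 - np.cos(angle))
    )


def _build_segments(spec: TreeSpec, rng: np.random.Generator):
    """Recursive construction; returns list of branch records."""
    sp = np.asarray(spec.spacing, dtype=float)
    shape = np.asarray(spec.shape, dtype=int)
    extent = (shape - 1) * sp
    start = np.array([extent[0] / 2.0, extent[1] / 2.0, extent[2] - 2.0 * sp[2]])
    theta = np.deg2rad(spec.half_angle_deg)

    records = []  # (id, parent_id, generation, p0, p1, r_lumen, r_outer)
    next_id = [0]

    def grow(p0, direction, binormal, diameter, generation, parent_id):
        bid = next_id[0]
        next_id[0] += 1
        length = spec.length_diameter_ratio * diameter
        if spec.length_jitter_frac > 0:
            length *= 1.0 + spec.length_jitter_frac * rng.uniform(-1, 1)
        p1 = p0 + direction * length
        r_l = diameter / 2.0
        r_o = r_l * (1.0 + spec.wall_fraction)
        records.append((bid, parent_id, generation, p0.copy(), p1.copy(), r_l, r_o))
        child_d = diameter * spec.diameter_ratio
        if generation >= spec.max_generation or child_d < spec.min_lumen_diameter_mm:
            return
        for sign in (+1.0, -1.0):
            ang = sign * theta
            if spec.angle_jitter_deg > 0:
                ang += np.deg2rad(spec.angle_jitter_deg) * rng.uniform(-1, 1)
            child_dir = _rotate(direction, binormal, ang)
            child_bin = np.cross(child_dir, binormal)
            child_bin /= np.linalg.norm(child_bin)
            grow(p1, child_dir, child_bin, child_d, generation + 1, bid)

    grow(start, np.array([0.0, 0.0, -1.0]), np.array([1.0, 0.0, 0.0]), spec.root_lumen_diameter_mm, 0, None)
    return records


def rasterize_airway_tree(spec: TreeSpec, seed: int = 0) -> tuple[ImageVolume, GroundTruth]:
    """Rasterise a bifurcating airway tree into an ideal HU volume + ground truth.

    Bifurcations are rounded by a sphere of the parent radius at each branch
    point, avoiding creases that would break front propagation.  Deterministic
    for a given seed.
    """
    rng = np.random.default_rng(seed)
    sp = np.asarray(spec.spacing, dtype=float)
    shape = np.asarray(spec.shape, dtype=int)
    if spec.min_lumen_diameter_mm < 2.0 * float(max(sp[0], sp[1])):
        warnings.warn(
            "min lumen diameter below 2x in-plane spacing: terminal branches "
            "may be under-resolved",
            stacklevel=2,
        )
    records = _build_segments(spec, rng)

    phys_lo = -0.5 * sp
    phys_hi = (shape - 0.5) * sp
    # the trachea may protrude through the cranial face (it is capped by the
    # grid); everything else must fit
    for bid, parent, gen, p0, p1, r_l, r_o in records:
        lo = np.minimum(p0, p1) - r_o
        hi = np.maximum(p0, p1) + r_o
        z_ok = hi[2] <= phys_hi[2] or parent is None
        if np.any(lo < phys_lo) or np.any(hi[:2] > phys_hi[:2]) or not z_ok:
            raise ValueError("tree escapes the grid; enlarge shape or shrink the tree")

    primitives = []
    has_children = {parent for _, parent, *_ in records if parent is not None}
    for bid, parent, gen, p0, p1, r_l, r_o in records:
        primitives.append((Capsule(p0, p1, r_o), r_l, r_o))
        if bid in has_children:
            primitives.append((Sphere(p1, r_o), r_l, r_o))

    f_lumen, f_solid = rasterize_solids(tuple(int(n) for n in shape), tuple(sp), primitives)
    values = fractions_to_volume(
        f_lumen, f_solid, sp, spec.hu_lumen, spec.hu_wall, spec.hu_background
    )
    volume = ImageVolume(values=values, spacing=tuple(sp))
    lumen_arr, wall_arr = fractions_to_masks(f_lumen, f_solid, sp)
    lumen_mask = BinaryMask(values=lumen_arr, spacing=tuple(sp))
    wall_mask = BinaryMask(values=wall_arr, spacing=tuple(sp))

    branches: dict[int, Branch] = {}
    lum_d: dict[int, float] = {}
    tot_d: dict[int, float] = {}
    for bid, parent, gen, p0, p1, r_l, r_o in records:
        n_pts = max(2, int(np.ceil(np.linalg.norm(p1 - p0))) + 1)
        branches[bid] = Branch(
            branch_id=bid,
            points=np.linspace(p0, p1, n_pts),
            parent_id=parent,
            generation=gen,
        )
        lum_d[bid] = 2.0 * r_l
        tot_d[bid] = 2.0 * r_o
    for bid, b in branches.items():
        if b.parent_id is not None:
            branches[b.parent_id].child_ids.append(bid)
    tree = CenterlineTree(branches=branches, root_id=0)
    tree.validate()

    gt = GroundTruth(
        lumen_mask=lumen_mask,
        wall_mask=wall_mask,
        trees=[tree],
        lumen_diameters_mm=[lum_d],
        total_diameters_mm=[tot_d],
    )
    return volume, gt
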