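"""Bronchial parameter measurement along branch centrelines.

Each branch is sampled every 0.5 mm along its (smoothed) centreline; at each
sample a plane perpendicular to the local tangent is resampled from the lumen
and wall masks, and area-equivalent radii are derived from the in-plane region
areas.  Per-section areas are averaged per branch (areas are averaged, not the
area of the averaged radius), giving LA, WA, WAP = 100*WA/(WA+LA),
SRWA = sqrt(WA) and the internal perimeter Pi = 2*pi*r_in.  Pi10, the SRWA of
a hypothetical airway of internal perimeter 10 mm, comes from an ordinary
least-squares regression of SRWA on Pi over branches of generations 1-6
(trachea excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import BinaryMask
from .tree import Branch, CenterlineTree, extract_branches, find_trachea_seed, largest_component

__all__ = [
    "CrossSection",
    "BranchMeasurement",
    "ScanSummary",
    "SegmentationScore",
    "sample_centerline",
    "measure_cross_section",
    "aggregate_branch",
    "measure_tree",
    "compute_pi10",
    "summarize_scan",
    "segmentation_metrics",
]


@dataclass
class CrossSection:
    position_mm: np.ndarray
    tangent: np.ndarray
    lumen_radius_mm: float
    outer_radius_mm: float
    valid: bool


@dataclass
class BranchMeasurement:
    branch_id: int
    parent_id: int | None
    generation: int
    length_mm: float
    n_sections: int
    mean_lumen_radius_mm: float
    mean_outer_radius_mm: float
    la_mm2: float
    wa_mm2: float
    wap_pct: float
    srwa_mm: float
    pi_mm: float


@dataclass
class ScanSummary:
    """Per-scan aggregate: generation means, Pi10, TAC, TLV, max generation."""

    mean_la_by_generation: dict[int, float]
    mean_wap_by_generation: dict[int, float]
    pi10_mm: float | None
    tac: int
    tlv_l: float | None
    max_generation: int

    def to_dict(self) -> dict:
        return {
            "mean_la_by_generation": {str(k): v for k, v in self.mean_la_by_generation.items()},
            "mean_wap_by_generation": {str(k): v for k, v in self.mean_wap_by_generation.items()},
            "pi10_mm": self.pi10_mm,
            "tac": self.tac,
            "tlv_l": self.tlv_l,
            "max_generation": self.max_generation,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ScanSummary":
        return cls(
            mean_la_by_generation={int(k): v for k, v in doc["mean_la_by_generation"].items()},
            mean_wap_by_generation={int(k): v for k, v in doc["mean_wap_by_generation"].items()},
            pi10_mm=doc["pi10_mm"],
            tac=doc["tac"],
            tlv_l=doc["tlv_l"],
            max_generation=doc["max_generation"],
        )


@dataclass
class SegmentationScore:
    dice: float
    completeness_pct: float
    leakage_pct: float


def _smooth_polyline(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing with end replication (keeps endpoints stable)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3 or window < 3:
        return pts
    half = window // 2
    padded = np.concatenate([pts[:1].repeat(half, axis=0), pts, pts[-1:].repeat(half, axis=0)])
    kernel = np.ones(window) / window
    out = np.stack([np.convolve(padded[:, i], kernel, mode="valid") for i in range(3)], axis=1)
    # anchor the endpoints so smoothing does not shorten the branch
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def sample_centerline(
    branch: Branch,
    step_mm: float = 0.5,
    exclude_junction_steps: bool = True,
    smooth_window: int = 5,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Arc-length samples ``(position, tangent)`` every ``step_mm`` along a branch.

    Samples run from the branch start in steps of ``step_mm`` up to the branch
    length (a final partial step is excluded).  With
    ``exclude_junction_steps``, samples within one step of a branch point (the
    proximal end if the branch has a parent, the distal end if it has
    children) are dropped; a branch too short to retain any sample yields an
    empty list and is skipped downstream.
    """
    pts = _smooth_polyline(branch.points, window=smooth_window)
    if len(pts) < 2:
        return []
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    length = float(arc[-1])
    if length <= 0:
        return []
    n = int(math.floor(length / step_mm + 1e-9)) + 1
    s_vals = np.arange(n) * step_mm
    if exclude_junction_steps:
        keep = np.ones(n, dtype=bool)
        if branch.parent_id is not None:
            keep &= s_vals >= step_mm - 1e-9
        if branch.child_ids:
            keep &= s_vals <= length - step_mm + 1e-9
        s_vals = s_vals[keep]
    if len(s_vals) == 0:
        return []
    pos = np.stack([np.interp(s_vals, arc, pts[:, i]) for i in range(3)], axis=1)
    # tangents by central differences on the resampled positions
    eps = min(step_mm, length) / 2.0
    fwd = np.stack([np.interp(np.minimum(s_vals + eps, length), arc, pts[:, i]) for i in range(3)], axis=1)
    bwd = np.stack([np.interp(np.maximum(s_vals - eps, 0.0), arc, pts[:, i]) for i in range(3)], axis=1)
    tan = fwd - bwd
    norms = np.linalg.norm(tan, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tan = tan / norms
    return [(pos[i], tan[i]) for i in range(len(s_vals))]


def _plane_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    a = np.zeros(3)
    a[np.argmin(np.abs(t))] = 1.0
    u = np.cross(t, a)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def measure_cross_section(
    lumen: BinaryMask,
    wall: BinaryMask,
    position_mm: np.ndarray,
    tangent: np.ndarray,
    inplane_step_mm: float = 0.25,
    half_extent_mm: float = 10.0,
) -> CrossSection:
    """Area-equivalent lumen/outer radii on a plane perpendicular to the tangent.

    Both masks are resampled bilinearly on a 2D grid (default 0.25 mm pitch),
    thresholded at 0.5, and the connected in-plane region containing the
    centre point is kept.  ``r_in = sqrt(A_lumen/pi)`` and
    ``r_out = sqrt((A_lumen + A_wall)/pi)``.  The section is invalid when the
    centre point does not land inside the lumen region.
    """
    if not lumen.same_grid(wall):
        raise ValueError("lumen and wall masks must share the same grid")
    nt = float(np.linalg.norm(tangent))
    if nt == 0:
        raise ValueError("tangent must be non-zero")
    u, v = _plane_basis(tangent)
    n_half = int(round(half_extent_mm / inplane_step_mm))
    coords_1d = (np.arange(-n_half, n_half + 1)) * inplane_step_mm
    A, B = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    # a small sub-pixel shift keeps sample points off exact voxel gridlines,
    # where bilinear interpolation of a binary mask is exactly at threshold
    eps_u, eps_v = 0.1234 * inplane_step_mm, 0.0567 * inplane_step_mm
    pts = (
        np.asarray(position_mm)[None, None, :]
        + (A[..., None] + eps_u) * u[None, None, :]
        + (B[..., None] + eps_v) * v[None, None, :]
    )
    idx = (pts - np.asarray(lumen.origin)) / np.asarray(lumen.spacing)
    flat = idx.reshape(-1, 3).T

    lum_vals = ndimage.map_coordinates(
        lumen.values.astype(np.float32), flat, order=1, mode="constant", cval=0.0
    ).reshape(A.shape)
    wall_vals = ndimage.map_coordinates(
        wall.values.astype(np.float32), flat, order=1, mode="constant", cval=0.0
    ).reshape(A.shape)

    invalid = CrossSection(
        position_mm=np.asarray(position_mm),
        tangent=np.asarray(tangent),
        lumen_radius_mm=float("nan"),
        outer_radius_mm=float("nan"),
        valid=False,
    )
    center = (n_half, n_half)
    struct = np.ones((3, 3), dtype=bool)

    def region_area(vals: np.ndarray) -> float | None:
        """Partial-volume-aware area of the thresholded region at the centre.

        The hard 0.5 threshold picks the connected region; the interpolated
        mass in a one-pixel fringe around it recovers the sub-pixel boundary
        contribution that thresholding clips.
        """
        binary = vals > 0.5
        if not binary[center]:
            return None
        lab, _ = ndimage.label(binary, structure=struct)
        region = lab == lab[center]
        fringe = ndimage.binary_dilation(region, structure=struct) & ~region
        mass = vals[region].sum() + vals[fringe].sum()
        return float(mass) * inplane_step_mm**2

    area_l = region_area(lum_vals)
    if area_l is None:
        return invalid
    area_t = region_area(np.minimum(lum_vals + wall_vals, 1.0))
    area_t = area_l if area_t is None else max(area_t, area_l)

    r_in = math.sqrt(area_l / math.pi)
    r_out = math.sqrt(area_t / math.pi)
    return CrossSection(
        position_mm=np.asarray(position_mm),
        tangent=np.asarray(tangent),
        lumen_radius_mm=r_in,
        outer_radius_mm=r_out,
        valid=True,
    )


def aggregate_branch(sections: list[CrossSection], branch: Branch) -> BranchMeasurement | None:
    """Average per-section areas into branch-level bronchial parameters.

    Per-section ``LA_i = pi*r_in^2``, ``total_i = pi*r_out^2``,
    ``WA_i = total_i - LA_i`` and ``Pi_i = 2*pi*r_in`` are averaged across
    valid sections; WAP and SRWA derive from the averaged areas.  Returns
    ``None`` when no valid section exists (branch excluded downstream).
    """
    valid = [s for s in sections if s.valid]
    if not valid:
        return None
    r_in = np.array([s.lumen_radius_mm for s in valid])
    r_out = np.array([s.outer_radius_mm for s in valid])
    la_i = math.pi * r_in**2
    tot_i = math.pi * r_out**2
    wa_i = tot_i - la_i
    pi_i = 2.0 * math.pi * r_in
    la = float(la_i.mean())
    wa = float(wa_i.mean())
    wap = 100.0 * wa / (wa + la)
    return BranchMeasurement(
        branch_id=branch.branch_id,
        parent_id=branch.parent_id,
        generation=branch.generation,
        length_mm=branch.length_mm,
        n_sections=len(valid),
        mean_lumen_radius_mm=float(r_in.mean()),
        mean_outer_radius_mm=float(r_out.mean()),
        la_mm2=la,
        wa_mm2=wa,
        wap_pct=wap,
        srwa_mm=math.sqrt(max(wa, 0.0)),
        pi_mm=float(pi_i.mean()),
    )


def measure_tree(
    lumen: BinaryMask,
    wall: BinaryMask,
    tree: CenterlineTree,
    step_mm: float = 0.5,
    inplane_step_mm: float = 0.25,
    half_extent_mm: float = 10.0,
) -> list[BranchMeasurement]:
    """Measure every branch of a tree; branches without valid sections are dropped."""
    out = []
    for bid in tree.topological_order():
        branch = tree.branches[bid]
        samples = sample_centerline(branch, step_mm=step_mm)
        sections = [
            measure_cross_section(
                lumen, wall, pos, tan, inplane_step_mm=inplane_step_mm, half_extent_mm=half_extent_mm
            )
            for pos, tan in samples
        ]
        m = aggregate_branch(sections, branch)
        if m is not None:
            out.append(m)
    return out


def compute_pi10(
    measurements: list[BranchMeasurement], min_generation: int = 1, max_generation: int = 6
) -> float:
    """Pi10 (mm): OLS of SRWA on internal perimeter over generations 1-6.

    The trachea (generation 0) is excluded; Pi10 is the regression prediction
    at Pi = 10 mm.
    """
    sel = [m for m in measurements if min_generation <= m.generation <= max_generation]
    pi = np.array([m.pi_mm for m in sel])
    srwa = np.array([m.srwa_mm for m in sel])
    if len(sel) < 2 or np.ptp(pi) == 0:
        raise ValueError("Pi10 undefined: need >= 2 branches with distinct Pi in generations 1-6")
    a, b = np.polyfit(pi, srwa, 1)
    return float(10.0 * a + b)


def summarize_scan(
    tree: CenterlineTree,
    measurements: list[BranchMeasurement],
    tlv_l: float | None = None,
) -> ScanSummary:
    """Per-generation means of LA and WAP, TAC, Pi10 and the maximum generation.

    Pi10 is reported absent (``None``) when undefined (e.g. a scan without
    generation 1-6 branches).
    """
    if not measurements:
        raise ValueError("no measurements to summarise")
    gens = sorted({m.generation for m in measurements})
    mean_la = {}
    mean_wap = {}
    for g in gens:
        ms = [m for m in measurements if m.generation == g]
        mean_la[g] = float(np.mean([m.la_mm2 for m in ms]))
        mean_wap[g] = float(np.mean([m.wap_pct for m in ms]))
    try:
        pi10 = compute_pi10(measurements)
    except ValueError:
        pi10 = None
    return ScanSummary(
        mean_la_by_generation=mean_la,
        mean_wap_by_generation=mean_wap,
        pi10_mm=pi10,
        tac=len(measurements),
        tlv_l=tlv_l,
        max_generation=max(gens),
    )


def _centerline_points_inside(tree: CenterlineTree, mask: BinaryMask, step_mm: float = 0.5):
    """(n_inside, n_total) of resampled centreline points falling in the mask."""
    inside = 0
    total = 0
    shape = np.asarray(mask.shape)
    for b in tree.branches.values():
        samples = sample_centerline(b, step_mm=step_mm, exclude_junction_steps=False)
        for pos, _ in samples:
            idx = np.round(mask.world_to_index(pos)).astype(int)
            total += 1
            if np.all(idx >= 0) and np.all(idx < shape) and mask.values[tuple(idx)] > 0:
                inside += 1
    return inside, total


def segmentation_metrics(
    pred: BinaryMask,
    gt: BinaryMask,
    gt_centerline: CenterlineTree,
    pred_centerline: CenterlineTree | None = None,
) -> SegmentationScore:
    """Dice overlap plus centreline completeness and leakage.

    Completeness: percentage of ground-truth centreline points (0.5 mm
    resampling) inside the prediction.  Leakage: percentage of the predicted
    mask's own centreline (front propagation on ``pred``) outside the ground
    truth, i.e. false-positive centreline length.
    """
    p = pred.values > 0
    g = gt.values > 0
    if not p.any() or not g.any():
        raise ValueError("empty prediction or ground truth")
    dice = 2.0 * float(np.logical_and(p, g).sum()) / float(p.sum() + g.sum())

    inside, total = _centerline_points_inside(gt_centerline, pred)
    completeness = 100.0 * inside / total if total else 0.0

    if pred_centerline is None:
        clean = largest_component(pred)
        seed = find_trachea_seed(clean)
        pred_centerline = extract_branches(clean, seed)
    inside_gt, total_pred = _centerline_points_inside(pred_centerline, gt)
    leakage = 100.0 * (total_pred - inside_gt) / total_pred if total_pred else 0.0
    return SegmentationScore(dice=dice, completeness_pct=completeness, leakage_pct=leakage)
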