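"""Triangulated initial surfaces from binary masks.

The airway-wall graph cut needs a closed starting surface on the lumen
boundary: a marching-cubes isosurface at the 0.5 level of the (zero-padded)
mask, Laplacian-smoothed, with outward vertex normals.  An optional midpoint
subdivision densifies coarse meshes so that enough columns sample small
airways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .image import BinaryMask

__all__ = ["SurfaceMesh", "extract_initial_surface"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (V, 3) mm
    normals: np.ndarray  # (V, 3) outward unit normals
    faces: np.ndarray  # (F, 3) vertex indices

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) unique undirected edges."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @property
    def mean_edge_length(self) -> float:
        e = self.edges
        return float(np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean())


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    fn = np.cross(v1 - v0, v2 - v0)  # area-weighted
    vn = np.zeros_like(vertices)
    for i in range(3):
        np.add.at(vn, faces[:, i], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vn / norms


def _laplacian_smooth(vertices: np.ndarray, faces: np.ndarray, iterations: int, lam: float) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    src = np.concatenate([e[:, 0], e[:, 1]])
    dst = np.concatenate([e[:, 1], e[:, 0]])
    deg = np.bincount(src, minlength=len(vertices)).astype(float)
    deg[deg == 0] = 1.0
    v = vertices.copy()
    for _ in range(iterations):
        acc = np.zeros_like(v)
        np.add.at(acc, src, v[dst])
        v = v + lam * (acc / deg[:, None] - v)
    return v


def _subdivide(vertices: np.ndarray, faces: np.ndarray):
    """Midpoint (1-to-4) subdivision; preserves watertightness."""
    edge_mid: dict[tuple[int, int], int] = {}
    verts = [vertices]
    next_id = len(vertices)

    def mid(a: int, b: int) -> int:
        nonlocal next_id
        key = (a, b) if a < b else (b, a)
        if key not in edge_mid:
            edge_mid[key] = next_id
            verts.append((vertices[a] + vertices[b])[None, :] / 2.0)
            next_id += 1
        return edge_mid[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces.extend([(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)])
    return np.concatenate(verts, axis=0), np.asarray(new_faces, dtype=np.int64)


def extract_initial_surface(
    mask: BinaryMask,
    smooth_iterations: int = 10,
    smooth_lambda: float = 0.5,
    target_edge_mm: float | None = None,
) -> SurfaceMesh:
    """Closed, smoothed isosurface of a single-component mask with outward normals.

    ``target_edge_mm`` triggers midpoint subdivision (at most twice) while the
    mean edge length exceeds the target, so small structures still receive a
    dense column set.
    """
    if mask.n_foreground == 0:
        raise ValueError("empty mask")
    _, n_comp = ndimage.label(mask.values, structure=_STRUCT_26)
    if n_comp != 1:
        raise ValueError(
            f"mask has {n_comp} connected components; take the largest component first"
        )
    padded = np.pad(mask.values.astype(np.float32), 1)
    verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    verts = verts - np.asarray(mask.spacing) + np.asarray(mask.origin)
    verts = _laplacian_smooth(verts, faces, smooth_iterations, smooth_lambda)

    if target_edge_mm is not None:
        for _ in range(2):
            mesh_tmp = SurfaceMesh(vertices=verts, normals=np.zeros_like(verts), faces=faces)
            if mesh_tmp.mean_edge_length <= target_edge_mm:
                break
            verts, faces = _subdivide(verts, faces)

    normals = _vertex_normals(verts, faces)
    # orient outward: mask value should decrease along the normal
    h = 0.5 * float(min(mask.spacing))
    vals = mask.values.astype(np.float32)
    sp = np.asarray(mask.spacing)
    org = np.asarray(mask.origin)

    def sample(points: np.ndarray) -> np.ndarray:
        idx = ((points - org) / sp).T
        return ndimage.map_coordinates(vals, idx, order=1, mode="constant", cval=0.0)

    outward = sample(verts + h * normals) < sample(verts - h * normals)
    if np.mean(outward) < 0.5:
        normals = -normals
        faces = faces[:, ::-1]
    return SurfaceMesh(vertices=verts, normals=normals, faces=faces)
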