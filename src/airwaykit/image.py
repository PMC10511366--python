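"""Volumetric image containers and medical-image I/O.

Volumes are indexed ``(x, y, z)`` with ``z`` the cranio-caudal axis (cranial
end at the largest z index).  Physical positions are computed as
``voxel_index * spacing + origin`` with 0-based indices; direction cosines are
assumed axis-aligned, and a non-identity orientation in a file raises a
warning rather than being resampled.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "export_results",
    "BRANCH_TABLE_COLUMNS",
]

_SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class ImageVolume:
    """A 3D scalar grid (attenuation in HU) with voxel spacing and origin in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.values.ndim}D (non-3D)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 positive components")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical mm coordinates."""
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Map physical mm coordinates to fractional voxel indices."""
        return (np.asarray(pos, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "ImageVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class BinaryMask(ImageVolume):
    """A {0,1} voxel mask sharing the grid of the volume it annotates."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.values.ndim}D (non-3D)")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.values = self.values.astype(np.uint8)
        super().__post_init__()

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    def foreground_indices(self) -> np.ndarray:
        """(N, 3) integer indices of foreground voxels."""
        return np.argwhere(self.values > 0)


def _check_extension(path: str) -> None:
    if not any(path.endswith(ext) for ext in _SUPPORTED_EXTENSIONS):
        raise ValueError(
            f"unsupported extension for {path!r}; expected one of {_SUPPORTED_EXTENSIONS}"
        )


def read_volume(path: str) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Returns an :class:`ImageVolume` with ``(x, y, z)`` axis order.  HU values
    are passed through unchanged.
    """
    _check_extension(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = sitk.ReadImage(path)
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D image, got non-3D ({img.GetDimension()}D)")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3)):
        warnings.warn(
            "non-identity direction cosines; axes are treated as axis-aligned",
            stacklevel=2,
        )
    # SimpleITK arrays come back (z, y, x); transpose to (x, y, z).
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(values=values, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def read_mask(path: str) -> BinaryMask:
    """Read a binary mask; any non-zero voxel is foreground."""
    vol = read_volume(path)
    return BinaryMask(values=(vol.values > 0).astype(np.uint8), spacing=vol.spacing, origin=vol.origin)


def write_volume(volume: ImageVolume, path: str) -> None:
    """Write a volume or mask; the format follows the file extension."""
    _check_extension(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    values = volume.values
    if isinstance(volume, BinaryMask):
        values = values.astype(np.uint8)
    else:
        values = values.astype(np.float32)
    img = sitk.GetImageFromArray(values.transpose(2, 1, 0))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, path)


BRANCH_TABLE_COLUMNS = [
    "branch_id",
    "parent_id",
    "generation",
    "length_mm",
    "mean_lumen_radius_mm",
    "mean_outer_radius_mm",
    "LA_mm2",
    "WA_mm2",
    "WAP_pct",
    "SRWA_mm",
    "Pi_mm",
    "n_cross_sections",
]


def export_results(measurements, summary, out_dir: str) -> dict[str, str]:
    """Write the per-branch CSV table and the per-scan JSON summary.

    ``measurements`` is a list of :class:`airwaykit.measure.BranchMeasurement`;
    ``summary`` an :class:`airwaykit.measure.ScanSummary`.  Returns the paths
    written.  Units are fixed by the column names (mm, mm^2, %).
    """
    if not measurements:
        raise ValueError("no branch measurements to export")
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for m in measurements:
        rows.append(
            {
                "branch_id": m.branch_id,
                "parent_id": -1 if m.parent_id is None else m.parent_id,
                "generation": m.generation,
                "length_mm": m.length_mm,
                "mean_lumen_radius_mm": m.mean_lumen_radius_mm,
                "mean_outer_radius_mm": m.mean_outer_radius_mm,
                "LA_mm2": m.la_mm2,
                "WA_mm2": m.wa_mm2,
                "WAP_pct": m.wap_pct,
                "SRWA_mm": m.srwa_mm,
                "Pi_mm": m.pi_mm,
                "n_cross_sections": m.n_sections,
            }
        )
    table_path = os.path.join(out_dir, "branches.csv")
    pd.DataFrame(rows, columns=BRANCH_TABLE_COLUMNS).to_csv(table_path, index=False)

    summary_path = os.path.join(out_dir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
    return {"branch_table": table_path, "summary": summary_path}
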