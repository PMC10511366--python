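"""Low-dose scanner model: isotropic Gaussian PSF blur plus additive noise.

The point-spread function is parameterised by its full width at half maximum
(FWHM, mm); after blurring, white Gaussian noise (SD in HU) is added, a
surrogate for the noise level of a 120 kVp / 20 mAs class screening protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from ..image import ImageVolume
from .treegen import TreeSpec, rasterize_airway_tree

__all__ = ["ScannerModel", "apply_scanner_model", "simulate_repeat_pair"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ScannerModel:
    psf_fwhm_mm: float = 0.8
    noise_sd_hu: float = 25.0
    noise_type: str = "gaussian"

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0:
            raise ValueError("PSF FWHM must be >= 0")
        if self.noise_sd_hu < 0:
            raise ValueError("noise SD must be >= 0")
        if self.noise_type != "gaussian":
            raise ValueError("only gaussian noise is supported")


def apply_scanner_model(ideal: ImageVolume, model: ScannerModel, seed: int = 0) -> ImageVolume:
    """Blur with the PSF then add voxelwise Gaussian noise (deterministic per seed)."""
    values = np.asarray(ideal.values, dtype=float)
    if model.psf_fwhm_mm > 0:
        sigma_vox = model.psf_fwhm_mm * _FWHM_TO_SIGMA / np.asarray(ideal.spacing)
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if model.noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, model.noise_sd_hu, size=values.shape)
    return ImageVolume(values=values, spacing=ideal.spacing, origin=ideal.origin)


def simulate_repeat_pair(
    spec: TreeSpec,
    model: ScannerModel,
    inflation_factor: float = 1.0,
    seeds: tuple[int, int] = (0, 1),
    geometry_seed: int = 0,
):
    """Two scans of the same airway tree at different inspiration levels.

    Scan 2 uses the same tree geometry (same geometry seed) with all linear
    dimensions scaled by ``inflation_factor ** (1/3)`` and independent noise.
    The lung-volume surrogate (TLV, litres) is the lumen volume of each scan,
    so TLV2 / TLV1 equals the inflation factor up to rasterisation error.

    Returns ``(scan1, scan2, (gt1, gt2), (tlv1, tlv2))``.
    """
    if inflation_factor <= 0:
        raise ValueError("inflation factor must be > 0")
    f = inflation_factor ** (1.0 / 3.0)
    spec2 = replace(
        spec,
        root_lumen_diameter_mm=spec.root_lumen_diameter_mm * f,
        min_lumen_diameter_mm=spec.min_lumen_diameter_mm * f,
    )
    ideal1, gt1 = rasterize_airway_tree(spec, seed=geometry_seed)
    ideal2, gt2 = rasterize_airway_tree(spec2, seed=geometry_seed)
    scan1 = apply_scanner_model(ideal1, model, seed=seeds[0])
    scan2 = apply_scanner_model(ideal2, model, seed=seeds[1])
    litres = 1e-6  # mm^3 -> L
    tlv1 = gt1.lumen_mask.n_foreground * gt1.lumen_mask.voxel_volume * litres
    tlv2 = gt2.lumen_mask.n_foreground * gt2.lumen_mask.voxel_volume * litres
    return scan1, scan2, (gt1, gt2), (tlv1, tlv2)
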