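import numpy as np
import pytest

from airwaykit.synthetic import TreeSpec, rasterize_airway_tree
from airwaykit.tree import extract_branches, find_trachea_seed, largest_component


@pytest.fixture(scope="session")
def gen2_tree():
    """Noise-free generation-2 airway tree volume with ground truth."""
    spec = TreeSpec()
    volume, gt = rasterize_airway_tree(spec, seed=0)
    return spec, volume, gt


@pytest.fixture(scope="session")
def gen2_extracted(gen2_tree):
    """Front-propagation tree recovered from the generation-2 lumen mask."""
    _, _, gt = gen2_tree
    mask = largest_component(gt.lumen_mask)
    seed = find_trachea_seed(mask)
    return mask, extract_branches(mask, seed)


def make_cylinder_mask(radius_vox=6, length_vox=40, pad=4, spacing=(1.0, 1.0, 1.0)):
    """Axis-aligned (z) digital cylinder mask."""
    from airwaykit.image import BinaryMask

    n_xy = 2 * (radius_vox + pad) + 1
    c = radius_vox + pad
    x, y = np.meshgrid(np.arange(n_xy), np.arange(n_xy), indexing="ij")
    disk = (x - c) ** 2 + (y - c) ** 2 <= radius_vox**2
    vals = np.zeros((n_xy, n_xy, length_vox + 2 * pad), dtype=np.uint8)
    vals[:, :, pad : pad + length_vox] = disk[:, :, None]
    return BinaryMask(values=vals, spacing=spacing)
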