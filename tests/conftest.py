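import numpy as np
import pytest

from airwaymorph import io_cli, phantom
from airwaymorph.core import AirwayMask


def make_tube_mask(radius=8.0, length=60.0, spacing=0.5, margin=3.0):
    """Voxelized circular tube spanning exactly [0, length] with boundary
    planes at its ends."""
    n = int(np.ceil(2 * (radius + margin) / spacing))
    c = (np.arange(n) + 0.5) * spacing - (radius + margin)
    zc = np.arange(spacing / 2, length, spacing)
    X, Y = np.meshgrid(c, c, indexing="ij")
    circ = (X**2 + Y**2) <= radius**2
    data = np.repeat(circ[:, :, None], len(zc), axis=2)
    return AirwayMask(data, (spacing,) * 3, (c[0], c[0], zc[0]),
                      z_top=length, z_bottom=0.0)


def make_sphere_mask(radius=6.0, spacing=0.5, margin=3.0):
    n = int(np.ceil(2 * (radius + margin) / spacing))
    c = (np.arange(n) + 0.5) * spacing - (radius + margin)
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    data = X**2 + Y**2 + Z**2 <= radius**2
    return AirwayMask(data, (spacing,) * 3, (c[0],) * 3)


def rasterize_reference_lumen(spec, volume):
    """Independent rasterization of the analytic lumen, cropped to the
    boundary slab — the ground-truth voxel set for Dice comparisons."""
    geo = phantom._Geometry(spec)
    x = volume.axis_coords(0)
    y = volume.axis_coords(1)
    z = volume.axis_coords(2)
    lumen = phantom._rasterize_lumen(spec, geo, x, y, z)
    in_slab = (z >= 0.0) & (z <= spec.axis_length)
    return lumen & in_slab[None, None, :]


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom (volume, landmarks, truth)."""
    spec = phantom.default_spec(noise_sd=0.0)
    vol, lm, truth = phantom.make_phantom(spec, seed=1)
    return spec, vol, lm, truth


@pytest.fixture(scope="session")
def measured_phantom(clean_phantom):
    """End-to-end measurement of the noise-free default phantom."""
    _, vol, lm, truth = clean_phantom
    records, mask, partition = io_cli.measure_scan(vol, lm)
    return records, mask, partition, truth
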