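import numpy as np
import pytest

from femorph.imaging import RegionMasks, extract_stack
from femorph.phantom import constant_spec, generate_phantom, trumpet_spec


@pytest.fixture(scope="session")
def trumpet():
    """Noise-free 50-slice trumpet phantom: (spec, stack, ground_truth)."""
    spec = trumpet_spec(n_slices=50)
    stack, gt = generate_phantom(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def trumpet_masks(trumpet):
    """Extracted masks of the trumpet phantom (all slices accepted)."""
    _, stack, _ = trumpet
    masks, flags = extract_stack(stack)
    assert flags == []
    return masks


@pytest.fixture(scope="session")
def big_ring():
    """Large constant circular annulus (generous geometry): (spec, stack, gt)."""
    spec = constant_spec(inner_mm=25.0, outer_mm=33.0, n_slices=2)
    stack, gt = generate_phantom(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def disk_masks():
    """Disk medullary mask of radius 50 px inside a thin annulus, 240x240."""
    yy, xx = np.mgrid[0:240, 0:240]
    r2 = (xx - 119.5) ** 2 + (yy - 119.5) ** 2
    medullary = r2 <= 50**2
    overall = r2 <= 55**2
    return RegionMasks(
        overall=overall,
        cortical=overall & ~medullary,
        medullary=medullary,
        slice_index=0,
    )
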