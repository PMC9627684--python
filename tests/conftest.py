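import numpy as np
import pytest

from upvs import (apply_threshold, rasterize_phantom, tube_spec, y_spec)
from upvs.skeleton import Skeleton


def brute_force_neighbor_counts(mask):
    """Independent 26-neighbour count: explicit triple loop over offsets."""
    nz, ny, nx = mask.shape
    counts = {}
    for z, y, x in np.argwhere(mask):
        c = 0
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == dy == dx == 0:
                        continue
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and mask[zz, yy, xx]:
                        c += 1
        counts[(int(z), int(y), int(x))] = c
    return counts


def skeleton_from_coords(coords, shape, spacing=(1.0, 1.0, 1.0)):
    """Build a Skeleton directly from voxel coordinates (radius = 1 everywhere)."""
    mask = np.zeros(shape, bool)
    for c in coords:
        mask[tuple(c)] = True
    return Skeleton(mask=mask, radius=mask.astype(float), spacing=spacing)


@pytest.fixture(scope="session")
def tube_vessels():
    vol, roi, truth = rasterize_phantom(tube_spec())
    return apply_threshold(vol, roi), truth


@pytest.fixture(scope="session")
def y_vessels():
    vol, roi, truth = rasterize_phantom(y_spec())
    return apply_threshold(vol, roi), truth
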