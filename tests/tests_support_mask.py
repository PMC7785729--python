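"""Shared helper: synthetic ellipsoidal masks for voxel-level tests."""

import numpy as np

from yokedbml.voxel import VolumeMask


def ellipsoid_mask(n_voxels: int, shape, voxel_mm: float = 2.0) -> VolumeMask:
    grid = np.indices(shape).reshape(3, -1).T
    center = (np.array(shape) - 1) / 2
    d = (((grid - center) / (np.array(shape) / 2)) ** 2).sum(axis=1)
    sel = np.argsort(d)[:n_voxels]
    data = np.zeros(shape, dtype=bool)
    data[grid[sel, 0], grid[sel, 1], grid[sel, 2]] = True
    return VolumeMask(data, np.diag([voxel_mm] * 3 + [1.0]))
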