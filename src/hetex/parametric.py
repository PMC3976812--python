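"""Voxel-wise parametric heterogeneity imaging.

A cube of odd edge length slides over the volume; at each interior voxel the
cube's voxels are treated as a delineated VOI, redigitized with their own
min-max range into a small number of levels (27 voxels cannot meaningfully
populate 64 bins, so the per-cube default is 8), and a single named index is
computed and stored at the center voxel. Edge voxels, whose cube would leave
the grid, stay undefined. Larger cubes average over more voxels and hence
produce smoother, lower-resolution maps.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import HetexConfig
from .features import FEATURE_REGISTRY, FeatureContext
from .volume_io import ImageVolume, VoiMask

__all__ = ["ParametricVolume", "parametric_map"]


@dataclasses.dataclass
class ParametricVolume:
    """A per-voxel heterogeneity index map with its validity mask."""

    values: np.ndarray            # (z, y, x) float, 0 where undefined
    defined: np.ndarray           # (z, y, x) bool
    feature_name: str
    cube_edge: int
    spacing_mm: tuple[float, float, float]


def parametric_map(vol: ImageVolume, feature_name: str, cube_edge: int = 3,
                   L: int = 8, mask: VoiMask | None = None,
                   config: HetexConfig | None = None) -> ParametricVolume:
    """Compute the named index on a sliding cube around every interior voxel.

    Parameters
    ----------
    vol : ImageVolume
        Source volume.
    feature_name : str
        A registered index name (for example ``"COOC_contrast"``).
    cube_edge : int
        Odd cube edge length, >= 3.
    L : int
        Per-cube redigitization levels (local min-max binning).
    mask : VoiMask, optional
        Restricts the map to cube centers inside the mask.
    """
    if feature_name not in FEATURE_REGISTRY:
        raise KeyError(f"unknown feature {feature_name!r}; "
                       f"known: {sorted(FEATURE_REGISTRY)}")
    if cube_edge < 3 or cube_edge % 2 == 0:
        raise ValueError("cube_edge must be an odd integer >= 3")
    if any(n < cube_edge for n in vol.shape):
        raise ValueError(f"volume {vol.shape} smaller than cube {cube_edge}")
    if mask is not None:
        mask.check_aligned(vol)

    cfg = (config or HetexConfig()).replace(levels=L)
    h = cube_edge // 2
    nz, ny, nx = vol.shape
    values = np.zeros(vol.shape)
    defined = np.zeros(vol.shape, dtype=bool)
    cube_mask = VoiMask(np.ones((cube_edge,) * 3, dtype=bool))

    for z in range(h, nz - h):
        for y in range(h, ny - h):
            for x in range(h, nx - h):
                if mask is not None and not mask.mask[z, y, x]:
                    continue
                cube = vol.voxels[z - h:z + h + 1, y - h:y + h + 1,
                                  x - h:x + h + 1]
                sub = ImageVolume(cube, vol.spacing_mm,
                                  intensity_units=vol.intensity_units)
                ctx = FeatureContext(sub, cube_mask, cfg)
                values[z, y, x] = ctx.get(feature_name)
                defined[z, y, x] = True
    return ParametricVolume(values, defined, feature_name, cube_edge,
                            vol.spacing_mm)
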