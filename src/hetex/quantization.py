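"""Intensity redigitization.

VOI intensities are quantized ("redigitized") into L discrete gray levels
before any parent matrix is built. Binning is equal-width over the VOI's own
[vmin, vmax] range, so the levels are invariant to positive affine rescaling
of the intensities.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volume_io import ImageVolume, VoiMask

__all__ = ["QuantizedVoi", "redigitize", "quantize_values"]

DEFAULT_LEVELS = 64


@dataclasses.dataclass
class QuantizedVoi:
    """VOI voxels with integer gray levels 1..L.

    coords are (z, y, x) integer triples in volume index space; levels is the
    parallel list of gray levels.
    """

    coords: np.ndarray      # (N, 3) int
    levels: np.ndarray      # (N,) int in 1..L
    L: int
    vmin: float
    vmax: float
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.intp).reshape(-1, 3)
        self.levels = np.asarray(self.levels, dtype=np.intp).reshape(-1)
        if len(self.coords) != len(self.levels):
            raise ValueError("coords and levels must be parallel")
        if self.levels.size and (self.levels.min() < 1 or self.levels.max() > self.L):
            raise ValueError("levels outside 1..L")
        if self.vmin > self.vmax:
            raise ValueError("vmin > vmax")

    @property
    def n_voxels(self) -> int:
        return len(self.levels)

    def dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (grid, offset): a cropped dense level array, 0 outside VOI.

        ``grid[c - offset] == level`` for each VOI coordinate c.
        """
        lo = self.coords.min(axis=0)
        hi = self.coords.max(axis=0)
        grid = np.zeros(tuple(hi - lo + 1), dtype=np.intp)
        idx = self.coords - lo
        grid[idx[:, 0], idx[:, 1], idx[:, 2]] = self.levels
        return grid, lo


def quantize_values(values: np.ndarray, L: int) -> tuple[np.ndarray, float, float]:
    """Equal-width quantization of raw values into integer levels 1..L.

    level(v) = 1 + floor((v - vmin) / (vmax - vmin) * L), clamped to L at
    v = vmax. A constant input maps everything to level 1.
    """
    values = np.asarray(values, dtype=float)
    vmin = float(values.min())
    vmax = float(values.max())
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.intp), vmin, vmax
    lev = 1 + np.floor((values - vmin) / (vmax - vmin) * L).astype(np.intp)
    np.clip(lev, 1, L, out=lev)
    return lev, vmin, vmax


def redigitize(vol: ImageVolume, mask: VoiMask, L: int = DEFAULT_LEVELS) -> QuantizedVoi:
    """Redigitize the VOI intensities of ``vol`` into L gray levels.

    Raises
    ------
    ValueError
        If L < 2 or the mask has fewer than 2 true voxels.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    mask.check_aligned(vol)
    coords = np.argwhere(mask.mask)
    if len(coords) < 2:
        raise ValueError("mask must contain at least 2 voxels")
    values = vol.voxels[mask.mask]
    levels, vmin, vmax = quantize_values(values, L)
    return QuantizedVoi(coords, levels, L, vmin, vmax, vol.spacing_mm)
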