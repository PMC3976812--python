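"""Semiautomatic tumor delineation.

Two methods: threshold-based region growing (the 26-connected component of
supra-threshold voxels containing a seed; with an SUV threshold of 2.5 this
reproduces the common outer-contour convention for FDG-avid tumors) and
fuzzy C-means clustering of intensities, whose highest-centroid cluster is
taken as tumor. A caller-supplied ROI restricts either method's scope,
standing in for a physician's manual pre-outline that excludes benign hot
tissue.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .volume_io import ImageVolume, VoiMask

__all__ = ["SegmentationResult", "region_grow", "fuzzy_cmeans"]


@dataclasses.dataclass
class SegmentationResult:
    mask: VoiMask
    method: str
    params: dict
    n_iterations: int = 0


def region_grow(vol: ImageVolume, seed: tuple[int, int, int],
                threshold: float, roi: VoiMask | None = None) -> SegmentationResult:
    """26-connected region growing from ``seed`` over {v : vol(v) >= threshold}.

    Raises
    ------
    ValueError
        ``"seed below threshold"`` when the seed voxel itself fails the test.
    IndexError
        When the seed lies outside the grid.
    """
    seed = tuple(int(c) for c in seed)
    if any(not 0 <= c < n for c, n in zip(seed, vol.shape)):
        raise IndexError(f"seed {seed} outside grid {vol.shape}")
    if vol.voxels[seed] < threshold:
        raise ValueError("seed below threshold")
    above = vol.voxels >= threshold
    if roi is not None:
        roi.check_aligned(vol)
        above &= roi.mask
    structure = ndimage.generate_binary_structure(3, 3)
    labeled, _ = ndimage.label(above, structure=structure)
    mask = labeled == labeled[seed]
    return SegmentationResult(VoiMask(mask), "region_growing",
                              {"seed": seed, "threshold": float(threshold)})


def fuzzy_cmeans(vol: ImageVolume, roi: VoiMask, c: int = 2, m: float = 2.0,
                 tol: float = 1e-5, max_iter: int = 200,
                 seed: int = 0) -> SegmentationResult:
    """Fuzzy C-means on the intensities within ``roi``.

    Centroids are initialized from intensity quantiles, so the result is
    deterministic; ``seed`` is accepted for interface stability and optional
    future jitter but does not affect the default behavior. Convergence is
    declared when the maximum membership change falls below ``tol``. The
    output mask contains the voxels whose maximal membership belongs to the
    highest-centroid cluster.

    Raises
    ------
    ValueError
        ``"degenerate intensities"`` when the ROI has fewer than ``c``
        distinct values.
    """
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    roi.check_aligned(vol)
    x = vol.voxels[roi.mask].astype(float)
    if len(np.unique(x)) < c:
        raise ValueError("degenerate intensities (fewer distinct values than clusters)")

    centroids = np.quantile(x, (np.arange(c) + 0.5) / c)
    if len(np.unique(centroids)) < c:
        # heavily imbalanced intensities: quantiles collapse; spread instead
        centroids = np.linspace(x.min(), x.max(), c)
    u = _memberships(x, centroids, m)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        um = u ** m
        centroids = (um @ x) / um.sum(axis=1)
        u_new = _memberships(x, centroids, m)
        change = float(np.abs(u_new - u).max())
        u = u_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"fuzzy C-means did not converge in {max_iter} iterations;"
                      " returning best iterate", RuntimeWarning, stacklevel=2)

    tumor = int(np.argmax(centroids))
    hard = np.argmax(u, axis=0) == tumor
    mask = np.zeros(vol.shape, dtype=bool)
    mask[roi.mask] = hard
    return SegmentationResult(
        VoiMask(mask), "fuzzy_cmeans",
        {"c": c, "m": m, "tol": tol, "seed": seed,
         "centroids": centroids.tolist()},
        n_iterations=n_iter)


def _memberships(x: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """FCM membership update; rows are clusters. Memberships sum to 1 per
    point; a point coinciding with a centroid gets full membership there."""
    d = np.abs(x[None, :] - centroids[:, None])
    zero = d < 1e-300
    if zero.any():
        u = np.zeros_like(d)
        cols = zero.any(axis=0)
        u[:, cols] = zero[:, cols] / zero[:, cols].sum(axis=0)
        if (~cols).any():
            u[:, ~cols] = _memberships(x[~cols], centroids, m)
        return u
    power = 2.0 / (m - 1.0)
    inv = d ** -power
    return inv / inv.sum(axis=0)


def fcm_objective(x: np.ndarray, u: np.ndarray, centroids: np.ndarray,
                  m: float) -> float:
    """The FCM objective J = sum_ik u_ik^m d_ik^2 (exposed for testing)."""
    d2 = (x[None, :] - centroids[:, None]) ** 2
    return float(((u ** m) * d2).sum())
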