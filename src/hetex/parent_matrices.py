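"""Parent-matrix builders.

Each tumor-wise heterogeneity index family is computed from an intermediate
"parent" matrix derived from the quantized VOI: gray-level co-occurrence,
voxel-alignment (run length), intensity size-zone, neighborhood intensity
difference (NGTDM), neighborhood gray-level dependence (NGLDM), texture
spectrum, texture feature coding (TFC), and TFC co-occurrence.

Conventions (documented limitations included):

* 3D pairing and runs use the 13 unique direction vectors of the
  26-neighborhood (modulo sign); co-occurrence accumulates both orders, so
  the matrix is symmetric by construction.
* Zones and neighborhoods use 26-connectivity; all neighborhoods are taken
  in index space, ignoring anisotropic spacing.
* Only voxels inside the VOI contribute; geometry outside the mask never
  enters a pair, run, zone or neighborhood.
* Texture spectrum and TFC are 2D constructs and are computed slice-wise.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .quantization import QuantizedVoi

__all__ = [
    "DIRECTIONS_13",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "SizeZoneMatrix",
    "NgtdmVectors",
    "NgldmMatrix",
    "TextureSpectrum",
    "TfcImage",
    "cooccurrence",
    "voxel_alignment",
    "size_zone",
    "ngtdm",
    "ngldm",
    "texture_spectrum",
    "tfc",
    "tfc_cooccurrence",
]

# The 13 unique 3D directions: 26-neighborhood offsets modulo sign, first
# nonzero component positive.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13

_OFFSETS_26 = [d for d in DIRECTIONS_13] + [tuple(-c for c in d) for d in DIRECTIONS_13]


def _pair_slices(shape, offset):
    """Complementary slice tuples (center, neighbor) for a lattice offset."""
    src, dst = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# Co-occurrence
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CooccurrenceMatrix:
    """Symmetric joint probability of level pairs at a fixed distance.

    ``level_values[i]`` is the numeric value attached to matrix row i when
    computing moment-based indices: the raw gray level for the plain matrix,
    or the standardized (zero-mean, unit-variance under the marginal) level
    for the normalized variant. ``degenerate`` marks a zero-variance marginal
    in the normalized case.
    """

    p: np.ndarray                 # (K, K), sums to 1
    n_pairs: int
    level_values: np.ndarray      # (K,)
    normalized: bool = False
    degenerate: bool = False


def _cooccurrence_from_grid(grid: np.ndarray, n_levels: int, distance: int,
                            directions) -> tuple[np.ndarray, int]:
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for d in directions:
        offset = tuple(int(c) * distance for c in d)
        if any(abs(o) >= n for o, n in zip(offset, grid.shape)):
            continue
        src, dst = _pair_slices(grid.shape, offset)
        a = grid[src].ravel()
        b = grid[dst].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        idx = (a[ok] - 1) * n_levels + (b[ok] - 1)
        counts += np.bincount(idx, minlength=n_levels * n_levels).reshape(
            n_levels, n_levels)
    counts = counts + counts.T  # both orders of every unordered pair
    return counts, int(counts.sum())


def cooccurrence(q: QuantizedVoi, distance: int = 1, normalized: bool = False,
                 directions=None) -> CooccurrenceMatrix:
    """Build the gray-level co-occurrence matrix pooled over 13 directions.

    With ``normalized=True`` the level values attached to the matrix are
    standardized to zero mean and unit variance under the marginal
    distribution, which is what the normalized-family indices consume.

    Raises
    ------
    ValueError
        ``"VOI too small for distance"`` when no in-VOI pair exists.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    grid, _ = q.dense()
    dirs = DIRECTIONS_13 if directions is None else list(directions)
    counts, n_pairs = _cooccurrence_from_grid(grid, q.L, distance, dirs)
    if n_pairs == 0:
        raise ValueError("VOI too small for distance")
    p = counts / n_pairs
    values = np.arange(1, q.L + 1, dtype=float)
    degenerate = False
    if normalized:
        marg = p.sum(axis=1)
        mu = float(marg @ values)
        var = float(marg @ (values - mu) ** 2)
        if var > 0:
            values = (values - mu) / np.sqrt(var)
        else:
            values = np.zeros_like(values)
            degenerate = True
    return CooccurrenceMatrix(p, n_pairs, values, normalized, degenerate)


# ---------------------------------------------------------------------------
# Voxel alignment (run length)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunLengthMatrix:
    """Run counts r(level, run_length), pooled over directions.

    Conservation: sum over r(i, j) * j equals n_voxels * n_directions.
    """

    r: np.ndarray                 # (L, Rmax) int
    n_runs: int
    n_voxels: int
    n_directions: int


def _runs_along(coords: np.ndarray, levels: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """Levels and lengths of maximal same-level collinear segments along d."""
    d = np.asarray(d, dtype=np.intp)
    k = int(np.flatnonzero(d)[0])  # first nonzero component is +1 by convention
    t = coords[:, k]
    base = coords - t[:, None] * d
    order = np.lexsort((t, base[:, 2], base[:, 1], base[:, 0]))
    tt = t[order]
    bb = base[order]
    ll = levels[order]
    new_run = np.ones(len(tt), dtype=bool)
    if len(tt) > 1:
        same_line = (bb[1:] == bb[:-1]).all(axis=1)
        contiguous = tt[1:] == tt[:-1] + 1
        same_level = ll[1:] == ll[:-1]
        new_run[1:] = ~(same_line & contiguous & same_level)
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, len(tt)))
    return ll[starts], lengths


def voxel_alignment(q: QuantizedVoi, directions=None) -> RunLengthMatrix:
    """Build the run-length (voxel-alignment) matrix pooled over 13 directions."""
    if q.n_voxels == 0:
        raise ValueError("empty VOI")
    dirs = DIRECTIONS_13 if directions is None else list(directions)
    all_levels, all_lengths = [], []
    for d in dirs:
        lv, ln = _runs_along(q.coords, q.levels, d)
        all_levels.append(lv)
        all_lengths.append(ln)
    lv = np.concatenate(all_levels)
    ln = np.concatenate(all_lengths)
    rmax = int(ln.max())
    r = np.zeros((q.L, rmax), dtype=np.int64)
    np.add.at(r, (lv - 1, ln - 1), 1)
    return RunLengthMatrix(r, int(len(lv)), q.n_voxels, len(dirs))


# ---------------------------------------------------------------------------
# Intensity size zone
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SizeZoneMatrix:
    """Zone counts z(level, size); zones are 26-connected iso-level components.

    Conservation: sum over z(i, s) * s equals n_voxels.
    """

    z: np.ndarray                 # (L, Smax) int
    n_zones: int
    n_voxels: int


def size_zone(q: QuantizedVoi, connectivity: int = 26) -> SizeZoneMatrix:
    """Build the intensity size-zone matrix (26-connected components)."""
    if q.n_voxels == 0:
        raise ValueError("empty VOI")
    grid, _ = q.dense()
    structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    zone_levels, zone_sizes = [], []
    for level in np.unique(q.levels):
        labeled, n_comp = ndimage.label(grid == level, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        zone_levels.extend([level] * n_comp)
        zone_sizes.extend(sizes.tolist())
    zone_levels = np.asarray(zone_levels, dtype=np.intp)
    zone_sizes = np.asarray(zone_sizes, dtype=np.intp)
    smax = int(zone_sizes.max())
    z = np.zeros((q.L, smax), dtype=np.int64)
    np.add.at(z, (zone_levels - 1, zone_sizes - 1), 1)
    return SizeZoneMatrix(z, int(len(zone_sizes)), q.n_voxels)


# ---------------------------------------------------------------------------
# Neighborhood intensity difference (NGTDM)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NgtdmVectors:
    """Per-level summed neighborhood differences and occupancy.

    s[i-1] sums |level - mean(in-VOI 26-neighbor levels)| over VOI voxels of
    level i that have at least one in-VOI neighbor; n[i-1] counts them;
    p = n / sum(n).
    """

    s: np.ndarray                 # (L,)
    n: np.ndarray                 # (L,) int
    p: np.ndarray                 # (L,)
    n_total: int


def ngtdm(q: QuantizedVoi) -> NgtdmVectors:
    """Build the neighborhood gray-tone difference vectors."""
    if q.n_voxels == 0:
        raise ValueError("empty VOI")
    grid, _ = q.dense()
    in_voi = grid > 0
    nb_sum = np.zeros(grid.shape, dtype=float)
    nb_cnt = np.zeros(grid.shape, dtype=np.int64)
    for offset in _OFFSETS_26:
        src, dst = _pair_slices(grid.shape, offset)
        nb_sum[src] += np.where(in_voi[dst], grid[dst], 0)
        nb_cnt[src] += in_voi[dst]
    valid = in_voi & (nb_cnt > 0)
    if not valid.any():
        raise ValueError("no VOI voxel has an in-VOI neighbor")
    levels = grid[valid]
    diffs = np.abs(levels - nb_sum[valid] / nb_cnt[valid])
    s = np.zeros(q.L)
    n = np.zeros(q.L, dtype=np.int64)
    np.add.at(s, levels - 1, diffs)
    np.add.at(n, levels - 1, 1)
    total = int(n.sum())
    return NgtdmVectors(s, n, n / total, total)


# ---------------------------------------------------------------------------
# Neighborhood gray-level dependence (NGLDM)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NgldmMatrix:
    """Dependence counts q(level, k): VOI voxels of a level whose number of
    in-VOI 26-neighbors within tolerance ``a`` equals k (k may be 0)."""

    q: np.ndarray                 # (L, 27) int
    n_voxels: int
    a: int


def ngldm(q: QuantizedVoi, a: int = 0) -> NgldmMatrix:
    """Build the neighborhood gray-level dependence matrix."""
    if q.n_voxels == 0:
        raise ValueError("empty VOI")
    grid, _ = q.dense()
    in_voi = grid > 0
    dep = np.zeros(grid.shape, dtype=np.int64)
    for offset in _OFFSETS_26:
        src, dst = _pair_slices(grid.shape, offset)
        dep[src] += in_voi[dst] & (np.abs(grid[src] - grid[dst]) <= a)
    levels = grid[in_voi]
    deps = dep[in_voi]
    mat = np.zeros((q.L, 27), dtype=np.int64)
    np.add.at(mat, (levels - 1, deps), 1)
    return NgldmMatrix(mat, q.n_voxels, a)


# ---------------------------------------------------------------------------
# Texture spectrum
# ---------------------------------------------------------------------------

# Fixed neighbor order for the 8-neighborhood texture unit (clockwise from
# the upper-left neighbor, in (dy, dx)).
_TS_NEIGHBORS = ((-1, -1), (-1, 0), (-1, 1), (0, 1),
                 (1, 1), (1, 0), (1, -1), (0, -1))


@dataclasses.dataclass
class TextureSpectrum:
    """Histogram of base-3 texture-unit numbers over slice-interior voxels."""

    s: np.ndarray                 # (3**8,) int
    n_units: int


@lru_cache(maxsize=1)
def texture_unit_complement() -> np.ndarray:
    """Index map swapping digits 0 <-> 2 in every base-3 texture unit."""
    units = np.arange(3 ** 8)
    comp = np.zeros_like(units)
    rem = units.copy()
    for k in range(8):
        digit = rem % 3
        rem //= 3
        comp += (2 - digit) * 3 ** k
    return comp


def texture_spectrum(q: QuantizedVoi) -> TextureSpectrum:
    """Build the texture spectrum, slice by slice.

    For each interior voxel (all 8 planar neighbors inside the VOI) the
    neighbors are compared to the center (less/equal/greater -> digit 0/1/2)
    in a fixed order, forming a base-3 texture unit number in 0..6560.

    Raises
    ------
    ValueError
        ``"VOI too thin for texture spectrum"`` if no slice has an interior
        voxel.
    """
    grid, _ = q.dense()
    hist = np.zeros(3 ** 8, dtype=np.int64)
    total = 0
    for k in range(grid.shape[0]):
        plane = grid[k]
        in_voi = plane > 0
        if in_voi.sum() < 9:
            continue
        interior = in_voi.copy()
        units = np.zeros(plane.shape, dtype=np.int64)
        for j, (dy, dx) in enumerate(_TS_NEIGHBORS):
            src, dst = _pair_slices(plane.shape, (dy, dx))
            ok = np.zeros(plane.shape, dtype=bool)
            ok[src] = in_voi[dst]
            interior &= ok
            digit = np.zeros(plane.shape, dtype=np.int64)
            digit_src = np.sign(plane[dst] - plane[src]) + 1  # 0/1/2
            digit[src] = digit_src
            units += digit * 3 ** j
        if interior.any():
            hist += np.bincount(units[interior], minlength=3 ** 8)
            total += int(interior.sum())
    if total == 0:
        raise ValueError("VOI too thin for texture spectrum")
    return TextureSpectrum(hist, total)


# ---------------------------------------------------------------------------
# Texture feature coding
# ---------------------------------------------------------------------------

# The 4 planar directions splitting the 8-neighborhood into connected
# opposite pairs, in (dy, dx).
_TFC_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))

# Gradient-variation classes per direction, from the thresholded sign pair
# (s1, s2) of the two successive differences along the line a -> c -> b:
#   0: both zero (no variation)       2: equal nonzero signs (monotone)
#   1: exactly one zero (one-sided)   3: opposite signs (peak / valley)
TFC_CLASS_NONE, TFC_CLASS_ONESIDED, TFC_CLASS_MONOTONE, TFC_CLASS_EXTREMUM = 0, 1, 2, 3


@dataclasses.dataclass
class TfcImage:
    """Per-voxel texture-feature codes on slice-interior VOI voxels.

    ``codes`` is a dense grid (cropped to the VOI bounding box) with the
    mixed base-4 code (sum over the 4 directions of class * 4**direction,
    0..255) where defined and -1 elsewhere. A constant VOI codes every
    interior voxel 0 (the zero-variation class in all directions).
    """

    codes: np.ndarray             # int, -1 where undefined
    n_coded: int
    delta: float

    @property
    def values(self) -> np.ndarray:
        return self.codes[self.codes >= 0]


def _sign_with_threshold(x: np.ndarray, delta: float) -> np.ndarray:
    s = np.sign(x).astype(np.int8)
    s[np.abs(x) <= delta] = 0
    return s


def _pair_class(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    zeros = (s1 == 0).astype(np.int8) + (s2 == 0).astype(np.int8)
    cls = np.empty(s1.shape, dtype=np.int64)
    cls[zeros == 2] = TFC_CLASS_NONE
    cls[zeros == 1] = TFC_CLASS_ONESIDED
    both = zeros == 0
    cls[both & (s1 == s2)] = TFC_CLASS_MONOTONE
    cls[both & (s1 != s2)] = TFC_CLASS_EXTREMUM
    return cls


def tfc(q: QuantizedVoi, delta: float = 0.0) -> TfcImage:
    """Texture feature coding, slice by slice.

    For each interior voxel the 8-neighborhood is split into 4 connected
    pairs along the planar directions; each pair's two successive level
    differences are thresholded (|d| <= delta -> 0) and the sign pair mapped
    to a gradient-variation class; the voxel's code aggregates the 4 classes
    as a mixed base-4 number. This follows the structure of the texture
    feature coding scheme; the exact class labelling is this package's
    documented convention.
    """
    grid, _ = q.dense()
    codes = np.full(grid.shape, -1, dtype=np.int64)
    total = 0
    for k in range(grid.shape[0]):
        plane = grid[k].astype(float)
        in_voi = grid[k] > 0
        if in_voi.sum() < 9:
            continue
        interior = in_voi.copy()
        code = np.zeros(plane.shape, dtype=np.int64)
        for j, (dy, dx) in enumerate(_TFC_DIRECTIONS):
            fwd_src, fwd_dst = _pair_slices(plane.shape, (dy, dx))
            bwd_src, bwd_dst = _pair_slices(plane.shape, (-dy, -dx))
            has_b = np.zeros(plane.shape, dtype=bool)
            has_b[fwd_src] = in_voi[fwd_dst]
            has_a = np.zeros(plane.shape, dtype=bool)
            has_a[bwd_src] = in_voi[bwd_dst]
            interior &= has_a & has_b
            b = np.zeros(plane.shape)
            b[fwd_src] = plane[fwd_dst]
            a = np.zeros(plane.shape)
            a[bwd_src] = plane[bwd_dst]
            s1 = _sign_with_threshold(plane - a, delta)   # d1 = c - a
            s2 = _sign_with_threshold(b - plane, delta)   # d2 = b - c
            code += _pair_class(s1, s2) * 4 ** j
        if interior.any():
            codes[k][interior] = code[interior]
            total += int(interior.sum())
    if total == 0:
        raise ValueError("VOI too thin for texture feature coding")
    return TfcImage(codes, total, delta)


def tfc_cooccurrence(t: TfcImage, distance: int = 1,
                     directions=None) -> CooccurrenceMatrix:
    """Co-occurrence of texture-feature codes.

    Built with the same pairing and normalization contract as gray-level
    co-occurrence (13 directions pooled, both orders, probabilities summing
    to 1), over the coded voxels; matrix rows correspond to the observed
    code values, which are also the numeric values used by moment-based
    indices.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    observed = np.unique(t.values)
    lookup = np.full(int(observed.max()) + 2, 0, dtype=np.intp)
    lookup[observed] = np.arange(1, len(observed) + 1)
    grid = np.where(t.codes >= 0, lookup[np.maximum(t.codes, 0)], 0)
    dirs = DIRECTIONS_13 if directions is None else list(directions)
    counts, n_pairs = _cooccurrence_from_grid(grid, len(observed), distance, dirs)
    if n_pairs == 0:
        raise ValueError("VOI too small for distance")
    return CooccurrenceMatrix(counts / n_pairs, n_pairs,
                              observed.astype(float), False, False)
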