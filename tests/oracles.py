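"""Brute-force reference implementations used as independent test oracles.

Everything here is written for clarity, not speed: explicit loops over voxel
pairs, runs, zones and neighborhoods on small dense label grids. ``grid`` is
a 2D or 3D integer array with 0 outside the VOI and gray levels 1..L inside.
"""

from __future__ import annotations

import numpy as np


def _as3d(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid)
    return grid[None] if grid.ndim == 2 else grid


def _in(grid, p) -> bool:
    return all(0 <= c < n for c, n in zip(p, grid.shape)) and grid[tuple(p)] > 0


def cooccurrence_pairs(grid, L, directions, distance=1):
    """Count ordered level pairs by explicit enumeration of +-d offsets."""
    grid = _as3d(grid)
    counts = np.zeros((L, L), dtype=int)
    for d in directions:
        for sign in (1, -1):
            off = np.array(d) * distance * sign
            for p in np.argwhere(grid > 0):
                q = p + off
                if _in(grid, q):
                    counts[grid[tuple(p)] - 1, grid[tuple(q)] - 1] += 1
    return counts


def runs(grid, directions):
    """Enumerate maximal same-level collinear in-VOI segments."""
    grid = _as3d(grid)
    out = []
    for d in directions:
        d = np.array(d)
        for p in np.argwhere(grid > 0):
            prev = p - d
            if _in(grid, prev) and grid[tuple(prev)] == grid[tuple(p)]:
                continue  # not a run start
            length = 1
            q = p + d
            while _in(grid, q) and grid[tuple(q)] == grid[tuple(p)]:
                length += 1
                q = q + d
            out.append((int(grid[tuple(p)]), length))
    return out


def _neighbors26(p):
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) != (0, 0, 0):
                    yield p[0] + dz, p[1] + dy, p[2] + dx


def zones(grid):
    """Flood-fill 26-connected iso-level components; returns (level, size)."""
    grid = _as3d(grid)
    seen = np.zeros(grid.shape, dtype=bool)
    out = []
    for start in map(tuple, np.argwhere(grid > 0)):
        if seen[start]:
            continue
        level = grid[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for q in _neighbors26(p):
                if _in(grid, q) and not seen[q] and grid[q] == level:
                    seen[q] = True
                    stack.append(q)
        out.append((int(level), size))
    return out


def ngtdm_vectors(grid, L):
    """Per-level |level - in-VOI neighborhood mean| sums and counts."""
    grid = _as3d(grid)
    s = np.zeros(L)
    n = np.zeros(L, dtype=int)
    for p in map(tuple, np.argwhere(grid > 0)):
        nb = [grid[q] for q in _neighbors26(p) if _in(grid, q)]
        if not nb:
            continue
        i = grid[p]
        s[i - 1] += abs(i - float(np.mean(nb)))
        n[i - 1] += 1
    return s, n


def ngldm_matrix(grid, L, a=0):
    """Dependence counts by explicit neighbor enumeration."""
    grid = _as3d(grid)
    q = np.zeros((L, 27), dtype=int)
    for p in map(tuple, np.argwhere(grid > 0)):
        dep = sum(1 for r in _neighbors26(p)
                  if _in(grid, r) and abs(int(grid[r]) - int(grid[p])) <= a)
        q[grid[p] - 1, dep] += 1
    return q


_TS_ORDER = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def texture_units(plane):
    """Base-3 texture-unit numbers of interior voxels of one 2D slice."""
    plane = np.asarray(plane)
    out = []
    for y in range(plane.shape[0]):
        for x in range(plane.shape[1]):
            if plane[y, x] <= 0:
                continue
            digits = []
            for dy, dx in _TS_ORDER:
                yy, xx = y + dy, x + dx
                if not (0 <= yy < plane.shape[0] and 0 <= xx < plane.shape[1]
                        and plane[yy, xx] > 0):
                    digits = None
                    break
                v, c = plane[yy, xx], plane[y, x]
                digits.append(0 if v < c else (1 if v == c else 2))
            if digits is not None:
                out.append(sum(d * 3 ** k for k, d in enumerate(digits)))
    return out
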