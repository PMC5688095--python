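"""Independent brute-force oracles for the image operators.

These deliberately avoid the morphology/filtering routines the package uses
(scipy.ndimage / scikit-image): neighbourhoods are enumerated explicitly,
connected components are grown by breadth-first search, distances are
exhaustive point-to-point minima.  They are slow and only meant for small
(<= 31 x 31) grids.
"""
from collections import deque

import numpy as np


def disk_offsets(radius):
    offs = []
    r = int(radius)
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if dr * dr + dc * dc <= r * r:
                offs.append((dr, dc))
    return offs


def _min_filter(grid, radius):
    r = int(radius)
    pad = np.pad(grid, r, mode="symmetric")  # boundary rule of the implementation
    h, w = grid.shape
    out = np.full((h, w), np.inf)
    for dr, dc in disk_offsets(radius):  # explicit neighbourhood enumeration
        np.minimum(out, pad[r + dr : r + dr + h, r + dc : r + dc + w], out=out)
    return out


def _max_filter(grid, radius):
    r = int(radius)
    pad = np.pad(grid, r, mode="symmetric")
    h, w = grid.shape
    out = np.full((h, w), -np.inf)
    for dr, dc in disk_offsets(radius):
        np.maximum(out, pad[r + dr : r + dr + h, r + dc : r + dc + w], out=out)
    return out


def oracle_tophat(grid, radius=3):
    """White top-hat: input minus (max filter of min filter)."""
    opening = _max_filter(_min_filter(np.asarray(grid, float), radius), radius)
    return np.asarray(grid, float) - opening


def _components_4(mask):
    """4-connected components by BFS in raster order; returns label grid."""
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] and labels[si, sj] == 0:
                nxt += 1
                q = deque([(si, sj)])
                labels[si, sj] = nxt
                while q:
                    i, j = q.popleft()
                    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        a, b = i + di, j + dj
                        if 0 <= a < h and 0 <= b < w and mask[a, b] and labels[a, b] == 0:
                            labels[a, b] = nxt
                            q.append((a, b))
    return labels, nxt


def oracle_morphology_mask(grid, threshold):
    """Threshold, keep largest 4-connected component, flood-fill holes."""
    fg = np.asarray(grid, float) > threshold
    if not fg.any():
        return fg
    labels, n = _components_4(fg)
    sizes = [np.count_nonzero(labels == k) for k in range(1, n + 1)]
    keep = labels == (1 + int(np.argmax(sizes)))
    # holes: background not reachable from the border (4-connectivity)
    h, w = keep.shape
    reach = np.zeros((h, w), dtype=bool)
    q = deque()
    for i in range(h):
        for j in (0, w - 1):
            if not keep[i, j] and not reach[i, j]:
                reach[i, j] = True
                q.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if not keep[i, j] and not reach[i, j]:
                reach[i, j] = True
                q.append((i, j))
    while q:
        i, j = q.popleft()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if 0 <= a < h and 0 <= b < w and not keep[a, b] and not reach[a, b]:
                reach[a, b] = True
                q.append((a, b))
    return keep | (~keep & ~reach)


def oracle_erode_once(mask):
    """One 4-connected binary erosion (outside the array counts as False)."""
    h, w = mask.shape
    pad = np.pad(mask, 1, constant_values=False)
    out = mask.copy()
    for di, dj in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
        out &= pad[1 + di : 1 + di + h, 1 + dj : 1 + dj + w]
    return out


def oracle_adaptive_erode(mask, percent):
    """Smallest iterate of the erosion sequence with area >= percent%."""
    area0 = mask.sum()
    target = percent / 100.0 * area0
    current = mask.copy()
    while True:
        nxt = oracle_erode_once(current)
        if nxt.sum() == 0 or nxt.sum() < target:
            return current
        current = nxt


def oracle_mcp(grid, mask, n_rings=8):
    """Distance-transform ring binning by exhaustive point-to-point minima."""
    mask = np.asarray(mask, bool)
    inside = np.argwhere(mask)
    outside = np.argwhere(~mask)
    assert len(outside) > 0, "oracle needs background pixels"
    d2 = ((inside[:, None, :] - outside[None, :, :]) ** 2).sum(axis=2)
    dist = np.sqrt(d2.min(axis=1))
    dmax = dist.max()
    pos = 1.0 - dist / dmax if dmax > 0 else np.zeros(len(inside))
    ring = np.minimum((pos * n_rings).astype(int), n_rings - 1)
    vals = np.asarray(grid, float)[mask]
    best, best_mean = 0, -np.inf
    for k in range(n_rings):
        sel = ring == k
        if sel.any():
            m = vals[sel].mean()
            if m > best_mean:
                best, best_mean = k, m
    return (best + 0.5) / n_rings


def oracle_max_pixel(grid, mask, background):
    best = 0.0
    grid = np.asarray(grid, float)
    for i, j in np.argwhere(np.asarray(mask, bool)):
        best = max(best, grid[i, j] - background)
    return max(best, 0.0)


def oracle_pearson_fisher(x, y, clip=0.999):
    """Pearson correlation + Fisher z from the definition sums."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x * x).sum() - sx * sx) * np.sqrt(n * (y * y).sum() - sy * sy)
    r = num / den
    r = min(max(r, -clip), clip)
    return 0.5 * np.log((1 + r) / (1 - r))
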