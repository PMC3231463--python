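"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit Python loops, BFS flood
fill, union-find — and shares no code path with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T

N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
N8 = N4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def abs_diff_loop(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.zeros(a.shape, dtype=np.uint8)
    it = np.nditer(a, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        out[idx] = abs(int(a[idx]) - int(b[idx]))
    return out


def rescale_loop(img: np.ndarray) -> np.ndarray:
    arr = img.astype(float)
    lo, hi = arr.min(), arr.max()
    out = np.zeros(arr.shape, dtype=np.uint8)
    if hi == lo:
        return out
    it = np.nditer(arr, flags=["multi_index"])
    for v in it:
        out[it.multi_index] = round((float(v) - lo) * 255.0 / (hi - lo))
    return out


def sobel_magnitude_loop(channel: np.ndarray) -> np.ndarray:
    """3x3 Sobel gradient magnitude with edge-replicated borders."""
    arr = channel.astype(float)
    padded = np.pad(arr, 1, mode="edge")
    h, w = arr.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = padded[i : i + 3, j : j + 3]
            gx = float((win * SOBEL_X).sum())
            gy = float((win * SOBEL_Y).sum())
            out[i, j] = np.hypot(gx, gy)
    return out


def or_loop(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    h, w = r.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            out[i, j] = bool(r[i, j]) or bool(g[i, j]) or bool(b[i, j])
    return out


def fill_holes_bfs(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Hole filling as BFS from the border over the background.

    Background connectivity is the complement of the foreground's
    (8-connected objects enclose 4-connected holes).
    """
    mask = mask.astype(bool)
    h, w = mask.shape
    bg_neigh = N4 if connectivity == 8 else N8
    reached = np.zeros((h, w), dtype=bool)
    queue: deque[tuple[int, int]] = deque()
    for i in range(h):
        for j in (0, w - 1):
            if not mask[i, j] and not reached[i, j]:
                reached[i, j] = True
                queue.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if not mask[i, j] and not reached[i, j]:
                reached[i, j] = True
                queue.append((i, j))
    while queue:
        i, j = queue.popleft()
        for di, dj in bg_neigh:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and not mask[ni, nj] and not reached[ni, nj]:
                reached[ni, nj] = True
                queue.append((ni, nj))
    return mask | ~reached


def union_find_components(mask: np.ndarray, connectivity: int = 8) -> list[int]:
    """Component areas (sorted) via union-find over foreground pixels."""
    mask = mask.astype(bool)
    h, w = mask.shape
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    def union(p, q):
        rp, rq = find(p), find(q)
        if rp != rq:
            parent[rp] = rq

    neigh = N8 if connectivity == 8 else N4
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                parent.setdefault((i, j), (i, j))
                for di, dj in neigh:
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w and mask[ni, nj]:
                        parent.setdefault((ni, nj), (ni, nj))
                        union((i, j), (ni, nj))
    sizes: dict[tuple[int, int], int] = {}
    for p in parent:
        sizes[find(p)] = sizes.get(find(p), 0) + 1
    return sorted(sizes.values())


def hourly_means_loop(times_s: np.ndarray, values: np.ndarray) -> dict[int, tuple[float, int]]:
    """Per-hour (mean, n) keyed by hour index since epoch, explicit loop."""
    bins: dict[int, list[float]] = {}
    for t, v in zip(times_s, values):
        bins.setdefault(int(t // 3600), []).append(float(v))
    return {k: (sum(vs) / len(vs), len(vs)) for k, vs in bins.items()}


def window_means_loop(
    times_s: np.ndarray, values: np.ndarray, cadence_s: float
) -> dict[int, float]:
    """Per-cadence-window mean keyed by window index, explicit loop."""
    bins: dict[int, list[float]] = {}
    for t, v in zip(times_s, values):
        bins.setdefault(int(t // cadence_s), []).append(float(v))
    return {k: sum(vs) / len(vs) for k, vs in bins.items()}
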