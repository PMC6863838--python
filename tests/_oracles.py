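"""Independent reference implementations used as test oracles.

Deliberately written with different mechanisms than the package (explicit
shifted-array morphology + BFS hole filling, pairwise-loop crossing counts)
so agreement is meaningful.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def dilate3(a: np.ndarray) -> np.ndarray:
    """3x3 dilation; outside the frame counts as background."""
    p = np.pad(a, 1, constant_values=False)
    out = np.zeros_like(a)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out |= p[1 + dr : 1 + dr + a.shape[0], 1 + dc : 1 + dc + a.shape[1]]
    return out


def erode3(a: np.ndarray) -> np.ndarray:
    """3x3 erosion; outside the frame counts as background."""
    p = np.pad(a, 1, constant_values=False)
    out = np.ones_like(a)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out &= p[1 + dr : 1 + dr + a.shape[0], 1 + dc : 1 + dc + a.shape[1]]
    return out


def fill_holes_bfs(a: np.ndarray) -> np.ndarray:
    """Fill 4-connected background regions not reachable from the border."""
    h, w = a.shape
    reach = np.zeros_like(a)
    dq: deque = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not a[r, c] and not reach[r, c]:
                reach[r, c] = True
                dq.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not a[r, c] and not reach[r, c]:
                reach[r, c] = True
                dq.append((r, c))
    while dq:
        r, c = dq.popleft()
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < h and 0 <= nc < w and not a[nr, nc] and not reach[nr, nc]:
                reach[nr, nc] = True
                dq.append((nr, nc))
    return a | ~reach


def close_fill_reference(mask: np.ndarray, rounds: int = 2) -> np.ndarray:
    m = mask.copy()
    for _ in range(rounds):
        m = erode3(fill_holes_bfs(dilate3(m)))
    return m


def count_crossings_reference(values) -> int:
    """Pairwise-loop crossing count with carry-previous-sign zero handling."""
    count = 0
    prev = 0
    for v in values:
        if v == 0:
            continue
        s = 1 if v > 0 else -1
        if prev != 0 and s != prev:
            count += 1
        prev = s
    return count
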