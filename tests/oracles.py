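"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive — explicit neighborhood scans, stack
flood fill, all-pairs loops — so it shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def dilate_scan(mask: np.ndarray, h: int, w: int) -> np.ndarray:
    """Neighborhood-scan dilation: cell is 1 iff any covered cell is 1."""
    m = np.asarray(mask, dtype=np.uint8)
    rows, cols = m.shape
    rh, rw = h // 2, w // 2
    out = np.zeros_like(m)
    for r in range(rows):
        for c in range(cols):
            hit = 0
            for dr in range(-rh, rh + 1):
                for dc in range(-rw, rw + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and m[rr, cc]:
                        hit = 1
            out[r, c] = hit
    return out


def erode_scan(mask: np.ndarray, h: int, w: int) -> np.ndarray:
    """Neighborhood-scan erosion: cell is 1 iff every covered cell is 1
    (out-of-bounds counts as 0)."""
    m = np.asarray(mask, dtype=np.uint8)
    rows, cols = m.shape
    rh, rw = h // 2, w // 2
    out = np.zeros_like(m)
    for r in range(rows):
        for c in range(cols):
            keep = 1
            for dr in range(-rh, rh + 1):
                for dc in range(-rw, rw + 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < rows and 0 <= cc < cols) or not m[rr, cc]:
                        keep = 0
            out[r, c] = keep
    return out


def closing_scan(mask: np.ndarray, h: int, w: int) -> np.ndarray:
    """Infinite-domain closing restricted to the grid: pad by the element
    radius, dilate then erode by scan, crop back."""
    m = np.asarray(mask, dtype=np.uint8)
    rh, rw = h // 2, w // 2
    padded = np.pad(m, ((rh, rh), (rw, rw)))
    closed = erode_scan(dilate_scan(padded, h, w), h, w)
    return closed[rh : rh + m.shape[0], rw : rw + m.shape[1]]


def flood_fill_components(mask: np.ndarray, connectivity: int):
    """Stack-based flood fill labeling; labels in row-major first-encounter
    order. Returns (labels, areas list)."""
    m = np.asarray(mask, dtype=np.uint8)
    rows, cols = m.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    labels = np.zeros((rows, cols), dtype=int)
    areas = []
    next_label = 0
    for r in range(rows):
        for c in range(cols):
            if m[r, c] and not labels[r, c]:
                next_label += 1
                stack = [(r, c)]
                labels[r, c] = next_label
                area = 0
                while stack:
                    rr, cc = stack.pop()
                    area += 1
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < rows
                            and 0 <= nc < cols
                            and m[nr, nc]
                            and not labels[nr, nc]
                        ):
                            labels[nr, nc] = next_label
                            stack.append((nr, nc))
                areas.append(area)
    return labels, areas


def fill_holes_flood(mask: np.ndarray) -> np.ndarray:
    """Border flood of the background with 4-connectivity; unreachable
    background becomes foreground."""
    m = np.asarray(mask, dtype=np.uint8)
    rows, cols = m.shape
    reach = np.zeros((rows, cols), dtype=bool)
    stack = []
    for r in range(rows):
        for c in (0, cols - 1):
            if not m[r, c]:
                stack.append((r, c))
    for c in range(cols):
        for r in (0, rows - 1):
            if not m[r, c]:
                stack.append((r, c))
    while stack:
        r, c = stack.pop()
        if reach[r, c] or m[r, c]:
            continue
        reach[r, c] = True
        for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and not m[nr, nc] and not reach[nr, nc]:
                stack.append((nr, nc))
    return (m.astype(bool) | ~reach).astype(np.uint8)


def cindex_pairs(times, events, risks, tie_credit=False) -> float:
    """All-pairs concordance: for i uncensored and T_j > T_i, concordant
    when R_i > R_j (0.5 for risk ties when tie_credit)."""
    num = 0.0
    den = 0
    n = len(times)
    for i in range(n):
        if not events[i]:
            continue
        for j in range(n):
            if times[j] > times[i]:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif tie_credit and risks[i] == risks[j]:
                    num += 0.5
    if den == 0:
        raise ZeroDivisionError
    return num / den


def cox_nll_direct(risks, times, events) -> float:
    """Direct double-loop negative log partial likelihood (Breslow ties),
    averaged over events."""
    r = np.asarray(risks, float)
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    total = 0.0
    for i in np.flatnonzero(e):
        total += r[i] - np.log(np.exp(r[t >= t[i]]).sum())
    return -total / e.sum()
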