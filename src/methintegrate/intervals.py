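"""Exact set algebra on genomic intervals.

All coordinates are 0-based half-open. An *interval set* here is an
``(n, 2)`` integer numpy array of merged, sorted, disjoint ``[start, end)``
rows on a single chromosome; the set operations below preserve that normal
form exactly, which is what lets the six-region partition identities
(e.g. P.CGI ∪ P.NCGI = promoter bases) hold to the base pair.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_set",
    "merge",
    "union",
    "intersect",
    "subtract",
    "total_length",
    "positions_in",
    "any_overlap",
]


def as_set(pairs) -> np.ndarray:
    """Normalize an iterable of (start, end) pairs into a merged interval set."""
    arr = np.asarray(list(pairs), dtype=np.int64).reshape(-1, 2)
    if arr.size and (arr[:, 0] >= arr[:, 1]).any():
        raise ValueError("intervals must satisfy start < end")
    return merge(arr)


def merge(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or abutting intervals."""
    if len(arr) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def union(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if len(a) == 0:
        return merge(np.asarray(b, dtype=np.int64).reshape(-1, 2))
    if len(b) == 0:
        return merge(np.asarray(a, dtype=np.int64).reshape(-1, 2))
    return merge(np.vstack([a, b]))


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    a, b = merge(np.asarray(a).reshape(-1, 2)), merge(np.asarray(b).reshape(-1, 2))
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Bases of ``a`` not covered by ``b``."""
    a = merge(np.asarray(a).reshape(-1, 2))
    b = merge(np.asarray(b).reshape(-1, 2))
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def total_length(a: np.ndarray) -> int:
    if len(a) == 0:
        return 0
    a = np.asarray(a).reshape(-1, 2)
    return int((a[:, 1] - a[:, 0]).sum())


def positions_in(pos: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Boolean mask: which positions fall inside the interval set."""
    pos = np.asarray(pos)
    if len(a) == 0:
        return np.zeros(pos.shape, dtype=bool)
    a = merge(np.asarray(a).reshape(-1, 2))
    idx = np.searchsorted(a[:, 0], pos, side="right") - 1
    ok = idx >= 0
    mask = np.zeros(pos.shape, dtype=bool)
    mask[ok] = pos[ok] < a[idx[ok], 1]
    return mask


def any_overlap(start: int, end: int, a: np.ndarray) -> bool:
    """True if [start, end) shares >= 1 base with the interval set."""
    return total_length(intersect(np.array([[start, end]]), a)) > 0
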