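"""Sorted half-open interval arithmetic on numpy arrays.

All functions operate on parallel ``starts``/``ends`` int arrays describing
0-based half-open intervals on one chromosome. Inputs are assumed sorted by
start; ``merge`` additionally collapses overlaps so the downstream two-pointer
routines can rely on disjointness.
"""

from __future__ import annotations

import numpy as np

__all__ = ["merge", "intersect", "intersect_bp", "difference", "total_bp"]


def merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and collapse overlapping or touching intervals."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    # running maximum of ends; a new block begins where start > max(end so far)
    run_max = np.maximum.accumulate(e)
    new_block = np.empty(s.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > run_max[:-1]
    block_id = np.cumsum(new_block) - 1
    out_s = s[new_block]
    out_e = np.maximum.reduceat(e, np.flatnonzero(new_block))
    # reduceat handles the grouping; block_id kept only for clarity
    del block_id
    return out_s, out_e


def _pair_index(a_starts, a_ends, b_starts, b_ends):
    """Index pairs (i in a, j in b) of potentially overlapping intervals.

    Both sets must be sorted and disjoint.
    """
    lo = np.searchsorted(b_ends, a_starts, side="right")
    hi = np.searchsorted(b_starts, a_ends, side="left")
    counts = hi - lo
    counts = np.maximum(counts, 0)
    total = int(counts.sum())
    if total == 0:
        return (np.empty(0, dtype=np.int64),) * 2
    ai = np.repeat(np.arange(a_starts.size), counts)
    offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    bj = np.repeat(lo, counts) + offs
    return ai, bj


def intersect(a_starts, a_ends, b_starts, b_ends) -> tuple[np.ndarray, np.ndarray]:
    """Intervals covered by both sets (each sorted & disjoint)."""
    a_starts = np.asarray(a_starts, dtype=np.int64)
    a_ends = np.asarray(a_ends, dtype=np.int64)
    b_starts = np.asarray(b_starts, dtype=np.int64)
    b_ends = np.asarray(b_ends, dtype=np.int64)
    ai, bj = _pair_index(a_starts, a_ends, b_starts, b_ends)
    if ai.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    s = np.maximum(a_starts[ai], b_starts[bj])
    e = np.minimum(a_ends[ai], b_ends[bj])
    keep = s < e
    return s[keep], e[keep]


def intersect_bp(a_starts, a_ends, b_starts, b_ends) -> int:
    """Total bp of overlap between two sorted disjoint interval sets."""
    s, e = intersect(a_starts, a_ends, b_starts, b_ends)
    return int((e - s).sum())


def difference(a_starts, a_ends, b_starts, b_ends) -> tuple[np.ndarray, np.ndarray]:
    """Parts of ``a`` not covered by ``b`` (each sorted & disjoint)."""
    a_starts = np.asarray(a_starts, dtype=np.int64)
    a_ends = np.asarray(a_ends, dtype=np.int64)
    b_starts = np.asarray(b_starts, dtype=np.int64)
    b_ends = np.asarray(b_ends, dtype=np.int64)
    out_s: list[int] = []
    out_e: list[int] = []
    lo = np.searchsorted(b_ends, a_starts, side="right")
    hi = np.searchsorted(b_starts, a_ends, side="left")
    for k in range(a_starts.size):
        cur = int(a_starts[k])
        end = int(a_ends[k])
        for j in range(int(lo[k]), int(hi[k])):
            bs, be = int(b_starts[j]), int(b_ends[j])
            if bs > cur:
                out_s.append(cur)
                out_e.append(min(bs, end))
            cur = max(cur, be)
            if cur >= end:
                break
        if cur < end:
            out_s.append(cur)
            out_e.append(end)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def total_bp(starts, ends) -> int:
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    return int((ends - starts).sum())
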