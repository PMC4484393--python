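"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — per-position loops, exhaustive
enumeration, per-bp set arithmetic — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_motif_scan(seq: str, motif: str) -> list[tuple[int, int]]:
    """All occurrences of an IUPAC motif by direct per-position comparison."""
    out = []
    m = len(motif)
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in IUPAC_SETS[motif[j]] for j in range(m)):
            out.append((i, i + m))
    return out


def brute_window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Truncated-window running mean by per-position loop."""
    half = window // 2
    n = values.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def brute_quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Rank / average / substitute quantile normalization, one cell at a time."""
    n, k = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(k):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        for i in range(n):
            ties = np.flatnonzero(col == col[i])
            tie_ranks = sorted(ranks[t] for t in ties)
            out[i, j] = np.mean([ref[r] for r in tie_ranks])
    return out


def brute_trimmed_mean(values: np.ndarray, trim: float) -> float:
    """Sort-and-slice trimmed mean: drop floor(trim*n) from each tail."""
    v = np.sort(np.asarray(values, dtype=float))
    g = int(math.floor(trim * v.size))
    return float(v[g: v.size - g].mean())


def brute_interval_intersection_bp(a: list[tuple[int, int]],
                                   b: list[tuple[int, int]]) -> int:
    """bp overlap via per-bp membership sets."""
    abp = set()
    for s, e in a:
        abp.update(range(s, e))
    bbp = set()
    for s, e in b:
        bbp.update(range(s, e))
    return len(abp & bbp)


def brute_nearest_border(point: int, borders: list[int]) -> int:
    return min(abs(point - b) for b in borders)


# ---------------------------------------------------------------------------
# exhaustive explicit-duration decoding
# ---------------------------------------------------------------------------

def path_logprob(labels: np.ndarray, codes: np.ndarray, emission: np.ndarray,
                 dpmf: np.ndarray, startprob: np.ndarray) -> float:
    """Log-probability of one labeling under the alternating-state model."""
    labels = np.asarray(labels)
    codes = np.asarray(codes)
    M = dpmf.shape[1]
    runs = []
    start = 0
    for i in range(1, labels.size):
        if labels[i] != labels[i - 1]:
            runs.append((int(labels[start]), i - start))
            start = i
    runs.append((int(labels[start]), labels.size - start))
    for i in range(1, len(runs)):
        assert runs[i][0] != runs[i - 1][0]
    lp = math.log(startprob[runs[0][0]]) if startprob[runs[0][0]] > 0 else -math.inf
    for state, dur in runs:
        if dur > M or dpmf[state, dur - 1] <= 0:
            return -math.inf
        lp += math.log(dpmf[state, dur - 1])
    for t in range(codes.size):
        p = emission[labels[t], codes[t]]
        if p <= 0:
            return -math.inf
        lp += math.log(p)
    return lp


def exhaustive_decode(codes: np.ndarray, emission: np.ndarray, dpmf: np.ndarray,
                      startprob: np.ndarray):
    """Argmax over every alternating segmentation by explicit enumeration.

    Returns (best logprob, best labeling, number of optima within 1e-9).
    """
    codes = np.asarray(codes)
    n = codes.size
    M = dpmf.shape[1]
    best_lp = -math.inf
    best_path = None
    n_opt = 0

    def rec(pos: int, state: int, labels: list[int]):
        nonlocal best_lp, best_path, n_opt
        if pos == n:
            lp = path_logprob(np.array(labels), codes, emission, dpmf, startprob)
            if lp == -math.inf:
                return
            if lp > best_lp + 1e-9:
                best_lp, best_path, n_opt = lp, list(labels), 1
            elif abs(lp - best_lp) <= 1e-9:
                n_opt += 1
            return
        for u in range(1, min(M, n - pos) + 1):
            rec(pos + u, 1 - state, labels + [state] * u)

    for s0 in (0, 1):
        rec(0, s0, [])
    return best_lp, (np.array(best_path) if best_path is not None else None), n_opt
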