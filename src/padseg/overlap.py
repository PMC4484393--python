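"""Domain-overlap statistics and the circular-permutation null model.

Observed PAD–feature overlaps (e.g. with lamina-associated domains) are
tested against a null that rotates the genome-wide vector of per-fragment-end
HSMM calls: the calls on all chromosomes are concatenated in karyotype
order into one vector of length n, rotated by a random k in [1..n], written
back onto the original fragment-end positions, and re-assembled into
"randomized PADs". The rotation preserves the entire run-length structure of
the calls (domain sizes, total PAD fraction) while randomizing genomic
position — rotated calls deliberately cross chromosome boundaries, as the
concatenation construction implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _intervals
from .domains import PAD, DomainSet, calls_to_domains
from .hsmm import StateCalls
from .io import FragmentEndMap, IntervalSet

__all__ = [
    "OverlapResult",
    "PermutationNull",
    "genomic_overlap",
    "circular_permutation_null",
    "pairwise_domain_overlap",
    "classify_constitutive_facultative",
    "partition_features_by_domain",
    "top_n_by_score",
]


@dataclass
class OverlapResult:
    bp: int
    percent: float
    denominator: str
    denominator_bp: int


@dataclass
class PermutationNull:
    """Empirical null distribution of an overlap statistic."""

    values: np.ndarray
    observed: float
    seed: int | None = None
    quantile_pair: tuple[float, float] = (0.05, 0.95)
    shifts: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def lower(self) -> float:
        return float(np.quantile(self.values, self.quantile_pair[0]))

    @property
    def upper(self) -> float:
        return float(np.quantile(self.values, self.quantile_pair[1]))

    def observed_inside_envelope(self) -> bool:
        return self.lower <= self.observed <= self.upper


def _domain_arrays(domains: DomainSet, label: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return domains.label_intervals(label).per_chrom(merged=True)


def genomic_overlap(
    a: DomainSet | IntervalSet,
    b: IntervalSet,
    denominator: str = "a_bp",
    label: str = PAD,
) -> OverlapResult:
    """Total bp of intersection between a domain label (or interval set) and b.

    ``denominator`` is 'a_bp' (percent of a's bp) or 'genome_bp' (percent of
    the summed chromosome lengths, available for DomainSet inputs).
    """
    if isinstance(a, DomainSet):
        a_arrays = _domain_arrays(a, label)
        genome_bp = sum(a.chrom_lengths.values())
    else:
        a_arrays = a.per_chrom(merged=True)
        genome_bp = 0
    b_arrays = b.per_chrom(merged=True)
    bp = 0
    a_bp = 0
    for chrom, (s, e) in a_arrays.items():
        a_bp += _intervals.total_bp(s, e)
        if chrom in b_arrays:
            bs, be = b_arrays[chrom]
            bp += _intervals.intersect_bp(s, e, bs, be)
    if denominator == "a_bp":
        den = a_bp
    elif denominator == "genome_bp":
        if genome_bp == 0:
            raise ValueError("genome_bp denominator requires chromosome lengths")
        den = genome_bp
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    pct = 100.0 * bp / den if den else 0.0
    return OverlapResult(bp, pct, denominator, den)


def _rotate_calls(is_pad: np.ndarray, k: int) -> np.ndarray:
    """Shift vector indices by k: element i of the result is element
    (i - k) mod n of the input, i.e. the vector starts with the last k
    elements of the original."""
    return np.roll(is_pad, k)


def _pad_intervals_from_calls(
    is_pad: np.ndarray, fragends: FragmentEndMap
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """PAD intervals per chromosome from a genome-wide call vector.

    Same construction as :func:`padseg.domains.calls_to_domains` (runs of
    identical calls; interior boundaries at fragment-end midpoints; terminal
    domains clipped to the fragment-end span) without the DataFrame overhead
    — used in the permutation loop.
    """
    out = {}
    pos = 0
    for chrom in fragends.chromosomes:
        n = fragends.n_ends(chrom)
        lab = is_pad[pos : pos + n]
        pos += n
        if n == 0:
            continue
        s = fragends.starts[chrom]
        e = fragends.ends[chrom]
        change = np.flatnonzero(lab[:-1] != lab[1:])
        cuts = (e[change] + s[change + 1]) // 2
        bounds = np.concatenate([[s[0]], cuts, [e[-1]]])
        run_starts = np.concatenate([[0], change + 1])
        is_pad_run = lab[run_starts]
        out[chrom] = (bounds[:-1][is_pad_run], bounds[1:][is_pad_run])
    return out


def circular_permutation_null(
    calls: StateCalls,
    fragends: FragmentEndMap,
    target: IntervalSet,
    n_iter: int = 1000,
    seed: int | None = 0,
    quantile_pair: tuple[float, float] = (0.05, 0.95),
) -> PermutationNull:
    """Null distribution of PAD–target overlap under circular call rotation."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if calls.is_pad.size == 0:
        raise ValueError("empty calls")
    n = calls.is_pad.size
    target_arrays = target.per_chrom(merged=True)

    def overlap_of(vec: np.ndarray) -> int:
        bp = 0
        for chrom, (s, e) in _pad_intervals_from_calls(vec, fragends).items():
            if chrom in target_arrays:
                ts, te = target_arrays[chrom]
                bp += _intervals.intersect_bp(s, e, ts, te)
        return bp

    observed = overlap_of(calls.is_pad)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, n + 1, size=n_iter)
    values = np.empty(n_iter)
    for i, k in enumerate(shifts):
        values[i] = overlap_of(_rotate_calls(calls.is_pad, int(k)))
    return PermutationNull(values, float(observed), seed, quantile_pair,
                           shifts.astype(np.int64))


def pairwise_domain_overlap(sets: dict[str, DomainSet], label: str = PAD) -> pd.DataFrame:
    """Matrix of pairwise overlaps as % of the column tissue's domain bp.

    Entry (i, j) = bp(label_i ∩ label_j) / bp(label_j) * 100; diagonal 100.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need >= 2 domain sets")
    arrays = {name: _domain_arrays(sets[name], label) for name in names}
    totals = {
        name: sum(_intervals.total_bp(s, e) for s, e in arrays[name].values())
        for name in names
    }
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i in names:
        for j in names:
            if i == j:
                mat.loc[i, j] = 100.0
                continue
            bp = 0
            for chrom, (s, e) in arrays[i].items():
                if chrom in arrays[j]:
                    js, je = arrays[j][chrom]
                    bp += _intervals.intersect_bp(s, e, js, je)
            mat.loc[i, j] = 100.0 * bp / totals[j] if totals[j] else 0.0
    return mat


def classify_constitutive_facultative(
    sets: dict[str, DomainSet], reference: str, contrast: str
) -> dict[str, IntervalSet]:
    """Partition the assessed genome by cross-tissue PAD status.

    constitutive_pad: intersection of PADs across all sets.
    constitutive_nonpad: intersection of non-PADs across all sets.
    <reference>_specific_pad: reference PADs ∩ contrast non-PADs.
    <contrast>_specific_pad: contrast PADs ∩ reference non-PADs.
    """
    for name in (reference, contrast):
        if name not in sets:
            raise ValueError(f"unknown set name {name!r}")
    all_chroms: list[str] = []
    for ds in sets.values():
        for c in ds.df["chrom"].unique():
            if c not in all_chroms:
                all_chroms.append(c)

    def arrays(name: str, label: str):
        return _domain_arrays(sets[name], label)

    def intersect_all(dicts):
        out = {}
        for chrom in all_chroms:
            cur = None
            for d in dicts:
                if chrom not in d:
                    cur = (np.empty(0, np.int64), np.empty(0, np.int64))
                    break
                if cur is None:
                    cur = d[chrom]
                else:
                    cur = _intervals.intersect(*cur, *d[chrom])
            out[chrom] = cur if cur is not None else (
                np.empty(0, np.int64), np.empty(0, np.int64))
        return out

    def to_set(per_chrom):
        chroms, starts, ends = [], [], []
        for chrom in all_chroms:
            s, e = per_chrom.get(chrom, (np.empty(0, np.int64),) * 2)
            chroms.extend([chrom] * s.size)
            starts.extend(s.tolist())
            ends.extend(e.tolist())
        return IntervalSet(pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}))

    pad_arrays = {name: arrays(name, PAD) for name in sets}
    non_arrays = {name: arrays(name, "nonPAD") for name in sets}
    out = {
        "constitutive_pad": to_set(intersect_all(list(pad_arrays.values()))),
        "constitutive_nonpad": to_set(intersect_all(list(non_arrays.values()))),
        f"{reference}_specific_pad": to_set(
            intersect_all([pad_arrays[reference], non_arrays[contrast]])
        ),
        f"{contrast}_specific_pad": to_set(
            intersect_all([pad_arrays[contrast], non_arrays[reference]])
        ),
    }
    return out


def partition_features_by_domain(
    features: IntervalSet, domains: DomainSet
) -> pd.DataFrame:
    """Assign each feature to the domain label containing its midpoint.

    Returns counts and percentages per label, plus 'unassigned' for features
    whose midpoint falls outside the assessed span.
    """
    labels = []
    dom_per_chrom = {
        chrom: grp for chrom, grp in domains.df.groupby("chrom", sort=False)
    }
    for row in features.df.itertuples(index=False):
        mid = (row.start + row.end) // 2
        grp = dom_per_chrom.get(row.chrom)
        label = "unassigned"
        if grp is not None:
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            idx = np.searchsorted(s, mid, side="right") - 1
            if idx >= 0 and mid < e[idx]:
                label = grp["label"].iloc[idx]
        labels.append(label)
    counts = pd.Series(labels).value_counts()
    all_labels = [PAD, "nonPAD", "unassigned"]
    counts = counts.reindex(all_labels, fill_value=0)
    total = counts.sum()
    return pd.DataFrame({
        "count": counts,
        "percent": 100.0 * counts / total if total else 0.0,
    })


def top_n_by_score(features: IntervalSet, n: int = 2000) -> IntervalSet:
    """The n highest-scoring intervals (e.g. top-expressed genes)."""
    if "score" not in features.df.columns:
        raise ValueError("features have no score column")
    df = features.df.sort_values("score", ascending=False, kind="stable").head(n)
    return IntervalSet(df.reset_index(drop=True))
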