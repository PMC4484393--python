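"""Replicate consensus and PAD / non-PAD domain construction.

Per-fragment-end HSMM calls from several biological replicates are combined
by majority vote (exact ties resolved by a "virtual replicate" decoded from
the pooled reads). Maximal runs of identical consensus calls become domains;
the border between two adjacent domains sits at the midpoint between the
last fragment end of one run and the first of the next. Domains are clipped
to the fragment-end span of each chromosome — regions outside any fragment
end carry no data and are left unassessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hsmm import StateCalls
from .io import CountTrack, FragmentEndMap, IntervalSet

__all__ = [
    "ConsensusCalls",
    "DomainSet",
    "BorderSet",
    "majority_vote",
    "pool_replicates",
    "calls_to_domains",
    "domain_size_stats",
    "write_domains",
    "read_domains",
    "write_borders",
]

PAD = "PAD"
NONPAD = "nonPAD"


@dataclass
class ConsensusCalls(StateCalls):
    """Majority-vote consensus across replicates."""

    n_replicates: int = 1
    n_ties: int = 0


@dataclass
class BorderSet:
    """PAD/non-PAD transition points.

    ``pad_side`` is ``'left'`` when the PAD lies on the lower-coordinate side
    of the border.
    """

    df: pd.DataFrame  # columns: chrom, pos, pad_side
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "pad_side"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"BorderSet needs columns {sorted(required)}")
        for chrom, grp in self.df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if pos.size > 1 and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: border positions not strictly increasing")
        self.df = self.df.reset_index(drop=True)

    def per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """chrom -> (positions, pad_is_left bool array)."""
        out = {}
        for chrom, grp in self.df.groupby("chrom", sort=False):
            out[str(chrom)] = (
                grp["pos"].to_numpy(np.int64),
                (grp["pad_side"] == "left").to_numpy(),
            )
        return out

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class DomainSet:
    """Alternating PAD / non-PAD intervals tiling the assessed span."""

    df: pd.DataFrame  # columns: chrom, start, end, label
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "label"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"DomainSet needs columns {sorted(required)}")
        for chrom, grp in self.df.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            lab = grp["label"].to_numpy()
            if np.any(s >= e):
                raise ValueError(f"{chrom}: empty domain")
            if s.size > 1:
                if np.any(e[:-1] != s[1:]):
                    raise ValueError(f"{chrom}: domains do not tile the span")
                if np.any(lab[:-1] == lab[1:]):
                    raise ValueError(f"{chrom}: adjacent domains share a label")
        self.df = self.df.reset_index(drop=True)

    def label_intervals(self, label: str) -> IntervalSet:
        sub = self.df[self.df["label"] == label]
        return IntervalSet(sub[["chrom", "start", "end"]].copy())

    def borders(self) -> BorderSet:
        rows = []
        for chrom, grp in self.df.groupby("chrom", sort=False):
            lab = grp["label"].to_numpy()
            starts = grp["start"].to_numpy(np.int64)
            for i in range(1, len(grp)):
                rows.append(
                    (chrom, int(starts[i]), "left" if lab[i - 1] == PAD else "right")
                )
        df = pd.DataFrame(rows, columns=["chrom", "pos", "pad_side"])
        return BorderSet(df, dict(self.chrom_lengths))

    def total_bp(self, label: str | None = None) -> int:
        sub = self.df if label is None else self.df[self.df["label"] == label]
        return int((sub["end"] - sub["start"]).sum())

    def __len__(self) -> int:
        return len(self.df)


def majority_vote(
    replicate_calls: list[StateCalls], pooled_calls: StateCalls | None = None
) -> ConsensusCalls:
    """Per-fragment-end majority vote across replicates.

    Exact ties (possible only with an even replicate count) are resolved by
    the call of the pooled virtual replicate at that position.
    """
    if not replicate_calls:
        raise ValueError("no replicates")
    ref = replicate_calls[0].fragends
    for rc in replicate_calls[1:]:
        if rc.fragends is not ref and rc.fragends != ref:
            raise ValueError("replicates are not aligned to the same map")
    n = len(replicate_calls)
    if n % 2 == 0 and pooled_calls is None:
        raise ValueError("even replicate count requires pooled_calls for tie-breaking")
    votes = np.sum([rc.is_pad.astype(np.int64) for rc in replicate_calls], axis=0)
    consensus = votes * 2 > n
    ties = votes * 2 == n
    n_ties = int(ties.sum())
    if n_ties:
        if pooled_calls.fragends is not ref and pooled_calls.fragends != ref:
            raise ValueError("pooled calls are not aligned to the same map")
        consensus[ties] = pooled_calls.is_pad[ties]
    return ConsensusCalls(ref, consensus, n_replicates=n, n_ties=n_ties)


def pool_replicates(tracks: list[CountTrack]) -> CountTrack:
    """Sum raw reads across replicates into the virtual pooled replicate."""
    if not tracks:
        raise ValueError("no tracks")
    ref = tracks[0].fragends
    for t in tracks[1:]:
        if t.fragends is not ref and t.fragends != ref:
            raise ValueError("tracks are not aligned to the same map")
    pooled = np.sum([t.values for t in tracks], axis=0)
    return CountTrack(ref, pooled, label="pooled")


def calls_to_domains(calls: StateCalls, fragends: FragmentEndMap | None = None) -> DomainSet:
    """Union runs of identical calls into domains; borders at midpoints.

    Interior boundaries sit at floor((end_i + start_{i+1}) / 2) for the last
    fragment end of one run and the first of the next; terminal domains
    extend to the first fragment-end start / last fragment-end end.
    """
    fragends = fragends or calls.fragends
    rows = []
    for chrom, lab in calls.per_chrom().items():
        if lab.size == 0:
            continue
        s = fragends.starts[chrom]
        e = fragends.ends[chrom]
        change = np.flatnonzero(lab[:-1] != lab[1:])  # run i ends at index change[i]
        cuts = (e[change] + s[change + 1]) // 2
        bounds = np.concatenate([[s[0]], cuts, [e[-1]]])
        run_starts = np.concatenate([[0], change + 1])
        for i, rs in enumerate(run_starts):
            rows.append(
                (chrom, int(bounds[i]), int(bounds[i + 1]), PAD if lab[rs] else NONPAD)
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return DomainSet(df, dict(fragends.chrom_lengths))


def domain_size_stats(
    domains: DomainSet, label: str = PAD, bin_edges: np.ndarray | None = None
) -> dict:
    """Count, bp-size quantiles and histogram of domains of one label."""
    sizes = (
        domains.df.loc[domains.df["label"] == label, "end"]
        - domains.df.loc[domains.df["label"] == label, "start"]
    ).to_numpy(float)
    out: dict = {"label": label, "count": int(sizes.size)}
    if sizes.size == 0:
        out.update({"median": None, "total_bp": 0, "histogram": None})
        return out
    out["median"] = float(np.median(sizes))
    out["total_bp"] = int(sizes.sum())
    out["quantiles"] = {
        q: float(np.quantile(sizes, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
    }
    if bin_edges is None:
        bin_edges = np.geomspace(max(sizes.min(), 1.0), sizes.max() + 1, 20)
    hist, edges = np.histogram(sizes, bins=bin_edges)
    out["histogram"] = {"counts": hist.tolist(), "edges": np.asarray(edges).tolist()}
    return out


# ---------------------------------------------------------------------------
# BED round-trip
# ---------------------------------------------------------------------------

def write_domains(domains: DomainSet, path) -> None:
    """Write a DomainSet as 4-column BED (name = PAD / nonPAD)."""
    with open(path, "w") as fh:
        for row in domains.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\n")


def read_domains(path, chrom_lengths: dict[str, int] | None = None) -> DomainSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return DomainSet(df, chrom_lengths or {})


def write_borders(borders: BorderSet, path) -> None:
    """Borders as BED: 1-bp intervals, orientation in the name field."""
    with open(path, "w") as fh:
        for row in borders.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\tPAD_{row.pad_side}\n")
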