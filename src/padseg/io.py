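"""Genomic containers and file I/O for the sat4C pipeline.

The coordinate system of the whole pipeline is the *fragment-end map*: the
ordered genomic positions of short sequences flanking primary restriction
sites (the "reduced genome" that 4C reads are mapped against). Everything
downstream — count tracks, windowed profiles, HSMM calls, domains — is indexed
by fragment end.

All coordinates are 0-based, half-open, matching BED/bedGraph conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import _intervals

__all__ = [
    "FragmentEndMap",
    "CountTrack",
    "IntervalSet",
    "ScoreTrack",
    "ParseError",
    "MapMismatchError",
    "read_fragend_counts",
    "read_bed",
    "read_bedgraph_scores",
    "write_bedgraph",
    "build_fragend_map",
    "iupac_to_regex",
]

# IUPAC nucleotide codes -> character classes (uppercase DNA alphabet)
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class ParseError(ValueError):
    """A track file line could not be parsed."""


class MapMismatchError(ValueError):
    """Records in a file do not match the fragment-end map."""


@dataclass
class FragmentEndMap:
    """Ordered fragment ends per chromosome.

    Parameters
    ----------
    starts, ends
        Mapping chromosome -> sorted int64 arrays of fragment-end intervals
        (0-based, half-open, non-overlapping).
    chrom_lengths
        Optional chromosome lengths in bp; required by operations that wrap
        coordinates (circular border shifts) or clip to chromosome bounds.
        Defaults to the last fragment end's ``end`` per chromosome.
    """

    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.starts:
            s = np.asarray(self.starts[chrom], dtype=np.int64)
            e = np.asarray(self.ends[chrom], dtype=np.int64)
            if s.shape != e.shape:
                raise ValueError(f"{chrom}: starts/ends length mismatch")
            if np.any(s >= e):
                raise ValueError(f"{chrom}: empty or inverted fragment end")
            if s.size > 1 and np.any(e[:-1] > s[1:]):
                raise ValueError(f"{chrom}: fragment ends overlap or are unsorted")
            self.starts[chrom] = s
            self.ends[chrom] = e
            length = self.chrom_lengths.get(chrom)
            if length is None:
                self.chrom_lengths[chrom] = int(e[-1]) if e.size else 0
            elif e.size and int(e[-1]) > length:
                raise ValueError(f"{chrom}: fragment end beyond chromosome length")

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in karyotype (insertion) order."""
        return list(self.starts)

    def n_ends(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.starts[chrom].size)
        return int(sum(v.size for v in self.starts.values()))

    def midpoints(self, chrom: str) -> np.ndarray:
        return (self.starts[chrom] + self.ends[chrom]) // 2

    def offsets(self) -> dict[str, int]:
        """Start offset of each chromosome in the genome-wide concatenation."""
        out, acc = {}, 0
        for chrom in self.chromosomes:
            out[chrom] = acc
            acc += self.starts[chrom].size
        return out

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, FragmentEndMap):
            return NotImplemented
        if self.chromosomes != other.chromosomes:
            return False
        return all(
            np.array_equal(self.starts[c], other.starts[c])
            and np.array_equal(self.ends[c], other.ends[c])
            for c in self.chromosomes
        )


@dataclass
class CountTrack:
    """Reads per fragment end for one experiment (one replicate)."""

    fragends: FragmentEndMap
    values: np.ndarray
    label: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.values.size != self.fragends.n_ends():
            raise ValueError(
                f"track length {self.values.size} != map size {self.fragends.n_ends()}"
            )
        if np.any(self.values < 0):
            raise ValueError("negative count values")

    def per_chrom(self) -> dict[str, np.ndarray]:
        out, pos = {}, 0
        for chrom in self.fragends.chromosomes:
            n = self.fragends.n_ends(chrom)
            out[chrom] = self.values[pos : pos + n]
            pos += n
        return out

    def total(self) -> float:
        return float(self.values.sum())

    def with_values(self, values: np.ndarray) -> "CountTrack":
        return CountTrack(self.fragends, values, self.label, self.replicate)


@dataclass
class IntervalSet:
    """Named genomic intervals (LADs, peaks, genes, ...)."""

    df: pd.DataFrame  # columns: chrom, start, end [, name, score]

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"IntervalSet needs columns {sorted(required)}")
        if len(self.df) and (self.df["start"] >= self.df["end"]).any():
            raise ValueError("interval with start >= end")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        names: Sequence[str] | None = None,
        scores: Sequence[float] | None = None,
    ) -> "IntervalSet":
        data = {"chrom": list(chroms), "start": list(starts), "end": list(ends)}
        if names is not None:
            data["name"] = list(names)
        if scores is not None:
            data["score"] = list(scores)
        return cls(pd.DataFrame(data))

    def per_chrom(self, merged: bool = True) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for chrom, grp in self.df.groupby("chrom", sort=False):
            s = grp["start"].to_numpy(dtype=np.int64)
            e = grp["end"].to_numpy(dtype=np.int64)
            if merged:
                s, e = _intervals.merge(s, e)
            else:
                order = np.argsort(s, kind="stable")
                s, e = s[order], e[order]
            out[str(chrom)] = (s, e)
        return out

    def total_bp(self) -> int:
        return sum(
            _intervals.total_bp(s, e) for s, e in self.per_chrom(merged=True).values()
        )

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ScoreTrack:
    """Scored genomic bins (directionality index, replication timing, ...)."""

    df: pd.DataFrame  # columns: chrom, start, end, value

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "value"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"ScoreTrack needs columns {sorted(required)}")
        if len(self.df) and not np.all(np.isfinite(self.df["value"].to_numpy(float))):
            raise ValueError("non-finite score value")
        self.df = self.df.reset_index(drop=True)

    def centers(self) -> pd.DataFrame:
        out = self.df.copy()
        out["center"] = (out["start"] + out["end"]) // 2
        return out

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# track reading / writing
# ---------------------------------------------------------------------------

def _parse_track_lines(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >=4 columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no records")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_fragend_counts(
    path: str | Path, fragends: FragmentEndMap | None = None
) -> CountTrack:
    """Read a 4-column chrom/start/end/count file as a CountTrack.

    When ``fragends`` is given every record must match one of its fragment
    ends exactly; otherwise the map is built from the records themselves.
    Records are sorted by (chrom, start); chromosome order is first-appearance
    order in the file when no map is given.
    """
    df = _parse_track_lines(path)
    chrom_order = list(dict.fromkeys(df["chrom"]))
    df = df.sort_values(["chrom", "start"], kind="stable", key=lambda col: (
        col.map({c: i for i, c in enumerate(chrom_order)}) if col.name == "chrom" else col
    ))
    if fragends is None:
        starts = {c: g["start"].to_numpy(np.int64) for c, g in df.groupby("chrom", sort=False)}
        ends = {c: g["end"].to_numpy(np.int64) for c, g in df.groupby("chrom", sort=False)}
        fragends = FragmentEndMap(starts, ends)
        values = df["value"].to_numpy(float)
    else:
        chunks = []
        seen = dict(iter(df.groupby("chrom", sort=False)))
        for chrom in fragends.chromosomes:
            if chrom not in seen:
                raise MapMismatchError(f"chromosome {chrom} missing from {path}")
            grp = seen.pop(chrom)
            s = grp["start"].to_numpy(np.int64)
            e = grp["end"].to_numpy(np.int64)
            ms, me = fragends.starts[chrom], fragends.ends[chrom]
            if s.size != ms.size or np.any(s != ms) or np.any(e != me):
                bad = 0
                if s.size == ms.size:
                    bad = int(np.flatnonzero((s != ms) | (e != me))[0])
                raise MapMismatchError(
                    f"{path}: record {chrom}:{int(s[min(bad, s.size - 1)])} does not "
                    "match the fragment-end map"
                )
            chunks.append(grp["value"].to_numpy(float))
        if seen:
            extra = next(iter(seen))
            raise MapMismatchError(f"{path}: chromosome {extra} not in the map")
        values = np.concatenate(chunks)
    if np.any(values < 0):
        raise ParseError(f"{path}: negative count")
    return CountTrack(fragends, values, label=Path(path).stem)


def read_bed(path: str | Path) -> IntervalSet:
    """Read a 3-6 column BED file."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4 and parts[4] != ".":
                row["score"] = float(parts[4])
            rows.append(row)
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
                       .dropna(axis=1, how="all")
                       if rows else pd.DataFrame(columns=["chrom", "start", "end"]))


def read_bedgraph_scores(path: str | Path) -> ScoreTrack:
    return ScoreTrack(_parse_track_lines(path))


def write_bedgraph(
    fragends: FragmentEndMap, values: np.ndarray, path: str | Path, fmt: str = "%.6g"
) -> None:
    """Write per-fragment-end values as bedGraph over the fragment-end intervals."""
    values = np.asarray(values)
    pos = 0
    with open(path, "w") as fh:
        for chrom in fragends.chromosomes:
            s, e = fragends.starts[chrom], fragends.ends[chrom]
            for i in range(s.size):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{fmt % values[pos + i]}\n")
            pos += s.size


# ---------------------------------------------------------------------------
# in-silico restriction digestion
# ---------------------------------------------------------------------------

def iupac_to_regex(motif: str) -> str:
    """Expand an IUPAC motif to a regex character-class pattern."""
    try:
        return "".join(_IUPAC[ch] for ch in motif.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in motif {motif!r}") from None


def _scan_motif(seq: str, motif: str) -> list[tuple[int, int]]:
    """All (start, end) occurrences of an IUPAC motif, overlapping allowed."""
    pat = re.compile(f"(?=({iupac_to_regex(motif)}))")
    return [(m.start(), m.start() + len(motif)) for m in pat.finditer(seq)]


def build_fragend_map(
    fasta: str | Path | Mapping[str, str],
    primary_motifs: Iterable[str] = ("RAATTY", "CAATTG"),
    flank_length: int = 50,
    both_strands: bool = False,
) -> FragmentEndMap:
    """Build the reduced-genome fragment-end map by in-silico digestion.

    For every primary-site occurrence two flanks of up to ``flank_length`` bp
    are emitted, one on each side of the recognition site, truncated at
    chromosome ends and at adjacent sites (so flanks never run into a
    neighbouring site). The default motifs are the ApoI (RAATTY) and MfeI
    (CAATTG) recognition sequences, which are strand-symmetric under IUPAC
    matching; ``both_strands`` additionally scans the reverse complement for
    asymmetric motifs.
    """
    if flank_length <= 0:
        raise ValueError("flank_length must be positive")
    motifs = list(primary_motifs)
    for m in motifs:
        iupac_to_regex(m)  # validate early
    if isinstance(fasta, (str, Path)):
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    else:
        records = {k: v.upper() for k, v in fasta.items()}

    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom, seq in records.items():
        L = len(seq)
        sites: set[tuple[int, int]] = set()
        for motif in motifs:
            sites.update(_scan_motif(seq, motif))
            if both_strands:
                rc = motif.translate(_COMPLEMENT)[::-1]
                if rc != motif:
                    sites.update(_scan_motif(seq, rc))
        ordered = sorted(sites)
        fe: list[tuple[int, int]] = []
        for i, (ms, me) in enumerate(ordered):
            prev_end = ordered[i - 1][1] if i > 0 else 0
            next_start = ordered[i + 1][0] if i + 1 < len(ordered) else L
            left = (max(prev_end, ms - flank_length), ms)
            right = (me, min(next_start, me + flank_length))
            for s, e in (left, right):
                if s < e:
                    fe.append((s, e))
        fe.sort()
        # collapse identical/overlapping flanks from overlapping site matches
        merged: list[list[int]] = []
        for s, e in fe:
            if merged and s < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
        ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)
        lengths[chrom] = L
    return FragmentEndMap(starts, ends, lengths)
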