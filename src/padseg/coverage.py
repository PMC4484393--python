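"""Normalized sat4C coverage profiles.

Raw per-fragment-end read counts are turned into smooth association profiles
in four steps: (1) cap the extreme top tail of counts (PCR-blowup guard),
(2) equalize sequencing depth across experiments, (3) average counts in a
running window of fragment ends per chromosome, (4) subtract the chromosome
mean. Profiles from several samples are made comparable by quantile
normalization of the profile matrix.

The domain-calling branch (:mod:`padseg.hsmm`) deliberately consumes raw
integer counts, not these profiles: the emission model is defined on count
categories per single fragment end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import CountTrack, FragmentEndMap

__all__ = [
    "Profile",
    "ProfileMatrix",
    "cap_counts",
    "depth_normalize",
    "running_window_profile",
    "mean_center",
    "quantile_normalize",
]

DEFAULT_CAP_QUANTILE = 0.99975
DEFAULT_WINDOW = 101


@dataclass
class Profile:
    """Windowed coverage values per fragment end."""

    fragends: FragmentEndMap
    values: np.ndarray
    window: int
    centered: bool = False
    quantile_normalized: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.fragends.n_ends():
            raise ValueError("profile length does not match the fragment-end map")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite profile value")

    def per_chrom(self) -> dict[str, np.ndarray]:
        out, pos = {}, 0
        for chrom in self.fragends.chromosomes:
            n = self.fragends.n_ends(chrom)
            out[chrom] = self.values[pos : pos + n]
            pos += n
        return out


@dataclass
class ProfileMatrix:
    """Fragment ends x samples matrix of profile values."""

    fragends: FragmentEndMap
    values: np.ndarray  # shape (n_ends, n_samples)
    labels: list[str]
    quantile_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.values.shape[0] != self.fragends.n_ends():
            raise ValueError("row count does not match the fragment-end map")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count does not match column count")

    @classmethod
    def from_profiles(cls, profiles: list[Profile]) -> "ProfileMatrix":
        if not profiles:
            raise ValueError("no profiles")
        ref = profiles[0].fragends
        for p in profiles[1:]:
            if p.fragends is not ref and p.fragends != ref:
                raise ValueError("profiles on different fragment-end maps")
        return cls(ref, np.column_stack([p.values for p in profiles]),
                   [p.label for p in profiles])


def cap_counts(track: CountTrack, upper_quantile: float = DEFAULT_CAP_QUANTILE) -> CountTrack:
    """Set the highest observed reads to the given per-experiment quantile.

    With the default 0.99975 the top 0.025% of values are clamped to the
    99.975% quantile. The quantile is nearest-rank (the order statistic at
    floor((n-1) q)) over the whole value vector, zeros included, which makes
    capping exactly idempotent; an interpolated quantile would drift
    downward on repeated application.
    """
    if not 0 < upper_quantile < 1:
        raise ValueError("upper_quantile must be in (0, 1)")
    if track.values.size == 0:
        raise ValueError("empty track")
    q = float(np.quantile(track.values, upper_quantile, method="lower"))
    return track.with_values(np.minimum(track.values, q))


def depth_normalize(
    tracks: list[CountTrack], target_total: float | str = "mean"
) -> list[CountTrack]:
    """Scale each track by a constant so all totals are equal.

    ``target_total`` is either a number or ``"mean"`` (mean of input totals).
    """
    if not tracks:
        raise ValueError("no tracks")
    totals = [t.total() for t in tracks]
    for t, tot in zip(tracks, totals):
        if tot <= 0:
            raise ValueError(f"track {t.label or '?'} has zero total; cannot depth-normalize")
    target = float(np.mean(totals)) if target_total == "mean" else float(target_total)
    return [t.with_values(t.values * (target / tot)) for t, tot in zip(tracks, totals)]


def running_window_profile(track: CountTrack, window: int = DEFAULT_WINDOW) -> Profile:
    """Mean count in a running window of ``window`` fragment ends.

    Computed per chromosome; edge positions use the truncated window (all
    available neighbours), so the profile is defined at every fragment end.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 3:
        raise ValueError("window must be >= 3")
    half = window // 2
    chunks = []
    for chrom, vals in track.per_chrom().items():
        n = vals.size
        if n == 0:
            chunks.append(vals)
            continue
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, n)
        chunks.append((csum[hi] - csum[lo]) / (hi - lo))
    return Profile(track.fragends, np.concatenate(chunks), window, label=track.label)


def mean_center(profile: Profile) -> Profile:
    """Subtract each chromosome's mean profile value (per-chromosome centering)."""
    chunks = [vals - vals.mean() if vals.size else vals
              for vals in profile.per_chrom().values()]
    return Profile(profile.fragends, np.concatenate(chunks), profile.window,
                   centered=True, quantile_normalized=profile.quantile_normalized,
                   label=profile.label)


def quantile_normalize(matrix: ProfileMatrix) -> ProfileMatrix:
    """Standard quantile normalization across samples.

    Each value is replaced by the across-column mean of values at its rank;
    ties receive the mean of the reference values over the tied rank range.
    Afterwards every column's sorted value vector equals the reference vector.
    """
    X = matrix.values
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    reference = np.sort(X, axis=0).mean(axis=1)
    # cumulative means of the reference support fractional (tied) ranks:
    # a value with average rank r over a tie-run [i..j] maps to
    # mean(reference[i..j]), which equals the difference of prefix sums.
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        rmin = rankdata(col, method="min").astype(np.int64) - 1
        rmax = rankdata(col, method="max").astype(np.int64)  # exclusive
        csum = np.concatenate([[0.0], np.cumsum(reference)])
        out[:, j] = (csum[rmax] - csum[rmin]) / (rmax - rmin)
    return ProfileMatrix(matrix.fragends, out, list(matrix.labels),
                         quantile_normalized=True)
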