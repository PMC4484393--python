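"""Synthetic sat4C data with known ground truth.

The generator emulates the statistical structure the segmentation model
assumes: irregularly spaced fragment ends along several chromosomes; a
two-state segmental truth with gamma-distributed sojourns (in fragment-end
units); state-conditional integer read counts — negative binomial by
default, capturing 4C overdispersion, or an exact-multinomial mode that
samples the 5 categories directly; several replicates sharing the truth but
with independent noise and per-replicate depth factors; and annotation
tracks (LAD-like intervals, a border-peaked directionality-index-like
track, scatterable point features) correlated with the truth to a
configurable degree.

All randomness flows from one master seed; per-stream seeds are derived by
stable hashing of (master seed, stream name, replicate), so adding streams
never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .domains import DomainSet, calls_to_domains
from .hsmm import CATEGORY_BOUNDS, N_CATEGORIES, StateCalls, discretize_sojourn
from .io import CountTrack, FragmentEndMap, IntervalSet, ScoreTrack

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_fragends",
    "simulate_truth",
    "simulate_counts",
    "simulate_annotations",
    "simulate_replicates",
    "nb_to_emission_row",
]

# A deliberately easy default regime: well-separated emission rows and long
# sojourns, the conditions under which segmentation accuracy is assessed.
DEFAULT_EMISSION = np.array([
    [0.60, 0.30, 0.09, 0.008, 0.002],   # state 0: non-PAD, low counts
    [0.03, 0.07, 0.30, 0.30, 0.30],     # state 1: PAD, high counts
])


@dataclass
class SimConfig:
    """Parameters of one synthetic study."""

    n_chromosomes: int = 10
    chromosome_lengths: list[int] | None = None  # bp; derived if None
    n_ends_per_chromosome: int = 2000
    spacing_mean: float = 1500.0  # bp between fragment-end starts
    spacing_sd: float = 750.0
    end_width: int = 50  # bp per fragment end
    emission: np.ndarray = field(default_factory=lambda: DEFAULT_EMISSION.copy())
    nb_mean: tuple[float, float] | None = None  # per-state NB mean (alt. to emission)
    nb_dispersion: float = 2.0  # NB size parameter (smaller = more overdispersed)
    sojourn_shape: tuple[float, float] = (4.0, 4.0)
    sojourn_scale: tuple[float, float] = (25.0, 25.0)  # mean sojourn 100 ends
    startprob: tuple[float, float] = (0.5, 0.5)
    n_replicates: int = 3
    depth_factors: list[float] | None = None  # default all 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mean <= 0:
            raise ValueError("spacing mean must be positive")
        self.emission = np.asarray(self.emission, dtype=float)
        if self.emission.shape != (2, N_CATEGORIES):
            raise ValueError("emission must be 2x5")
        if not np.allclose(self.emission.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("emission rows must sum to 1")
        if self.depth_factors is None:
            self.depth_factors = [1.0] * self.n_replicates
        if len(self.depth_factors) != self.n_replicates:
            raise ValueError("one depth factor per replicate")

    def rng(self, stream: str, replicate: int | None = None) -> np.random.Generator:
        """Independent generator for a named stream (stable across streams)."""
        parts = [self.seed, zlib.crc32(stream.encode())]
        if replicate is not None:
            parts.append(replicate)
        return np.random.default_rng(np.random.SeedSequence(parts))

    def effective_emission(self) -> np.ndarray:
        """The 2x5 category distribution the counts actually follow."""
        if self.nb_mean is None:
            return self.emission
        return np.vstack([
            nb_to_emission_row(self.nb_mean[s], self.nb_dispersion) for s in (0, 1)
        ])


@dataclass
class SimTruth:
    """Ground truth of one simulation."""

    fragends: FragmentEndMap
    labels: StateCalls  # True = PAD (state 1)
    domains: DomainSet


def nb_to_emission_row(mean: float, dispersion: float) -> np.ndarray:
    """Category masses implied by a negative binomial count distribution.

    ``dispersion`` is the NB size parameter r (variance = mean + mean^2/r).
    """
    p = dispersion / (dispersion + mean)
    cdf = stats.nbinom.cdf(np.concatenate([CATEGORY_BOUNDS - 1, [np.inf]]),
                           dispersion, p)
    row = np.diff(np.concatenate([[0.0], cdf]))
    return row / row.sum()


def simulate_fragends(config: SimConfig) -> FragmentEndMap:
    """Lay down fragment ends with positive random gaps along each chromosome."""
    rng = config.rng("fragends")
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        n = config.n_ends_per_chromosome
        if config.spacing_sd > 0:
            gaps = rng.gamma(
                (config.spacing_mean / config.spacing_sd) ** 2,
                config.spacing_sd**2 / config.spacing_mean,
                size=n,
            )
        else:
            gaps = np.full(n, config.spacing_mean)
        gaps = np.maximum(np.round(gaps), config.end_width + 1).astype(np.int64)
        s = np.cumsum(gaps) - gaps[0]
        e = s + config.end_width
        if config.chromosome_lengths is not None:
            L = int(config.chromosome_lengths[c])
            keep = e <= L
            s, e = s[keep], e[keep]
        else:
            L = int(e[-1]) if e.size else 0
        starts[chrom] = s
        ends[chrom] = e
        lengths[chrom] = L
    return FragmentEndMap(starts, ends, lengths)


def simulate_truth(fragends: FragmentEndMap, config: SimConfig) -> SimTruth:
    """Alternate the two states with discretized-gamma sojourn lengths."""
    rng = config.rng("truth")
    max_dur = max(
        int(np.ceil(stats.gamma.ppf(0.99999, a=config.sojourn_shape[s],
                                    scale=config.sojourn_scale[s])))
        for s in (0, 1)
    )
    pmfs = [
        discretize_sojourn(config.sojourn_shape[s], config.sojourn_scale[s], max_dur)
        for s in (0, 1)
    ]
    labels = []
    for chrom in fragends.chromosomes:
        n = fragends.n_ends(chrom)
        lab = np.empty(n, dtype=bool)
        state = int(rng.choice(2, p=config.startprob))
        pos = 0
        while pos < n:
            dur = int(rng.choice(np.arange(1, max_dur + 1), p=pmfs[state]))
            lab[pos : pos + dur] = bool(state)
            pos += dur
            state = 1 - state
        labels.append(lab)
    calls = StateCalls(fragends, np.concatenate(labels))
    return SimTruth(fragends, calls, calls_to_domains(calls, fragends))


def simulate_counts(truth: SimTruth, config: SimConfig, replicate: int = 0) -> CountTrack:
    """Integer counts per fragment end from the state-conditional distribution.

    Negative-binomial mode (``config.nb_mean`` set): counts drawn from
    NB(depth * mean_state, dispersion). Multinomial mode (default): a
    category is drawn from the state's emission row and a representative
    count from within the category is emitted (uniform over the category's
    count range; category 4 adds a geometric tail above 8). The depth factor
    scales NB means; in multinomial mode it is applied as a thinning /
    amplification of the representative counts only for factors != 1.
    """
    if replicate >= config.n_replicates:
        raise ValueError("replicate index out of range")
    rng = config.rng("counts", replicate)
    lab = truth.labels.is_pad
    n = lab.size
    depth = config.depth_factors[replicate]
    counts = np.zeros(n, dtype=np.int64)
    if config.nb_mean is not None:
        for s in (0, 1):
            mask = lab == bool(s)
            mu = config.nb_mean[s] * depth
            r = config.nb_dispersion
            p = r / (r + mu)
            counts[mask] = rng.negative_binomial(r, p, size=int(mask.sum()))
    else:
        cat_reps = [(0, 0), (1, 1), (2, 4), (5, 7), (8, 8)]
        for s in (0, 1):
            mask = lab == bool(s)
            m = int(mask.sum())
            cats = rng.choice(N_CATEGORIES, size=m, p=config.emission[s])
            vals = np.empty(m, dtype=np.int64)
            for c, (lo, hi) in enumerate(cat_reps):
                cmask = cats == c
                k = int(cmask.sum())
                if lo == hi:
                    vals[cmask] = lo
                else:
                    vals[cmask] = rng.integers(lo, hi + 1, size=k)
            tail = cats == 4
            vals[tail] += rng.geometric(0.5, size=int(tail.sum())) - 1
            if depth != 1.0:
                vals = rng.poisson(vals * depth)
            counts[mask] = vals
    return CountTrack(truth.fragends, counts, label="sim", replicate=f"rep{replicate}")


def simulate_replicates(truth: SimTruth, config: SimConfig) -> list[CountTrack]:
    return [simulate_counts(truth, config, r) for r in range(config.n_replicates)]


def simulate_annotations(
    truth: SimTruth,
    config: SimConfig,
    lad_jaccard: float = 0.8,
    di_bin: int = 40_000,
    di_bump_height: float = 2.0,
    di_bump_sd: float = 100_000.0,
    di_noise_sd: float = 0.5,
    n_features: int = 500,
    feature_enrichment: float = 1.0,
) -> dict:
    """Annotation tracks correlated with the truth.

    lads: LAD-like intervals = true PAD intervals with borders jittered by an
    amount scaled by (1 - lad_jaccard); at 1.0 they equal the PADs exactly.
    di: a 40-kb score track of Gaussian noise plus bumps of the given height
    near true PAD borders (height 0 gives a border-independent track).
    features: point-like intervals scattered with the given enrichment weight
    for PAD bp (1.0 = uniform by bp).
    """
    rng = config.rng("annotations")
    pads = truth.domains.label_intervals("PAD").df
    # LAD-like intervals: jitter PAD borders
    if lad_jaccard >= 1.0:
        lads = IntervalSet(pads[["chrom", "start", "end"]].copy())
    else:
        sizes = (pads["end"] - pads["start"]).to_numpy(float)
        scale = (1.0 - lad_jaccard) * np.median(sizes) / 2 if len(sizes) else 0.0
        rows = []
        for row in pads.itertuples(index=False):
            s = row.start + int(rng.normal(0, scale))
            e = row.end + int(rng.normal(0, scale))
            L = truth.fragends.chrom_lengths[row.chrom]
            s, e = max(0, s), min(L, e)
            if s < e:
                rows.append((row.chrom, s, e))
        lads = IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    # directionality-index-like track on fixed bins
    borders = truth.domains.borders().per_chrom()
    di_rows = []
    for chrom in truth.fragends.chromosomes:
        L = truth.fragends.chrom_lengths[chrom]
        starts = np.arange(0, L, di_bin, dtype=np.int64)
        ends = np.minimum(starts + di_bin, L)
        centers = (starts + ends) // 2
        noise = rng.normal(0, di_noise_sd, size=starts.size)
        bump = np.zeros(starts.size)
        if chrom in borders and di_bump_height != 0:
            bpos = borders[chrom][0]
            d = np.abs(centers[:, None] - bpos[None, :]).min(axis=1)
            bump = di_bump_height * np.exp(-0.5 * (d / di_bump_sd) ** 2)
        sign = rng.choice([-1.0, 1.0], size=starts.size)
        vals = sign * np.abs(noise + bump)
        for s, e, v in zip(starts, ends, vals):
            di_rows.append((chrom, int(s), int(e), float(v)))
    di = ScoreTrack(pd.DataFrame(di_rows, columns=["chrom", "start", "end", "value"]))

    # scattered point features, optionally enriched inside PADs
    per_label_weight = {True: feature_enrichment, False: 1.0}
    dom = truth.domains.df
    weights = (dom["end"] - dom["start"]).to_numpy(float) * np.array(
        [per_label_weight[l == "PAD"] for l in dom["label"]]
    )
    weights = weights / weights.sum()
    picks = rng.choice(len(dom), size=n_features, p=weights)
    f_rows = []
    for i in picks:
        row = dom.iloc[int(i)]
        pos = int(rng.integers(row["start"], row["end"]))
        f_rows.append((row["chrom"], pos, pos + 1))
    features = IntervalSet(
        pd.DataFrame(f_rows, columns=["chrom", "start", "end"]).sort_values(
            ["chrom", "start"], kind="stable"
        )
    )
    return {"lads": lads, "di": di, "features": features}
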