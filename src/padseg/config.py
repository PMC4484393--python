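"""End-to-end pipeline orchestration from a single YAML config.

Every tunable parameter lives in :class:`PipelineConfig` with the study's
standard value as its default; all randomness flows from the one master
seed. A run writes each stage's outputs plus a machine-readable manifest
(parameters, seeds, input checksums, package version). Reruns with the same
config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, borderstats, coverage, hsmm, overlap
from .domains import (calls_to_domains, domain_size_stats, majority_vote,
                      pool_replicates, write_borders, write_domains)
from .io import read_bed, read_bedgraph_scores, read_fragend_counts, write_bedgraph

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("padseg")


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the study's standard values."""

    counts: list[str] = field(default_factory=list)  # one path per replicate
    lads: str | None = None
    di: str | None = None
    outdir: str = "padseg_out"

    cap_quantile: float = 0.99975
    window: int = 101
    tol: float = 1e-6
    max_iter: int = 200
    seed: int = 0
    genome_bin: int = 20_000
    heatmap_distance_bin: int = 125_000
    di_distance_bin: int = 80_000
    trim: float = 0.05
    n_randomizations: int = 1000
    max_shift: int = 6_400_000
    quantile_lower: float = 0.05
    quantile_upper: float = 0.95
    max_border_distance: int = 2_000_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run profile -> fit/decode -> consensus -> domains -> border stats ->
    overlap on the configured inputs; returns the output directory."""
    # -- validation before any stage runs
    if not config.counts:
        raise ValueError("config.counts is empty")
    for p in list(config.counts) + [config.lads, config.di]:
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input does not exist: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {str(p): _sha256(p) for p in config.counts
                   + [x for x in (config.lads, config.di) if x]},
        "stages": [],
    }

    def stage_done(name: str, **info):
        log.info("stage %s complete", name)
        manifest["stages"].append({"name": name, **info})

    # -- load counts
    tracks = []
    fragends = None
    for p in config.counts:
        t = read_fragend_counts(p, fragends)
        fragends = t.fragends
        tracks.append(t)
    stage_done("load", n_replicates=len(tracks), n_fragends=fragends.n_ends())

    # -- profiles
    capped = [coverage.cap_counts(t, config.cap_quantile) for t in tracks]
    depth = coverage.depth_normalize(capped)
    profiles = [
        coverage.mean_center(coverage.running_window_profile(t, config.window))
        for t in depth
    ]
    for i, prof in enumerate(profiles):
        write_bedgraph(fragends, prof.values, outdir / f"rep{i + 1}.profile.bedgraph")
    if len(profiles) >= 2:
        qn = coverage.quantile_normalize(coverage.ProfileMatrix.from_profiles(profiles))
        for i in range(qn.values.shape[1]):
            write_bedgraph(fragends, qn.values[:, i],
                           outdir / f"rep{i + 1}.profile.qnorm.bedgraph")
    stage_done("profile", window=config.window, cap=config.cap_quantile)

    # -- fit & decode per replicate
    calls = []
    for i, t in enumerate(tracks):
        seq = hsmm.bin_counts(t)
        fit = hsmm.em_fit(seq, tol=config.tol, max_iter=config.max_iter,
                          seed=config.seed)
        with open(outdir / f"rep{i + 1}.model.json", "w") as fh:
            json.dump(fit.model.to_dict(), fh, indent=1, sort_keys=True)
        sc = hsmm.decode(fit.model, seq)
        calls.append(sc)
        write_bedgraph(fragends, sc.is_pad.astype(float),
                       outdir / f"rep{i + 1}.calls.bedgraph", fmt="%d")
    stage_done("fit_decode", n_models=len(calls))

    # -- consensus; the pooled virtual replicate only with an even count
    pooled_calls = None
    if len(tracks) % 2 == 0:
        pooled = pool_replicates(tracks)
        pseq = hsmm.bin_counts(pooled)
        pfit = hsmm.em_fit(pseq, tol=config.tol, max_iter=config.max_iter,
                           seed=config.seed)
        pooled_calls = hsmm.decode(pfit.model, pseq)
    consensus = majority_vote(calls, pooled_calls)
    write_bedgraph(fragends, consensus.is_pad.astype(float),
                   outdir / "consensus.calls.bedgraph", fmt="%d")
    doms = calls_to_domains(consensus, fragends)
    write_domains(doms, outdir / "domains.bed")
    borders = doms.borders()
    write_borders(borders, outdir / "borders.bed")
    stats = {lab: domain_size_stats(doms, lab) for lab in ("PAD", "nonPAD")}
    with open(outdir / "domain_stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
    stage_done("domains", n_pads=stats["PAD"]["count"], n_ties=consensus.n_ties)

    # -- border statistics (directionality-index style curves)
    if config.di:
        di = read_bedgraph_scores(config.di)
        curve = borderstats.border_profile(
            di, borders, bin_width=config.di_distance_bin,
            aggregate="trimmed_mean", trim=config.trim,
            max_distance=config.max_border_distance, absolute=True,
        )
        curve.to_frame().to_csv(outdir / "di_border_profile.tsv", sep="\t",
                                index=False, float_format="%.6g")
        rand = borderstats.circular_shift_borders(
            borders, max_shift=config.max_shift,
            n_iter=config.n_randomizations, seed=config.seed,
        )
        acc = []
        for bset in rand:
            c = borderstats.border_profile(
                di, bset, bin_width=config.di_distance_bin,
                aggregate="trimmed_mean", trim=config.trim,
                max_distance=config.max_border_distance, absolute=True,
            )
            acc.append(c.values)
        rand_curve = borderstats.DistanceBinnedCurve(
            curve.edges, _nanmean_columns(np.vstack(acc)),
            np.full(curve.n.size, len(rand)), kind=curve.kind,
        )
        rand_curve.to_frame().to_csv(outdir / "di_border_profile.randomized.tsv",
                                     sep="\t", index=False, float_format="%.6g")
        stage_done("borderstats", n_randomizations=config.n_randomizations)

    # -- overlap with LADs + circular permutation null
    if config.lads:
        lads = read_bed(config.lads)
        obs = overlap.genomic_overlap(doms, lads)
        null = overlap.circular_permutation_null(
            consensus, fragends, lads,
            n_iter=config.n_randomizations, seed=config.seed,
            quantile_pair=(config.quantile_lower, config.quantile_upper),
        )
        result = {
            "observed_bp": obs.bp,
            "observed_percent_of_pads": obs.percent,
            "null_mean_bp": null.mean,
            "null_lower_bp": null.lower,
            "null_upper_bp": null.upper,
            "quantile_pair": list(null.quantile_pair),
            "n_iter": int(null.values.size),
            "inside_envelope": bool(null.observed_inside_envelope()),
        }
        with open(outdir / "lad_overlap.json", "w") as fh:
            json.dump(result, fh, indent=1, sort_keys=True)
        stage_done("overlap", observed_bp=obs.bp)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir


def _nanmean_columns(stack: "np.ndarray") -> "np.ndarray":
    """Column means ignoring NaN; all-NaN columns stay NaN without warning."""
    counts = np.sum(np.isfinite(stack), axis=0)
    sums = np.nansum(stack, axis=0)
    out = np.full(stack.shape[1], np.nan)
    ok = counts > 0
    out[ok] = sums[ok] / counts[ok]
    return out
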