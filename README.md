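# padseg

Genome segmentation into **pericentromere-associated domains (PADs)** from
sat4C fragment-end read counts.

In mouse nuclei, megabase arrays of pericentromeric major satellite repeats
from different chromosomes cluster into chromocenters. sat4C — a modified 4C
(circular chromosome conformation capture) assay that uses the major
satellite repeat as a collective viewpoint — measures, for every restriction
fragment end in a "reduced genome", how often that locus contacts
pericentromeric satellite DNA. `padseg` turns those per-fragment-end read
counts into satellite-association profiles and calls the large alternating
domains of high and low association (PADs and non-PADs), with the statistics
needed to relate the calls to other chromatin annotations (LADs, TADs, DNase
hotspots, expression).

Intended users: computational biologists analysing 4C-style count tracks who
need a reproducible, testable domain caller with an explicit generative
model, plus a synthetic-data generator so every stage can be validated
against known ground truth.

## The model

Counts per fragment end are binned into five categories
([0], [1], [2–4], [5–7], [>7] reads). A chromosome is modelled by a
**two-state explicit-duration hidden semi-Markov model**:

* hidden states s ∈ {non-PAD, PAD} strictly alternate (no self-transitions),
* a visit to state *s* lasts *u* fragment ends with
  u ~ Gamma(α_s, θ_s), discretized to unit steps and truncated at *M*,
* while in state *s*, each fragment end emits category *c* independently
  with multinomial probability B\[s, c\],
* initial state probabilities π.

Parameters (B, α, θ, π) are estimated per replicate by EM with
explicit-duration forward–backward recursions; segmentations come from
explicit-duration Viterbi (contiguous by construction) or smoothed posterior
argmax. Replicates are combined by majority vote, with a "virtual replicate"
decoded from pooled reads breaking exact ties. Domain borders are the
midpoints between adjacent fragment ends with discordant calls.

Around the segmentation, the package provides

* the profile branch: top-tail capping (99.975% quantile), sequencing-depth
  equalization, running-window coverage (101 fragment ends), per-chromosome
  mean centering, and cross-sample quantile normalization;
* border-aligned statistics: features aggregated in 20-kb genome bins and
  averaged by signed distance to the nearest PAD border (125-kb distance
  bins for feature heatmaps; 80-kb bins with a 5% trimmed mean of the
  absolute Hi-C directionality index), with a circular border-shift null
  (uniform shifts up to 6.4 Mb, 1000 sets);
* overlap statistics: bp overlap of PADs with interval annotations, with a
  circular-permutation null that rotates the genome-wide call vector by a
  random offset k ∈ \[1..n\] (1000 rotations, 5%/95% envelope), pairwise
  cross-tissue PAD overlap matrices, and constitutive/facultative PAD
  classification;
* a synthetic-data module generating fragment-end maps, segmental ground
  truth with gamma sojourns, replicate count tracks (negative-binomial or
  exact-multinomial emissions), and truth-correlated annotation tracks.

## Worked example

Simulate a 4-chromosome study with known truth, fit each replicate, decode,
and build consensus domains:

```python
import numpy as np
from padseg.simulate import (SimConfig, simulate_fragends, simulate_truth,
                             simulate_replicates)
from padseg.hsmm import bin_counts, em_fit, decode
from padseg.domains import majority_vote, calls_to_domains, domain_size_stats

cfg = SimConfig(n_chromosomes=4, n_ends_per_chromosome=1000, seed=7)
fragends = simulate_fragends(cfg)
truth = simulate_truth(fragends, cfg)
tracks = simulate_replicates(truth, cfg)

calls = []
for track in tracks:
    seq = bin_counts(track)
    fit = em_fit(seq, tol=1e-6, max_iter=200, seed=7)
    calls.append(decode(fit.model, seq))

consensus = majority_vote(calls)
domains = calls_to_domains(consensus, fragends)
stats = domain_size_stats(domains, "PAD")
accuracy = (consensus.is_pad == truth.labels.is_pad).mean()
print(f"{stats['count']} PADs, median size {stats['median'] / 1e3:.0f} kb, "
      f"per-fragment-end accuracy {100 * accuracy:.1f}%")
```

Output:

```
19 PADs, median size 130 kb, per-fragment-end accuracy 100.0%
```

For the first replicate the fitted model prints

```
replicate 1: converged after 11 EM iterations, log-likelihood -4739.2
fitted emission rows (non-PAD, PAD):
[[0.602 0.3   0.089 0.009 0.001]
 [0.027 0.075 0.296 0.3   0.302]]
fitted mean sojourns: 105.4 and 98.9 fragment ends
```

against simulated truth rows (0.60, 0.30, 0.09, 0.008, 0.002) /
(0.03, 0.07, 0.30, 0.30, 0.30) and a true mean sojourn of 100 fragment ends:
the emission rows are recovered to about ±0.01 and the sojourn means to a
few percent, and the consensus segmentation reproduces the simulated PAD
layout essentially exactly — the regime a well-powered sat4C experiment is
designed to reach.

The same pipeline runs from the shell:

```sh
padseg simulate --outdir sim/ --seed 7
padseg run --config study.yaml        # profiles, models, calls, domains,
                                      # border curves, overlap nulls, manifest
```

`HSMMSegmenter` is a scikit-learn-style estimator (`fit`, `predict`,
`predict_proba`, `get_params`/`set_params`), so it composes with sklearn
tooling; `em_fit`/`decode` are thin functional wrappers over it.

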