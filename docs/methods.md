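# Methods

## Coordinate system and the fragment-end map

All computation is indexed by *fragment ends*: short sequences flanking
primary restriction sites, the mapping units of 4C-style assays. The map
builder performs an in-silico digestion of a genome FASTA: every
forward-strand occurrence of the primary-site motifs (defaults ApoI =
`RAATTY`, MfeI = `CAATTG`, both strand-symmetric under IUPAC matching; a
`both_strands` flag covers asymmetric motifs) yields two flanks of up to
`flank_length` bp, truncated at chromosome ends and at neighbouring sites so
flanks never cover another site; overlapping flanks from overlapping motif
matches are merged. Coordinates are 0-based half-open throughout, matching
BED/bedGraph. The secondary digestion steps of the wet protocol (NlaIII,
AcuI) shape library construction, not coordinates, and are ignored here.
`flank_length` has no canonical value and is an explicit parameter
(default 50 bp).

## Profile branch

The profile branch summarizes association strength for visualization and
cross-sample comparison; the segmentation branch (below) never consumes it.

1. **Capping.** Per experiment, counts above the 99.975% quantile are set to
   that quantile (guards against PCR blow-ups). The quantile is
   *nearest-rank* (the order statistic at floor((n−1)·q)): with an
   interpolated quantile the cap value mixes an order statistic with an
   already-capped neighbour and drifts downward on repeated application,
   whereas the nearest-rank cap is exactly idempotent.
2. **Depth normalization.** Each track is scaled by one constant so all
   totals equal the mean input total (or an explicit target).
3. **Running window.** Mean count in a window of 101 fragment ends, per
   chromosome, with truncated windows at chromosome edges so the profile is
   defined at every fragment end and stays on the same index set as the
   per-fragment-end domain calls. Windows never cross chromosomes.
4. **Mean centering.** The chromosome-wide mean is subtracted per
   chromosome (a visualization aid; values above/below 0 do not by
   themselves mean associated/unassociated).
5. **Quantile normalization** across samples: each value is replaced by the
   across-column mean of values at its rank; ties receive the mean of the
   reference values over the tied rank range, so every column's sorted
   vector equals the common reference afterwards.

Capping precedes depth normalization, and quantile normalization applies to
the windowed, mean-centered profiles; both orderings follow the processing
sequence the profiles are defined by.

## Segmentation: two-state explicit-duration HSMM

Raw integer counts per fragment end are binned into five categories —
[0], [1], [2–4], [5–7], [>7] reads. Binning is deliberately performed on raw
counts (fractional, normalized values have no multinomial interpretation); a
pooled "virtual replicate" is binned the same way after summing replicate
counts.

The generative model per chromosome: hidden states 0/1 strictly alternate;
a visit to state *s* lasts *u* fragment ends with probability proportional
to F(u) − F(u−1), where F is the Gamma(α_s, θ_s) CDF, truncated at *M* and
renormalized; every fragment end in the visit emits its category from the
multinomial row B[s]. Chromosomes of one replicate are independent
observation sequences sharing parameters (the natural reading of a
genome-wide fit; per-chromosome fits would leave short chromosomes badly
determined). First and last segments are treated as ordinary (uncensored)
sojourns by default; duration censoring at chromosome ends is available but
off, keeping the likelihood simple.

**E-step.** Explicit-duration forward–backward over segment endpoints in
log space. Segment emission products use prefix sums of log-emissions;
log(0) is replaced by a large finite negative sentinel (−1e15) so the
prefix-sum subtraction never produces NaN, and any total below −1e13 is
treated as a zero-probability sequence (reported with a pointer to the
emission floor). Per-position state occupancies are accumulated by a
telescoping recursion over segment-start and segment-end posteriors; they
sum to 1 at every position to 1e-10.

**M-step.** Emission rows and initial probabilities update in closed form
from expected counts. Emission probabilities are floored at 1e-6 and
renormalized to avoid zero-probability lockout. Gamma sojourn parameters
update by method of moments on the expected duration mean and variance
(closed form, no iteration). Because moment matching does not maximize the
expected duration log-likelihood Σ_u η_s(u) log d_s(u), the candidate is
accepted only if it does not lower that objective; if it does, the objective
is maximized directly (Nelder-Mead over log-parameters, started at the
moment estimate), and the previous parameters are retained only when even
that fails. This keeps the convenient closed-form update on essentially
every iteration while preserving EM's monotone log-likelihood, including
from poor initializations.

**Truncation.** M is the smallest duration whose gamma CDF reaches 0.999 at
the current parameters, recomputed each iteration but never decreased
(successive log-likelihoods then refer to nested model families and the
monotone trace remains meaningful), capped at 5,000 fragment ends and at
the longest sequence.

**Initialization** is deterministic: category codes are smoothed with a
short running mean (11 ends), thresholded at their median; the two sides
seed the emission rows (with Laplace smoothing), the run lengths of the
thresholding seed the gamma parameters by moments, and the first-position
labels seed π. A `random_state` parameter is recorded for provenance.

**Convergence** is declared when the relative log-likelihood improvement
falls below `tol` (default 1e-6) within `max_iter` (default 200). If an
iteration's log-likelihood regresses — possible only through sub-tolerance
numerical noise from the emission floor — the previous iterate is restored
and the fit reported converged, so the recorded trace is non-decreasing.

**Decoding.** Explicit-duration Viterbi is the default (domain calls should
be contiguous, which Viterbi guarantees given the duration model); smoothed
posterior argmax is available. Ties break toward the lower-indexed state
and, through first-argmax over durations, toward shorter segments — fixed
and documented so outputs are reproducible. The state with the greater
expected emitted category is labeled PAD, making labels stable across
initializations.

## Consensus, domains, borders

Per-tissue calls are the majority vote across replicates; an exact tie
(even replicate counts) is resolved by the call of the virtual replicate
decoded from pooled reads, computed lazily only when ties exist. Runs of
identical consensus calls become domains; interior boundaries sit at
floor((end_i + start_{i+1})/2) between the last fragment end of one run and
the first of the next (bp midpoint; index-space midpoints would ignore the
irregular spacing), and terminal domains extend to the fragment-end span of
the chromosome, not its full length — regions outside any fragment end
carry no data and are left unassessed.

## Border-aligned statistics

The genome is tiled into consecutive non-overlapping bins (20 kb default;
the last bin per chromosome is shorter). Interval features aggregate as the
fraction of bin bp covered (0 where uncovered); scored features as the mean
of overlapping records (missing where none). Each bin center gets a signed
distance to the nearest PAD border — negative on the PAD-interior side, so
left and right borders superimpose with PAD interiors aligned — and values
are aggregated within fixed distance bins (125 kb for feature heatmaps,
min–max normalized per feature row with degenerate rows mapping to 0; 80 kb
with a 5% trimmed mean of absolute values for directionality-index
amplitude curves). The trimmed mean drops floor(trim·n) values from each
tail (scipy's convention).

The border null shifts all borders of a chromosome by one uniform draw from
[0, max_shift) (default 6.4 Mb), modulo the chromosome length, per
iteration (default 1000): one shift per chromosome rather than per border,
preserving inter-border spacing, which is what makes the null conservative
for spatially autocorrelated tracks. Exact rotation-invariance of averaged
randomized curves holds when every rotation is reachable; the flatness
property test therefore shifts over the full chromosome length, while the
pipeline default keeps the 6.4 Mb scale appropriate to real chromosome
sizes.

## Overlap statistics and the circular-permutation null

PAD–annotation overlap is reported in bp and as a percentage of a stated
denominator (PAD bp, or assembled genome bp). The significance null
concatenates the per-fragment-end calls of all chromosomes (karyotype
order, fixed) into one vector of length n, rotates it by k drawn uniformly
from [1..n] per iteration, reassigns the rotated calls to the original
fragment-end positions, rebuilds domains, and records the overlap; rotated
calls deliberately cross chromosome boundaries, which is what concatenation
implies, and k = n reproduces the observed overlap exactly. The envelope is
the 5%/95% quantile pair by default (configurable — published figure
captions sometimes describe the same construction as a 99% interval).
Pairwise cross-tissue overlap matrices use the column tissue's PAD bp as
denominator (diagonal 100). Constitutive PADs are the intersection of PAD
intervals across all tissues; tissue-specific PADs intersect one tissue's
PADs with another's non-PADs. Features are assigned to domains by midpoint
(a bp-weighted mode exists behind a flag); top-N selection by score (e.g.
top 2000 expressed genes) is a caller-side filter utility.

## Synthetic data

The generator emulates exactly the structure the model assumes, so
recovery tests are well-posed: fragment ends laid down by positive gamma
gaps (mean 1,500 bp, SD 750 bp, 50-bp ends — the scale at which 101
fragment ends span roughly the observed few-hundred-kb windows); segmental
truth by alternating discretized-gamma sojourns; counts per fragment end
from the state-conditional distribution — either exact multinomial over
the five categories with a representative count drawn inside the category
(geometric tail above 8), or negative binomial (size parameter 2 by
default, capturing 4C overdispersion) with a utility converting NB
parameters to the implied category masses for oracle comparisons. Replicate
depth factors scale NB means, or thin/amplify multinomial counts via a
Poisson step. Annotations: LAD-like intervals are truth PADs with borders
jittered by an amount scaled by (1 − agreement), a directionality-index-like
40-kb track is Gaussian noise plus Gaussian bumps at true borders, and
point features scatter with a configurable PAD enrichment weight.

The default study regime — 10 chromosomes × 2,000 fragment ends, 3
replicates, emission rows (0.60, 0.30, 0.09, 0.008, 0.002) and (0.03, 0.07,
0.30, 0.30, 0.30) (Bhattacharyya distance ≈ 0.66), gamma sojourns with
shape 4 and scale 25 (mean 100 fragment ends) — is the well-separated
regime in which segmentation accuracy is assessed; it represents a
well-powered experiment, not a hard case.

What the simulations do *not* emulate: mappability and GC bias along the
genome, PCR duplication structure beyond a capped top tail,
distance-to-viewpoint decay, inter-replicate correlation beyond the shared
truth, or copy-number variation. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the stated model,
not robustness to every artifact of real sat4C libraries.

One master seed drives everything; per-stream generators derive from
(seed, CRC32(stream name), replicate) via numpy SeedSequence, so adding a
stream never perturbs existing ones and all outputs are bit-reproducible.

## Problem sizes and defaults

Library defaults mirror the study's standard parameter values (cap
quantile 0.99975, window 101, EM tol 1e-6 / max_iter 200, 20-kb genome
bins, 125-kb and 80-kb distance bins, 5% trim, 1000 randomizations, 6.4-Mb
max shift, 5%/95% envelope), all overridable in one `PipelineConfig` and
echoed into the run manifest together with input checksums and the package
version. The test suite and the acceptance script size their simulations to
what the properties need: study-scale recovery uses the full 10 × 2,000-end
regime; EM sanity checks run 50 smaller datasets (2 × 300 ends) across
randomized identifiable regimes; null-model calibration uses 100
independent rounds of 3 × 400 ends with 200 rotations each, enough to
estimate envelope coverage to a few percent.

## Known limitations

* Exactly two states; no sub-classification of PAD strength.
* Durations are gamma; multimodal sojourn structure would be mis-fit.
* The strict-alternation model has no "unmappable" state; assay gaps are
  simply absent fragment ends, which lengthens apparent sojourns across
  deserts.
* The circular rotation null conditions on the observed run-length
  structure; it does not model replicate-level variance of the calls.
* Emission identifiability requires the two states to differ in category
  usage; the fit flags (`identifiable_ = False`) but does not refuse
  degenerate data.
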