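# Methods

## Model and assumptions

`popmatch` treats the per-congener concentration (pg/g) and TEQ (pg-TEQ/g)
vectors of a sample as a contamination fingerprint. The working assumptions
are those of receptor-style pattern matching:

* a source's congener pattern is approximately preserved when the
  contamination transfers into food, up to multiplicative noise and
  background — differential absorption, metabolism and excretion across
  congeners are *not* modelled (transfer rates can be expressed manually as
  per-congener weights);
* measurement background is congener-specific and stationary, so it can be
  estimated from a collection of blank samples;
* samples are compared only over congeners quantified in every sample
  involved ("common congeners"); congeners missing from any sample are
  dropped with a warning rather than imputed as zero, since absence from a
  file means "not measured", not "not detected".

## Preprocessing

**Censoring.** For each congener, the expected detection error is
mean + `censor_multiplier` · SD over the blank collection (default
multiplier 2; sample SD with the n−1 denominator, the standard choice for QC
data). Values below the threshold are set to zero; values above it have the
threshold subtracted. Concentration and TEQ are censored independently
against thresholds fit from blank concentrations and blank TEQs
respectively, not by scaling the concentration threshold through the TEF.
Censoring is deliberately non-idempotent (a second pass would subtract the
detection error again), so profiles carry a flag and the pipeline refuses to
censor twice. Censoring is applied to the contaminated sample as well as to
the candidates (`apply_censor_to_target`, default true) so the score stays
symmetric in its inputs.

**Normalization.** Each censored pattern is divided by its maximum value.
A fully censored (all-zero) pattern normalizes to all zeros rather than
raising on 0/0; downstream, two such patterns score 1, which is the desired
reading — neither sample shows anything above blank noise, so nothing
distinguishes them.

## The similarity score

For normalized patterns c, p ∈ [0, 1]ⁿ, weights wᵢ ≥ 0 (not all zero) and
adjustment a > 0:

S = Σᵢ [ wᵢ(cᵢ + pᵢ + a) / Σⱼ wⱼ(cⱼ + pⱼ + a) ] · [ 2/(1 + |cᵢ − pᵢ|) − 1 ]

Properties (all enforced by tests): S ∈ [0, 1]; S(x, x) = 1; S symmetric;
each agreement factor is non-increasing in |cᵢ − pᵢ|. The prefactors are a
convex combination, so high-level congeners dominate while the additive a
keeps low-level and censored congeners contributing.

**Denominator convention.** With the weights in the denominator (the
default), the prefactors sum to exactly 1 for *any* valid weight vector, so
focusing on a congener subset via 0/1 weights still gives S(x, x) = 1. With
an unweighted denominator (`strict_eq2_denominator`), down-weighting
congeners caps self-similarity below 1, and weights above 1 can push the
score above 1; that mode is provided for comparability but is only bounded
for weights in [0, 1]. The weighted denominator is the package default
because it is the only reading under which the documented focus-weighting
behaviour (duplicates scoring 1 under congener subsets) holds.

**Adjustment constant.** Default a = 0.2566, the mean blank congener
concentration of the reference laboratory's 100-blank collection. When a
blank collection is supplied, a is recomputed as the grand mean of all blank
concentrations over congeners and samples; a config/CLI override takes
precedence over both. The constant is treated as a dimensionless additive
smoothing term added to normalized values, exactly as the score is defined —
its provenance on the raw pg/g scale is noted, but the formula adds it on
the normalized scale.

**Numerics.** The score is computed vectorized and verified against an
independent scalar loop at 1e-12. The exact value lies in [0, 1] but the
floating-point dot product can overshoot either bound by an ulp, so the
default-mode result is clamped to [0, 1] (strict mode returns the raw
value). Reports round scores to 4 decimals; full precision is kept
internally.

## Ranking

Four methods: `teq`, `concentration`, `weighted` (convex combination of the
two scores after normalizing the two weights to sum to 1) and `consensus`
(intersect the top-n TEQ and top-n concentration lists, order by mean
score). Default n = 5. Ties break by ascending candidate id so rankings are
deterministic and permutation-invariant. A consensus intersection smaller
than n is returned as-is with a warning — padding would fabricate consensus;
disjoint lists yield an empty table.

## Synthetic scenarios

Real regulatory data are confidential, so tests and examples run on
synthetic scenarios. Defaults, chosen once to mirror the reference setting:

| parameter | default | meaning |
|---|---|---|
| panel | 20 congeners | 7 dioxins, 10 furans, 3 dl-PCBs |
| `n_blanks` | 100 | blank collection size |
| `blank_mean`, `blank_sd` | 0.25, 0.05 pg/g | blank noise level; puts the fitted adjustment near the canonical 0.2566 and the blank maxima near the ~0.33 pg/g scale seen in practice |
| `n_sources` | 11 | candidates, one of which is the true source |
| `source_magnitude` | 50 pg/g | max congener of a source, two orders above blank noise |
| `pattern_sigma` | 1.5 | log-scale spread making patterns distinctive |
| `transfer_fraction`, `transfer_cv` | 0.5, 0.2 | source-to-food carry-over and multiplicative lognormal transfer noise |
| `duplicate_cv` | 0.05 | duplicate analytical error |

Blank values are normal, truncated at zero (at these settings truncation is
a 5-sigma event, so the configured mean is effectively exact). Transfer and
duplicate noise are unit-mean lognormal, emulating proportional analytical
error while preserving the pattern. All draws flow from one
`numpy.random.default_rng(seed)`, so written fixtures are byte-identical
across runs.

What passing synthetic tests do **not** show about real data: congener
patterns that genuinely change through the food chain, correlated noise
across congeners, batch effects or drift in blanks, and candidate sets whose
decoys are themselves related to the true source — all of these make the
real problem harder than the simulated one.

## Degenerate inputs and edge cases

* All-zero weight vectors, negative values, mismatched congener orders and
  empty congener intersections raise validation errors naming the sample or
  congener.
* Non-detects (`ND`, empty cells) parse to 0.0.
* Congener names are canonicalized (uppercase, collapsed whitespace, unified
  dashes, no spaces around `-`/`,`) so lab spelling variants match by name;
  matching by row position is not supported.
* Fewer than 2 blanks is an error (the SD is undefined).
* PCA projection centers but does not re-scale the normalized pattern matrix
  (patterns already share the [0, 1] scale) and requires ≥ 3 profiles.

## Problem sizes

The test suite and the acceptance script run the score-bound experiment at
10,000 random 20-congener pairs, the oracle comparison at 1,000 pairs, the
consensus-oracle check at 100 random candidate sets, and the source-recovery
experiment at 100 seeded replicates of the default 11-candidate scenario —
sizes at which every check completes in seconds on one CPU.

## Known limitations

* The score compares patterns, not absolute levels; a candidate with the
  right pattern at the wrong magnitude still scores high by design.
* Top-ranked candidates are suggestions for investigation, not attributions:
  multiple or mixed sources, and pattern drift through the food chain, can
  put the wrong candidate first.
* The GUI of the original workflow is replaced by the `popmatch` CLI
  (`rank`, `inspect`, `simulate`); no interactive use or sample database is
  provided.
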