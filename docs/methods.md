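# Methods

## Data model and assumptions

The analysis targets protein-level reporter-ion intensity tables from
multiplexed isobaric-labeling (iTRAQ 6-plex) experiments. Its validity
rests on three assumptions:

1. **Identical blocked design across batches.** Every batch carries the
   same group composition (2 samples from each of 3 groups), with channels
   assigned randomly within the batch. Group-vs-batch confounding is then
   impossible by construction, and per-batch effects are shared nuisance
   factors rather than biases.
2. **Equal loading within a batch**, up to a per-channel multiplicative
   factor that the correction step removes.
3. **Most proteins are not differentially expressed**, so the expected
   mean share of every channel is 100/6 % and the comparison-wise mean
   log2 ratio is a valid centering constant.

Missingness is modeled — and handled — at the protein-per-batch level: a
protein not identified in a batch has no reporter ions in any of that
batch's channels. Cells are excluded pairwise downstream; nothing is
imputed.

## Normalization

Within-protein normalization divides each intensity by the protein's
channel sum (×100). This is exact cancellation, not an estimate: any
factor common to the six channels of a protein's row — ionization
efficiency, batch-wise abundance offsets, identification depth — drops
out. The equal-loading correction then rescales each channel by
`(100/6) / (channel mean over observed proteins)`. It is a single
multiplicative pass; rows are *not* re-normalized afterwards, so row sums
may drift slightly from 100 %. Only the channel-mean condition is imposed
because only it is identified by the assumptions; iterative proportional
fitting would additionally enforce row sums but imposes a constraint the
model does not state. The correction is idempotent and repairs any
per-channel multiplicative loading imbalance exactly (verified against
regeneration with unit multipliers).

Values are carried in percent units so the 16.67 % invariant is literal.
Channel means are computed over observed proteins only; an all-zero row
carries no information and is reclassified as missing rather than
poisoning the batch.

## Differential expression

Per pairwise comparison (defaults: G1–Ctrl, G2–Ctrl, G1–G2):

- **Presence filter** — retain a protein iff its observed count in every
  group is ≥ ⌈threshold · group size⌉; at the default 0.7 with groups of
  12 this is 9. The ceiling convention makes "equal or greater than 70 %"
  exact for non-divisible group sizes.
- **Normality screen** — Lilliefors-corrected Kolmogorov–Smirnov test on
  the pooled, group-mean-centered residuals of the two groups (≥ 3
  observations per group required). The Lilliefors correction is needed
  because mean and variance are estimated from the same sample; the plain
  KS test with estimated parameters is anticonservative. Proteins failing
  the screen get no *t*-test verdict and can never be called significant.
- **Welch t-test**, two-sided. Welch is the safer default under unequal
  group variances and coincides with Student's when variances agree.
- **Ratio statistics** — ratio of arithmetic group means of the
  normalized intensities (not the mean of per-sample ratios, which is not
  defined across batches without pairing); `l2r = log2(ratio)`; centering
  subtracts the comparison-wise *mean* l2r. Mean rather than median: the
  centering constant estimates the normalization's residual global offset
  under the mostly-null assumption, and no robustness qualifier is part
  of the procedure. With DE signs balanced, mean and median agree in
  expectation.
- **Magnitude p-value** — a Gaussian with mean 0 (by construction) and
  sd = sample sd over proteins is fitted to the centered l2r values; the
  p-value is the two-sided tail probability of each |centered l2r|. At
  least 10 proteins are required to estimate the spread; zero spread
  returns p = 1 for all proteins with a warning.
- **Dual criterion** — significant iff t-p < α and magnitude-p < α and
  the normality screen passed (α = 0.05). No multiple-testing correction
  by default; a Benjamini–Hochberg flag exists but is off, matching the
  procedure's definition. Because the two statistics are positively
  correlated under the null (both are driven by the group-mean
  difference), the dual criterion's null discovery fraction is ~0.035,
  below the nominal 0.05 of either test alone.

Fold changes use the signed convention `2^l2r` (up) / `−2^(−l2r)` (down),
so |fold| ≥ 1 and fold(0) = 1 — recomputable exactly from the stored l2r.

## Clustering QC

Samples are clustered on the Euclidean distance of their normalized
profiles, average linkage (UPGMA) by default — the distance is part of the
procedure, the linkage is a config knob chosen as the expression-heatmap
convention. Proteins with any missing value among the clustered samples
are dropped (complete-case): a missing-aware distance would introduce an
undocumented convention. Agreement between a k-cluster cut and external
labels is scored with the adjusted Rand index, accompanied by a
permutation null band (labels shuffled, clustering fixed): batch labels
should score inside the band, group labels above it. Dendrograms are
serialized as Newick with merge heights as branch lengths.

## MRM validation

A peptide is quantifiable in a (pooled) group sample when it has ≥ 3
light-transition peak areas; its quantity is their sum. Fewer transitions
exclude the peptide (never zero-fill); adding transitions can only add
peptides. Heavy-standard rows are validated but excluded from
quantification — they serve identity confirmation. Protein group values
are means of peptide quantities (the roll-up is a package convention;
the source procedure does not specify one), and cross-platform agreement
is fold-change *sign* concordance — the weakest reading of per-protein
"positive correlation", chosen so stricter definitions remain derivable
from the per-protein detail rows the module emits.

## Synthetic cohort generator

The generator emulates the study conditions: 6 batches × 6 channels, 2
samples per group per batch (36 samples, 12 per group), log2-normal
baseline abundances `N(10, 2)` (keeps intensities positive and
realistically right-skewed; no abundance distribution is prescribed by
the design, so this is a convention), group effects on the log2 scale,
per-protein-per-batch offsets, per-(batch, channel) multiplicative
loading factors, i.i.d. per-cell log2 noise, and protein-per-batch
missingness. Defaults: 2000 proteins, 10 % DE with |log2 effect| 1.0
(G1 vs Ctrl) and 0.5 (G2 vs Ctrl) under random per-protein signs,
within-group sd 0.5 log2, batch-effect sd 0.25 log2, loading factors
log-uniform on [0.5, 2], missing rate 0.1. Effect sizes are parameterized
per comparison against the reference group (Ctrl); the third comparison's
effect follows by subtraction, since arbitrary effects for all three
pairs are not jointly realizable. One top-level seed drives a single
`numpy` Generator; identical parameters give bit-identical tables.

What the generator does *not* emulate — and hence what passing tests do
not certify about real data: peptide-to-protein roll-up and shared
peptides, intensity-dependent missingness (missingness here is
abundance-independent), reporter-ion isotope impurity, ratio compression
from co-isolation, and heavy-tailed or correlated noise. Results on real
cohorts depend on those factors; the synthetic results certify the
*procedure* (its algebra, calibration and invariances), not field
performance.

## Calibration evidence (computed by the tests and acceptance script)

- The equal-loading invariant holds to 1e−9 relative on generated batches
  with loading imbalance (acceptance script target `t7`).
- Under a global null at the study design (no effects, 2000 proteins,
  12 vs 12, 20 replicates) the dual criterion's mean discovery fraction
  is ≈ 0.035 ≤ 0.05 (target `t9`), and the significant set is always a
  subset of the t-test-alone set.
- At the default effect settings, the dual criterion's sensitivity
  (G1 vs Ctrl) averages ≈ 0.74 with false-positive rate < 0.001 among
  null proteins. A pre-build Monte-Carlo oracle at the same settings —
  direct simulation of multiplicative 12-vs-12 data with 10 %
  protein-batch missingness, dual criterion applied with independent
  code — gives 0.695 ± 0.033; the pipeline is required to reach at least
  that. The idealized additive-log2 oracle (no missingness, tests in log
  space) gives 0.855; the gap is attributable to the normality screen's
  lower pass rate on the raw multiplicative scale (~0.81) and to
  missingness reducing per-group n.
- Batch-effect elimination: with strong per-protein batch offsets
  (sd 1.0 log2) raw-scale clustering recovers batches almost perfectly
  (ARI ≈ 1); after the two-step normalization the batch ARI falls inside
  the permutation null band. The demonstration uses sd 1.0 because at the
  default 0.25 the raw-space batch signal is already weaker than
  within-group noise and invisible to clustering either way.

## Problem sizes

Simulation-based tests and the acceptance script use 2000-protein
cohorts (20 replicates for null calibration, 3 for parameter recovery)
and 120–500-protein cohorts for structural tests — sizes at which the
Monte-Carlo error of the measured fractions (≈ 0.005–0.03) is small
relative to the margins being asserted.

## Known limitations

- The magnitude p-value assumes a single global Gaussian for the centered
  l2r distribution; heavy tails or intensity-dependent spread would
  miscalibrate it (no binned or moderated variant is provided).
- With a large DE fraction or strongly unbalanced DE signs, mean-centering
  absorbs part of the true effect.
- The loading correction repairs only multiplicative per-channel
  imbalance; channel-by-protein interactions (e.g. isotope impurity) are
  out of scope.
- Clustering drops incomplete proteins; under heavy missingness few
  complete rows may remain and the QC becomes unstable (an error is
  raised below 2 rows).
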