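# itraqpipe

Quantitative analysis of multi-batch isobaric-labeling (iTRAQ) proteomics
cohorts **without an internal reference channel**: reference-free
cross-batch normalization, presence filtering, dual-criterion differential
protein expression, clustering-based batch-effect QC, and targeted-MS
(MRM) sign-concordance validation — plus a synthetic cohort generator that
reproduces the blocked design all of this relies on.

## The problem

In an iTRAQ experiment, up to 6 samples are labeled with distinct reporter
channels, pooled, and acquired in one LC-MS/MS run (a *batch*). Reporter-ion
intensities encode relative abundance only *within* a batch, so multi-batch
cohorts normally spend one channel per batch on a common reference sample.
If instead every batch carries the same balanced group composition — here 2
poorly controlled diabetic (G1), 2 well-controlled (G2) and 2 healthy
control (Ctrl) saliva samples per 6-plex batch, with channels randomly
assigned — the reference channel can be dropped and all 6 channels used for
subjects. This package implements the analysis that makes that design work.

## The method

**Normalization** (per batch, two steps):

1. *Within protein*: each protein's reporter intensity becomes its percent
   share of the protein's channel sum,
   `x_ic = 100 · I_ic / Σ_c I_ic`, so every present row sums to 100 %.
   Any protein-level factor common to a batch's channels (run efficiency,
   batch-wise abundance shifts) cancels exactly here.
2. *Equal loading*: assuming equal loading and that most proteins are not
   differentially expressed, every channel's mean share over identified
   proteins must equal 100/6 ≈ 16.67 %; each channel is rescaled by
   `(100/6) / mean_c` so this holds exactly.

**Presence filter**: a protein is analyzed only if observed in ≥ 70 % of
the samples of *every* group (≥ 9 of 12 at the study design).

**Differential expression** (per pairwise comparison A vs B), the dual
criterion:

- Welch *t*-test on the normalized intensities — applied only to proteins
  whose pooled group-centered residuals pass a Lilliefors-corrected
  Kolmogorov–Smirnov normality screen;
- magnitude test: `l2r = log2(mean_A / mean_B)` is centered on the
  comparison-wide mean, a Gaussian `N(0, σ̂²)` is fitted to the centered
  values, and each protein's magnitude p-value is the two-sided tail
  probability of its |centered l2r|.

A protein is differentially expressed iff **both** p-values are < 0.05.
Fold changes use the signed convention `fold = 2^l2r` for up-regulation
and `−2^(−l2r)` for down-regulation (|fold| ≥ 1).

**QC**: hierarchical clustering (Euclidean distance, average linkage) of
samples on the normalized matrix; adjusted Rand index against batch and
group labels, with a permutation null band, turns "no batch-oriented
grouping" into a number.

**MRM validation**: peptides are quantified as the sum of ≥ 3 light
transition peak areas (heavy standards confirm identity only), proteins as
the mean of their peptides per group, and cross-platform agreement is
reported as fold-change sign concordance, "k out of n proteins".

## Worked example

```python
import itraqpipe as ip

params = ip.GeneratorParams(n_proteins=500, seed=42)   # 6 batches x 6 channels
design, tables, truth = ip.generate_synthetic_study(params)

norm = [ip.normalize_batch(t) for t in tables]          # each channel mean -> 16.67 %
matrix = ip.assemble_matrix(norm, design)               # 500 proteins x 36 samples
filtered, counts = ip.presence_filter(matrix, design, 0.7)
stats = ip.compare(filtered, design, "G1-Ctrl")
print(filtered.shape[0], int(stats["significant"].sum()))
```

prints `449 35`: 449 of 500 proteins survive the ≥ 9-of-12 presence filter
(10 % of proteins are dropped per batch by the generator), and 35 are
called differentially expressed between G1 and Ctrl by the dual criterion.
The top rows of `stats` look like

```
            t_p     ratio     l2r     l2r_p   fold_change
P00210      0.0001  0.3643  -1.4568  0.0002   -2.7451
P00099      0.0000  0.3783  -1.4026  0.0003   -2.6437
P00364      0.0000  2.5584   1.3553  0.0003    2.5584
```

— e.g. P00210 is 2.75-fold down in G1 (ratio 0.364, log2 ratio −1.46),
with both the *t*-test and the magnitude p-value far below 0.05. Against
the generator's truth table this run recovers 78 % of the injected
±1.0-log2 effects with no false positives, and clustering the filtered
matrix gives a group-label ARI of 0.55 versus a batch-label ARI of −0.04:
biological structure present, batch structure gone.

The same workflow is available from the shell:

```bash
itraqpipe simulate --n-proteins 500 --seed 42 --out synth
itraqpipe normalize --design synth/design.tsv --reporter synth/reporter_B1.tsv \
    ... --out results
itraqpipe diffexp --design synth/design.tsv --matrix results/expression_matrix.tsv
itraqpipe qc      --design synth/design.tsv --matrix results/expression_matrix.tsv
itraqpipe run     --config pipeline.yaml      # everything, from a config file
```

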