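# Methods note

This note records, in the package's own words, the statistical and
computational conventions implemented in `twindhmr`. Every empirical number
quoted in this repository (README, acceptance output, tests) is computed by
the code at run time; **no empirical result is claimed that the tests do not
themselves compute.** The only externally sourced quantities are published
summary constants used as comparison targets in the acceptance tests (a
12-row annotation composition table and a decision-boundary slope/intercept
pair), which are re-derived arithmetically by the package's own accounting
functions before comparison.

## Simulation

`simulate_cohort` draws a paired cohort: for each twin pair, one "case" and
one "control" sample. Window counts are negative binomial (NB2,
var = μ + αμ²) around a common baseline mean, with a per-pair log-normal
random effect shared by both co-twins (inducing within-pair correlation) and
per-sample size factors. Spike-in regions multiply the case mean by
2^log2fc, optionally with partial penetrance (a per-pair Bernoulli carriage
indicator) and a covariate-linked confounder. Co-twins share their age; sex
is shared within MZ pairs. With fragment emission enabled, the NB draw is
reinterpreted as the number of 200 bp fragment starts in the window and the
count matrix is defined by overlap-binning the emitted fragments, so
`bin_fragments(emit_fragments(cohort)) == cohort.counts` holds exactly.
All randomness flows from a single `numpy.random.default_rng(seed)`.

## Windowing and candidate regions

Chromosomes are tiled into non-overlapping 50 bp windows (a trailing partial
window is kept). Fragments are counted into every window they overlap.
Per-sample noise cutoffs are the smallest count c with
P(X ≥ c) ≤ FDR·(non-empty windows)/(total windows) under a Poisson fit to
the per-window mean — the classical enrichment-seq background model.
Normalization uses DESeq median-of-ratios size factors (geometric-mean
reference over windows with all-positive counts).

Signal windows must pass the count cutoff in every case sample of enough
pairs and show case > control (or the reverse for hypo) consistently;
per-window paired tests are corrected by **stratified Benjamini–Hochberg**:
windows are binned by integer mean normalized count, BH is applied within
each stratum, and a window qualifies if its q-value passes at its own or any
lower-count stratum (the lowest-qualifying-level rule). Adjacent significant
windows of the same direction merge into regions when the gap is ≤ 200 bp;
regions shorter than 150 bp are dropped; direction changes always split.

## Region-level inference

Each candidate region's summed counts are tested by NB ANODEV: a full model
with a case/control group term against the nested reduction without it,
fitted by iteratively reweighted least squares with log link and
log-size-factor offsets (step damping of 0.5 from iteration 30 onward to
break oscillation; up to 200 iterations to tolerance 1e-8). Three covariate
models are fitted: (1) group + pair factor, (2) adding sex and zygosity,
(3) adding age, BMI, smoking, alcohol. Covariates that are constant within
every pair (age by construction, sex in MZ pairs) are exactly collinear with
the pair factor and are dropped from the design with a warning — the
matched design already adjusts for them, which is the point of a twin study.

Two reference distributions are available:

- **Pipeline route** (used by phases 1–2): a common NB dispersion is
  estimated once by maximizing the Cox–Reid adjusted profile likelihood
  pooled over up to 300 evenly spaced regions, and the deviance difference
  is referred to χ²₁. Pooling stabilizes the dispersion (per-region moment
  estimates at n = 24 are too noisy, making plug-in χ²₁ anti-conservative).
- **Standalone route** (default for a single region with no supplied
  dispersion): per-region moment dispersion with an n/(n−p) correction, and
  a quasi-likelihood F(1, n−p) reference scaled by the full-model Pearson
  dispersion, which is calibrated without pooling.

The per-region effect size is log2((mean normalized case + 0.5) /
(mean normalized control + 0.5)), deliberately model-independent.

Phase 1 selects regions with BH q ≤ 0.01 in **all three models** and
consistent sign. Phase 2 refits model 3 **without the pair factor** in the
7 validation pairs (pair dummies would saturate: 14 parameters for 14
samples) and confirms at nominal p ≤ 0.01 with matching sign.
Non-converged fits are treated as non-significant (p = 1), never dropped.

## Classifier

Confirmed-DhMR normalized counts per sample are z-scored using
training-sample means/SDs (zero-variance features dropped), projected by
PCA computed from the SVD of the centered training matrix (n−1 variance
divisor; each component's sign fixed so its largest-magnitude loading is
positive). Two components are kept, chosen by the largest absolute
standardized mean difference between groups unless overridden. A single
tanh unit σ(w₁x₁ + w₂x₂ + b) is trained by full-batch gradient descent on
squared error (learning rate 0.05, ≤ 5000 epochs), restarted from 1000
uniform(−1, 1) initializations evaluated in a vectorized sweep; the restart
with lexicographically best (sensitivity, AUC, specificity) on the training
samples wins, ties broken by restart index for determinism. AUC is the
Mann–Whitney statistic with ties counted ½.

The decision boundary x₂ = m·x₁ + c is decomposed as a transformation of
the vertical (PC2) axis: a clockwise rotation of θ = atan2(1, m) degrees
followed by a vertical translation of c. The round-trip residual (applying
the rotation matrix and translation to the vertical axis and comparing to
the boundary) is reported and must vanish to numerical precision.

## Annotation

Gene models are read from GTF (converted to 0-based half-open internally).
Region midpoints are classified with precedence TSS ±1 kb → TTS ±1 kb →
5′UTR → 3′UTR → coding exon → non-coding exon → intron → intergenic
(nearest gene reported). TSS/TTS are strand-aware. Biotypes collapse to
protein-coding / ncRNA / pseudogene / snoRNA / other. The summary table
gives counts and percentages by category and, within each category, by gene
type, split into all/hyper/hypo columns; percentages are reported raw and
rounded both to integers and to one decimal.

## Determinism and serialization

Every stage is a pure function of (config, seed). The pipeline summary is
serialized with sorted keys and all floats coerced to 10 significant
digits, and `summary_checksum` is the SHA-256 of that canonical JSON; two
runs of the same config produce byte-identical `run_summary.json` files,
which the acceptance suite verifies.

## What the benchmarks measure

`twindhmr.benchmarks` provides two self-contained experiments used by the
acceptance suite and `scripts/acceptance.py`:

- **Calibration**: 2000 null NB regions (dispersion 0.3, 12 pairs) tested
  with the pipeline route; reports the KS p-value of the p-value
  distribution against uniform, the empirical rate at p ≤ 0.01, and the
  number of BH selections at q ≤ 0.01.
- **Recovery**: 500 regions with 20 spiked at |log2fc| = 2 (half each
  direction), run through phases 1 and 2 with 12 training + 7 validation
  pairs; reports sensitivity, the mean absolute error of the estimated
  log2fc over confirmed true regions, sign correctness, and false
  positives.

These are simulations of the package's own generative model; they
characterize the implementation's statistical behavior and make no claim
about any external dataset.
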