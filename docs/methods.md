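# Methods

## Scope and model

`utrlen` studies the within-species association between 5'UTR length and
per-sequence composition features.  The response is Y = log10 L (L in
nucleotides); the candidate predictors are G+C content, the
observed-to-expected (OE) ratios of the four trinucleotides AUG, UGA, UAA,
UAG, and the OE ratios of the four dinucleotides CG, UG, UU, UA, with an
optional 0/1 upstream-ORF presence flag.  Ordinary least squares with an
intercept is fit by statsmodels (orthogonal-decomposition based); a raw
normal-equations solver exists only as an independent test oracle.

## Feature definitions and conventions

* **Frequencies.**  f_i = (count of base i)/L, per sequence.  Ambiguity
  codes are not masked; a record containing any is dropped entirely,
  because masked positions would make f_i ill-defined.  DNA input is
  transparently mapped to RNA (T→U); all motifs are RNA-spelled.
* **Expected counts.**  E[m] = L · ∏ f_b over the bases of m.  The number
  of windows is taken as L rather than L−k+1 — the standard closed form
  for CpG-style OE statistics; the exact-window alternative is available
  via `windows="L-k+1"` everywhere.  The difference is O(k/L) and matters
  only for very short sequences.
* **Observed counts.**  Overlapping sliding-window occurrences (the usual
  convention for OE statistics; for self-overlapping motifs such as UU
  this counts every window).
* **OE = 0 convention.**  When a required base is absent the expected
  count is 0 and the observed count is necessarily 0; the ratio is defined
  as 0.  Sequences shorter than the motif also yield 0.
* **uORFs.**  One AUG, the *first* downstream in-frame stop codon
  (UAA/UAG/UGA) lying entirely within the UTR, and at least one non-stop
  codon in between (stop offset − AUG offset ≥ 6).  AUGs whose first
  in-frame stop is immediately adjacent yield nothing.  Overlapping uORFs
  (stop inside the downstream CDS) cannot be seen from UTR sequence alone
  and are deliberately out of scope.  Coordinates are 0-based half-open;
  BED export follows BED conventions.
* **Minimal length.**  1/∏f_b, the length at which the motif is expected
  once by chance; infinite when a base is absent.
* Records shorter than 3 nt (one trinucleotide window) are dropped with a
  logged reason.

## Data cleaning

The default filter removes every UTR with **more than one** zero among the
four trinucleotide OE ratios.  Zeros there are uninformative — for
sequences below the minimal length, absence of a motif is the chance
expectation, not evidence of selection.  Dinucleotide OE zeros are never
inspected (their expected counts are an order of magnitude larger).  An
alternative hard length threshold (default: drop L < 30) exists for
comparison; on log-normal synthetic sets it leaves the log-length
distribution visibly further from normality (quantile/normality report:
Shapiro–Francia-type correlation of ordered log10 lengths with normal
order-statistic quantiles), which is why the zero-OE rule is the default.
Transcript selection happens before filtering: one transcript per gene,
uniform at random under an explicit seed.

## Model selection and importance statistics

* **Backward elimination** removes one predictor per step — the one with
  the largest t-test p-value — while that p-value exceeds α (default
  0.05); the intercept is never removed.  The per-variable type-I
  retention rate of this procedure was verified ≈ α on iid designs.
* **VIF** is computed as the diagonal of the inverse predictor correlation
  matrix, algebraically identical to 1/(1−R²_j) from regressing predictor
  j on the others with an intercept, and numerically exact (VIF = 1.0) for
  orthogonal designs.  Singular correlation matrices fall back to
  per-predictor fits, reporting infinite VIF with a flag; any VIF > 10 is
  flagged.  VIF is screened on the full candidate set and recomputed on
  the final model.
* **RCVE** uses unadjusted R² in both the full and the reduced model, with
  both models fit on identical rows; an adjusted-R² variant is available
  for sensitivity analysis (its values can be negative).  Nested-model
  monotonicity (R²_reduced ≤ R²_full) is asserted on every call.
* **Partial correlations** use the residual method (correlate the
  residuals of response and target after regressing both on the remaining
  predictors) and equal t/√(t²+df) from the full-model t statistic.  By
  default they condition on the backward-selected predictor set, with
  eliminated predictors reported as `ns`; conditioning on all candidates
  is a config option.
* No multiple-testing correction is applied across the nine candidates.

## The synthetic generator

`SyntheticSpec` describes one species-like set:

* **Lengths** are log-normal with median `length_median` (default 160 nt,
  a typical metazoan 5'UTR median) — concretely, log10 L = β0 + Σ β_k
  (x_k − E[x_k]) + ε with ε ~ N(0, `noise_sd`), default sd 0.30 log10
  units, giving a right-skewed distribution with ~95% of lengths between
  roughly 40 and 650 nt.  Centering the covariates keeps the median at
  `length_median` whatever the planted coefficients.  Raw draws below 3 nt
  are clipped to 3; a spec producing more than 1% such draws is rejected.
* **Composition.**  Per-gene G+C is Beta(11, 8) by default (mean 0.58,
  sd 0.11, matching the wide G+C spread of real 5'UTR sets); bases are
  drawn iid with P(G) = P(C) = gc/2.
* **Motif modifiers.**  A per-motif factor s (fixed, or drawn per gene
  from a uniform range) rescales the motif's occurrence rate: occurrences
  are thinned (kept with probability min(s,1); rejected windows are
  redrawn, iterating over newly created occurrences up to a capped number
  of passes, default 10) and, for s > 1, extra copies are planted at a
  Poisson rate (s−1)·L·∏f.  s = 1 reproduces the iid model exactly; s = 0
  eliminates the motif.  Realized suppression is whatever the emitted
  sequences show — it is measured, not assumed.
* **Transcripts.**  `transcripts_per_gene` emits several transcripts per
  gene sharing the gene's covariates, with independent noise and sequence
  realizations.

What the generator does **not** emulate: phylogenetic relatedness between
species, transcription-start-signal gain/loss dynamics, secondary
structure, positional motif clustering, and real UTR databases' curation
artifacts.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not biological
conclusions about any species.

## Measurement attenuation, recovery, and two findings

Effects are planted on *generative* covariates (gc, motif factors) but the
pipeline regresses on features *measured* from the realized sequences —
exactly the errors-in-variables situation of the real analysis.  Two
consequences, documented here because the test suite relies on them:

1. **Attenuation.**  Measured G+C has reliability ~0.8 at median length
   160; a motif OE ratio is a far noisier surrogate of the generative
   factor (reliability ~0.15).  Naive coefficients are therefore biased
   toward zero and slightly mixed across features.  The recovery analysis
   corrects this by multivariate regression calibration: each true
   covariate is regressed on all measured features and the response is
   refit on the calibrated values; the calibration matrix is reported.
2. **Within-sequence coupling.**  A UTR's measured OE ratios are
   mechanically coupled to its own length: E[OE|L] ≈ 1 − k/L under the
   L-window convention, and the ratio estimator obs/(L·∏f̂) carries O(1/L)
   bias (largest for the self-overlapping UU).  Since the response *is*
   log L, feature measurement error correlates with the response — so a
   generative null (no planted effects) is **not** a statistical null for
   the measured features (in simulations the UU OE "survives" selection in
   half the null runs), and within-sequence calibration retains a small
   bias.  Both recovery-coverage and null-calibration checks therefore use
   a **sibling-transcript design**: the response is taken from a second
   transcript of the same gene, which shares the generative covariates but
   has independent noise and sequence, making measurement error exactly
   independent of the response.  Under this design corrected coefficients
   are unbiased with nominal 2-SE coverage (~95%), and per-predictor
   survival of backward selection under the null is ≈ α.  The coupling
   itself is worth remembering when interpreting real-data fits: part of
   any OE–length association at short lengths is mechanical.

## Problem sizes and numerical choices

The acceptance suite runs 500 recovery replicates at 5,000 genes and 1,000
null replicates at 500 genes (sizes chosen to keep the default test run on
one CPU in a few minutes); the acceptance script runs scaled-down versions
(60 and 300 replicates) of the same studies.  Quantities asserted to
machine precision (fixture features, RCVE/partial-correlation identities)
use tolerances of 1e-10; Monte-Carlo assertions use bands derived from
their sampling error.  The scalar and vectorized feature paths evaluate
the OE expectation in the same left-to-right order so their results agree
bit for bit.  Degenerate inputs (empty sequences, constant responses,
rank-deficient designs, perfect collinearity) raise informative errors
rather than returning NaN, except that VIF reports perfect collinearity as
an infinite, flagged value.
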