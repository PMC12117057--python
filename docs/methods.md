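# Methods

## Measurement model and the RADDi estimator

A tissue lysate is split into two aliquots after lysis.  The total aliquot
is measured as is; the depleted aliquot is reacted with an active-site
probe and stripped of captured active enzymes, so an enzyme with active
fraction α retains (1 − α) of its signal.  The per-sample depletion ratio
is computed on summed matched transitions (transitions observed in both
extracts of that sample), and the active fraction is estimated as
RADDi = 1 − 2^(log2ΔInt), clamped to [0, 1].

Clamping embodies a deliberate asymmetry: a positive ratio (apparent
enrichment in the depleted extract) cannot arise from depletion chemistry
and is treated as noise, consistent with the one-sided gating hypothesis.
Summing intensities before taking the ratio (rather than averaging
per-transition ratios) weights transitions by signal, which is the right
behaviour when transition intensities span orders of magnitude.

Properties relied on throughout:

* **Exact recovery.** Noiseless data give RADDi = α to machine precision
  for every gated enzyme.
* **Scale invariance.** Multiplying both extracts of a sample by a common
  factor leaves every ratio unchanged, so sample-level loading differences
  cancel.

## ISP selection and normalization

Internal standard peptides are endogenous housekeeping/cytoskeletal
peptides stable between paired extracts.  Selection applies five joint
filters on quantile-normalized log2 peptide values (quantile normalization
is internal to selection only, not a user-facing normalization mode):
candidate-list membership; missing fraction < 5 % over transition × run
cells; a two-sided variance-equality F-test between depleted-run and
total-run values with p > 0.2 (larger variance in the numerator — "no
variability difference" is directionless); paired Pearson r > 0.6 with
p < 0.05; and length ≥ 8 residues ("more than 7 amino acids" read
strictly).  Peptides whose paired values are exactly equal (zero variance)
are accepted as perfectly stable — the degenerate limit of the correlation
filter.  Filters operate per (protein, peptide) key; charge states are not
distinguished by the data model.

Normalization shifts each run's log2 intensities so that the run's ISP
median equals the grand median (the median of per-run ISP medians).  It is
idempotent, preserves within-run differences and ranks, and—because the
shift is per run (sample × extract)—also removes extract-level drift from
all depletion ratios.

## Imputation and protein summarization

Missing values are drawn per (protein, extract) from
Normal(0.9 × min observed, 0.5 × SD observed), floored at 0 and
reproducible under a seed; a fully missing protein group falls back to the
global minimum (warned, not fatal).  The moments are taken on the scale of
the stored intensities (linear) by default, matching the convention that
missingness concentrates just below the detection floor; a `scale="log2"`
option draws in log space instead, since the scale convention is a
genuinely open choice.

Protein-level log2 abundance matrices are produced by Tukey median polish
over each protein's transition × sample submatrix (single-transition
proteins pass through).  Median polish is the robust summary used as the
default by mainstream protein-quantification software; we use it directly
rather than a linear mixed-model fit, trading per-feature variance
modelling for simplicity and robustness to single-transition outliers
(one contaminated transition in five moves the summary by < 0.1 log2 in
the tests).

## The KS activity gate

Per enzyme and condition, the per-sample ratios are compared with the
pooled (ISP protein × sample) reference ratios of the same condition using
the one-sided two-sample Kolmogorov–Smirnov statistic
D⁺ = sup_t[F̂_enzyme(t) − F̂_reference(t)], i.e. the R `ks.test`
`alternative="greater"` orientation in which the enzyme ratios are
stochastically smaller (more depleted).  The p-value is the asymptotic
bound exp(−2·m·n·D⁺²/(m+n)), matching R's large-sample behaviour and
verified against R to 12 digits; an exact small-sample mode is available
behind a flag.  The asymptotic bound is conservative for small m, so the
realized type-I rate sits below the nominal 5 % (≈ 3 % at m = 6 in the
calibration test) without ever exceeding it.

Gating requires at least 3 per-sample ratios in the condition
(configurable); undersized enzymes are left ungated with a missing p.  The
reference is built at ISP-protein × sample granularity to match the
enzyme-side granularity entering the same test.  An alternative mode pools
per-peptide ratios on the enzyme side, exposed as `enzyme_input="peptides"`,
because the granularity the gate should pool over is ambiguous in
principle; per-sample enzyme ratios are the default.  Where the gate
fails, RADDi is set to 0; where the measurement itself is absent, the cell
stays missing rather than 0.

## Differential statistics

Family follows layer: Gaussian/identity for log2 abundances (fitted by
OLS, so a two-group fit with no covariates is exactly the pooled
two-sample t-test), quasibinomial/probit for RADDi proportions with
dispersion estimated by Pearson χ²/df (values exactly 0 or 1 are nudged by
1e−6 off the boundary; all-zero groups are flagged degenerate with missing
p), and Poisson/log for counts.  Age, sex (0/1) and smoking (0/1) enter as
confounders; a covariate collinear with the condition factor raises a
rank-deficiency error rather than silently dropping a coefficient.

With more than two conditions all pairwise contrasts are computed from one
fit; the within-feature post-hoc adjustment is single-step max-|z| by
seeded multivariate-normal resampling of the contrast correlation matrix,
with Bonferroni behind a flag — the exact multiple-contrast procedure is a
convention choice, so both are provided.  Raw and BH-adjusted p-values are
always emitted side by side (activity comparisons are conventionally read
unadjusted).

Fisher co-occurrence testing of a mutation table against an anchor
oncogene is one-sided (enrichment) on the 2×2 gene × anchor table — equal
to the hypergeometric upper tail, which the tests enumerate directly — with
BH across genes and a descriptive per-residue mutation rate when protein
lengths are supplied.

## Interactome enrichment

Co-depletion of background proteins is called by the two-sided KS test
against the same ISP reference, per condition and pooled, at the 0.05 and
0.01 strata (the strict stratum is nested by construction).  Called
proteins are annotated 1st degree (direct enzyme neighbor), 2nd degree
(neighbor of a 1st-degree interactor), or unannotated, with 1st-degree
precedence.

Two permutation nulls, each summarized by a one-tailed normal z-test on
the observed count vs the null mean and SD: (i) random pseudo-target
interactomes — pseudo-enzyme sets of the same size drawn without
replacement from the quantified-protein universe, their pooled 1st-degree
neighborhoods intersected with the depleted set (default 200 iterations);
(ii) random protein subsets re-pairing the correlation-selected
enzyme–protein pairs, counting experimental-evidence edges (default 100
iterations).  Enrichment only is tested; depletion direction is reported
but not tested.  A degenerate null (SD = 0) reports a boundary p with a
warning.

Enzyme–protein pairing applies the selection rule |r| > 0.4 with two-sided
p < 0.05 from t = r√(n−2)/√(1−r²) to plain Pearson correlations across
samples; the multi-block model additionally exposes latent-space
(sGCCA-style) pair similarities for users wanting the latent-variable
variant of the same rule.

## Discriminant signatures

Single-block PLS-DA is NIPALS PLS2 against the centered one-hot class
matrix with n_classes − 1 components by default, hard top-k truncation of
each component's weight vector (mixOmics keepX semantics; caps of 30 for
activity-sized and 500 for proteome-sized matrices are the conventional
settings), classic regression deflation, and features autoscaled by
default (RADDi matrices are conventionally fitted unscaled — per-block
`scale` flags).  The dense two-class solution reproduces the classical
direction w ∝ Xᵀ(centered indicator) and matches scikit-learn's
PLSRegression scores; VIP satisfies mean(VIP²) = 1 identically.

Multi-block integration alternates sGCCA-style weight updates maximizing
the design-weighted sum of covariances between block scores and the class
block (fully connected design, weight 1, by default; configurable).  Each
block deflates on its own scores; the class block deflates on the
consensus (average) score, which makes the single-block case coincide with
plain PLS-DA.  Prediction is nearest class centroid in consensus score
space, Euclidean by default with Mahalanobis behind a flag.  `tune_cv`
grids over candidate keeps and component counts with stratified k-fold
cross-validation (refolding with a fresh seed, up to 10 attempts, if a
class is missing from a training fold) and returns the argmin model; the
tuning grid is user-supplied since no canonical grid exists.

A note on density: with few samples, dense high-dimensional fits shrink
new-sample scores toward the origin and can classify poorly even when
training separation is perfect (the reference PLS implementation behaves
identically) — this is precisely why the per-component variable caps are
tuned rather than fixed.

## Spectral-library assembly and permutation FDR

A targeted sub-library is filtered from two source assay libraries:
project-specific entries win on peptide overlap, peptides mapping to more
than one target protein are excluded as non-proteotypic, and each peptide
keeps its top six transitions by relative intensity (ties broken by
product m/z ascending).  Assembly is idempotent.

The sub-library's error rate is estimated by permutation: virtual source
matrices of the published sizes (139,449 and 30,000 entries — the second
library's size is not published, so a fixed default of 30,000 is used)
are each seeded with ⌊1 %⌋ false targets, and 100 random sub-libraries of
3,593 entries are drawn uniformly without replacement from the pool.  The
per-draw empirical FDR distribution is summarized by mean, SD, quantiles
(95th percentile ≈ 1.3 %, comfortably below the 2 % bound, matching the
binomial closed form) and the one-sided exceedance probability of a stated
bound.  Uniform subsampling is the permutation direction that reproduces
the published bound; a label-permutation alternative is the natural other
reading and can be composed from the same primitives.

## The synthetic cohort generator

The generator emulates the paired-extract design: 12 patients by default,
each contributing one tumor and one nontumor sample, split into long/short
survival halves (4 conditions × 6 samples).  Per transition,

* baseline log2 abundance ~ Normal(14, 2) — spans a DIA-like dynamic range;
* per-(protein, sample) biological variation ~ Normal(0, 0.5) shared by
  both aliquots (the split happens after lysis), which carries the paired
  correlation the ISP filters measure and cancels exactly in every ratio;
* per-sample run shift ~ Normal(0, 0.3) shared by both extracts (LC-MS
  drift), plus an optional per-(sample, extract) shift (default 0) that
  only ISP normalization can remove;
* independent multiplicative noise 2^ε, ε ~ Normal(0, noise_sd_log2), on
  each extract — so a single-transition protein's ratio has SD
  noise_sd·√2;
* depleted = total × (1 − α) for the condition's planted α; coupled
  partner proteins receive α_partner = strength × α_enzyme; ISP proteins
  (the `HK` namespace) always have α = 0.

Missingness is MCAR by default with a left-censored (intensity-dependent)
option, since real DIA missingness concentrates at low intensity.  All
outputs are byte-reproducible from the seed and the planted truth is
returned for recovery tests.

What the generator does **not** emulate: chromatography, spectral
interference, identification error, charge states, correlated
(protein-complex) abundance structure, or survival times.  Passing tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every real-data pathology.

ISP proteins share the global noise SD by default (`isp_noise_factor`
exposes a reduced-noise variant).  This is load-bearing: the one-sided
gate compares enzyme ratios to the ISP reference, and a reference narrower
than the enzymes' own technical noise would make the gate anticonservative
by construction.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen to make each
property measurable: 50 enzymes × 10 planted activity levels for exact
recovery; 2,500 enzymes × 4 conditions (10,000 null gates, ≈ 3 % realized
rate) for gate calibration; 200 replicate experiments × 200 permutations
for null uniformity (KS distance from Uniform < 0.1); 24-sample,
two-block cohorts for classifier properties.  Convergence tolerances:
NIPALS weight change < 1e−9 (≤ 500 iterations); median polish residual
change < 1e−9 (≤ 20 sweeps).  Ties in transition truncation break by m/z;
ties in CV tuning break toward the earliest grid cell, making tuning
deterministic under a fixed seed.

## Known limitations

* RADDi is a relative index: it cannot distinguish probe-inaccessible
  active sites from inactive enzyme, and α near 1 compresses onto the
  ratio's noise floor.
* The asymptotic KS gate is conservative at very small per-condition
  sample counts; the exact mode trades speed for accuracy there.
* The quasibinomial probit fit treats per-sample RADDi values as
  independent proportions; within-patient pairing (T and N from the same
  patient) is handled only through covariates, not random effects.
* Permutation nulls assume the quantified-protein universe is the right
  sampling frame; ascertainment structure in the universe propagates into
  the null.
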