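# Methods

## Scope and model

`enrvar` analyzes two-group (CTRL vs ENR) cross-sectional phenotype
screens in which both the means and the variances of each trait are of
interest. The variance comparison is the scientific core: the working
model of individualization is that enrichment amplifies initially small
inter-individual differences, which manifests as a larger within-group
variance in the enriched group for the affected traits, with the
variance ratio ρ = σ²_ENR / σ²_CTRL as the effect size.

## Roaming entropy

A trajectory is a strictly time-ordered sequence of (x, y) positions in a
square arena (default 60 cm side, matching a standard open-field box).
The arena is partitioned into `rows × cols` equal subfields (default
10×10, k = 100); each inter-sample interval is credited to the subfield
of its *starting* sample, so cell weights are dwell time, not sample
counts — the two coincide up to one frame at a constant frame rate, but
dwell time remains correct under irregular sampling. Cells are half-open
`[low, high)` with the top/right arena edge closed, so every in-bounds
point belongs to exactly one cell. Points outside the arena by at most
1% of the side (tracking jitter) are clamped to the boundary; anything
farther is rejected as corrupt. Roaming entropy is the Shannon entropy
of the occupancy distribution normalized by log k, with the 0·log 0 = 0
limit; it is base-invariant and lies in [0, 1], maximized uniquely by
uniform coverage.

Habituation is reported as ΔRE = RE(trial 1) − RE(trial 2), so a
*decrease* in coverage on re-exposure scores positive. The opposite sign
convention exists in the literature; the subtraction order here is fixed
and documented rather than configurable silently. A missing trial-2
record propagates as NaN — an animal whose recording was lost must not
score as "no habituation".

## Behavioral derivations

* **Discrimination index**: DI = (new − old)/(new + old) on trial-3
  exploration times; scale-invariant, so seconds and proportions of trial
  time are equivalent. DI is undefined (error, never silently 0) when
  both times are zero. The exclusion rule removes animals that did not
  explore object A in either of trials 1–2 or explored nothing in
  trial 3; "did not explore" means time ≤ threshold with threshold = 0 s
  by default (no minimal-exploration-time criterion is imposed; the
  threshold is exposed for labs that use one). Animals with missing trial
  records are flagged as data errors, not auto-excluded.
* **Rotarod**: the per-animal summary is the arithmetic mean over
  non-missing trials (nominally 9 = 3 days × 3 trials, each capped at the
  300 s ceiling). Missing trials are ignored rather than imputed as 0: a
  lost record is not a fall at t = 0.
* **Stereology**: new-neuron/astrocyte counts are total BrdU⁺ count ×
  marker co-labeling fraction, unrounded; Cavalieri volumes are
  point count × grid spacing² × section interval (defaults 25 µm and
  240 µm).

## Statistical engine

Per trait, missing values are dropped per group (pairwise-complete) and
the remaining n is reported; fewer than 3 values in either group flags
the trait untestable rather than skipping it. Traits on a declared log
list (defaults: corticosterone, triglycerides — right-skewed plasma
measures) are natural-log transformed *before* both the normality gate
and the tests; non-positive values in such traits are an error with the
offending rows identified.

The branch gate runs Shapiro–Wilk per group; the parametric pair
(Welch t, variance-ratio F) is used iff **both** groups pass at the same
α as the tests (0.05). Both-groups-pass is the strictest defensible
reading when the original per-trait choices are not recoverable; the gate
is a single place in the code and easy to change.

Conventions for the individual tests:

* Welch t uses the Welch–Satterthwaite df — mandatory here, since unequal
  variances are the hypothesis, not a nuisance.
* The two-tailed F p-value doubles the smaller tail probability, capped
  at 1 (the `var.test` convention), which makes it invariant under group
  swap.
* Wilcoxon rank-sum uses the exact null distribution for tie-free
  combined n ≤ 50 and the tie- plus continuity-corrected normal
  approximation otherwise.
* Brown–Forsythe is the one-way ANOVA F on |x − group median| with
  F(1, n₁+n₂−2). It is known to be slightly conservative under normality
  at these sample sizes (empirical size ≈ 0.045 at n = 40/group in this
  package's own 100k-rep calibration), a property of the test, traded for
  robustness to non-normality.
* Primary inference is marginal per trait — each trait's response to
  enrichment is a separate question, so no family-wise correction is
  applied to the flags; BH-adjusted columns are appended for the
  experiment-wide reading but are advisory only.

Power of the two-tailed F test is exact: s²₁/s²₂ ÷ ρ is central
F(n₁−1, n₂−1), so power = P(F < c_lo/ρ) + P(F > c_hi/ρ) at the α/2
critical values. It reduces to α at ρ = 1, is monotone in ρ and n, and is
invariant under (swap groups, invert ρ). The implementation is
cross-validated against vectorized Monte-Carlo rejection rates in the
test suite.

## Correlation structure

Spearman ρ is Pearson on midranks, p from the t-approximation
t = ρ√((n−2)/(1−ρ²)) with n−2 df, two-tailed; entries need ≥ 3
pairwise-complete observations and a non-constant pair, otherwise they
are NaN and listed as undefined. Matrices are computed strictly within
group — pooling would manufacture correlation out of group mean
differences. Trait order comes from average-linkage agglomerative
clustering of the ENR matrix at distance d = 1 − ρ (signed, so
anticorrelated traits land far apart; undefined entries are imputed as 0
for ordering only) and the same order is applied to both groups. The
restructuring report classifies each pair by Δρ, sign flip, and
significance transition at α; no formal test of matrix equality is
attempted (none is established for this design).

## Synthetic cohort generator

The generator defines the study conditions the package is validated
under: 40 animals per group, a 30-column trait panel (26 simulated
directly, plus roaming entropy of two trials, habituation, and the
discrimination index derived from simulated raw records), variance-ratio
effects of 2.5 confined to behavior- and plasticity-related traits
(object exploration, BrdU⁺ cells, new neurons, new astrocytes, motor
cortex thickness), mean shifts on body size and metabolism, and
correlated blocks (metabolic triad ρ = 0.5; neurogenesis triad ρ = 0.8;
body-size triad ρ = 0.6). Eight CTRL animals lose their trial-2 tracking
record; cortical thickness and corticosterone carry a few percent MCAR
missingness. Effect sizes are illustrative of a realistic screen, not
estimates from any particular cohort.

Mechanics and their rationale:

* **Correlated traits** are drawn via a Gaussian copula per block with
  latent correlation r = 2 sin(πρ_S/6), so the realized *Spearman* ρ
  converges to the declared target under any monotone marginal —
  including the lognormal ones.
* **Lognormal marginals** interpret `ctrl_mean`/`ctrl_sd` (and the shift
  and variance ratio) on the data scale, with log-scale μ, σ solved by
  moment matching, so "variance ratio 2.5" means the same thing for every
  family.
* **Missingness** is completely at random per trait: the losses being
  emulated are technical (staining failures, lost recordings), not
  outcome-dependent.
* **Trajectories** are reflected Gaussian random walks (default: 60 cm
  arena, 300 s at dt = 0.2 s, 4 cm step dispersion) with a constant
  outward drift toward the nearest wall (thigmotaxis, 1 cm/step), a
  short-range repulsion from the lit corner decaying linearly over half
  the arena diagonal, and a per-trial step-dispersion multiplier
  `habituation_factor` < 1 on trial 2 — the simplest process that
  reproduces peripheral occupancy heat maps, a corner-avoidance
  asymmetry, and a positive mean ΔRE. Cohort-level runs add per-animal
  lognormal jitter on the step scale and group-specific habituation
  distributions (CTRL 0.85 ± 0.05, ENR 0.70 ± 0.12, clipped to [0.05, 1])
  with a mild ENR step shrinkage (×0.85), giving the enriched group lower
  RE and stronger, more variable habituation.

What the generator does **not** emulate — and what passing tests
therefore cannot certify about real data: autocorrelated measurement
sessions, informative missingness, litter/cage substructure within
groups, heavy-tailed contamination beyond lognormality, social dynamics
in the enrichment cage, or any mechanistic link between the simulated
neurogenesis counts and the simulated behavior. Validation here shows
the *statistical machinery* is calibrated and powered as designed, not
that any biological effect exists.

## Numerical and design choices

* Explicit seeds everywhere (`numpy.random.default_rng`); no global
  state. The pipeline derives per-stage sub-seeds by hashing
  (seed, stage-name), so stages are independently reproducible and all
  derived seeds stay below 2³¹.
* Trial-2 trajectories use a seed sequence (walk seed, trial), so the two
  trials of one animal are distinct but jointly deterministic.
* Entropy at the extremes is clipped into [0, 1] to absorb float
  round-off (≤ 1e−15) at the uniform limit.
* Degenerate inputs fail loudly and specifically: single-sample
  trajectories, k < 2 grids, constant samples in Shapiro–Wilk, zero
  variance in the F denominator, all-zero exploration in DI,
  non-positive-definite correlation blocks.
* Problem sizes in the validation suite: the null-calibration and
  power-recovery simulations use 5000 replicate cohorts at 40/group; the
  analytic-vs-Monte-Carlo power check uses 100,000 replicates
  (vectorized); trajectory property checks use 60–200 simulated trials of
  60–120 s at dt = 0.2–0.25 s, which is ample for sign and bound checks.

## Known limitations

* Longitudinal traits (e.g. repeated body weights) are analyzed per time
  point cross-sectionally; mixed-effects and rank-based longitudinal
  models are out of scope and better served by dedicated packages.
* The Brown–Forsythe branch is mildly conservative (see above), so
  variance effects in non-normal traits are detected at slightly below
  nominal power.
* The normality gate at n = 40/group has its own error rates; traits
  near the gate boundary can switch branches between cohorts, which the
  loop-closure tests account for by tracking the branch mixture.
* `spearman_matrix` is O(traits² · n log n) with a Python pair loop —
  fine for tens of traits, not built for omics-scale matrices.
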