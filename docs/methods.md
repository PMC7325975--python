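# Methods

This note documents the models, estimators and design choices behind
`custress`, in the order the pipeline uses them. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from external data.

## Treatment schedules and dose-days

A schedule is a non-decreasing daily concentration vector (copper is only
added, never removed); day *i*'s concentration prevails for the whole
24-hour period following that day's addition. *Dose-days* are the discrete
area under the curve, Σᵢ cᵢ (mM·day), computed with a compensated sum. We
chose the daily-sum convention (each post-addition level held exactly one
day) because it matches the 24-hour addition cadence and makes the default
pairing exactly dose-equivalent: an n-day linear ramp to concentration *c*
delivers Σᵢ c·i/n = c·(n+1)/2 dose-days and a step to *c* on day *s*
delivers c·(n−s+1), so the default n = 9, s = 5 gives 5c in both arms. The
5-day copper-free pre-incubation is a property of the simulated experiment,
not of the schedule, so dose-day accounting covers only the treatment
phase. Daily nutrient additions are assumed to have no effect; they exist
in the real protocol only so arms differ solely in copper delivery.

## The synthetic experiment

The generator's job is to emulate the *statistical structure* of a
liquid-culture panel experiment — isolate heterogeneity, four qualitatively
distinct reaction patterns, strategy quadrants, optional phylogenetic trait
structure — not copper toxicology. Per isolate it integrates, with Heun's
method at dt = 0.01 day:

    dB/dt = r_max · B (1 − B/K_cap) · inhib(c) · e^(−damage)
    d(damage)/dt = damage_rate · c(t)
    dQ/dt = [uptake_vmax · c/(c + uptake_halfsat) + baseline_uptake] · B
            − efflux_rate · e^(−damage) · Q

with `inhib(c) = 1/(1 + (c/ec50)^hill)`, plus a multiplicative shock
`B ← B · exp(−shock_sens · (Δc − jump_thresh))` at any day boundary whose
concentration jump Δc exceeds `jump_thresh`. Copper accumulation is
Q(T)/B(T) (mg · g⁻¹). Lognormal noise (sd `noise_sigma` on the log scale)
is applied once to each endpoint, matching a single-harvest measurement
design; trajectories themselves are deterministic.

Model-structure notes:

* **Why Heun rather than forward Euler.** At dt = 0.01 forward Euler
  deviates from the logistic closed form by up to 5 × 10⁻³ relative in the
  exponential-phase regime (r = 0.4, K = 4 g over 14 days), too coarse for
  a 10⁻³ oracle check; Heun at the same step is accurate to ~10⁻⁵ at twice
  the cost. A divergence guard raises `SimulationDivergedError` on
  non-finite or non-positive biomass.
* **Why uptake is saturable.** Under dose-day-equalized schedules, any
  uptake law of the form f(c, cumulative dose)·B integrates to an
  arm-independent total per frozen unit of biomass (∫c·g(D) ds = G(D_T) is
  the same 5 mM·day in both arms), and biomass weighting then favors the
  abrupt arm, whose exposure coincides with peak biomass. Higher gradual
  accumulation — a robust qualitative outcome in this experimental system —
  therefore requires sensitivity to exposure *duration*: Michaelis–Menten
  saturation in c (half-saturation ~0.1–0.25 mM) makes nine days of partial
  exposure deliver more per-gram uptake than five days at 1 mM. This is
  the kinetic form of the passive cell-wall-binding interpretation.
* **Why damage impairs efflux.** Cumulative exposure damage multiplying
  both the growth rate and the efflux rate encodes the hypothesis that
  chronically damaged cells can neither grow nor run resource-consuming
  exclusion mechanisms. It is what makes damage-prone isolates accumulate
  more copper under gradual delivery.
* **Separability.** Because the growth ODE factors as dB/F(B) = m(t)dt,
  the noise-free endpoint depends on the schedule only through
  ∫ inhib(c(t))·e^(−damage(t)) dt. Two consequences are load-bearing:
  shocks aside, *any* equal-integral pair of schedules produces identical
  endpoints regardless of saturation; and raising concentrations can only
  lower the integral, giving monotonicity of treated biomass in dose.

**Presets.** Four parameter regions map onto the four reaction patterns;
within a region, parameters are jittered uniformly and the panel order is
shuffled (so preset blocks never align with tree-tip order, which would
fabricate phylogenetic signal):

| preset | mechanism | key ranges |
|---|---|---|
| `no_effect` | tolerant | ec50 ∈ [10, 20] mM |
| `uniform_reduction` | pure inhibition, arm-balanced | ec50 ∈ [0.62, 0.80] mM, Hill exponent solved (below) |
| `gradual_worse` | chronic damage | damage_rate ∈ [0.25, 0.45] /(mM·day), ec50 ∈ [2.5, 4] |
| `abrupt_worse` | shock sensitivity | shock_sens ∈ [1.5, 3], jump_thresh 0.2 mM |

The `uniform_reduction` preset exploits separability: for each jittered
ec50 the Hill exponent is solved (Brent's method) so that
Σᵢ inhib(i/9) = 4 + 5·inhib(1), making the ramp and the step *exactly*
equivalent in integrated inhibition — both arms reduce biomass identically
(to integrator precision), which is what "reduced, but no difference
between deliveries" means mechanistically. A root with hill ≥ 1 exists
only for ec50 > 5/9 mM, hence the preset's ec50 range. The default preset
mix (4 : 6 : 5 : 2 over 17 isolates) reproduces the relative pattern
frequencies reported for the original panel; `noise_sigma` defaults to
0.05 (≈5 % endpoint CV), a tight but realistic replicate noise for
gravimetric endpoints on clonal liquid cultures. Growth parameters
(r_max ≈ 0.4–0.9 d⁻¹, K_cap ≈ 0.3–4 g from a 0.01 g inoculum) span
saturated to still-exponential 14-day trajectories, which is what creates
the negative association between control biomass and biomass effect size.

**Seeding.** One master seed; per-replicate noise streams derive from
SHA-256 hashes of (seed, isolate, treatment, replicate), so tables are
bitwise reproducible and independent of evaluation order.

**What the generator does *not* emulate.** Real copper toxicology (ROS,
metallothioneins, pigmentation), between-replicate initial-condition
variation, non-lognormal measurement error, batch effects, or any
particular real isolate. Passing recovery tests therefore demonstrates
that the statistical machinery is correct and well calibrated under the
declared noise model — not that it would label any particular real fungus
correctly.

## Effect sizes and the bootstrap

Effect sizes are unstandardized mean differences (treated − control) in
native units; "absolute" effect size here means *not standardized*, not
|·| — effects are signed and reductions are negative. The replicate within
an arm is the only exchangeable unit, so resampling is with replacement
within arms, independently. CIs are percentile intervals (the minimal
faithful reading of "non-parametric bootstrap"); 9999 iterations and
α = 0.05 by default.

The gradual-vs-abrupt contrast Δ = ES_abrupt − ES_gradual algebraically
cancels the control mean, so only the treated arms are resampled. Its
p-value is **studentized**: p_boot doubles the smaller tail proportion of
t\* = (D\* − Δ)/SE\* relative to t_obs = Δ/SE, with the (count+1)/(m+1)
correction so p ≥ 2/(n_boot+1). The raw percentile distribution was
measured to reject a true three-arm null at 10–12 % at n = 5 per arm
(bootstrap variance deficit of (n−1)/n per arm compounded by a noisy
variance estimate; recentring alone does not fix it), while the
studentized version rejects at 3.5–4.5 % with a null p-distribution within
KS ≤ 0.03 of uniform. Equal-size treated arms use a mirrored resample
layout (each index pair appears once per role ordering) plus symmetric
quantile evaluation, making the contrast *exactly* antisymmetric under arm
swap: Δ and the CI negate, p_boot is unchanged. No multiplicity correction
is applied across isolates — deliberately mirroring common practice in
this experimental literature — and the report says so.

## Classification rules

The four reaction patterns are narrative categories; the classifier
formalizes them as an ordered decision rule at one α over one inferential
family (the bootstrap — Tukey results are reported alongside but never
drive the call, to avoid mixing two test families in one rule):

1. neither arm's ES CI excludes 0 → `no_effect`
2. contrast p_boot ≥ α → `uniform_reduction`
3. ES_gradual < ES_abrupt → `gradual_worse`
4. otherwise → `abrupt_worse`

The rule is total and deterministic. Strategy quadrants split the biomass
ES and the copper ES at the *panel medians* for the same arm (no absolute
thresholds exist for these axes); values exactly at a median tie-break to
the "lower" side, so an isolate sitting on both medians is
`d_inhibited_exclude`.

## Classical tests

Tukey HSD uses the pooled MSE with N − k degrees of freedom and
q = |ȳᵢ − ȳⱼ| / √(MSE/2 · (1/nᵢ + 1/nⱼ)) against the studentized-range
distribution (scipy's quantile routine; agreement with a 10⁶-draw
Monte-Carlo range oracle is ~10⁻³ in p). Zero pooled variance with unequal
means reports p at the machine floor with a warning. Per isolate the ANOVA
is run jointly on all three arms. Pearson correlations (isolate means, one
point per isolate) carry t-test p-values and Fisher-z CIs
(atanh r ± z₀.₉₇₅/√(n−3), back-transformed); r = ±1 degenerates to a point
CI with p = 0.

## Phylogenetic signal

The tip covariance matrix C holds shared root-to-MRCA path lengths
(diagonal = root-to-tip depths), built in one post-order sweep.
Zero-length terminal branches are perturbed by 10⁻⁸ × tree depth (with a
warning) to keep C invertible. Blomberg's K divides the observed
MSE₀/MSE ratio about the phylogenetic GLS mean by its Brownian-motion
expectation [tr C − n/(1ᵀC⁻¹1)]/(n−1); K is invariant to affine trait
transformations and to uniform branch rescaling, both asserted
numerically. Significance comes from shuffling trait values across tips
(999 permutations by default — a standard choice; the original test's
null) with the +1-corrected p. The pipeline runs the test on the six
isolate-mean response vectors and reports unadjusted p-values. Simulated
Yule trees use general-sampling-approach conditioning so terminal branches
have positive length.

## Numerical and degenerate-input policy

Invalid schedule or simulator parameters raise `InvalidParameterError`;
groups with fewer than 2 replicates raise `InsufficientReplicationError`;
constant traits or singular covariances raise `UndefinedStatisticError`;
mismatched α between effect sizes and contrast raises
`ConfigurationError`. Replicate tables are validated on read (unknown
treatments, non-numeric or non-positive responses, duplicate keys, empty
arms) with every offending row listed. Output CSVs are written at full
precision; rounding happens only in the human-readable report.

## Calibration experiments and problem sizes

The `validation` module re-runs the pipeline's statistical guarantees from
scratch; the acceptance tests assert them at these scales, chosen so each
experiment's Monte-Carlo standard error is small against its tolerance
band while the whole suite stays fast:

* contrast type-I error: 3000 three-arm null isolates (n = 5, 999
  bootstrap iterations) → 5 % ± 2 %;
* percentile-CI coverage: 5000 normal simulations at n = 30 → [0.93, 0.97]
  (true percentile coverage at this n is ≈ 0.94, slightly below nominal,
  as expected for percentile intervals);
* pattern recovery: 40 isolates per rate-sensitive preset at 5 % noise
  (≥ 90 % correct), 200-isolate uniform-reduction panels at 5 % and 15 %
  noise (≤ 10 % false rate-sensitive calls — the false-call rate is
  α-limited because the arms are exactly equivalent by construction);
* Blomberg's K: 500 Brownian simulations on a fixed 32-tip Yule tree
  (mean K ∈ [0.9, 1.1]), 500 signal-free datasets at 199 permutations
  (rejection 5 % ± 2.5 %), and an exact 3-taxon value checked against a
  hand-inverted covariance matrix to 10⁻¹⁰.

## Known limitations

* The mechanistic model is a caricature built to make the four patterns
  and the accumulation asymmetry *attainable*; its parameters have no
  calibrated correspondence to real copper kinetics.
* Percentile CIs under-cover slightly at small n (hence coverage ≈ 0.94 at
  n = 30, lower at n = 5); BCa or studentized intervals would improve this
  at the cost of the simple percentile reading.
* The strategy quadrants are panel-relative (medians), so labels are not
  comparable across panels with different compositions.
* The permutation test for K has power only against clustering-type
  signal; it does not distinguish Brownian motion from other
  signal-generating processes.
* With all-zero copper exposure and no baseline uptake, control
  accumulation is exactly zero and its signal test is undefined; the
  default panels include a small baseline uptake (trace copper in the
  medium) so all six response vectors are testable.
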