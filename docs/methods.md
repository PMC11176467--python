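# Methods

This note documents the statistical model, the estimators' numerical
details, the synthetic-data generator, and the design decisions made where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

Two-sample MR treats each genetic variant j as an instrument: its
association with the exposure (β_Xj, se_Xj) comes from one GWAS, its
association with the outcome (β_Yj, se_Yj) from another, non-overlapping
GWAS. Under the instrument assumptions — relevance (β_Xj ≠ 0),
independence from confounders, and exclusion (the variant affects the
outcome only through the exposure) — each Wald ratio θ̂_j = β_Yj/β_Xj
estimates the causal effect θ on the log-odds (or trait-SD) scale, and the
estimators below pool them. Horizontal pleiotropy violates exclusion;
the Egger intercept, weighted median, Cochran's Q and MR-PRESSO address it
in different ways. Effects from case-control GWAS are log-odds; the
non-collapsibility of odds ratios means mediation proportions computed on
this scale are approximations (see Limitations).

## Pipeline stages and parameters

**Instrument selection.** Candidates must pass `p < p_threshold` (default
5e-8, genome-wide significance). Greedy clumping then walks candidates in
ascending p-order (ties broken by chromosome, position, SNP id for
determinism) and accepts a SNP iff no already-accepted SNP lies within
± `window_kb`·1000 bp (default 10,000 kb, inclusive, 1-based coordinates)
on the same chromosome with r² ≥ `r2_max` (default 0.001). LD information
is a caller-supplied pairwise r² lookup (pair list or square matrix file) —
the package ships no reference panel; without one the distance rule alone
applies and the relaxation is logged. Pairs absent from a supplied lookup
count as unlinked.

**Harmonization.** Outcome effects are re-expressed for the exposure's
effect allele: matching orientation is kept; swapped alleles negate the
outcome beta and complement its frequency; strand-complement matches are
complemented first. Palindromic SNPs (A/T, C/G) carry no strand information
in their allele letters, so under the default `drop_ambiguous_frequency`
policy a palindrome is dropped when either trait's effect-allele frequency
is missing or within `ambiguity_window` (default 0.08) of 0.5, and
otherwise oriented by whether the two frequencies fall on the same side of
0.5. The stricter `drop_all` policy removes every palindrome. Incompatible
allele pairs are always removed; every removal is written to an audit table
with a reason code. Duplicate SNP ids in either input are a hard error
(ambiguous join).

**Instrument strength.** Per-SNP F_j = (β_Xj/se_Xj)²; the mean is compared
with the conventional adequacy threshold of 10. This per-SNP formula is the
implemented choice; variance-explained (R²-based) alternatives exist and
give systematically different values, which is worth remembering when
comparing reported mean F values across analyses.

**Estimators.**

- *IVW*: closed-form precision-weighted mean; `mode="auto"` (the headline
  rule) uses multiplicative random-effects inflation √max(1, Q/(J−1)) iff
  Cochran's Q p < 0.05, else fixed effects. The multiplicative (rather than
  additive) random-effects model was chosen to match the Egger treatment
  and common practice.
- *MR-Egger*: weighted least squares (statsmodels WLS) of β_Y on β_X with
  intercept, weights 1/se_Y²; both SEs inflated by √max(1, Q/(J−2)).
  Instruments are re-signed so β_Xj ≥ 0 before fitting; this orientation
  convention is recorded in the run manifest. A consequence verified in the
  test suite: directional pleiotropy planted relative to the *unoriented*
  effects is partially cancelled by re-signing of negative-strength
  instruments, so intercept-recovery studies must plant pleiotropy on
  positively-oriented instruments. Egger additionally needs instrument
  strengths that are well spread relative to their SEs (the NOME
  assumption); with strength spread comparable to the exposure SE,
  regression dilution biases slope and intercept for any correct
  implementation.
- *Weighted median*: ratios sorted, standardized midpoint-cumulative
  weights s_j = (Σ_{k≤j}w_k − w_j/2)/Σw interpolated at 0.5. The penalized
  variant multiplies each weight by min(1, 20·q_j), q_j the χ²(1) upper
  tail of that SNP's Q contribution around the unpenalized estimate; the
  constant 20 is configurable. SEs are the SD of the estimate over `n_boot`
  (default 1000) parametric-bootstrap resamples redrawing both betas from
  their sampling normals, with an explicit seed; the bootstrap is batched
  so the default costs milliseconds.
- *Maximum likelihood*: the profile objective
  f(θ) = ½Σ(β_Yj − θβ_Xj)²/(se_Yj² + θ²se_Xj²) is minimized (Nelder-Mead,
  started at the IVW estimate); the SE is the inverse square root of the
  numeric second derivative at the optimum (central differences,
  h = 1e-5·(1+|θ̂|)). Non-convergence raises an error carrying the
  optimizer diagnostics.

All point estimates get normal-approximation two-sided p-values and 95%
CIs on the log-odds scale; empirical and analytic p-values are clamped into
(0, 1] so downstream invariants hold under extreme z.

**Diagnostics.** Cochran's Q decomposes exactly into per-SNP contributions
w_j(θ̂_j − fitted_j)² with df J−1 (IVW) or J−2 (Egger). Leave-one-out
re-estimates with each SNP removed; a SNP is flagged as influential when
its removal moves the estimate outside the all-SNP CI, when the all-SNP
estimate falls outside the leave-one-out CI, or when the sign flips. The
second direction is needed because a strong outlier inflates the
random-effects full CI enough to swallow its own removal (the shift-to-SE
ratio is bounded by √((J−1)/J)); the leave-one-out CI, clean of the
outlier, still exposes it. Funnel symmetry is summarized quantitatively by
the precision-weighted skewness of ratios around the IVW estimate
(|skew| < 0.5 reported as symmetric, configurable), so what is usually a
visual check is assertable.

**MR-PRESSO.** The observed statistic is the weighted residual sum
Σ_j(β_Yj − θ̂_(−j)β_Xj)²/se_Yj² with θ̂_(−j) the leave-one-out IVW slope.
The null is built from `n_dist` (default 1000) parametric simulations
redrawing the outcome-side effects from normals centered on the fitted
values with the observed SEs — exposure effects are held at their observed
values, a simplification of the published construction that redraws both
sides; each simulated dataset gets its own leave-one-out slopes. Empirical
p-values use the add-one rule (1 + #{sim ≥ obs})/(n_dist + 1) and are never
zero. A SNP is an outlier when its Bonferroni-adjusted per-SNP p is below
0.05; the outlier hunt runs only when the global test fires. The distortion
test compares (corrected − raw)/raw against the distribution obtained by
removing random same-size subsets. One seed drives the whole bundle
bit-reproducibly. The whole simulation is vectorized ((n_dist × J) arrays),
so 1000 distributions on 20–50 SNPs cost milliseconds.

**Mediation.** indirect = β₂β₃ exactly; SE by the first-order (Sobel)
delta method with zero covariance — justified because β₂ and β₃ come from
independent two-sample analyses. direct = β₁ − β₂β₃ with
SE = √(se₁² + indirect_se²). proportion = indirect/β₁ with an approximate
delta-method SE computed without dividing by the (possibly tiny) indirect
effect. |β₂β₃| ≥ |β₁| indicates a logical inconsistency; the result is
returned with `consistent=False` and a logged warning. A zero total effect
makes the proportion undefined (error by default, None on request).

## The synthetic-data generator

Simulation is at the summary level: strengths γ_j ~ N(mean, sd²) with
|γ_j| clipped away from zero, observed β_Xj = γ_j + N(0, se_X²), observed
β_Yj = θγ_j + α_j + N(0, se_Y²), with pleiotropy α_j on a configurable
fraction of SNPs (balanced, directional, or correlated-with-γ, the last
violating the InSIDE assumption). The mediation scenario adds independent
mediator instruments δ_j and builds three GWAS tables over all SNPs with
true effects (γ, β₂γ, β₁γ) and (0, δ, β₃δ), so β₁ = direct + β₂β₃ by
construction. One root seed is split via `numpy.random.SeedSequence.spawn`
into per-stage streams, making every output bit-reproducible.

Defaults describe a well-powered two-sample study at the scale of large
psychiatric/neurological GWAS: J = 50 instruments, γ ~ N(0.10, 0.02²)
clipped at 0.06, se_X = 0.018 (per-SNP F ≈ 30, comfortably past the F ≥ 10
rule), se_Y = 0.03, θ = 0.278 log-odds (the scale of a depression→migraine
effect), and a mediation block β₂ = 0.084, β₃ = 0.569, direct = 0.230204
(β₁ = 0.278, true proportion mediated 17.19%) with 36 mediator instruments
at se_M = 0.01. Allele metadata (frequencies uniform on [0.05, 0.95],
optional palindromic fraction, default 0 — i.e. instruments that already
survived palindrome filtering) and optional block-LD pair lists exist so
the selection and harmonization stages are exercisable; positions place
independent SNPs ≥ 15 Mb apart, outside any ±10 Mb clumping window.

What the generator does *not* emulate: realistic LD beyond block
structure, sample overlap between the two GWAS, liability-scale
binary-trait effects, allele-frequency-dependent power, population
stratification. Passing tests therefore demonstrate correctness of the
estimators and pipeline under the stated sampling model, not robustness to
every artifact of real consortium data.

## Simulation-study design choices

- *IVW calibration* (bias within 2 Monte-Carlo SEs, coverage in
  [0.92, 0.975]; 500 replicates, J = 50, F ≈ 30) uses a null causal effect.
  Ratio estimators carry a weak-instrument attenuation of relative order
  1/F that scales with θ (at θ = 0.278 and F ≈ 30 it is ≈ −3%, larger than
  2 MC SEs at 500 replicates for any |θ| ≳ 0.1), so a null design is the
  one that isolates implementation bias and CI calibration from that known
  property. The paper-scale attenuation is reported separately by the
  acceptance script (`ivw_attenuation_pct`) rather than hidden.
- *Egger intercept recovery* uses positive-support, well-spread strengths
  (γ ~ N(0.12, 0.04²), min 0.02) with se_X = 0.005, for the orientation and
  NOME reasons above.
- *Weighted-median robustness* plants directional pleiotropy (mean 0.05)
  on 40% of instruments and compares absolute mean bias against IVW.
- *PRESSO power* plants a 10×-noise outlier among 20 SNPs; the
  *distortion-recovery* scenario plants a 20×-noise outlier because with a
  c·σ outlier among J instruments the probability the corrected estimate
  beats the raw one is Φ(c/(2√J)) — about 0.87 at c = 10, J = 20, and
  about 0.99 at c = 20 — a property of the comparison, not of the test.
- *End-to-end mediation recovery* runs selection → harmonization → IVW per
  pair → decomposition on 200 replicates of the default mediation scenario.
  Genome-wide selection on the observed exposure GWAS induces winner's-curse
  attenuation in β̂₁ and β̂₂ individually, but both use the same selected
  instruments and proportional weights, so the attenuation cancels in the
  proportion β̂₂β̂₃/β̂₁ — which is why the proportion is recoverable at
  these instrument strengths even though roughly half the simulated
  instruments fail the 5e-8 filter in any one replicate.

Replicate counts (500/200/2000/100) balance Monte-Carlo resolution against
a single-CPU budget; the full acceptance script runs in ~20 s.

## Known limitations

- Proportions mediated are computed on the log-odds scale; odds-ratio
  non-collapsibility means they are not exactly proportions of a
  collapsible effect. This mirrors standard practice and is documented, not
  corrected.
- The Egger p-values use the normal approximation (not t with J−2 df);
  with few instruments they are slightly anti-conservative.
- Multi-allelic variants, genome-build liftover, and remote
  confounder-lookup services are out of scope; LD must be supplied by the
  caller.
- No multiple-testing correction is applied across trait pairs, matching
  the analysis shape the package reproduces; the report tables carry raw
  p-values.
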