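# Methods

## Task model

One trial of the simulated task presents a cloud of 1100 dots (250 ms)
whose per-dot direction is

    dot_direction = sign(stimulus) * mean_orientation + N(0, direction_sd)

with sign −1/+1 for left/right of vertical and `direction_sd` fixed per
variance condition (defaults 20° and 30°). Dots are never rendered; the
formula defines the stimulus statistics the observer responds to, and
`sample_dot_directions` exposes it directly. Frame-level details of real
displays (dot lifetime, aperture wrap-around, screen geometry) are out of
scope.

Each variance condition runs its own adaptive staircase on
`mean_orientation`: two consecutive correct responses lower the level by
one step (harder), a single error raises it (easier), with the level
clamped to [floor, ceiling]. The rule's asymptotic fixed point is the
accuracy p solving p² = ½, i.e. √0.5 ≈ 70.7% — the mechanism that equates
first-order performance across subjects and groups. Step size 0.5°,
floor 0.1°, ceiling 45° and start level 10° are configurable; none is
dictated by the design itself, so they are package defaults. Conditions
are interleaved by shuffling an exactly balanced sequence within each of
the four 36-trial blocks; staircase state carries across blocks.

## Observer model

The two-stage signal-detection observer is this package's construction —
it supplies the statistical structure the analysis assumes, so every
stage is testable on synthetic data with known ground truth.

1. First-order evidence: `x ~ N(sign * k_signal * level * penalty(v),
   sigma_perc)`; the choice is right iff x > 0. `k_signal` (evidence
   units per degree, default 0.08 with `sigma_perc` = 1) sets the
   psychometric slope; `variance_penalty` (default 1.0 at 20°, 0.75 at
   30°) attenuates the effective signal in the high-variance condition,
   so its staircase settles at a higher orientation.
2. Confidence: a second-order copy `x2 = x + N(0, sigma_meta)` is read
   out as `confidence = logistic(conf_gain * (|x2| − conf_center))`.
   `sigma_meta` is the metacognitive-noise parameter: at 0 confidence is
   a deterministic function of the decision evidence (the observer's
   information ceiling), and as it grows AUROC2 falls to 0.5. With
   `conf_gain = 0` confidence is constant at the midpoint.
3. Response times are shifted-lognormal (`rt_location_ms +
   rt_scale_ms * exp(rt_sigma * Z)`, clipped to the response window);
   with probability `p_fast` (default 0.01) an anticipatory <100 ms
   response occurs and with `p_miss` (default 0.02) the response is
   missing — both are exclusion fodder, mirroring real lapses. The
   confidence-slider start position (jittered ±12% around midpoint) is
   retained as a column for realism but never analysed.

### Default calibration

Group defaults model a noradrenergic-blockade study: placebo and the
dopaminergic group share `sigma_meta = 0.8`, the noradrenergic group gets
`sigma_meta = 0.25`; nothing else differs. Two constraints fixed these
numbers. First, the start level should sit near the staircase equilibrium
(6.8°/9.1° at k_signal = 0.08), as after a training phase whose final
threshold seeds the main task; a much steeper psychometric slope would
put equilibrium far below the start and inflate within-session accuracy.
Second, at the 70.7% operating point the observer's information ceiling
is AUROC2 ≈ 0.675 (measured with `sigma_meta = 0`), so group means of
roughly 0.60 vs 0.67 with a subject-level Cohen's d ≈ 1.2 are the largest
realistic contrast this architecture supports; we chose the pair that
reproduces an effect size of that magnitude rather than pushing the
placebo mean higher at the cost of a vanishing drug effect.

A known artefact of the readout: `sigma_meta` inflates |x2| on average,
so it also shifts the overall confidence level, not only its coupling to
accuracy. Group contrasts in median confidence therefore mix a main
effect into what a real drug might express purely as a
group-by-correctness interaction. Conclusions from synthetic cohorts
about *which* confidence statistic carries an effect should be read with
that in mind; AUROC2 itself is bias-free by construction.

Seeding is counter-based: subject i draws from
`SeedSequence(master_seed, spawn_key=(i,))`, so cohorts are byte-for-byte
reproducible and earlier subjects are invariant to roster growth.

## Preprocessing

* Block 1 dropped (staircase stabilisation), then trials with rt <
  100 ms, rt > 1500 ms, or missing response/confidence; variance
  conditions pooled. A clean 144-trial session keeps 108 trials. The
  exclusion report's categories are disjoint and always sum.
* Subject exclusion: accuracy below Q1 − 1.5·IQR (lower whisker of a
  boxplot; quartiles by linear interpolation). Only the lower fence is
  applied — the rule targets poor performers. The rule can be disabled
  (`outlier_rule: none`).
* Confidence binning: per-subject six-quantile bins. A rating exactly on
  a boundary takes the lower bin, so ties never split and the map is
  monotone; with 108 distinct ratings bins hold exactly 18 trials.
  Subjects with no error (or no correct) trials after filtering have an
  undefined type-II ROC; they are reported and dropped from AUROC2
  analyses, never imputed.

## Metrics

AUROC2 is computed from the binned ratings via cumulative-rate trapezoid
area, which provably equals the tie-corrected Mann–Whitney probability;
the test suite pins the implementation to an exhaustive pairwise oracle
at 1e−12 on a thousand random instances. Computing from the continuous
ratings instead is available (`n_bins` large) but binned is the default
analysis path. d′ and c use the conventions above; a
`printed_criterion_sign` switch exposes the variant c = −(z(H) − z(FA))/2
that sometimes appears in print, which makes c proportional to d′ and is
not the default. Empty rate cells get a half-count (1/(2N)) correction.

## Inference

One-way ANOVA and pooled t-tests are computed from sums of squares
(η² = SS_between/SS_total; d = mean difference / pooled SD; with two
groups F = t² exactly). The ANCOVA fits `value ~ group + covariates` by
OLS and tests the group factor by extra sums of squares — the Type-III
partial test, appropriate because the covariates are continuous and the
question is the adjusted group effect. The 2×2 mixed ANOVA delegates to
`pingouin.mixed_anova`, with η² recomputed as SS_effect over the total SS
of the data; an independent split-plot sums-of-squares decomposition
serves as its oracle in the tests. No multiplicity correction is applied.

The Bayesian two-sample t-test uses the JZS family: effect size
δ ~ Cauchy(0, r) under the alternative (default r = 1), equivalently
g ~ InvGamma(½, r²/2) mixing the variance. BF01 is computed by adaptive
quadrature over the scale-free variable g/r² (tolerances 1e−12 absolute,
1e−10 relative) and verified against a 200,001-point fine-grid trapezoid
oracle to four significant figures. A Normal(0, r²) "unit-information"
prior is available in closed form (`prior="normal"`); the Cauchy form is
the default. As r → 0 the prior collapses on the null and BF01 → 1.

## Problem sizes and determinism

Simulation-based checks use the study-scale design throughout: 144
trials/subject, 20 subjects/group. The staircase fixed-point check runs
12,000 trials discarding 2,000 burn-in; parameter-recovery and null-
calibration studies use 100 replicate cohorts each. Every stochastic
path is seeded; identical (config, seed) pairs reproduce all output
files byte for byte.

## Limitations

* The observer has no sequential dynamics: no learning, fatigue, serial
  dependence of confidence, or post-error slowing; RTs are independent
  of evidence strength.
* Confidence bias (scale use) is homogeneous across simulated subjects
  except through `sigma_meta`'s level artefact noted above; AUROC2's
  robustness to idiosyncratic scale use is therefore exercised only via
  the binning equivariance property, not via realistic heterogeneity.
* The mixed ANOVA path assumes both correctness cells exist per subject;
  subjects without errors are excluded upstream.
* Passing tests on synthetic cohorts shows the pipeline recovers effects
  under the stated generative assumptions, not that those assumptions
  hold for any particular real dataset.
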