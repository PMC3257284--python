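# Methods

This note documents the models, estimators, and numerical choices behind
lacprofiler, and what the synthetic-data generator does and does not emulate.

## Synthetic single-cell fluorescence

The generator is phenomenological: it reproduces the statistical structure
the downstream analysis assumes, not the biochemistry of the LacI/LacY
positive-feedback switch.

- The induced fraction at inducer concentration *c* follows a Hill function
  `p(c) = c^h / (c^h + K^h)`; `p(K) = 1/2` exactly for any steepness *h*.
- A **bimodal** strain assigns each cell independently to a low or high
  log-normal expression mode with probability `p(c)`. A **graded** strain
  draws every cell from a single log-normal whose log-median interpolates
  linearly from the low to the high mode's log-median by the same Hill
  fraction. A **constitutive** strain draws from the high mode at every
  concentration. Expression modes are log-normal because flow data are
  acquired in log mode and show heavy right tails; the paper-free choice of
  distribution is a stand-in, not a mechanistic claim.
- Defaults describe an ancestor-like switch: `K = 25 µM`, `h = 5.6`, low and
  high mode medians 1.5 and 84 RFU (CVs 0.40/0.35), 25,000 events per well,
  a 12-point TMG ladder (0–100 µM). With these settings the two-mode
  coexistence band (minority fraction ≥ 5%) spans ≈15–42 µM, so the tested
  concentrations flagged bimodal are 15–30 µM. The steepness 5.6 was chosen
  once so that the 15 µM ladder point sits just inside the coexistence band;
  the lower-threshold strain uses `K = 4 µM`. The RFP (CRP-reporter) channel
  is log-normal and inducer-independent. Scatter is bivariate normal;
  spillover defaults to 2% GFP→FL2 and 1% RFP→FL1.
- Because a graded strain's *median* interpolates geometrically while the
  half-max metric is defined on the *arithmetic* mean, the measured TMG½Max
  of a graded strain sits somewhat above its generator `K` (≈5.3 µM for
  `K = 4`); this is a property of the metric, not an estimator error, and it
  stays within one ladder step of `K`.
- All randomness flows from one integer seed per generator call;
  per-concentration streams are derived with `SeedSequence([seed, i])`, so
  outputs are bit-identical across runs.

What the generator does **not** emulate: instrument log-binning and
saturation, autofluorescence, doublets, day effects, cell-cycle structure,
or any correlation between scatter and expression. Passing recovery tests on
this generator therefore demonstrates correctness of the estimators under
the stated statistical model, not robustness to every instrument artifact.

## Flow-cytometry pipeline

- **Compensation** inverts the 2×2 spillover matrix per event; negative
  compensated values are clamped to zero and counted (`attrs["n_clamped"]`),
  never dropped, so induced-fraction denominators are preserved.
- **Gate.** The gate center is the mode of a smoothed 2-D histogram of
  (FSC, SSC) (64 bins per axis, Gaussian smoothing σ = 3 bins, parabolic
  refinement of the peak bin). The covariance is the population covariance
  of events inside the 97.5% chi-square contour of an initial fit, rescaled
  by the analytic truncation consistency factor
  `E[r² | r² < u]/2 = (2 − (u+2)e^{−u/2})/(2q)`; this trimmed estimator
  resists fluorescence-correlated outliers at a small fraction of the cost
  of a full minimum-covariance-determinant fit. Population (ddof = 0)
  covariance keeps the gate exactly invariant under duplication of the event
  list. Gating retains events with Mahalanobis distance ≤ threshold
  (default 0.5, retaining `1 − e^{−t²/2}` ≈ 11.75% of a bivariate normal).
- **Bimodality.** 1- vs 2-component Gaussian mixtures on log₁₀ RFU (values
  floored at 0.01 RFU), `n_init = 2` with a fixed random state so calls are
  deterministic. Bimodal iff ΔBIC ≥ 10 *and* both weights ≥ 5% *and* mode
  separation ≥ 0.5 decades. The thresholds are explicit because the
  published description of the original detector is not; they reproduce the
  qualitative calls on synthetic analogues and are exposed as keyword
  arguments.
- **TMG½Max** interpolates linearly in log₁₀ concentration between the
  bracketing tested points (ladders are log-spaced); an exact grid hit is
  returned exactly; the segment anchored at 0 µM is interpolated linearly in
  concentration since log spacing is undefined there. A flat profile
  (baseline = saturation, e.g. constitutive strains) has no half-max and
  returns `None` with a warning.
- **Class precedence** is constitutive (< 2-fold mean variation) → bimodal
  (any flagged concentration) → lower-threshold/graded. Constitutive is
  checked first because a flat profile makes the other two metrics
  meaningless.

## Growth-curve analysis

The μMax estimand is the steepest slope of ln(OD600) versus time over a
10-point sliding window; lag is that regression line extrapolated to the
constant reference density OD600 = 0.06 (a fixed reference is used instead
of each curve's initial density because initial densities are noisy).
Numerical choices:

- OD values are floored at 10⁻³ (plate-reader detection-limit scale) before
  the log transform.
- Windows with regression r² < 0.98 are ineligible, so read noise cannot
  masquerade as fast growth; a perfectly flat window counts as r² = 1.
- **Stabilization (default).** Reporting the literal steepest single window
  is an extreme-value statistic: with read noise of 0.002 OD it is biased
  upward by several times the printed uncertainty of typical rate estimates.
  By default the sliding windows are therefore used only to *locate* the
  steepest cleanly-exponential stretch: the contiguous block of eligible
  windows with the largest median slope is selected (median, so one lucky
  noisy window cannot win), windows whose slope deviates > 4% from the block
  median (boundary-straddling windows) are dropped, and the phase support is
  refined by expanding outward from the block center while residuals stay
  within 3 robust SDs of the line (absolute floor 10⁻⁹ for noise-free
  input). One pooled regression over that support gives the rate and
  intercept. On noise-free piecewise-exponential input only exactly-on-line
  points survive the refinement, so the recovered rate and lag are exact to
  machine precision; under noise the pooled fit is unbiased with a standard
  error several-fold below the single-window rule. `stabilize=False`
  restores the literal steepest-window behaviour.
- **Diauxie.** Candidate phases are contiguous runs of windows with slope
  ≥ 50% of the curve maximum; the two steepest runs become phases 1 and 2.
  The "end of the first growth phase" OD is operationalized as the OD at the
  center of the minimum-slope window between the phases (it is not defined
  numerically elsewhere), and the diauxic lag is the time between the two
  phase lines crossing that OD. If the inter-phase slope minimum exceeds 50%
  of the smaller phase rate, growth never paused and the diauxic lag is
  reported as "none" — this rule fires both for single-exponential curves
  and for a zero-length plateau (a kink), keeping the two cases consistent.
- Negative extrapolated lags are reported and flagged rather than clipped;
  they are diagnostic of a curve already past the reference density.
- An optional `od_range` restricts eligible windows to a density band, for
  rate comparisons over matched ranges (e.g. a mutant's single phase against
  an ancestor's second phase). The choice of band is exposed, not
  hard-coded, because which windows to exclude is a judgment call.
- The growth generator starts curves at the 0.06 reference density so that
  its `lag1` parameter *is* the reference-density lag, making ground truth
  exact; real curves start lower and their extrapolated lag depends on the
  reference convention.

## Fitness

`W = ln(Ñ_T2/N_T0)/ln(Ñ_R2/N_R0)` with `Ñ_x2 = N_x2 · D^(cycles−1)`: the
intermediate transfer dilutions are compounded back into both final
densities, making W the Malthusian ratio over the full propagation. The
correction is identical for both competitors, so it cancels from every
between-strain comparison and reduces to the plain formula for one cycle. A
per-generation normalization (`1 + (m_T − m_R)/(g·ln 2)`) is available
behind a flag but off by default. Reference final/initial ratios ≤ 1 make
the denominator undefined and raise. Replicate sets are summarized with a
t-based 95% CI and a two-tailed one-sample t-test against W = 1 (Welch's
test is provided separately for A-vs-B comparisons); zero-variance replicate
sets yield a degenerate CI and an undefined P, both flagged rather than
fabricated.

## Mutation target size and association

The target model multiplies locus length × per-bp rate × deleterious
fraction, reporting both the exact product (21 × 5×10⁻¹⁰ = 1.05×10⁻⁸;
÷3 = 3.5×10⁻⁹) and the 1-significant-figure rounding path (1×10⁻⁸ → 3×10⁻⁹)
conventional for order-of-magnitude mutation-frequency estimates.

The exact two-sided association P enumerates every 2×2 table with the
observed margins and sums hypergeometric point probabilities ≤ the observed
table's (the "minimum-likelihood" convention, with a 10⁻⁷ relative tolerance
on the comparison; a doubled-one-tail variant is exposed). Degenerate
margins return P = 1 with a warning. The default table reconstruction
classifies each population by its majority-frequency clone's lesion type
(operator vs repressor), pools the lactose-only and alternating environments
against glucose+lactose, and excludes populations carrying both lesion types
(polymorphic); every inclusion decision is emitted in an audit table. The
packaged clone-records table has 46 clones in 24 populations; clone
frequencies that undershoot 1 (isolated clones need not exhaust a
population) warn rather than error.

## Genotyping

Variant calling is anchored exact matching, not general alignment: the
hotspot events are exact 4-bp-unit gains/losses in a 12-bp tract and the
operator events are single-base substitutions, so flank anchoring is both
sufficient and unambiguous. Operator coordinates are 1-based from the first
base of the 21-bp O1 element; the reference validates at load time that
positions 5, 9, and 11 are G, which pins the coordinate convention to the
recognized substitution set (G5A/G9T/G11A). The packaged lacI amplicon is a
**synthetic** in-frame construct (three TGGC repeats with clean flanks, Leu
at codon 71) standing in for the unpublished amplicon sequence; all
genotyping tests are round-trip tests against the paired generator, not
literal sequence comparisons. Missense calling is restricted to a
configurable known-null list (seeded with L71Q) — the package deliberately
does not predict mutational effects.

## Problem sizes used in tests

Property tests run 50 seeds for class recovery, half-max, bimodal range, and
growth recovery; 1,000 meta-replicates (8 Poisson-sampled competitions each)
for CI coverage; and an exhaustive sweep of all 2×2 tables with total ≤ 30
against an integer-arithmetic enumeration oracle. Flow panels use the full
25,000 events per well; unit tests use smaller panels where the property
under test does not depend on event count.

## Known limitations

- The flow generator's independence assumptions (expression ⊥ scatter, no
  temporal drift) mean gate-induced selection effects on fluorescence cannot
  be studied with it.
- The bimodality thresholds (ΔBIC 10, 5% minority, 0.5 decades) are
  package choices; detectors with different thresholds will disagree near
  the boundaries of the bimodal band.
- The diauxie segmenter assumes at most two growth phases and a monotone
  backbone; triauxic curves or death phases are out of scope.
- The association rules engine supports alternative reconstructions (e.g.
  excluding populations with non-unique operator alleles), but no default is
  shipped for them because the population set behind such variants is not
  uniquely determined by the records table.
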