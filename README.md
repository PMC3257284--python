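# lacprofiler

Quantitative analysis of *lac* operon regulatory evolution in *Escherichia
coli*. The package reimplements, as a tested and reusable pipeline, the
measurements used to characterize how experimentally evolved populations
rewire lactose utilization: single-cell inducer-response profiling from flow
cytometry, growth-curve parameter extraction, β-galactosidase and
promoter-activity calculations, serial-transfer competitive fitness,
mutation-target-size modelling with exact association testing, and *lac*
locus genotyping. A synthetic-data generator with known ground truth makes
every stage testable end to end without any instrument data.

It is written for experimental-evolution and systems-biology groups who work
with the *lac* system (or any small regulatory network with a switch-like
reporter) and want the analysis side of such a study — classification of
regulatory phenotypes, growth and fitness statistics, and the population
genetics of small mutational targets — as an importable, deterministic
library rather than a pile of one-off scripts.

## The measurements

**Inducer response.** For each strain, per-cell reporter fluorescence is
measured across a ladder of TMG (a non-metabolizable inducer) concentrations.
After spillover compensation and an elliptical scatter gate (Mahalanobis
distance ≤ 0.5 from the peak of FSC–SSC cell density), each concentration's
log₁₀ fluorescence distribution is tested for bimodality with a 1-vs-2
component Gaussian-mixture comparison (ΔBIC ≥ 10, minority weight ≥ 5%, mode
separation ≥ 0.5 decades). Three metrics summarize the profile: TMG½Max (the
concentration where mean expression crosses halfway between baseline and
saturation, interpolated log-linearly between tested concentrations), the
bimodal concentration range, and the fully induced expression level. A
precedence rule assigns the regulatory class: *constitutive* if mean
expression varies < 2-fold across the ladder, else *bimodal* if any
concentration is bimodal, else *lower-threshold/graded*.

**Growth.** μMax (h⁻¹) is the steepest slope of ln(OD600) vs time over a
10-point sliding window; lag is the μMax regression line extrapolated to the
constant reference density OD600 = 0.06. Diauxic curves are segmented into
two phases; the diauxic lag is the time between the two phase regression
lines crossing the OD at the end of the first growth phase.

**Enzyme assays.** Miller units = (1000 × OD420)/(volume·mL × OD600 ×
minutes) for endpoint assays, or (1000 × slope)/(volume·mL × OD600) for
kinetic assays; promoter activity = Miller units × maximum doubling rate.

**Fitness.** W = ln(N_T2/N_T0)/ln(N_R2/N_R0) over a serial-transfer
competition, with intermediate dilutions compounded back identically into
both competitors' final densities.

**Mutation target size and association.** The 21-bp primary operator at a
point-mutation rate of 5×10⁻¹⁰ /bp/generation yields ~1×10⁻⁸ substitutions
per generation, of which roughly a third of the 63 possible single-base
changes severely impair repressor binding (~3×10⁻⁹) — about 1000-fold below
the repressor-null frequency. Whether operator mutants associate with a
selective environment is tested with an exact two-sided Fisher test computed
by full enumeration of 2×2 tables with the observed margins.

**Genotyping.** Amplicons are called against a reference locus: ±4-bp
repeat-unit events in the *lacI* TGGC×3 hotspot (frameshift → constitutive),
single-base operator substitutions (e.g. G11A → lower threshold), and a
configurable known-null missense list (L71Q).

## Worked example

```python
import lacprofiler as lp
from lacprofiler.flow import SpilloverMatrix, build_profile

panel = lp.generate_flow_panel(
    lp.FlowSimParams(response_class="bimodal", half_max_conc=25.0, seed=1))
profile = build_profile(panel, spill=SpilloverMatrix(), strain="ancestor-like")
print(profile.response_class, profile.tmg_half_max, profile.bimodal_range)
```

prints

```
bimodal 24.903493247251095 (15.0, 30.0)
```

— the strain is correctly called bimodal, with a half-maximal induction
point of ~24.9 µM TMG (generator truth 25 µM) and a bimodal response between
15 and 30 µM, the inducer band where uninduced and fully induced cells
coexist. `examples/` contains one short narrative script per capability
(inducer profiling, growth, enzyme assays, fitness, mutation model and
association, genotyping); each builds a small input, runs the method, and
explains the numbers it prints.

A thin CLI wraps the same functions for shell use:

```bash
lacprofiler demo --out demo --seed 1        # synthetic mini-study
lacprofiler run --data demo --out results   # full pipeline + JSON report
lacprofiler flow|growth|assay|fitness|assoc|genotype --help
```

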