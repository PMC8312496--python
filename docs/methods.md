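# Methods

This note documents the models, estimators, defaults and design choices
behind `thermonorms`, and what the synthetic-data generator does and does
not emulate.

## Growth-rate estimation

The estimator assumes the classical exponential model for the growth phase:
blank-corrected OD obeys OD(t) = OD₀·e^{µt}, with µ the specific growth
rate (h⁻¹) and doubling time T_d = ln 2 / µ. Whole curves are not
exponential (they carry lag, deceleration and stationary phases), so µ is
taken from a windowed log-linear regression:

1. **Blanking.** OD is blank-corrected using the per-plate blank declared in
   the metadata (`blank_od`) when present, otherwise the per-series minimum
   OD — instrument exports are not always blank-corrected, and the reader
   must accept both. Corrected values are floored at a detection limit
   (default OD 0.005) so logarithms are always defined. The floor is the
   practical resolution of plate readers near the medium background; values
   below it carry no usable growth signal.
2. **Growth call.** A curve is scored *no-growth* (µ = 0, T_d undefined)
   when its peak never reaches `growth_threshold` (default 1.5×) times its
   baseline. Peak and baseline are medians of the three largest and three
   earliest corrected values respectively: with a signal floor of a few
   millo-OD, a single noisy sample could otherwise flip the call.
3. **Window search.** Over all contiguous windows of at least `min_points`
   samples (default 5, i.e. 2 h at 30-min sampling), the least-squares
   slope of ln OD is computed via prefix sums (O(1) per window). Among
   windows with R² ≥ `min_r2` (default 0.98) the maximal slope is selected;
   ties (within 1e-12 relative) go to the larger window, then the earlier
   start, which makes the fit fully reproducible and selects the whole
   series on perfect exponentials. If growth is evident but no window
   reaches the R² bar, the global max-slope window is used and the fit is
   flagged `low_quality` rather than dropped.

Replicates are aggregated as mean/SD of µ (no-growth replicates contribute
µ = 0), with a no-growth consensus when a strict majority of replicates are
no-growth; T_d is summarized as ln 2 / mean µ.

The windowed estimator is slightly biased downward on logistic curves
(the log-slope is attenuated by a factor ≈ 1 − x̄/K over the fitted window)
and upward under noise (max-slope selection); with the default 2%
multiplicative log-OD noise the net median relative error is ~2–3%
(measured by the acceptance script).

## Reaction norms, optima and the thermal niche

Reaction norms are empirical: the replicate-mean µ at each assayed grid
temperature, sorted ascending, with no-growth consensus temperatures
contributing µ = 0. No parametric thermal-performance model is fitted to
the norm, and nothing is extrapolated beyond the grid.

The **optimum** is the grid temperature with maximal mean µ. Temperatures
within `plateau_tol` (default 5%) of the maximum are reported as co-optima:
plateau-shaped strains can hold near-maximal growth across several grid
temperatures, and declaring a unique optimum there would be arbitrary.

The **thermal niche** at fraction `f` (default 0.75) is the interval over
which the piecewise-linear interpolant of the norm stays at or above
f·µ_max. Linear interpolation between grid points is the minimal assumption
given point-wise measurements. Crossings are sought outward from the
outermost optima (leftmost optimum leftward, rightmost rightward), stopping
at the first segment that dips below threshold — for non-monotone norms this
"first crossing" convention guarantees the optimum always lies inside the
niche and that niches nest as f grows. A bound whose grid-edge value is
still above threshold is clamped to the edge and flagged *censored*: the
true crossing lies outside the tested range and the reported breadth is a
lower bound.

The niche is computed on the growth rate µ, never on doubling time: a
"75% of maximum doubling time" criterion taken literally would invert the
interval (large T_d means slow growth).

The default grid is 17, 27, 37, 41, 43, 46, 49, 55 °C, but the grid is
entirely data-driven; any strictly increasing set of ≥ 2 temperatures works.

## Heat sensitivity and sporulation

Viability after incubation at increasing temperature is modelled as
exponential decline, N(T) = N₀·e^{k(T−T_ref)}, a straight line in a semilog
plot. The sensitivity constant k (ln-units per °C) is estimated either:

* `endpoint` (default): k = (ln N(T₂) − ln N(T₁)) / (T₂ − T₁) over the two
  extreme assay temperatures with surviving counts, using the per-
  temperature mean of ln CFU over replicates (the geometric mean of
  counts, appropriate for multiplicative plating noise). This matches a
  single straight line through the ends of the assay.
* `least_squares`: the regression slope of ln CFU on temperature over all
  replicate-level points with CFU > 0 — the maximum-likelihood slope under
  lognormal count noise, and the robust choice with more than two
  temperatures.

Zero-CFU temperatures (complete kill) are excluded with a flag: a count of
zero has no defined logarithm and any pseudo-count would dominate the
slope. A *literal difference* form ln(N₂ − N₁)/(T₂ − T₁) is available
behind an explicit flag for auditing legacy calculations only; it is
dimensionally inconsistent with a semilog survival line and undefined for
declining counts. K is the arithmetic group mean of strain-level k.

Sporulation fraction is spore CFU / total CFU capped at 1; spore counts may
exceed totals by up to 10% (plating noise) and are then flagged and capped,
while larger excesses are rejected as irreconcilable. A zero total leaves
the fraction undefined (flagged), not zero. Colony-diameter summaries are
mean/SD over up to three colonies, with an all-zero condition flagged
no-growth.

## Group comparisons

At each grid temperature, replicate-level µ values are pooled within groups
and compared by classic one-way ANOVA (Welch's variant selectable) or a
two-sided two-sample t-test, at α = 0.05. Replicates — not strain means —
are the unit of analysis: with three strains per group, strain-level means
would leave almost no within-group degrees of freedom. No multiple-testing
correction is applied across temperatures by default (each temperature is
reported at nominal α, as is conventional for per-condition screens); a
Holm adjustment is available. Temperatures with fewer than two populated
groups are omitted with a warning; a temperature where all pooled values
are identical is flagged degenerate with an undefined p. The environment
contrast restricts to the T and H groups by default so that a laboratory
strain does not form a spurious third group.

## The synthetic-data generator

The generator defines the study conditions the tests assume:

* **TPC archetypes.** `sharp_drop`: µ rises linearly from T_min to a single
  optimum and collapses linearly to zero within a few °C — the fast,
  thermally brittle archetype. `plateau`: a trapezoid holding µ_max over an
  interval with a gentler decline — the slower, broad-tolerance archetype.
  Piecewise-linear forms were chosen deliberately: their f-of-maximum
  crossings have closed forms, so niche oracles are exact.
* **Default panel.** 13 strains: three per lineage × environment plus one
  laboratory strain. Bc presets grow faster (µ_max ≈ 1.4 h⁻¹, doubling time
  ≈ 30 min, typical of fast *Bacillus* growth at optimum) and collapse
  within ~4 °C above the optimum with an upper limit near 41 °C (T) / 44 °C
  (H); Bs presets are slower (µ_max ≈ 0.9 h⁻¹) with an 8-°C plateau and
  upper limits near 48 °C (T) / 51 °C (H). Hot-spring presets sit 3 °C
  above their temperate counterparts in optimum and upper limit — the
  modest shift expected when heat tolerance evolves near a physiological
  ceiling. Within each trio, small fixed offsets (±0.4 °C, ±3% µ_max) keep
  strains distinct but deterministic.
* **OD curves.** Logistic trajectories x(t) with lag 1 h, inoculum OD
  0.005, carrying capacity OD 1.5, plus a medium blank of 0.04 recorded in
  the metadata, observed at 30-min intervals for 20 h under multiplicative
  lognormal noise (σ of log-OD = 0.02, typical plate-reader repeatability).
  Above T_max the biomass stays at the inoculum level: a flat noisy
  baseline.
* **Viability.** Totals decline as N₀·e^{k(T−37)} from a baseline of 10⁸
  CFU/ml with lognormal noise (σ = 0.15); an expected count below one cell
  is recorded as 0 (complete kill). Lineage decay presets (Bc ≈ −2.3,
  Bs ≈ −1.46 per °C, H strains slightly hardier than T) were set so the
  lineage-mean ln-survival drop across the 37–50 °C assay is ≈ −30 (Bc)
  and ≈ −19 (Bs). Spore counts are a binomial plating subsample (depth
  1000 colonies) at per-strain sporulation fractions of 0.10–0.35,
  reproducing the replicate-to-replicate variability of plate counts.
  With noise switched off the generator is exactly deterministic, enabling
  1e-9-level recovery checks.

**What the generator does not emulate:** real TPCs are smooth and
asymmetric rather than piecewise linear; lag and carrying capacity vary
with temperature; OD–biomass calibration is nonlinear at high density;
plate edge effects, condensation artefacts and autocorrelated reader drift
are absent; viability kinetics are reduced to a single per-°C slope with no
time-kill dimension; and sporulation is a fixed per-strain propensity, not
a regulated decision. Passing tests therefore demonstrate correctness of
the estimators under the stated statistical model, not robustness to every
artefact of real plate data.

## Numerical choices and degenerate inputs

* Window regressions use centered prefix-sum formulas in double precision;
  R² is clipped to [0, 1] and a window with zero OD variance gets R² = 0.
* Slope ties are resolved within 1e-12 relative tolerance (larger window,
  then earlier start).
* A best window with non-positive slope is reported as no-growth rather
  than a negative rate; µ is never negative.
* All-zero norms raise for niche computation but are carried through the
  table-level API as flagged rows, so one dead strain cannot abort a run.
* Temperatures are kept as given (float °C): no rounding or binning.
* CSV round-trips preserve full float precision (shortest-repr writing).

## Problem sizes

The bundled acceptance checks use 200 noisy-curve recovery replicates, 50
random TPCs for the niche oracle, 200 random norms for the invariance
properties, 1000 null replicates for ANOVA calibration, and the full
13-strain default experiment; together they complete in well under a minute
on a single core.
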