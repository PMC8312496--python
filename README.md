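# thermonorms

Reaction norms, thermal niches and heat-tolerance statistics for microbial
growth phenotyping.

`thermonorms` is a pipeline for quantifying thermal phenotypic plasticity in
bacteria from standard laboratory assays: plate-reader growth curves taken
across a temperature grid, CFU viability counts after incubation at elevated
temperatures, spore counts after a heat-selection treatment, and colony-size
measurements on solid medium. It was built for the common two-factor design
in microbial thermal ecology — strains of two related lineages (e.g. the
*Bacillus cereus* and *B. subtilis* groups, "Bc" / "Bs") isolated from
contrasting thermal environments (temperate "T" vs hot-spring "H") — but all
components work on any long-format strain × temperature dataset.

## What it computes

**Specific growth rate.** During exponential growth, blank-corrected optical
density follows OD(t) = OD₀·e^{µt}, so ln OD is linear in time with slope µ
(h⁻¹) and doubling time T_d = ln 2 / µ. µ is estimated per replicate curve by
a windowed log-linear regression: among all contiguous windows of ≥ 5 samples
whose fit reaches R² ≥ 0.98, the maximal slope wins. Curves that never rise
1.5-fold over baseline are scored no-growth (µ = 0).

**Reaction norms and the thermal niche.** Replicate means of µ over the
temperature grid form each strain's reaction norm. The optimum is the grid
temperature of maximal µ (near-ties within 5% are reported as co-optima —
plateau-shaped strains may genuinely have several). The thermal niche is the
interval [T_lo, T_hi] over which the piecewise-linear interpolant of the norm
stays at or above 0.75·µ_max; bounds clamped at the grid edge are flagged
censored. Niche breadth = T_hi − T_lo.

**Heat sensitivity and sporulation.** Viable counts after incubation at
increasing temperatures fall on a straight line in a semilog plot; the
heat-sensitivity constant is its slope k = d ln(CFU)/dT (per °C), estimated
from the extreme assay temperatures or by least squares, and averaged to a
group mean K. Spore fractions are spore CFU / total CFU, capped at 1.

**Group comparisons.** At each grid temperature, replicate-level µ values are
pooled by lineage or by environment and compared with a one-way ANOVA (or
two-sample t-test) at α = 0.05, yielding the count of temperatures at which
groups differ.

**Synthetic data.** A seeded generator produces plate, CFU and metadata
tables with known ground truth: piecewise-linear thermal performance curves
in two archetypes (sharp post-optimum collapse vs broad plateau), logistic OD
trajectories with lag and multiplicative noise, and exponential viability
decline — so every stage is testable without external data.

## Worked example

```python
import thermonorms as tn
from thermonorms.cli import run_analysis

cfg = tn.SimulationConfig(seed=1)          # 13 strains x 8 temperatures x 3 replicates
plate = tn.simulate_plate_experiment(cfg)
cfu = tn.simulate_viability_assay(cfg)
tables = run_analysis(plate, cfu=cfu)

cols = ["strain_id", "lineage", "environment", "mu_max", "optima", "t_lo", "t_hi", "breadth"]
print(tables["thermal_niches"][cols].round(3).head(7).to_string(index=False))
```

```
strain_id lineage environment  mu_max optima   t_lo   t_hi  breadth
  Bc-H-11      Bc           H   1.288     37 29.473 41.392   11.920
  Bc-H-28      Bc           H   1.232     37 29.296 41.125   11.829
  Bc-H-51      Bc           H   1.297  37;41 29.883 41.765   11.882
 Bc-T-102      Bc           T   1.369     37 29.236 38.000    8.764
Bc-T-111b      Bc           T   1.363     37 28.746 38.134    9.389
Bc-T-370a      Bc           T   1.209     37 26.481 38.000   11.519
   Bs-H-2      Bs           H   0.903  37;41 29.141 44.647   15.506
```

Each row is one strain's thermal niche: its maximal growth rate (h⁻¹), the
optimum temperature(s), and the 75%-of-maximum interval. Here the fast
Bc strains from the temperate environment lose growth just above 38 °C,
while their hot-spring counterparts extend roughly 3 °C higher; the slower
plateau-shaped Bs strain keeps ≥ 75% performance up to ~44.6 °C. Group heat
sensitivity from the same run:

```python
sens = tables["heat_sensitivity"]
print(sens[(sens.scope == "group") & (sens.grouping == "lineage")]
      [["id", "k", "sd_k", "n"]].round(3).to_string(index=False))
```

```
id      k  sd_k  n
Bc -2.313 0.130  6
Bs -1.455 0.085  7
```

K = −2.31 ln-units/°C for the Bc lineage vs −1.45 for Bs: across the
37→50 °C viability assay that is an ln-survival drop of about −30 vs −19,
i.e. the fast-growing lineage pays for its speed with markedly steeper
viability loss above its optimum.

The same pipeline runs from the shell:

```sh
thermonorms simulate --seed 1 --out-dir data/
thermonorms analyze --plate data/plate.csv --meta data/strain_metadata.csv \
                    --cfu data/cfu.csv --out-dir results/
thermonorms report --results-dir results/
```

`analyze` writes six result tables (growth fits, reaction norms, thermal
niches, heat sensitivity, sporulation, comparisons) plus a run-parameter
echo and manifest; `report` renders the norm/niche, comparison and semilog
viability figures as SVG.

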