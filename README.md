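# famlong — familial transmission of human longevity

`famlong` is a Python toolkit for the family-based analysis of human
longevity: given three-generation pedigree data (or its built-in simulator),
it asks **beyond which birth-cohort survival percentile do long-lived
relatives predict a survival advantage for their kin**, and whether that
advantage is additive in the number of long-lived relatives — the signature
of a transmitted quantitative genetic trait rather than shared environment.

It is aimed at epidemiologists and genetic demographers who work with
registry-style person tables (one row per individual with family links,
vital dates, and covariates) and cohort lifetables.

## The statistics at the core

**Survival percentiles.** From sex- and birth-year-specific cohort
lifetables with yearly hazards `h_x`, the package computes `H_{x+1} = H_x +
h_x`, `S_x = exp(-H_x)`, and assigns each person the percentile
`100 * S(age at death or last observation)` — smaller is longer-lived;
"top x%" means percentile ≤ x. HMD-dialect cohort lifetable files, a simple
hazard CSV, and a Gompertz–Makeham synthesizer
(`h(t) = λ + a·e^{bt}`) are supported.

**Exposures and weights.** For each index person (IP) the package counts
top-x parents (0/1/2) and siblings (0/1/2+), assigns mutually exclusive
groups g1..g6 by the most long-lived relative (boundaries 1, 5, 10, 15, 20),
and attaches analytical weights `w = k/S` (qualifying siblings over
classifiable sibship size) so large sibships cannot dominate extreme
categories. An IP with siblings at percentiles {1, 6, 8, 30} carries
w = 3/4 in a top-10% analysis, w = 1/4 at top-5%, and w = 1/4 in the
exclusive-group analysis (g1).

**Models.** Survival models follow the Model/Results convention:

```python
fit = CoxModel(rows, exposures=["parent_1", "parent_2"],
               covariates=[...], weights_col="weight").fit()
fit.summary()          # coef, se, HR, 95% CI, p per term
```

`CoxModel` is a weighted Cox proportional-hazards model with delayed entry
(IPs and spouses enter the risk set at the later of marriage and first-child
age), Efron ties, and sandwich SEs for weighted fits.
`SharedFrailtyCoxModel` adds a log-normal shared frailty
`λ(t) = u_i λ0(t) exp(β'Z)`, `log u_i ~ N(0, θ)`, per family — fitted by
penalized partial likelihood with a Laplace profile over θ. Kaplan–Meier /
Nelson–Aalen baselines, scaled-Schoenfeld PH checks, and Bonferroni-corrected
pairwise group contrasts round out the model layer.

**The five analyses** (`famlong.analyses`): (1) a cumulative top-x sweep
over x = 1..60; (2) mutually exclusive percentile groups with automatic
longevity-threshold detection; (3) a top-10% integrated parent+sibling
design with a no-longevous-parent stratum; (4) verification in the children
generation with the shared-frailty model; (5) a spouse analysis separating
genetic transmission from shared-environment/assortative patterns.

**The simulator** (`famlong.simulate`) generates three-generation families
(founders, sibships averaging 6.3, one IP with spouse and children) whose
mortality is Gompertz–Makeham modulated by an additive genetic log-frailty
(mid-parent transmission plus segregation noise), with administrative
censoring, covariates, assortative-mating and lineage knobs. Every
downstream stage is therefore testable without restricted registry data.

## Worked example

```python
import numpy as np
from famlong import (GompertzMakehamParams, SimConfig, simulate_study,
                     synthesize_collection)
from famlong.analyses import run_exclusive_groups, run_top10_integrated

tables = synthesize_collection(GompertzMakehamParams())   # synthetic cohort lifetables
table = simulate_study(SimConfig(n_families=3000, sigma_g2=0.6,
                                 sigma_e2=0.2, seed=42))  # strong transmission

res = run_top10_integrated(table, tables)
print(res["joint"].summary().loc[["parent_1", "parent_2", "sib_1", "sib_2plus"],
                                 ["hr", "ci_low", "ci_high", "p"]])

fit, threshold = run_exclusive_groups(table, tables, kind="siblings")
print("sibling longevity threshold:", threshold.threshold_percentile)
```

Output (printed by the code above):

```
                 hr    ci_low   ci_high             p
covariate
parent_1   0.803610  0.734599  0.879104  1.818661e-06
parent_2   0.714865  0.593707  0.860747  3.962168e-04
sib_1      0.777826  0.701681  0.862235  1.753888e-06
sib_2plus  0.685210  0.611898  0.767304  5.844367e-11
sibling longevity threshold: 15.0
```

Read: IPs with one top-10% parent have a 20% lower hazard of dying than IPs
with none (HR 0.80), two top-10% parents 29% lower, and the sibling
dose–response is ordered the same way (HR 0.78 → 0.69) — the additive
pattern expected under transmission as a quantitative trait. The detected
sibling threshold is the upper bound of the last percentile group still
showing a significant advantage; under this continuous-frailty simulation
the advantage genuinely extends a little past the 10th percentile, so the
rule reports 15%. When the generative advantage is confined to families
with a sub-10th-percentile sibling (see `simulate_threshold_scenario`), the
detected threshold localises at 10%.

A console CLI wraps the same pipeline for shell use:

```bash
famlong simulate --seed 7 --n-families 2000 --out table.csv
famlong validate table.csv
famlong run-all table.csv --seed 7 --out results/
```

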