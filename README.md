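# firbiomass

Individual-tree and stand biomass modelling for Chinese Fir
(*Cunninghamia lanceolata*) plantations — and, more generally, a toolkit for
selecting, refining and validating allometric total-biomass equations and
upscaling them to the stand level.

## The problem

Estimating the dry biomass of a tree (and of a whole stand) from routine
forest measurements is the basis of carbon accounting and plantation
management. Hundreds of allometric equations have been published that
predict whole-tree biomass `B` (kg) from the diameter at breast height `D`
(cm), total height `H` (m), wood density `WD` (kg·m⁻³), basal area `G`
(m²), or stem volume `V` (m³) — but their accuracy varies strongly across
species and sites, and few of them scale cleanly from the tree to the
stand.

This package implements that whole workflow:

1. **Model catalogue** — 74 published total-biomass model forms (log-linear,
   power-law, polynomial, ratio forms), each encoded with its response scale,
   required predictors and the reference parameter values and fit statistics
   published for a 35-tree Chinese Fir sample (with a machine-readable errata
   column for every repaired transcription).
2. **Tree metrics** — stem volume by numerically integrating a Chinese Fir
   taper equation,

   `V = (π/40000) ∫₀ᴴ D² ((H−h)/(H−1.3))^(3.482321 − 2.153699·h^0.007) dh`,

   and the conversion factors `BEF = aboveground/trunk mass`,
   `WD = trunk mass / V`, `BCEF = BEF·WD = aboveground mass / V`.
3. **Fit engine** — multi-start nonlinear least squares (Latin-hypercube
   starts, seeded) for any catalogued form, with the standard criteria
   MAB, RMSE, ARE, R², AIC, BIC; log-response forms are fitted on the log
   scale and always evaluated in kg.
4. **Refinement** — the two-step refined tree model
   `ln(TB) = a + b·ln(TV) + c·ln(WD)` and then
   `ln(TB) = a + b·ln(TV) + c·ln(WD) + d·ln(BCEF)` (the headline model),
   solved exactly by least squares with collinearity diagnostics.
5. **Jackknife validation** — leave-one-out refitting with held-out error
   criteria and per-fold coefficient summaries.
6. **Stand upscaling** — the stand biomass coefficient
   `bi = exp(a + b·ln(TV) + c·ln(WD) + d·ln(BCEF))` (kg) applied as
   `SB = bi · SV/TV`, with a sensitivity report over the reference-tree
   choice.
7. **Synthetic data** — a seeded generator reproducing the calibration
   moments of the published 35-tree sample (D 5.1–38.4 cm, WD 117–427 kg·m⁻³,
   BCEF 236–614 kg·m⁻³, …) with the refined biomass law as its mean
   structure, so every stage is testable without the original field data.

## Worked example

```python
from firbiomass import (generate_trees, fit_tv_wd_bcef_model, taper_volume,
                        biomass_coefficient, stand_biomass)
from firbiomass.validation import jackknife_loglinear

trees, truth = generate_trees(n_trees=35, seed=7)     # synthetic field sample
print(taper_volume(17.0, 15.8))                       # 0.1746 m^3

fit = fit_tv_wd_bcef_model(trees)                     # headline tree model
# coefficients: intercept -0.5054, ln(TV) 0.9753, ln(WD) 0.2830, ln(BCEF) 0.8392
# MAB = 1.929 kg, RMSE = 2.945 kg, R2 = 0.9978

jk = jackknife_loglinear(trees)                       # leave-one-out check
# held-out MAB = 2.199 kg, R2 = 0.9970

bi = biomass_coefficient(0.2655, 304.2, 391.8)        # 124.51 kg
rec = stand_biomass(100.0, {"V": 0.2655, "WD": 304.2, "BCEF": 391.8})
print(rec.SB)                                         # 46896 kg for 100 m^3
```

Read the output as follows: the taper integral turns the mean tree
(D = 17 cm, H = 15.8 m) into 0.1746 m³ of stem; the refined model explains
99.8 % of the biomass variance on this sample with a 1.9 kg mean absolute
bias; the jackknife confirms that accuracy holds out of sample; and a stand
carrying 100 m³ of such trees holds about 47 t of dry biomass.

The same operations are available from the shell:

```bash
firbiomass simulate --n 35 --seed 7 --out trees.csv
firbiomass fit-all --input trees.csv --rank-by mab --seed 42 --out table.csv
firbiomass refine --input trees.csv --out refinement.json
firbiomass jackknife --input trees.csv --out jk.json
firbiomass stand --sv 100 --tree-tv 0.2655 --tree-wd 304.2 --tree-bcef 391.8
```

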