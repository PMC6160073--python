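# gudscale

Size scaling of patch-departure behaviour in foraging experiments:
allometric cohort design, ³²P radiotracer accounting, giving-up
descriptors, energy-equivalence modelling and scaling inference — with an
individual-based synthetic mesocosm generator so the whole pipeline is
testable end to end.

## The scientific problem

Optimal-foraging theory predicts that a forager abandons a resource patch
when its intake rate drops below what its energy budget demands. Because
metabolic rate scales allometrically with body size, `I = aM^b` with
`b < 1`, larger foragers should *give up sooner* (shorter giving-up time,
GUT) and *at higher residual resource density* (higher giving-up density,
GUD) than smaller ones — even when whole cohorts are matched for total
energy demand.

`gudscale` implements the analysis for a mesocosm design that tests this
with three freshwater gastropods spanning a ~35-fold size range
(*Galba truncatula*, 12.88 mg AFDW; *Bithynia tentaculata*, 7.77;
*Ecrobia ventrosa*, 0.37). Cohorts graze 16 ³²P-labelled leaf disks in a
two-patch maze for 96 h; departures are logged on a 30-min day / overnight
observation grid, and resource transfer is read off the radioactive charge
of disks and forager tissue.

Core quantities:

* **Allometry & design** — `I = 0.69·M^0.79` mJ day⁻¹ (mg AFDW), cohort
  totals by summation, per-biomass demand `∝ M^(b−1) = M^−0.21`, and
  numeric- / biomass- / energy-equivalent cohort sizes with delta-method CI
  propagation from the size CIs.
* **Tracer accounting** — blank/efficiency correction, ³²P decay
  back-correction (half-life 14.268 d), 1 DPM = 4.556×10⁻¹³ Ci.
* **Four descriptors** per treatment × series — GUT (censored foragers
  excluded), net accumulation rate (nCi h⁻¹), GUD (nCi disk⁻¹), exploited
  fraction `1 − grazed/control`.
* **Energy equivalence** — per-series piecewise-linear interpolation of
  each descriptor to the cohort size whose summed metabolic rate matches
  four *G. truncatula* (6 *B. tentaculata*, 66 *E. ventrosa*).
* **Scaling fits** — log-log OLS power laws `Y = aX^b` with t-based CIs,
  logit-link binomial fits with McFadden pseudo-R² for fractions, Pearson
  r with Fisher-z CI, and the one-way residual-charge ANOVA.

## Worked example

```python
from gudscale import PipelineConfig
from gudscale.pipeline import accumulation_scaling_fit, run_pipeline

res = run_pipeline(PipelineConfig(seed=1))     # full synthetic study, 4 series
fit = accumulation_scaling_fit(res.descriptors_series)
print(f"slope = {fit.slope:.3f} +- {fit.slope_ci95:.3f}, R2 = {fit.r_squared:.3f}")
```

prints

```
slope = 0.759 +- 0.047, R2 = 0.992
```

— the cross-species scaling exponent of the net tracer accumulation rate
at energy equivalence. The study was generated with ingestion exponent
0.75, and the fit recovers it within the 95% CI: at matched overall demand
the patch is depleted equally fast for every species, so realised intake
stays proportional to `M^γ`.

The design engine alone reproduces the treatment table arithmetic:

```python
from gudscale import design_table
print(design_table().round(2))
```

giving, e.g., individual rates 5.20 / 3.49 / 0.31 mJ day⁻¹, the biomass
cells 51.52, 54.39 and 53.65 mg AFDW, and the modelled energy-equivalent
counts 6 and 66. `examples/` contains one short script per capability
(design, tracer correction, descriptors, equivalence, fits); each prints
the numbers it computes and what they mean.

A thin CLI wraps the same functions:

```bash
gudscale design
gudscale simulate --seed 1 --out study/
gudscale descriptors --foragers study/foragers.csv --disks study/disks.csv --out desc.csv
gudscale report --seed 1 --out report/
```

All artifacts are plain CSVs with `#` provenance headers (seed, config
hash). Forager tables carry `treatment_id, series_id, species,
size_mg_afdw, entry_time_h, departure_time_h` (empty = censored),
`body_charge_nci` and optional raw-count columns; disk tables carry
`series_id, treatment_id, role` (grazed / start_control / final_control)
and `charge_nci`.

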