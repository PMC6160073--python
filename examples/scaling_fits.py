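"""Scaling inference on a full synthetic study.

Runs the complete pipeline (4 series, 7 observed + 2 modelled treatments),
prints the cross-species scaling fits per equivalence class, the
residual-charge ANOVA, and the recovery of the generating ingestion
exponent (0.75) from the accumulation-rate-vs-size fit.
"""

from gudscale import PipelineConfig
from gudscale.pipeline import accumulation_scaling_fit, run_pipeline

res = run_pipeline(PipelineConfig(seed=1))

cross = res.fits[res.fits.scope == "cross_species"]
cols = ["group", "descriptor", "intercept", "slope", "slope_ci95",
        "r_squared", "r_pearson", "p_value"]
print(cross[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))

a = res.anova
print(f"\nresidual-charge ANOVA: F[{a.df_between}, {a.df_within}] = "
      f"{a.f_statistic:.2f}, p = {a.p_value:.2g}")

fit = accumulation_scaling_fit(res.descriptors_series)
print(f"\naccumulation-rate scaling at energy equivalence: "
      f"slope = {fit.slope:.3f} +- {fit.slope_ci95:.3f} (95% CI), "
      f"R2 = {fit.r_squared:.3f}")
print(
    "\nThe slope estimates the ingestion exponent the study was generated with"
    "\n(0.75): matched overall cohort demand equalises patch depletion across"
    "\nspecies, so realised intake stays proportional to M**gamma.  Power-law"
    "\nfits report the back-transformed intercept a and exponent b of Y = aX^b;"
    "\nexploitation rows are logit-link fits with McFadden pseudo-R2."
)
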