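"""Simulate a small synthetic study and compute the four patch descriptors.

Generates two replicate series of the full treatment design (7 cohorts of
three gastropod species grazing 16 labelled leaf disks for 96 h), then
summarises giving-up time (GUT), net tracer accumulation rate, giving-up
density (GUD) and the exploited resource fraction per treatment.
"""

from gudscale import (
    SimulationConfig,
    compute_descriptors,
    generate_study,
    summarise_descriptors,
)

cfg = SimulationConfig(n_series=2)
study = generate_study(cfg, seed=7)
per_series = compute_descriptors(study.foragers, study.disks, horizon=cfg.horizon_h)
summary = summarise_descriptors(per_series)

cols = [
    "treatment_id", "n_individuals", "gut_mean_h", "accumulation_rate_nci_h",
    "gud_nci_disk", "exploitation_frac",
]
print(summary[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\nGUT is the mean hours leavers stayed (censored foragers excluded); the"
    "\naccumulation rate is body charge per hour on the patch; GUD the residual"
    "\ndisk charge; exploitation the fraction of the final-control charge removed."
    "\nNote GUD falling and exploitation rising across the E. ventrosa (EV)"
    "\nabundance gradient - more grazers strip the patch further before leaving."
)
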