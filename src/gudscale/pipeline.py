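"""End-to-end analysis pipeline.

Ties the stages together: synthetic study (or externally supplied record
tables) -> tracer correction -> patch-departure descriptors -> modelled
energy-equivalence rows -> scaling fits and the residual-charge ANOVA.
Intermediate artifacts are plain CSVs with provenance headers so each stage
is independently inspectable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, descriptors, equivalence, scaling, synth, tracer
from .allometry import MetabolicModel, TreatmentDesign
from .io import config_hash, write_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report",
           "accumulation_scaling_fit", "cross_species_fits", "abundance_fits"]

log = logging.getLogger("gudscale")

#: cross-species equivalence-class membership (treatment ids of the default design)
CLASS_MEMBERS = {
    "numeric": ("GT_n4", "BT_n4", "EV_n4"),
    "biomass": ("GT_n4", "BT_n7", "EV_n145"),
    "energy": ("GT_n4", "BT_n6", "EV_n66"),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Switches and parameters for one reproducible pipeline run."""

    seed: int = 0
    simulation: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    calibration: tracer.TracerCalibration | None = None
    use_raw_dpm: bool = True  # exercise the tracer stage on synthetic raw counts
    interpolation_mode: str = "piecewise"
    logit_eps: float = 1e-6


@dataclass(frozen=True)
class PipelineResult:
    design_table: pd.DataFrame
    descriptors_series: pd.DataFrame  # incl. modelled energy-equivalence rows
    descriptors_summary: pd.DataFrame
    fits: pd.DataFrame
    anova: scaling.AnovaResult
    foragers: pd.DataFrame
    disks: pd.DataFrame
    ground_truth: dict


def _stage(name: str):
    log.info("stage: %s", name)


def _recover_charges(study: synth.StudyData, cfg: PipelineConfig) -> synth.StudyData:
    """Re-derive nCi charges from the synthetic raw DPM via the tracer stage."""
    cal = study.calibration
    foragers = tracer.process_measurements(study.foragers, cal)
    disks = tracer.process_measurements(study.disks, cal)
    foragers["body_charge_nci"] = foragers.pop("charge_nci")
    return synth.StudyData(foragers, disks, study.ground_truth, cal)


def abundance_fits(per_series: pd.DataFrame, logit_eps: float = 1e-6) -> pd.DataFrame:
    """Within-species descriptor-vs-abundance fits on series-level values.

    For every species observed at >= 2 abundances, each descriptor is
    fitted against abundance: power law for GUT, accumulation rate and GUD,
    logit link for the exploitation fraction.  Modelled rows are excluded.
    Series values that are undefined (no leavers) or non-positive on the
    log scale are dropped with a row-count note.
    """
    obs = per_series[~per_series["modelled"]]
    rows = []
    for species, sp in obs.groupby("species", sort=True):
        if sp["n_individuals"].nunique() < 2:
            continue
        for col in descriptors.DESCRIPTOR_COLUMNS:
            x = sp["n_individuals"].to_numpy(dtype=float)
            y = sp[col].to_numpy(dtype=float)
            keep = np.isfinite(y)
            if col != "exploitation_frac":
                keep &= y > 0  # negatives handled by clipping for the logit fit
            dropped = int((~keep).sum())
            if keep.sum() < 3:
                log.warning("%s %s: only %d usable points, fit skipped",
                            species, col, int(keep.sum()))
                continue
            try:
                if col == "exploitation_frac":
                    fit = scaling.fit_logit_fraction(
                        x[keep], np.clip(y[keep], 0.0, 1.0), eps=logit_eps
                    )
                else:
                    fit = scaling.fit_power_law(x[keep], y[keep])
            except ValueError as exc:
                log.warning("%s %s: fit failed (%s)", species, col, exc)
                continue
            rows.append(
                {"scope": "abundance", "group": species, "descriptor": col,
                 "predictor": "n_individuals", "n_dropped": dropped,
                 **fit.__dict__}
            )
    return pd.DataFrame(rows)


def cross_species_fits(
    per_series: pd.DataFrame,
    class_members: dict[str, tuple[str, ...]] | None = None,
    logit_eps: float = 1e-6,
) -> pd.DataFrame:
    """Descriptor-vs-size fits per equivalence class on series-level values.

    The energy class uses the modelled (interpolated) rows for the smaller
    species — that is its purpose; numeric and biomass classes use observed
    treatments only.
    """
    members = class_members or CLASS_MEMBERS
    rows = []
    for eq_class, tids in members.items():
        sel = per_series[per_series["treatment_id"].isin(tids)]
        if sel.empty:
            log.warning("equivalence class %s: no rows", eq_class)
            continue
        for col in descriptors.DESCRIPTOR_COLUMNS:
            x = sel["size_mg_afdw"].to_numpy(dtype=float)
            y = sel[col].to_numpy(dtype=float)
            keep = np.isfinite(y)
            if col != "exploitation_frac":
                keep &= y > 0
            dropped = int((~keep).sum())
            if keep.sum() < 3:
                log.warning("%s %s: only %d usable points, fit skipped",
                            eq_class, col, int(keep.sum()))
                continue
            try:
                if col == "exploitation_frac":
                    fit = scaling.fit_logit_fraction(
                        x[keep], np.clip(y[keep], 0.0, 1.0), eps=logit_eps
                    )
                else:
                    fit = scaling.fit_power_law(x[keep], y[keep])
            except ValueError as exc:
                log.warning("%s %s: fit failed (%s)", eq_class, col, exc)
                continue
            rows.append(
                {"scope": "cross_species", "group": eq_class, "descriptor": col,
                 "predictor": "size_mg_afdw", "n_dropped": dropped,
                 **fit.__dict__}
            )
    return pd.DataFrame(rows)


def accumulation_scaling_fit(
    per_series: pd.DataFrame, treatment_ids=CLASS_MEMBERS["energy"]
) -> scaling.ScalingFit:
    """Cross-species power-law fit of net accumulation rate vs body size.

    Observations are series-level mean rates, by default at energy
    equivalence (3 species x n_series points).  Matched overall cohort
    demand equalises patch depletion across species, so the realised mean
    intake stays proportional to ``c * M**gamma`` and the fitted exponent
    estimates the generating ingestion exponent with minimal
    depletion-induced bias.
    """
    sel = per_series[per_series["treatment_id"].isin(treatment_ids)]
    return scaling.fit_power_law(
        sel["size_mg_afdw"].to_numpy(dtype=float),
        sel["accumulation_rate_nci_h"].to_numpy(dtype=float),
    )


def residual_charge_groups(disks: pd.DataFrame) -> list[np.ndarray]:
    """Disk-charge groups for the treatment ANOVA: each treatment + final controls."""
    grazed = disks[disks["role"] == "grazed"]
    groups = [g["charge_nci"].to_numpy() for _, g in grazed.groupby("treatment_id")]
    ctrl = disks[disks["role"] == "final_control"]["charge_nci"].to_numpy()
    if ctrl.size:
        groups.append(ctrl)
    return groups


def run_pipeline(config: PipelineConfig, study: synth.StudyData | None = None) -> PipelineResult:
    """Execute the full analysis on a (generated or supplied) study."""
    cfg = config
    sim = cfg.simulation
    _stage("design")
    design = allometry.design_table(model=sim.model)

    if study is None:
        _stage("simulate")
        study = synth.generate_study(sim, cfg.seed, calibration=cfg.calibration)
    if cfg.use_raw_dpm and "raw_dpm" in study.foragers.columns:
        _stage("tracer")
        study = _recover_charges(study, cfg)

    _stage("descriptors")
    try:
        per_series = descriptors.compute_descriptors(
            study.foragers, study.disks, horizon=sim.horizon_h
        )
    except ValueError as exc:
        raise RuntimeError(f"descriptors stage failed: {exc}") from exc
    sizes = {name: sp.mean_size for name, sp in sim.species.items()}
    per_series["size_mg_afdw"] = per_series["species"].map(sizes)
    log.info("descriptors: %d treatment x series rows, %d foragers in, %d censored",
             len(per_series), len(study.foragers), int(per_series["n_censored"].sum()))

    _stage("equivalence")
    reference = TreatmentDesign(
        allometry.GALBA_TRUNCATULA, 4, "numeric", treatment_id="GT_n4"
    )
    try:
        modelled = equivalence.energy_equivalence_table(
            per_series, reference, sim.model, mode=cfg.interpolation_mode
        )
    except ValueError as exc:
        raise RuntimeError(f"equivalence stage failed: {exc}") from exc
    all_series = pd.concat([per_series, modelled], ignore_index=True)

    _stage("scaling")
    try:
        fits = pd.concat(
            [
                abundance_fits(all_series, cfg.logit_eps),
                cross_species_fits(all_series, logit_eps=cfg.logit_eps),
            ],
            ignore_index=True,
        )
        anova = scaling.residual_charge_anova(residual_charge_groups(study.disks))
    except ValueError as exc:
        raise RuntimeError(f"scaling stage failed: {exc}") from exc

    summary = descriptors.summarise_descriptors(all_series)
    return PipelineResult(
        design_table=design,
        descriptors_series=all_series,
        descriptors_summary=summary,
        fits=fits,
        anova=anova,
        foragers=study.foragers,
        disks=study.disks,
        ground_truth=study.ground_truth,
    )


def write_report(result: PipelineResult, outdir, config: PipelineConfig) -> dict[str, Path]:
    """Write the report bundle (design, descriptor, fit tables + run log)."""
    outdir = Path(outdir)
    meta = {"seed": config.seed, "config_hash": config_hash(config)}
    paths = {
        "design": write_table(result.design_table, outdir / "design_table.csv", meta),
        "descriptors_series": write_table(
            result.descriptors_series, outdir / "descriptors_series.csv", meta
        ),
        "descriptors_summary": write_table(
            result.descriptors_summary, outdir / "descriptors_summary.csv", meta
        ),
        "fits": write_table(result.fits, outdir / "scaling_fits.csv", meta),
        "foragers": write_table(result.foragers, outdir / "foragers.csv", meta),
        "disks": write_table(result.disks, outdir / "disks.csv", meta),
    }
    anova_df = pd.DataFrame([result.anova.__dict__])
    paths["anova"] = write_table(anova_df, outdir / "residual_charge_anova.csv", meta)
    return paths
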