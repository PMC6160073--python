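"""Radioisotope (32P) charge accounting.

Raw liquid-scintillation counts (DPM, disintegrations per minute) are
turned into comparable charges by three steps: blank subtraction and
counting-efficiency correction, decay correction back to a common reference
instant, and conversion to curie-scale units (1 DPM = 4.556e-13 Ci; charges
are reported in nCi).  32P decays with a half-life of 14.268 days, so
measurements taken days after a trial systematically undercount unless
back-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TracerCalibration",
    "correct_dpm",
    "decay_correct",
    "dpm_to_curie",
    "dpm_to_nanocurie",
    "curie_to_dpm",
    "nanocurie_to_dpm",
    "process_measurements",
    "P32_HALF_LIFE_DAYS",
    "DPM_TO_CI",
]

P32_HALF_LIFE_DAYS = 14.268
DPM_TO_CI = 4.556e-13


@dataclass(frozen=True)
class TracerCalibration:
    """Counter calibration and decay bookkeeping.

    counting_efficiency
        fraction of true disintegrations registered, in (0, 1].
    blank_dpm
        background count rate subtracted from every sample.
    half_life_days
        of the tracer isotope (default 32P).
    reference_time
        instant to which all charges are decay-corrected; by convention the
        trial start.  May be a timestamp (ISO-8601 string / datetime) or a
        float in days on the same axis as measurement times.
    dpm_to_ci
        curies per DPM.
    """

    counting_efficiency: float = 1.0
    blank_dpm: float = 0.0
    half_life_days: float = P32_HALF_LIFE_DAYS
    reference_time: object = 0.0
    dpm_to_ci: float = DPM_TO_CI

    def __post_init__(self) -> None:
        if not 0 < self.counting_efficiency <= 1:
            raise ValueError(
                f"counting_efficiency must be in (0, 1], got {self.counting_efficiency}"
            )
        if self.blank_dpm < 0:
            raise ValueError("blank_dpm must be >= 0")
        if not self.half_life_days > 0:
            raise ValueError("half_life_days must be > 0")
        if not self.dpm_to_ci > 0:
            raise ValueError("dpm_to_ci must be > 0")


def correct_dpm(raw, cal: TracerCalibration):
    """Blank-subtract and efficiency-correct a raw count: ``(raw - blank) / eff``.

    Negative corrected values are clamped to zero with a warning — blanks
    legitimately exceed near-background samples.
    """
    r = np.asarray(raw, dtype=float)
    if np.any(r < 0):
        raise ValueError("raw DPM must be >= 0")
    out = (r - cal.blank_dpm) / cal.counting_efficiency
    if np.any(out < 0):
        warnings.warn(
            "raw DPM below blank: corrected count clamped to zero", stacklevel=2
        )
        out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(raw) else out


def decay_correct(dpm, elapsed_days, cal: TracerCalibration):
    """Back-correct a count to the reference instant: ``dpm * 2**(elapsed/half_life)``.

    ``elapsed_days`` is measurement time minus reference time; negative
    values forward-correct (divide) symmetrically.
    """
    d = np.asarray(dpm, dtype=float)
    t = np.asarray(elapsed_days, dtype=float)
    out = d * 2.0 ** (t / cal.half_life_days)
    if np.isscalar(dpm) and np.isscalar(elapsed_days):
        return float(out)
    return out


def dpm_to_curie(dpm, cal: TracerCalibration | None = None):
    factor = DPM_TO_CI if cal is None else cal.dpm_to_ci
    out = np.asarray(dpm, dtype=float) * factor
    return float(out) if np.isscalar(dpm) else out


def dpm_to_nanocurie(dpm, cal: TracerCalibration | None = None):
    out = np.asarray(dpm_to_curie(dpm, cal)) * 1e9
    return float(out) if np.isscalar(dpm) else out


def curie_to_dpm(ci, cal: TracerCalibration | None = None):
    factor = DPM_TO_CI if cal is None else cal.dpm_to_ci
    out = np.asarray(ci, dtype=float) / factor
    return float(out) if np.isscalar(ci) else out


def nanocurie_to_dpm(nci, cal: TracerCalibration | None = None):
    out = np.asarray(curie_to_dpm(np.asarray(nci, dtype=float) * 1e-9, cal))
    return float(out) if np.isscalar(nci) else out


def _elapsed_days(measurement_time, reference_time) -> np.ndarray:
    """Elapsed days between measurement and reference, from floats or timestamps."""
    mt = pd.Series(measurement_time)
    if pd.api.types.is_numeric_dtype(mt):
        return mt.to_numpy(dtype=float) - float(reference_time)
    mt = pd.to_datetime(mt)
    ref = pd.to_datetime(reference_time)
    return ((mt - ref) / pd.Timedelta(days=1)).to_numpy(dtype=float)


def process_measurements(
    measurements: pd.DataFrame, cal: TracerCalibration
) -> pd.DataFrame:
    """Full correction pipeline for a measurement table.

    Expects columns ``raw_dpm`` and ``measurement_time`` (plus any subject
    identifiers, which pass through).  Adds ``corrected_dpm`` (blank and
    efficiency corrected, at measurement time), ``reference_dpm``
    (decay-corrected to the calibration reference) and ``charge_nci``.
    """
    for col in ("raw_dpm", "measurement_time"):
        if col not in measurements.columns:
            raise ValueError(f"measurement table lacks required column {col!r}")
    out = measurements.copy()
    corrected = correct_dpm(out["raw_dpm"].to_numpy(dtype=float), cal)
    elapsed = _elapsed_days(out["measurement_time"], cal.reference_time)
    at_ref = decay_correct(corrected, elapsed, cal)
    out["corrected_dpm"] = corrected
    out["reference_dpm"] = at_ref
    out["charge_nci"] = dpm_to_nanocurie(at_ref, cal)
    return out
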