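"""Energy-equivalence treatment by per-series interpolation.

Energy-equivalent cohorts of the smaller species (the number of individuals
whose summed metabolic rate matches the reference cohort, by default four
G. truncatula) were never run as trials.  Their descriptors are modelled:
within each independent series, every descriptor is linearly interpolated
across the abundances that *were* observed for that species, at the
energy-equivalent count.  Interpolation is piecewise-linear between the two
bracketing abundances, so observed abundances pass through exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import (
    DEFAULT_MODEL,
    MetabolicModel,
    TreatmentDesign,
    equivalent_count,
    individual_metabolic_rate,
    population_energetics,
)
from .descriptors import DESCRIPTOR_COLUMNS

__all__ = [
    "SeriesDescriptorCurve",
    "interpolate_descriptor",
    "energy_equivalence_table",
]


@dataclass(frozen=True)
class SeriesDescriptorCurve:
    """Descriptor values of one species in one series across abundances."""

    species: str
    series_id: str
    points: tuple[tuple[float, float], ...]  # (abundance, descriptor value)

    def __post_init__(self) -> None:
        if len({n for n, _ in self.points}) < 2:
            raise ValueError(
                "at least two distinct abundances are required for interpolation"
            )


def interpolate_descriptor(
    points, target_n: float, mode: str = "piecewise"
) -> float:
    """Descriptor value at abundance ``target_n`` from observed (n, value) points.

    'piecewise' (default) interpolates linearly between the two abundances
    bracketing the target and passes through observed points exactly;
    outside the observed range it extrapolates from the nearest segment
    with a warning.  'global_linear' instead evaluates the least-squares
    line through all points.  Points with undefined (nan) values are
    dropped with a warning; fewer than two usable distinct abundances is an
    error.
    """
    if isinstance(points, SeriesDescriptorCurve):
        points = points.points
    if target_n <= 0:
        raise ValueError("target_n must be > 0")
    pts = np.asarray(sorted(points), dtype=float)
    keep = ~np.isnan(pts[:, 1])
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} point(s) with undefined descriptor value",
            stacklevel=2,
        )
        pts = pts[keep]
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct abundances to interpolate")
    if mode == "global_linear":
        slope, intercept = np.polyfit(x, y, 1)
        return float(slope * target_n + intercept)
    if mode != "piecewise":
        raise ValueError(f"unknown interpolation mode {mode!r}")
    if target_n < x[0] or target_n > x[-1]:
        warnings.warn(
            f"target abundance {target_n} outside observed range "
            f"[{x[0]:g}, {x[-1]:g}]: extrapolating from the nearest segment",
            stacklevel=2,
        )
        i = 0 if target_n < x[0] else len(x) - 2
        slope = (y[i + 1] - y[i]) / (x[i + 1] - x[i])
        return float(y[i] + slope * (target_n - x[i]))
    return float(np.interp(target_n, x, y))


def energy_equivalence_table(
    per_series: pd.DataFrame,
    reference: TreatmentDesign,
    model: MetabolicModel = DEFAULT_MODEL,
    mode: str = "piecewise",
) -> pd.DataFrame:
    """Modelled per-series descriptor rows at energy equivalence.

    For every species in ``per_series`` other than the reference species,
    the energy-equivalent count ``round(reference overall rate / species
    individual rate)`` is computed from the metabolic model, and each
    descriptor is interpolated at that count within each series.  Rows
    carry ``modelled=True`` and the same schema as ``per_series`` so they
    can be concatenated; series with fewer than two observed abundances are
    skipped with a warning.

    Requires a ``size_mg_afdw`` column (species mean size) in
    ``per_series`` to evaluate individual rates.
    """
    ref_rate = population_energetics(reference, model).overall_rate
    rows = []
    for species, sp_df in per_series.groupby("species", sort=True):
        if species == reference.species.name:
            continue
        size = float(sp_df["size_mg_afdw"].iloc[0])
        ind_rate = individual_metabolic_rate(size, model)
        target = equivalent_count(ref_rate, ind_rate, mode="energy")
        for sid, ser_df in sp_df.groupby("series_id", sort=True):
            if ser_df["n_individuals"].nunique() < 2:
                warnings.warn(
                    f"series {sid!r} of {species} has <2 abundances: skipped",
                    stacklevel=2,
                )
                continue
            row = {
                "treatment_id": f"{''.join(w[0] for w in species.split()).upper()}_n{target.count}",
                "series_id": sid,
                "species": species,
                "size_mg_afdw": size,
                "n_individuals": target.count,
                "equivalence_ratio": target.ratio,
                "modelled": True,
            }
            for col in DESCRIPTOR_COLUMNS:
                pts = list(zip(ser_df["n_individuals"], ser_df[col]))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row[col] = interpolate_descriptor(pts, target.count, mode=mode)
            rows.append(row)
    return pd.DataFrame(rows)
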