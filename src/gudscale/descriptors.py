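"""Patch-departure descriptors.

Four quantities summarise how a cohort used a labelled resource patch over
a trial:

* giving-up time (GUT): mean hours leavers spent on the patch before
  departing; foragers still present at the horizon are censored and
  excluded from this mean.
* net accumulation rate: final body charge divided by time on patch
  (nCi h^-1); censored foragers use the full horizon as denominator since
  they kept feeding throughout.
* giving-up density (GUD): mean residual charge of the grazed disks at the
  end of the trial (nCi per disk).
* resource exploitation: the complement 1 - grazed/control of the grazed
  disks' mean charge relative to the ungrazed final-control disks' mean —
  i.e. the exploited fraction of the resource.

Departure times are recorded on the observation grid (checks every 30 min
during daytime, one check covering the night), so the module also provides
the discretisation that maps a true departure instant to the time it would
first be noticed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ObservationSchedule",
    "GutResult",
    "GudResult",
    "ExploitationResult",
    "giving_up_time",
    "net_accumulation_rate",
    "giving_up_density",
    "exploitation_fraction",
    "discretize_departure",
    "compute_descriptors",
    "summarise_descriptors",
    "mean_ci95",
    "DESCRIPTOR_COLUMNS",
]

#: descriptor value columns shared by per-series and modelled tables
DESCRIPTOR_COLUMNS = (
    "gut_mean_h",
    "accumulation_rate_nci_h",
    "gud_nci_disk",
    "exploitation_frac",
)


@dataclass(frozen=True)
class ObservationSchedule:
    """Direct-observation check times over a trial.

    Checks run every ``day_interval_h`` while the clock is inside the
    daytime window [day_start, day_end) and once at the end of each night
    block (the first morning check).  ``trial_start_clock`` is the wall
    clock (hours, 0-24) at trial time zero.
    """

    horizon_h: float = 96.0
    day_interval_h: float = 0.5
    day_start: float = 6.0
    day_end: float = 18.0
    trial_start_clock: float = 6.0

    def __post_init__(self) -> None:
        if not self.horizon_h > 0:
            raise ValueError("horizon_h must be > 0")
        if not 0 < self.day_interval_h <= self.horizon_h:
            raise ValueError("day_interval_h must be in (0, horizon]")
        if not 0 <= self.day_start < self.day_end <= 24:
            raise ValueError("need 0 <= day_start < day_end <= 24")

    def is_night(self, t) -> np.ndarray | bool:
        """Whether trial time ``t`` (hours) falls outside the daytime window."""
        clock = (self.trial_start_clock + np.asarray(t, dtype=float)) % 24.0
        night = (clock < self.day_start) | (clock >= self.day_end)
        return bool(night) if np.isscalar(t) else night

    def check_times(self) -> np.ndarray:
        """Sorted observation instants in (0, horizon]."""
        n_steps = int(round(self.horizon_h / self.day_interval_h))
        grid = np.arange(1, n_steps + 1) * self.day_interval_h
        grid = grid[grid <= self.horizon_h + 1e-9]
        # A grid point is a check if it lies in daytime (checks happen through
        # the day and at day_end) or exactly at a morning boundary (the check
        # that clears the night block).
        clock = (self.trial_start_clock + grid) % 24.0
        day_check = (clock > self.day_start + 1e-9) & (clock <= self.day_end + 1e-9)
        morning = np.isclose(clock, self.day_start, atol=1e-9)
        return grid[day_check | morning]


def discretize_departure(true_time: float, schedule: ObservationSchedule) -> float:
    """Map a true departure instant to the first later observation check.

    Returns ``nan`` (censored) when no check at or after ``true_time`` falls
    within the horizon.  Idempotent: a time already on the grid maps to
    itself.
    """
    if true_time < 0:
        raise ValueError("departure time must be >= 0")
    checks = schedule.check_times()
    idx = int(np.searchsorted(checks, true_time - 1e-9, side="left"))
    if idx >= len(checks):
        return math.nan
    return float(checks[idx])


class GutResult(NamedTuple):
    mean_h: float
    ci95_h: float
    n_leavers: int
    n_censored: int


class GudResult(NamedTuple):
    mean_nci: float
    ci95_nci: float
    n_disks: int


class ExploitationResult(NamedTuple):
    exploited: float  # 1 - grazed/control
    residual_ratio: float  # grazed/control
    flagged: bool  # True when grazed exceeds control (negative exploitation)


def mean_ci95(values: np.ndarray) -> tuple[float, float]:
    """Mean and t-based 95% CI half-width; half-width is nan for n < 2."""
    v = np.asarray(values, dtype=float)
    n = v.size
    mean = float(v.mean())
    if n < 2:
        return mean, math.nan
    sem = v.std(ddof=1) / math.sqrt(n)
    return mean, float(stats.t.ppf(0.975, n - 1) * sem)


def giving_up_time(
    entry_times, departure_times, horizon: float = 96.0
) -> GutResult:
    """Mean time-on-patch of the leavers, with t-based 95% CI.

    ``departure_times`` uses ``nan`` for censored foragers (still present at
    the horizon); those are counted but excluded from the mean, per the
    study's exclusion rule.  With no leavers the GUT is undefined (nan).
    """
    entry = np.asarray(entry_times, dtype=float)
    dep = np.asarray(departure_times, dtype=float)
    if entry.size == 0:
        raise ValueError("no forager records")
    if entry.shape != dep.shape:
        raise ValueError("entry and departure arrays must align")
    censored = np.isnan(dep)
    leavers = ~censored
    if np.any(dep[leavers] <= entry[leavers]) or np.any(dep[leavers] > horizon + 1e-9):
        raise ValueError("departure times must lie in (entry, horizon]")
    n_left = int(leavers.sum())
    if n_left == 0:
        return GutResult(math.nan, math.nan, 0, int(censored.sum()))
    mean, ci = mean_ci95(dep[leavers] - entry[leavers])
    return GutResult(mean, ci, n_left, int(censored.sum()))


def net_accumulation_rate(
    body_charge, entry_times, departure_times, horizon: float = 96.0
):
    """Per-forager net charge accumulation rate (nCi h^-1).

    Final body charge divided by time on patch; censored foragers (nan
    departure) were present until the horizon and use ``horizon - entry``.
    """
    charge = np.asarray(body_charge, dtype=float)
    entry = np.asarray(entry_times, dtype=float)
    dep = np.asarray(departure_times, dtype=float)
    if np.any(charge < 0):
        raise ValueError("body charge must be >= 0")
    time_on_patch = np.where(np.isnan(dep), horizon - entry, dep - entry)
    if np.any(time_on_patch <= 0):
        raise ValueError("zero or negative time on patch")
    out = charge / time_on_patch
    return float(out) if out.ndim == 0 else out


def giving_up_density(charges) -> GudResult:
    """Mean residual charge of grazed disks with t-based 95% CI."""
    c = np.asarray(charges, dtype=float)
    if c.size == 0:
        raise ValueError("no grazed disks selected")
    if np.any(c < 0):
        raise ValueError("disk charges must be >= 0")
    mean, ci = mean_ci95(c)
    return GudResult(mean, ci, int(c.size))


def exploitation_fraction(grazed_mean: float, control_mean: float) -> ExploitationResult:
    """Exploited fraction ``1 - grazed/control`` against per-series controls.

    Both the exploited complement and the raw residual ratio are returned.
    Negative exploitation (grazed disks hotter than controls) is reported,
    not suppressed, but flagged.
    """
    if control_mean <= 0:
        raise ValueError("control mean charge must be > 0")
    if grazed_mean < 0:
        raise ValueError("grazed mean charge must be >= 0")
    ratio = grazed_mean / control_mean
    exploited = 1.0 - ratio
    flagged = exploited < 0
    if flagged:
        warnings.warn(
            f"negative exploitation ({exploited:.3f}): grazed disks exceed controls",
            stacklevel=2,
        )
    return ExploitationResult(exploited, ratio, flagged)


def _final_control_means(disks: pd.DataFrame) -> pd.Series:
    ctrl = disks[disks["role"] == "final_control"]
    if ctrl.empty:
        raise ValueError(
            "exploitation stage requires final_control disks; none found"
        )
    return ctrl.groupby("series_id")["charge_nci"].mean()


def compute_descriptors(
    foragers: pd.DataFrame,
    disks: pd.DataFrame,
    horizon: float = 96.0,
) -> pd.DataFrame:
    """All four descriptors for every treatment x series.

    ``foragers`` columns: treatment_id, series_id, species, entry_time_h,
    departure_time_h (nan = censored), body_charge_nci.
    ``disks`` columns: series_id, role ('grazed'/'start_control'/
    'final_control'), treatment_id (for grazed), charge_nci.
    """
    controls = _final_control_means(disks)
    grazed = disks[disks["role"] == "grazed"]
    rows = []
    for (tid, sid), grp in foragers.groupby(["treatment_id", "series_id"], sort=True):
        gut = giving_up_time(
            grp["entry_time_h"].to_numpy(),
            grp["departure_time_h"].to_numpy(),
            horizon,
        )
        rates = net_accumulation_rate(
            grp["body_charge_nci"].to_numpy(),
            grp["entry_time_h"].to_numpy(),
            grp["departure_time_h"].to_numpy(),
            horizon,
        )
        dsel = grazed[(grazed["treatment_id"] == tid) & (grazed["series_id"] == sid)]
        gud = giving_up_density(dsel["charge_nci"].to_numpy())
        if sid not in controls.index:
            raise ValueError(f"no final_control disks for series {sid!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expl = exploitation_fraction(gud.mean_nci, float(controls.loc[sid]))
        rows.append(
            {
                "treatment_id": tid,
                "series_id": sid,
                "species": grp["species"].iloc[0],
                "n_individuals": len(grp),
                "gut_mean_h": gut.mean_h,
                "gut_ci95_h": gut.ci95_h,
                "n_leavers": gut.n_leavers,
                "n_censored": gut.n_censored,
                "accumulation_rate_nci_h": float(np.mean(rates)),
                "gud_nci_disk": gud.mean_nci,
                "gud_ci95": gud.ci95_nci,
                "exploitation_frac": expl.exploited,
                "residual_ratio": expl.residual_ratio,
                "exploitation_flagged": expl.flagged,
                "modelled": False,
            }
        )
    return pd.DataFrame(rows)


def summarise_descriptors(per_series: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-series descriptors to one row per treatment.

    Means and t-based 95% CIs are taken across the independent series
    (typically four), matching how replicate averages are summarised.
    Undefined per-series GUTs (no leavers) are dropped from the GUT
    aggregate only.
    """
    rows = []
    for tid, grp in per_series.groupby("treatment_id", sort=True):
        row = {
            "treatment_id": tid,
            "species": grp["species"].iloc[0],
            "n_individuals": int(grp["n_individuals"].iloc[0]),
            "n_series": len(grp),
            "modelled": bool(grp["modelled"].any()),
        }
        for col in DESCRIPTOR_COLUMNS:
            vals = grp[col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size:
                mean, ci = mean_ci95(vals)
            else:
                mean, ci = math.nan, math.nan
            row[col] = mean
            row[col + "_ci95"] = ci
            row[col + "_n_series"] = int(vals.size)
        rows.append(row)
    return pd.DataFrame(rows)
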