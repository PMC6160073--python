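"""Patch-departure descriptors and the observation-grid discretisation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gudscale.descriptors import (
    ObservationSchedule,
    compute_descriptors,
    discretize_departure,
    exploitation_fraction,
    giving_up_density,
    giving_up_time,
    net_accumulation_rate,
    summarise_descriptors,
)

SCHED = ObservationSchedule()  # 96 h, day 06:00-18:00, trial starts 06:00


class TestGivingUpTime:
    def test_mean_of_leavers(self):
        res = giving_up_time([0.0, 0.0], [20.0, 30.0])
        assert res.mean_h == 25.0 and res.n_leavers == 2 and res.n_censored == 0

    def test_all_censored_is_undefined(self):
        res = giving_up_time([0.0, 0.0], [np.nan, np.nan])
        assert math.isnan(res.mean_h) and res.n_leavers == 0 and res.n_censored == 2

    def test_zero_variance_has_zero_ci(self):
        res = giving_up_time([0.0] * 4, [26.0] * 4)
        assert res.mean_h == 26.0 and res.ci95_h == 0.0

    def test_censored_records_do_not_shift_the_mean(self):
        base = giving_up_time([0.0, 0.0], [20.0, 30.0])
        with_cens = giving_up_time([0.0] * 5, [20.0, 30.0, np.nan, np.nan, np.nan])
        assert with_cens.mean_h == base.mean_h and with_cens.ci95_h == base.ci95_h
        assert with_cens.n_censored == 3

    @given(
        deps=st.lists(st.floats(min_value=0.5, max_value=96), min_size=2, max_size=10),
        n_cens=st.integers(min_value=0, max_value=5),
    )
    def test_censoring_invariance_property(self, deps, n_cens):
        entries = [0.0] * len(deps)
        base = giving_up_time(entries, deps)
        aug = giving_up_time(entries + [0.0] * n_cens, deps + [np.nan] * n_cens)
        assert aug.mean_h == pytest.approx(base.mean_h)
        assert aug.n_censored == n_cens

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            giving_up_time([], [])


class TestAccumulationRate:
    def test_division(self):
        assert net_accumulation_rate(2.6, 0.0, 26.0) == pytest.approx(0.1)

    def test_zero_charge(self):
        assert net_accumulation_rate(0.0, 0.0, 26.0) == 0.0

    def test_censored_uses_full_horizon(self):
        assert net_accumulation_rate(9.6, 0.0, np.nan, horizon=96.0) == pytest.approx(0.1)

    def test_zero_time_on_patch_rejected(self):
        with pytest.raises(ValueError):
            net_accumulation_rate(1.0, 5.0, 5.0)


class TestGivingUpDensity:
    def test_equal_charges(self):
        assert giving_up_density([31.2] * 16).mean_nci == pytest.approx(31.2)

    def test_mean(self):
        res = giving_up_density([10.0, 20.0, 30.0])
        assert res.mean_nci == 20.0 and res.n_disks == 3

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            giving_up_density([])


class TestExploitation:
    def test_ungrazed_is_zero(self):
        assert exploitation_fraction(31.2, 31.2).exploited == 0.0

    def test_half_exploited(self):
        res = exploitation_fraction(15.6, 31.2)
        assert res.exploited == pytest.approx(0.5)

    def test_negative_exploitation_flagged_not_suppressed(self):
        with pytest.warns(UserWarning, match="negative"):
            res = exploitation_fraction(33.0, 31.2)
        assert res.exploited == pytest.approx(-0.0577, abs=1e-4) and res.flagged

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            exploitation_fraction(1.0, 0.0)

    @given(
        g=st.floats(min_value=0, max_value=100),
        c=st.floats(min_value=0.1, max_value=100),
    )
    def test_complement_identity(self, g, c):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = exploitation_fraction(g, c)
        assert res.exploited + g / c == pytest.approx(1.0, abs=1e-12)


class TestDiscretize:
    def test_daytime_rounds_up_to_half_hour(self):
        assert discretize_departure(10.2, SCHED) == 10.5

    def test_check_time_unchanged(self):
        assert discretize_departure(10.5, SCHED) == 10.5

    def test_night_maps_to_block_end(self):
        # night block starts 12 h after the 06:00 trial start; 2 h in -> next
        # morning check at t=24
        assert discretize_departure(14.0, SCHED) == 24.0

    def test_beyond_horizon_censored(self):
        assert math.isnan(discretize_departure(96.2, SCHED))

    @given(t=st.floats(min_value=0.01, max_value=95.9))
    def test_idempotent_and_never_decreases(self, t):
        once = discretize_departure(t, SCHED)
        assert once >= t - 1e-9
        assert discretize_departure(once, SCHED) == once

    def test_grid_structure(self):
        checks = SCHED.check_times()
        # first day: 30-min checks from 06:30 to 18:00, then one at 06:00 next day
        assert checks[0] == 0.5 and checks[23] == 12.0 and checks[24] == 24.0
        assert checks[-1] == 96.0


def _toy_tables():
    foragers = pd.DataFrame(
        {
            "treatment_id": ["T1"] * 3 + ["T2"] * 2,
            "series_id": ["S1"] * 5,
            "species": ["a"] * 3 + ["b"] * 2,
            "entry_time_h": 0.0,
            "departure_time_h": [20.0, 30.0, np.nan, 48.0, 48.0],
            "body_charge_nci": [2.0, 3.0, 9.6, 4.8, 4.8],
        }
    )
    disks = pd.DataFrame(
        {
            "series_id": ["S1"] * 6,
            "treatment_id": ["T1", "T1", "T2", "T2", "", ""],
            "role": ["grazed"] * 4 + ["final_control"] * 2,
            "charge_nci": [10.0, 20.0, 15.0, 25.0, 30.0, 30.0],
        }
    )
    return foragers, disks


def test_compute_descriptors_toy_example():
    foragers, disks = _toy_tables()
    out = compute_descriptors(foragers, disks).set_index("treatment_id")
    t1 = out.loc["T1"]
    assert t1["gut_mean_h"] == 25.0 and t1["n_censored"] == 1
    # rates: 2/20, 3/30, 9.6/96 -> all 0.1
    assert t1["accumulation_rate_nci_h"] == pytest.approx(0.1)
    assert t1["gud_nci_disk"] == 15.0
    assert t1["exploitation_frac"] == pytest.approx(0.5)
    t2 = out.loc["T2"]
    assert t2["gud_nci_disk"] == 20.0 and t2["exploitation_frac"] == pytest.approx(1 / 3)


def test_compute_descriptors_requires_final_controls():
    foragers, disks = _toy_tables()
    with pytest.raises(ValueError, match="final_control"):
        compute_descriptors(foragers, disks[disks["role"] == "grazed"])


def test_summarise_across_series_drops_undefined_gut():
    per = pd.DataFrame(
        {
            "treatment_id": ["T"] * 3,
            "series_id": ["S1", "S2", "S3"],
            "species": "a",
            "n_individuals": 4,
            "modelled": False,
            "gut_mean_h": [20.0, 30.0, np.nan],
            "accumulation_rate_nci_h": [0.1, 0.2, 0.3],
            "gud_nci_disk": [10.0, 10.0, 10.0],
            "exploitation_frac": [0.5, 0.4, 0.3],
        }
    )
    out = summarise_descriptors(per).iloc[0]
    assert out["gut_mean_h"] == 25.0 and out["gut_mean_h_n_series"] == 2
    assert out["accumulation_rate_nci_h"] == pytest.approx(0.2)
    assert out["gud_nci_disk_ci95"] == 0.0
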