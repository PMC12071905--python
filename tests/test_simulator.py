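import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from ormsim import (
    ControlSetting,
    sample_arrival_counts,
    sample_service_time,
    simulate_week,
    system_time,
    total_cost,
)
from ormsim.scenario import STATIONS, CapacityParams
from ormsim.simulator import RECORD_COLUMNS, UndefinedAverageError


def _record_row(**overrides):
    row = {c: 0.0 for c in RECORD_COLUMNS}
    row.update({"patient_id": 0, "day": 1, "treated": 1, "regular_flag": 1})
    row.update(overrides)
    return row


# ---------------------------------------------------------------------------
# arrival sampling


def test_zero_rate_gives_no_arrivals(rng):
    counts, offsets = sample_arrival_counts(0.0, 5, rng)
    assert counts.tolist() == [0] * 5
    assert all(len(o) == 0 for o in offsets)


def test_negative_rate_rejected(rng):
    with pytest.raises(ValueError):
        sample_arrival_counts(-1.0, 5, rng)


def test_arrival_offsets_sorted_within_window(rng):
    counts, offsets = sample_arrival_counts(40.0, 20, rng, window_minutes=600.0)
    for c, offs in zip(counts, offsets):
        assert len(offs) == c
        assert np.all(np.diff(offs) > 0)
        assert np.all(offs <= 600.0)


def test_arrival_mean_tracks_rate(rng):
    # CLT: 3 sigma band for the mean of 3000 Poisson(25) days
    counts, _ = sample_arrival_counts(25.0, 3000, rng)
    assert abs(counts.mean() - 25.0) < 3 * math.sqrt(25.0 / 3000)


# ---------------------------------------------------------------------------
# service sampling


def test_degenerate_normal_returns_mean(rng):
    draws = sample_service_time(30.0, 0.0, rng, size=10)
    assert np.all(draws == 30.0)


def test_service_floor_applies(rng):
    draws = sample_service_time(2.0, 10.0, rng, floor=1.0, size=5000)
    assert draws.min() >= 1.0


def test_service_mean_recovered(rng):
    draws = sample_service_time(30.0, 5.0, rng, size=100_000)
    assert abs(draws.mean() - 30.0) < 0.15     # truncation negligible at mu/sd=6


def test_service_sd_must_be_nonnegative(rng):
    with pytest.raises(ValueError):
        sample_service_time(30.0, -1.0, rng)


# ---------------------------------------------------------------------------
# responses on constructed ledgers


def test_total_cost_single_regular_patient(fixture_config):
    # y=60 regular minutes at (nr+ar+cr)=3, bed 30 min at 0.5, fixed 100
    costs = dataclasses.replace(
        fixture_config.cost_rates,
        holding_nurse_regular=1.0, holding_nurse_overtime=1.0,
        anesthetist_regular=1.0, anesthetist_overtime=1.0,
        circulating_nurse_regular=1.0, circulating_nurse_overtime=1.0,
        bed_per_minute=0.5, treatment_fixed=100.0)
    records = pd.DataFrame([_record_row(regular_minutes=60.0, bed_minutes=30.0)])
    assert total_cost(records, None, costs, 1) == pytest.approx(295.0)


def test_total_cost_empty_sums_are_zero(fixture_config):
    records = pd.DataFrame(columns=RECORD_COLUMNS)
    assert total_cost(records, None, fixture_config.cost_rates, 1) == 0.0


def test_total_cost_linear_in_overtime_rates(fixture_config):
    records = pd.DataFrame([
        _record_row(patient_id=0, regular_minutes=40.0, overtime_minutes=20.0,
                    regular_flag=0, bed_minutes=10.0),
        _record_row(patient_id=1, regular_minutes=50.0),
    ])
    base = fixture_config.cost_rates
    doubled = dataclasses.replace(
        base,
        holding_nurse_overtime=2 * base.holding_nurse_overtime,
        anesthetist_overtime=2 * base.anesthetist_overtime,
        circulating_nurse_overtime=2 * base.circulating_nurse_overtime)
    diff = total_cost(records, None, doubled, 2) - total_cost(records, None, base, 2)
    assert diff == pytest.approx(base.overtime_sum * 20.0 / 2)


def test_total_cost_undefined_for_zero_patients(fixture_config):
    with pytest.raises(UndefinedAverageError):
        total_cost(pd.DataFrame(columns=RECORD_COLUMNS), None,
                   fixture_config.cost_rates, 0)


def test_system_time_hand_averages():
    one = pd.DataFrame([_record_row(total_wait=20.0, total_service=90.0)])
    assert system_time(one, 1) == pytest.approx(110.0)
    two = pd.DataFrame([
        _record_row(total_wait=10.0, total_service=100.0),
        _record_row(patient_id=1, total_wait=30.0, total_service=120.0),
    ])
    assert system_time(two, 2) == pytest.approx(130.0)
    with pytest.raises(UndefinedAverageError):
        system_time(two, 0)


# ---------------------------------------------------------------------------
# the discrete-event pass


def _uncongested(cfg):
    cap = dataclasses.replace(cfg.capacity, n_operating_rooms=10_000,
                              pacu_beds=10_000)
    return dataclasses.replace(cfg, capacity=cap)


def test_uncongested_limit_no_waiting(fixture_config):
    cfg = _uncongested(fixture_config)
    setting = ControlSetting(10_000, 10_000, 10_000, 10_000)
    out = simulate_week(cfg, setting, np.random.default_rng(3),
                        regime_override=(0.85, 5.0))
    r = out.records
    assert out.n_dropped == 0
    assert np.allclose(r["total_wait"], 0.0, atol=1e-9)
    assert (r["regular_flag"] == 1).all()
    assert (r["overtime_minutes"] == 0.0).all()
    # ST converges on the closed-form sum of station service means
    mu_total = cfg.station_times.total_service_mean
    sd_total = math.sqrt(cfg.station_times.total_service_var)
    assert abs(out.st - mu_total) < 4 * sd_total / math.sqrt(out.n_completed)


def test_same_seed_identical_outcome(fixture_config):
    setting = ControlSetting(15, 25, 20, 10)
    a = simulate_week(fixture_config, setting, np.random.default_rng(11))
    b = simulate_week(fixture_config, setting, np.random.default_rng(11))
    assert a.tc == b.tc and a.st == b.st and a.n_completed == b.n_completed
    pd.testing.assert_frame_equal(a.records, b.records)
    pd.testing.assert_frame_equal(a.ledgers, b.ledgers)


def test_minute_conservation_and_daily_caps(fixture_config):
    setting = ControlSetting(10, 15, 15, 10)
    out = simulate_week(fixture_config, setting, np.random.default_rng(5),
                        regime_override=(0.75, 80.0))
    r = out.records
    # y + x equals the OR-stage service minutes for every completed patient
    assert np.allclose(r["regular_minutes"] + r["overtime_minutes"],
                       r["service_operating_room"], atol=1e-6)
    # regular flag iff no overtime minutes
    assert ((r["overtime_minutes"] == 0.0) == (r["regular_flag"] == 1)).all()
    # per-station sums match the totals exactly
    waits = sum(r[f"wait_{s}"] for s in STATIONS)
    servs = sum(r[f"service_{s}"] for s in STATIONS)
    assert np.allclose(waits, r["total_wait"])
    assert np.allclose(servs, r["total_service"])
    led = out.ledgers
    assert (led["regular_consumed"] <= led["regular_capacity"] + 1e-6).all()
    assert (led["overtime_consumed"] <= led["overtime_cap"] + 1e-6).all()
    assert (led["regular_consumed"] >= 0).all()
    # ledger consumption equals the patient-level minute totals
    assert led["regular_consumed"].sum() == pytest.approx(r["regular_minutes"].sum())
    assert led["overtime_consumed"].sum() == pytest.approx(r["overtime_minutes"].sum())


def test_halving_operating_rooms_slows_system(fixture_config):
    setting = ControlSetting(15, 25, 20, 10)
    halved = dataclasses.replace(
        fixture_config,
        capacity=dataclasses.replace(fixture_config.capacity, n_operating_rooms=4))
    st_full, st_half = [], []
    for rep in range(30):
        st_full.append(simulate_week(fixture_config, setting,
                                     np.random.default_rng(100 + rep)).st)
        st_half.append(simulate_week(halved, setting,
                                     np.random.default_rng(100 + rep)).st)
    assert np.mean(st_half) > np.mean(st_full)


def test_literal_times_mode_matches_closed_form(fixture_config):
    setting = ControlSetting(10, 15, 15, 5)
    out = simulate_week(fixture_config, setting, np.random.default_rng(9),
                        literal_times=True)
    st = fixture_config.station_times
    wait_mu = sum(st.of(s).wait_mean for s in STATIONS)
    mu = wait_mu + st.total_service_mean
    assert out.n_dropped == 0
    assert abs(out.st - mu) < 15.0           # loose CLT band, ~390 patients
    assert (out.records["total_wait"] >= 0).all()
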