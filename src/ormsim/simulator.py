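"""Discrete-event simulation of the weekly operating-room patient flow.

Patients arrive by a Poisson process (sampled by exponential inter-arrival
inversion), queue FIFO for a preoperative bed plus a holding nurse, receive
ward preparation, then wait — still occupying the bed — for an operating
room together with one anesthetist and one circulating nurse, recover in the
PACU, and finally go through return/discharge.  Waiting times emerge from
resource contention; in the uncongested limit the total system time reduces
to the closed-form sum-of-normals service model.

OR minutes are metered per day: each day t offers a regular budget
R_t = utilization(t) * n_OR * shift_minutes and an overtime cap O_t.  A
patient's OR minutes accrue first against the regular budget (y_it), then
against overtime (x_it); patients who cannot start within R_t + O_t are
deferred to the next day, and end-of-horizon leftovers are dropped from N.

Responses per replicate: TC, the average per-patient total cost (overtime
staff + regular staff + preoperative-bed + fixed treating cost), and ST, the
average per-patient system time (total waiting + total service minutes).
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenario import (
    DAY_MINUTES,
    STATIONS,
    ControlSetting,
    CostRates,
    ScenarioConfig,
)

__all__ = [
    "SimOutcome",
    "sample_arrival_counts",
    "sample_service_time",
    "simulate_week",
    "total_cost",
    "system_time",
    "UndefinedAverageError",
]

#: Columns of the per-patient records table.
RECORD_COLUMNS = (
    ["patient_id", "day", "arrival_minute"]
    + [f"wait_{s}" for s in STATIONS]
    + [f"service_{s}" for s in STATIONS]
    + ["total_wait", "total_service", "bed_minutes",
       "regular_minutes", "overtime_minutes", "treated", "regular_flag"]
)

_EPS = 1e-9


class UndefinedAverageError(ZeroDivisionError):
    """TC or ST requested for a run with zero completed patients."""


def sample_arrival_counts(arrival_rate: float, n_days: int, rng: np.random.Generator,
                          window_minutes: float = 600.0):
    """Sample daily arrival counts by exponential inter-arrival inversion.

    Uniform draws theta are inverted through the exponential CDF,
    gap = -ln(1-theta)/rate, and accumulated until the admission window is
    exceeded; the count of accumulated events is that day's number of
    arrivals, so counts are Poisson with mean ``arrival_rate``.

    Returns ``(counts, offsets)``: an int array of per-day counts and a list
    of per-day arrival-offset arrays (minutes into the day), retained for the
    discrete-event pass.
    """
    if arrival_rate < 0:
        raise ValueError(f"arrival_rate must be >= 0, got {arrival_rate}")
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    if window_minutes <= 0:
        raise ValueError("window_minutes must be > 0")
    counts = np.zeros(n_days, dtype=np.int64)
    offsets: list[np.ndarray] = []
    if arrival_rate == 0:
        return counts, [np.empty(0) for _ in range(n_days)]
    rate = arrival_rate / window_minutes  # events per minute
    block = int(arrival_rate + 10.0 * math.sqrt(arrival_rate) + 10.0)
    for d in range(n_days):
        gaps = -np.log1p(-rng.random(block)) / rate
        times = np.cumsum(gaps)
        while times[-1] <= window_minutes:
            gaps = -np.log1p(-rng.random(block)) / rate
            times = np.concatenate([times, times[-1] + np.cumsum(gaps)])
        k = int(np.searchsorted(times, window_minutes, side="right"))
        counts[d] = k
        offsets.append(times[:k])
    return counts, offsets


def sample_service_time(mean: float, sd: float, rng: np.random.Generator,
                        floor: float = 1.0, size=None):
    """Draw normal service times truncated below at ``floor`` minutes."""
    if mean <= 0:
        raise ValueError(f"service mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"service sd must be >= 0, got {sd}")
    draws = rng.normal(mean, sd, size=size)
    return np.maximum(draws, floor)


# ---------------------------------------------------------------------------
# outcome container


@dataclass
class SimOutcome:
    """One replicate's result: responses, per-patient records, day ledgers."""

    tc: float
    st: float
    n_completed: int
    n_dropped: int
    records: pd.DataFrame
    ledgers: pd.DataFrame

    def summary(self) -> dict:
        return {
            "TC": self.tc,
            "ST": self.st,
            "n_completed": self.n_completed,
            "n_dropped": self.n_dropped,
            "ledgers": self.ledgers.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# responses (cost and system time)


def total_cost(records: pd.DataFrame, ledgers: pd.DataFrame | None,
               costs: CostRates, n: int) -> float:
    """Average per-patient total cost.

    TC = [ sum (no+ao+co)(X-Y)x  +  sum (nr+ar+cr) y X
           + sum b B X  +  sum c X ] / N
    with x/y the patient's overtime/regular OR minutes, B the preoperative-bed
    minutes and c the fixed treating cost.  ``ledgers``, when given, are
    checked against the daily regular/overtime caps before summing.
    """
    if n < 1:
        raise UndefinedAverageError("TC undefined for N = 0 completed patients")
    if ledgers is not None and len(ledgers):
        bad_reg = ledgers["regular_consumed"] > ledgers["regular_capacity"] + _EPS
        bad_ot = ledgers["overtime_consumed"] > ledgers["overtime_cap"] + _EPS
        if bool(bad_reg.any()) or bool(bad_ot.any()):
            raise ValueError("day ledger violates regular/overtime capacity")
    if not len(records):
        return 0.0
    treated = records["treated"].to_numpy(dtype=float)
    regular_flag = records["regular_flag"].to_numpy(dtype=float)
    x = records["overtime_minutes"].to_numpy(dtype=float)
    y = records["regular_minutes"].to_numpy(dtype=float)
    bed = records["bed_minutes"].to_numpy(dtype=float)
    overtime_term = costs.overtime_sum * float(((treated - regular_flag) * x).sum())
    regular_term = costs.regular_sum * float((y * treated).sum())
    bed_term = costs.bed_per_minute * float((bed * treated).sum())
    fixed_term = costs.treatment_fixed * float(treated.sum())
    return (overtime_term + regular_term + bed_term + fixed_term) / n


def system_time(records: pd.DataFrame, n: int) -> float:
    """Average per-patient system time ST = (sum W + sum S) / N in minutes."""
    if n < 1:
        raise UndefinedAverageError("ST undefined for N = 0 completed patients")
    if not len(records):
        return 0.0
    return float((records["total_wait"].sum() + records["total_service"].sum()) / n)


# ---------------------------------------------------------------------------
# the discrete-event pass


@dataclass
class _Patient:
    pid: int
    arrival_day: int
    arrival_time: float
    services: tuple[float, float, float, float]
    bed_assign: float = math.nan
    preop_end: float = math.nan
    or_start: float = math.nan
    or_end: float = math.nan
    pacu_start: float = math.nan
    done: float = math.nan
    or_day: int = 0
    y: float = 0.0
    x: float = 0.0
    regular_flag: int = 0
    deferred_until: float = -math.inf
    dropped: bool = False


def _day_of(time: float) -> int:
    return int(time // DAY_MINUTES) + 1


def simulate_week(config: ScenarioConfig, setting: ControlSetting,
                  rng: np.random.Generator, *,
                  regime_override: tuple[float, float] | None = None,
                  literal_times: bool = False) -> SimOutcome:
    """Simulate one week of patient flow under ``setting``.

    ``regime_override=(utilization, arrival_rate)`` replaces the config's
    day-of-week regimes with a single uniform condition (used by the DOE so
    outer factors are not confounded with day of week).  ``literal_times``
    bypasses resource contention and draws each patient's total waiting time
    directly from the closed-form normal model (sum of per-station waiting
    means/variances) — the uncoupled textbook form, kept for testing the
    response definitions in isolation.
    """
    cap = config.capacity
    n_days = cap.horizon_days
    floor = config.service_floor_minutes

    if regime_override is not None:
        util_by_day = {t: float(regime_override[0]) for t in range(1, n_days + 1)}
        lam_by_day = {t: float(regime_override[1]) for t in range(1, n_days + 1)}
    else:
        util_by_day = {t: config.regime_for_day(t).signal.utilization
                       for t in range(1, n_days + 1)}
        lam_by_day = {t: config.regime_for_day(t).noise.arrival_rate
                      for t in range(1, n_days + 1)}

    # Arrivals first, then all service draws in patient order: the draw
    # sequence is independent of capacities, so paired-seed runs are true
    # common-random-number comparisons.
    arrival_times: list[float] = []
    arrival_days: list[int] = []
    for t in range(1, n_days + 1):
        _, offs = sample_arrival_counts(lam_by_day[t], 1, rng,
                                        cap.arrival_window_minutes)
        for off in offs[0]:
            arrival_times.append((t - 1) * DAY_MINUTES + float(off))
            arrival_days.append(t)
    n_pat = len(arrival_times)

    service_draws = {}
    for s in STATIONS:
        st = config.station_times.of(s)
        service_draws[s] = (sample_service_time(st.service_mean, st.service_sd,
                                                rng, floor, size=n_pat)
                            if n_pat else np.empty(0))

    if literal_times:
        return _literal_outcome(config, arrival_times, arrival_days,
                                service_draws, rng)

    patients = [
        _Patient(pid=i, arrival_day=arrival_days[i], arrival_time=arrival_times[i],
                 services=tuple(float(service_draws[s][i]) for s in STATIONS))
        for i in range(n_pat)
    ]

    reg_rem = {t: cap.regular_minutes(util_by_day[t]) for t in range(1, n_days + 1)}
    reg_cap = dict(reg_rem)
    ot_rem = {t: float(cap.overtime_cap_minutes) for t in range(1, n_days + 1)}
    deferred_count = {t: 0 for t in range(1, n_days + 1)}

    free = {
        "bed": setting.preoperative_beds,
        "hold": setting.holding_nurses,
        "or": cap.n_operating_rooms,
        "anes": setting.anesthetists,
        "circ": setting.circulating_nurses,
        "pacu": cap.pacu_beds,
    }

    q_ward: deque[int] = deque()
    q_or: list[int] = []
    q_pacu: deque[int] = deque()

    heap: list[tuple[float, int, str, int]] = []
    seq = 0

    def push(time: float, kind: str, pid: int = -1):
        nonlocal seq
        heapq.heappush(heap, (time, seq, kind, pid))
        seq += 1

    for p in patients:
        push(p.arrival_time, "arrive", p.pid)
    for t in range(2, n_days + 1):
        push((t - 1) * DAY_MINUTES, "day_start")

    def try_start_ward(now: float):
        while free["bed"] > 0 and free["hold"] > 0 and q_ward:
            pid = q_ward.popleft()
            p = patients[pid]
            free["bed"] -= 1
            free["hold"] -= 1
            p.bed_assign = now
            push(now + p.services[0], "preop_done", pid)

    def drop(p: _Patient):
        p.dropped = True
        free["bed"] += 1  # bed held since assignment

    def try_start_or(now: float):
        day = _day_of(now)
        progressed = True
        while progressed and free["or"] > 0 and free["anes"] > 0 and free["circ"] > 0:
            progressed = False
            for idx, pid in enumerate(q_or):
                p = patients[pid]
                if p.deferred_until > now + _EPS:
                    continue
                if day > n_days:
                    # beyond the planning horizon: weekly leftover, dropped
                    del q_or[idx]
                    drop(p)
                    progressed = True
                    break
                s2 = p.services[1]
                avail = max(reg_rem[day], 0.0) + max(ot_rem[day], 0.0)
                if s2 <= avail + _EPS:
                    y = min(s2, max(reg_rem[day], 0.0))
                    x = s2 - y
                    reg_rem[day] -= y
                    ot_rem[day] -= x
                    p.y, p.x = y, x
                    p.regular_flag = 1 if x <= _EPS else 0
                    if p.regular_flag:
                        p.y, p.x = s2, 0.0
                    p.or_day = day
                    p.or_start = now
                    free["or"] -= 1
                    free["anes"] -= 1
                    free["circ"] -= 1
                    free["bed"] += 1  # bed released at OR entry
                    del q_or[idx]
                    push(now + s2, "or_done", pid)
                    progressed = True
                    break
                # cannot fit in today's OR budget: defer to next day
                if day >= n_days:
                    del q_or[idx]
                    drop(p)
                else:
                    p.deferred_until = day * DAY_MINUTES
                    deferred_count[day] += 1
                progressed = True
                break

    def try_start_pacu(now: float):
        while free["pacu"] > 0 and q_pacu:
            pid = q_pacu.popleft()
            p = patients[pid]
            free["pacu"] -= 1
            p.pacu_start = now
            push(now + p.services[2], "pacu_done", pid)

    while heap:
        now, _, kind, pid = heapq.heappop(heap)
        if kind == "arrive":
            q_ward.append(pid)
            try_start_ward(now)
        elif kind == "preop_done":
            p = patients[pid]
            free["hold"] += 1
            p.preop_end = now
            q_or.append(pid)
            try_start_or(now)
            try_start_ward(now)
        elif kind == "or_done":
            p = patients[pid]
            free["or"] += 1
            free["anes"] += 1
            free["circ"] += 1
            p.or_end = now
            q_pacu.append(pid)
            try_start_pacu(now)
            try_start_or(now)
            try_start_ward(now)
        elif kind == "pacu_done":
            p = patients[pid]
            free["pacu"] += 1
            p.done = now + p.services[3]  # return/discharge needs no contended resource
            try_start_pacu(now)
        elif kind == "day_start":
            try_start_or(now)
            try_start_ward(now)

    completed = [p for p in patients if not p.dropped and not math.isnan(p.done)]
    n_dropped = sum(1 for p in patients if p.dropped)

    rows = []
    for p in completed:
        w_ward = p.bed_assign - p.arrival_time
        w_or = p.or_start - p.preop_end
        w_pacu = p.pacu_start - p.or_end
        w_disc = 0.0
        s1, s2, s3, s4 = p.services
        rows.append((
            p.pid, p.or_day, p.arrival_time - (p.arrival_day - 1) * DAY_MINUTES,
            w_ward, w_or, w_pacu, w_disc, s1, s2, s3, s4,
            w_ward + w_or + w_pacu + w_disc, s1 + s2 + s3 + s4,
            p.or_start - p.bed_assign, p.y, p.x, 1, p.regular_flag,
        ))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)

    ledgers = pd.DataFrame({
        "day": list(range(1, n_days + 1)),
        "regular_capacity": [reg_cap[t] for t in range(1, n_days + 1)],
        "overtime_cap": [float(cap.overtime_cap_minutes)] * n_days,
        "regular_consumed": [reg_cap[t] - reg_rem[t] for t in range(1, n_days + 1)],
        "overtime_consumed": [cap.overtime_cap_minutes - ot_rem[t]
                              for t in range(1, n_days + 1)],
        "deferred_count": [deferred_count[t] for t in range(1, n_days + 1)],
    })

    n = len(completed)
    tc = total_cost(records, ledgers, config.cost_rates, n) if n else 0.0
    st = system_time(records, n) if n else 0.0
    return SimOutcome(tc=tc, st=st, n_completed=n, n_dropped=n_dropped,
                      records=records, ledgers=ledgers)


def _literal_outcome(config: ScenarioConfig, arrival_times, arrival_days,
                     service_draws, rng: np.random.Generator) -> SimOutcome:
    """Uncoupled mode: waits drawn from the closed-form normal model."""
    n_pat = len(arrival_times)
    wait_mean = sum(config.station_times.of(s).wait_mean for s in STATIONS)
    wait_var = sum(config.station_times.of(s).wait_sd ** 2 for s in STATIONS)
    total_wait = (np.maximum(rng.normal(wait_mean, math.sqrt(wait_var), n_pat), 0.0)
                  if n_pat else np.empty(0))
    rows = []
    for i in range(n_pat):
        s = [float(service_draws[st][i]) for st in STATIONS]
        rows.append((
            i, arrival_days[i],
            arrival_times[i] - (arrival_days[i] - 1) * DAY_MINUTES,
            float(total_wait[i]), 0.0, 0.0, 0.0, s[0], s[1], s[2], s[3],
            float(total_wait[i]), sum(s), 0.0, s[1], 0.0, 1, 1,
        ))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    n_days = config.capacity.horizon_days
    ledgers = pd.DataFrame({
        "day": list(range(1, n_days + 1)),
        "regular_capacity": [math.inf] * n_days,
        "overtime_cap": [float(config.capacity.overtime_cap_minutes)] * n_days,
        "regular_consumed": [0.0] * n_days,
        "overtime_consumed": [0.0] * n_days,
        "deferred_count": [0] * n_days,
    })
    tc = total_cost(records, None, config.cost_rates, n_pat) if n_pat else 0.0
    st = system_time(records, n_pat) if n_pat else 0.0
    return SimOutcome(tc=tc, st=st, n_completed=n_pat, n_dropped=0,
                      records=records, ledgers=ledgers)
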