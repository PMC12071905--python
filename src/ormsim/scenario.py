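"""Scenario configuration for the operating-room management-system (ORMS) model.

Everything the simulator, DOE, surrogate and optimizer need to know about the
modelled hospital week lives in a :class:`ScenarioConfig`: the four control
factors and their Taguchi levels, the signal levels (target OR utilization),
the noise levels (patient arrival rate), station service-time distributions,
cost rates, and physical capacities.  Configs are plain YAML (canonical) or
JSON files; :func:`default_fixture_scenario` builds the packaged fixture
scenario programmatically.

Units: all times in minutes, cost rates in currency-units per minute, arrival
rates in patients per day.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ConfigError",
    "ControlSetting",
    "FactorLevels",
    "SignalLevel",
    "NoiseLevel",
    "StationTime",
    "StationTimeParams",
    "CostRates",
    "CapacityParams",
    "Regime",
    "ScenarioConfig",
    "load_config",
    "write_config",
    "default_fixture_scenario",
    "FACTOR_NAMES",
    "FACTOR_LETTERS",
    "STATIONS",
    "DAY_MINUTES",
]

#: Minutes in a calendar day; day t spans [(t-1)*DAY_MINUTES, t*DAY_MINUTES).
DAY_MINUTES = 1440.0

#: The four control factors, in Taguchi column order A-D.
FACTOR_NAMES = (
    "holding_nurses",
    "circulating_nurses",
    "anesthetists",
    "preoperative_beds",
)
FACTOR_LETTERS = ("A", "B", "C", "D")

#: The four stations a patient visits, in flow order.
STATIONS = ("ward", "operating_room", "pacu", "discharge")


class ConfigError(ValueError):
    """A scenario file or value violates the documented schema."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


def _require(cond: bool, key: str, message: str) -> None:
    if not cond:
        raise ConfigError(key, message)


@dataclass(frozen=True)
class ControlSetting:
    """One point in the integer control-factor box (staff and bed counts)."""

    holding_nurses: int
    circulating_nurses: int
    anesthetists: int
    preoperative_beds: int

    def __post_init__(self):
        for name in FACTOR_NAMES:
            v = getattr(self, name)
            _require(isinstance(v, (int,)) and not isinstance(v, bool), name,
                     f"must be an integer, got {v!r}")
            _require(v >= 1, name, f"must be >= 1, got {v}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return tuple(getattr(self, n) for n in FACTOR_NAMES)  # type: ignore[return-value]

    @classmethod
    def from_tuple(cls, values) -> "ControlSetting":
        a, b, c, d = (int(v) for v in values)
        return cls(a, b, c, d)


@dataclass(frozen=True)
class FactorLevels:
    """Three ascending integer levels per control factor (the L9 level values).

    The GA search box for each factor is ``[level1, level3]``.
    """

    holding_nurses: tuple[int, int, int]
    circulating_nurses: tuple[int, int, int]
    anesthetists: tuple[int, int, int]
    preoperative_beds: tuple[int, int, int]

    def __post_init__(self):
        for name in FACTOR_NAMES:
            lv = tuple(int(v) for v in getattr(self, name))
            object.__setattr__(self, name, lv)
            _require(len(lv) == 3, name, f"needs exactly 3 levels, got {len(lv)}")
            _require(lv[0] < lv[1] < lv[2], name,
                     f"levels must be strictly ascending, got {lv}")
            _require(lv[0] >= 1, name, "level 1 must be >= 1")

    def levels_of(self, factor: str) -> tuple[int, int, int]:
        return getattr(self, factor)

    @property
    def search_bounds(self) -> dict[str, tuple[int, int]]:
        """Per-factor integer search interval [level1, level3]."""
        return {n: (self.levels_of(n)[0], self.levels_of(n)[2]) for n in FACTOR_NAMES}

    def setting_from_indices(self, indices) -> ControlSetting:
        """Map four 1-based level indices (an L9 row) to integer factor values."""
        vals = []
        for name, idx in zip(FACTOR_NAMES, indices):
            _require(idx in (1, 2, 3), name, f"level index must be 1..3, got {idx}")
            vals.append(self.levels_of(name)[idx - 1])
        return ControlSetting.from_tuple(vals)

    def contains(self, setting: ControlSetting) -> bool:
        return all(lo <= v <= hi for v, (lo, hi)
                   in zip(setting.as_tuple(), self.search_bounds.values()))

    def box_size(self) -> int:
        return math.prod(hi - lo + 1 for lo, hi in self.search_bounds.values())


@dataclass(frozen=True)
class SignalLevel:
    """Target operating-room utilization, the Taguchi signal factor."""

    utilization: float

    def __post_init__(self):
        _require(0.0 < self.utilization <= 1.0, "utilization",
                 f"must be in (0,1], got {self.utilization}")


@dataclass(frozen=True)
class NoiseLevel:
    """Patient arrival rate (patients/day), the Taguchi noise factor."""

    arrival_rate: float

    def __post_init__(self):
        _require(self.arrival_rate > 0, "arrival_rate",
                 f"must be > 0, got {self.arrival_rate}")


@dataclass(frozen=True)
class StationTime:
    """Normal service-time parameters for one station (minutes).

    ``wait_mean``/``wait_sd`` parameterize the closed-form normal waiting-time
    model used only by the simulator's literal-times mode; in the default
    resource-coupled mode waits emerge from contention and these are unused.
    """

    service_mean: float
    service_sd: float
    wait_mean: float = 0.0
    wait_sd: float = 0.0

    def __post_init__(self):
        _require(self.service_mean > 0, "service_mean",
                 f"must be > 0, got {self.service_mean}")
        _require(self.service_sd >= 0, "service_sd",
                 f"must be >= 0, got {self.service_sd}")
        _require(self.wait_mean >= 0, "wait_mean", "must be >= 0")
        _require(self.wait_sd >= 0, "wait_sd", "must be >= 0")


@dataclass(frozen=True)
class StationTimeParams:
    """Service-time parameters for the four stations in flow order."""

    ward: StationTime
    operating_room: StationTime
    pacu: StationTime
    discharge: StationTime

    def of(self, station: str) -> StationTime:
        return getattr(self, station)

    @property
    def total_service_mean(self) -> float:
        return sum(self.of(s).service_mean for s in STATIONS)

    @property
    def total_service_var(self) -> float:
        return sum(self.of(s).service_sd ** 2 for s in STATIONS)


@dataclass(frozen=True)
class CostRates:
    """Per-minute staff/bed cost rates and the fixed per-patient treating cost.

    Staff rates apply to the patient's OR minutes: regular rates to the
    regular-time portion y_it, overtime rates to the overtime portion x_it.
    """

    holding_nurse_regular: float
    holding_nurse_overtime: float
    anesthetist_regular: float
    anesthetist_overtime: float
    circulating_nurse_regular: float
    circulating_nurse_overtime: float
    bed_per_minute: float
    treatment_fixed: float

    def __post_init__(self):
        pairs = [
            ("holding_nurse", self.holding_nurse_regular, self.holding_nurse_overtime),
            ("anesthetist", self.anesthetist_regular, self.anesthetist_overtime),
            ("circulating_nurse", self.circulating_nurse_regular,
             self.circulating_nurse_overtime),
        ]
        for role, reg, ot in pairs:
            _require(reg >= 0, f"{role}_regular", "must be >= 0")
            _require(ot >= reg, f"{role}_overtime",
                     f"overtime rate ({ot}) must be >= regular rate ({reg})")
        _require(self.bed_per_minute >= 0, "bed_per_minute", "must be >= 0")
        _require(self.treatment_fixed >= 0, "treatment_fixed", "must be >= 0")

    @property
    def regular_sum(self) -> float:
        """nr + ar + cr: combined regular-time staff rate per OR minute."""
        return (self.holding_nurse_regular + self.anesthetist_regular
                + self.circulating_nurse_regular)

    @property
    def overtime_sum(self) -> float:
        """no + ao + co: combined overtime staff rate per OR minute."""
        return (self.holding_nurse_overtime + self.anesthetist_overtime
                + self.circulating_nurse_overtime)


@dataclass(frozen=True)
class CapacityParams:
    """Fixed physical capacities and the daily time structure."""

    n_operating_rooms: int = 10
    pacu_beds: int = 20
    shift_minutes_per_day: float = 480.0
    overtime_cap_minutes: float = 480.0
    horizon_days: int = 7
    arrival_window_minutes: float = 600.0

    def __post_init__(self):
        _require(self.n_operating_rooms >= 1, "n_operating_rooms", "must be >= 1")
        _require(self.pacu_beds >= 1, "pacu_beds", "must be >= 1")
        _require(self.shift_minutes_per_day > 0, "shift_minutes_per_day", "must be > 0")
        _require(self.overtime_cap_minutes >= 0, "overtime_cap_minutes", "must be >= 0")
        _require(self.horizon_days >= 1, "horizon_days", "must be >= 1")
        _require(0 < self.arrival_window_minutes <= DAY_MINUTES,
                 "arrival_window_minutes", f"must be in (0, {DAY_MINUTES}]")

    def regular_minutes(self, utilization: float) -> float:
        """Daily regular OR-minute budget R_t = u * n_OR * shift minutes."""
        return utilization * self.n_operating_rooms * self.shift_minutes_per_day


@dataclass(frozen=True)
class Regime:
    """A (signal, noise) operating condition applied to a set of weekdays."""

    name: str
    signal: SignalLevel
    noise: NoiseLevel
    days: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "days", tuple(int(d) for d in self.days))
        _require(len(self.days) >= 1, f"regime {self.name}", "needs at least one day")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one ORMS study.

    ``regimes`` assign a (utilization, arrival-rate) pair to each day of the
    7-day week — the paper-style mixed week (Mon-Thu high demand at 85%
    utilization, Fri-Sun low demand at 75%).  The DOE overrides this with a
    single uniform (signal, noise) pair per outer-array cell.
    """

    factor_levels: FactorLevels
    regimes: tuple[Regime, ...]
    station_times: StationTimeParams
    cost_rates: CostRates
    capacity: CapacityParams
    replicates: int = 1000
    seed: int = 0
    service_floor_minutes: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "regimes", tuple(self.regimes))
        _require(self.replicates >= 1, "replicates", "must be >= 1")
        _require(self.service_floor_minutes >= 0, "service_floor_minutes",
                 "must be >= 0")
        all_days = [d for r in self.regimes for d in r.days]
        expected = list(range(1, self.capacity.horizon_days + 1))
        _require(sorted(all_days) == expected, "regimes",
                 f"days {sorted(all_days)} must cover 1..{self.capacity.horizon_days} "
                 "exactly once")

    def regime_for_day(self, day: int) -> Regime:
        for r in self.regimes:
            if day in r.days:
                return r
        raise ConfigError("regimes", f"no regime covers day {day}")

    @property
    def signal_levels(self) -> list[SignalLevel]:
        """Distinct signal levels in regime order."""
        seen: list[SignalLevel] = []
        for r in self.regimes:
            if r.signal not in seen:
                seen.append(r.signal)
        return seen

    @property
    def noise_levels(self) -> list[NoiseLevel]:
        """Distinct noise levels in regime order."""
        seen: list[NoiseLevel] = []
        for r in self.regimes:
            if r.noise not in seen:
                seen.append(r.noise)
        return seen

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            return obj

        d = {
            "factor_levels": {n: list(self.factor_levels.levels_of(n))
                              for n in FACTOR_NAMES},
            "regimes": [
                {"name": r.name, "utilization": r.signal.utilization,
                 "arrival_rate": r.noise.arrival_rate, "days": list(r.days)}
                for r in self.regimes
            ],
            "station_times": {s: plain(self.station_times.of(s)) for s in STATIONS},
            "cost_rates": plain(self.cost_rates),
            "capacity": plain(self.capacity),
            "replicates": self.replicates,
            "seed": self.seed,
            "service_floor_minutes": self.service_floor_minutes,
        }
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ScenarioConfig":
        def need(mapping, key, where):
            if not isinstance(mapping, Mapping):
                raise ConfigError(where, "must be a mapping")
            if key not in mapping:
                raise ConfigError(f"{where}.{key}" if where else key,
                                  "missing required field")
            return mapping[key]

        try:
            fl_raw = need(data, "factor_levels", "")
            fl = FactorLevels(**{n: tuple(need(fl_raw, n, "factor_levels"))
                                 for n in FACTOR_NAMES})
            regimes = []
            for r in need(data, "regimes", ""):
                regimes.append(Regime(
                    name=str(need(r, "name", "regimes")),
                    signal=SignalLevel(float(need(r, "utilization", "regimes"))),
                    noise=NoiseLevel(float(need(r, "arrival_rate", "regimes"))),
                    days=tuple(need(r, "days", "regimes")),
                ))
            st_raw = need(data, "station_times", "")
            st = StationTimeParams(**{
                s: StationTime(**{k: float(v)
                                  for k, v in need(st_raw, s, "station_times").items()})
                for s in STATIONS})
            cr = CostRates(**{k: float(v)
                              for k, v in need(data, "cost_rates", "").items()})
            cap_raw = dict(need(data, "capacity", ""))
            for int_key in ("n_operating_rooms", "pacu_beds", "horizon_days"):
                if int_key in cap_raw:
                    cap_raw[int_key] = int(cap_raw[int_key])
            cap = CapacityParams(**cap_raw)
            return cls(
                factor_levels=fl,
                regimes=tuple(regimes),
                station_times=st,
                cost_rates=cr,
                capacity=cap,
                replicates=int(data.get("replicates", 1000)),
                seed=int(data.get("seed", 0)),
                service_floor_minutes=float(data.get("service_floor_minutes", 1.0)),
            )
        except ConfigError:
            raise
        except TypeError as exc:
            raise ConfigError("config", f"schema mismatch: {exc}") from exc
        except (ValueError, KeyError) as exc:
            raise ConfigError("config", f"invalid value: {exc}") from exc


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario from a YAML (canonical) or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(str(path), "config file does not exist")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigError(str(path), "config file must contain a mapping at top level")
    return ScenarioConfig.from_dict(data)


def write_config(config: ScenarioConfig, path: str | Path) -> Path:
    """Write a scenario to YAML or JSON; round-trips through load_config."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def default_fixture_scenario(seed: int = 0, replicates: int = 1000) -> ScenarioConfig:
    """The packaged fixture scenario.

    Factor levels, signal levels (85%/75% utilization) and noise levels
    (80/30 patients/day) follow the published study design.  Service-time and
    cost parameters are NON-PAPER stand-ins (the source hospital's values are
    unpublished), chosen as a plausible high-throughput internal-medicine OR
    suite and documented in docs/methods.md.  Deterministic for a given seed.
    """
    return ScenarioConfig(
        factor_levels=FactorLevels(
            holding_nurses=(10, 15, 20),
            circulating_nurses=(15, 25, 35),
            anesthetists=(15, 20, 25),
            preoperative_beds=(5, 10, 15),
        ),
        regimes=(
            Regime("weekday", SignalLevel(0.85), NoiseLevel(80.0), days=(1, 2, 3, 4)),
            Regime("weekend", SignalLevel(0.75), NoiseLevel(30.0), days=(5, 6, 7)),
        ),
        station_times=StationTimeParams(
            ward=StationTime(service_mean=60.0, service_sd=20.0,
                             wait_mean=20.0, wait_sd=8.0),
            operating_room=StationTime(service_mean=52.0, service_sd=15.0,
                                       wait_mean=15.0, wait_sd=6.0),
            pacu=StationTime(service_mean=40.0, service_sd=12.0,
                             wait_mean=10.0, wait_sd=4.0),
            discharge=StationTime(service_mean=20.0, service_sd=5.0,
                                  wait_mean=5.0, wait_sd=2.0),
        ),
        cost_rates=CostRates(
            holding_nurse_regular=2.0, holding_nurse_overtime=9.0,
            anesthetist_regular=4.0, anesthetist_overtime=18.0,
            circulating_nurse_regular=2.0, circulating_nurse_overtime=9.0,
            bed_per_minute=2.0, treatment_fixed=500.0,
        ),
        capacity=CapacityParams(
            n_operating_rooms=8,
            pacu_beds=20,
            shift_minutes_per_day=600.0,
            overtime_cap_minutes=480.0,
            horizon_days=7,
            arrival_window_minutes=600.0,
        ),
        replicates=replicates,
        seed=int(seed),
    )
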