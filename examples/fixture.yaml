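# Packaged fixture scenario for the ORMS design pipeline.
#
# NON-PAPER VALUES: factor levels, utilization signal levels (0.85/0.75) and
# arrival-rate noise levels (80/30 patients/day) follow the published study
# design; every other number (station service times, cost rates, capacities,
# admission window) is a stand-in chosen for a plausible high-throughput
# internal-medicine OR suite, because the source hospital's parameters are
# unpublished.  See docs/methods.md.
#
# Units: minutes for times, currency-units/minute for rates, patients/day
# for arrival rates.
capacity:
  arrival_window_minutes: 600.0
  horizon_days: 7
  n_operating_rooms: 8
  overtime_cap_minutes: 480.0
  pacu_beds: 20
  shift_minutes_per_day: 600.0
cost_rates:
  anesthetist_overtime: 18.0
  anesthetist_regular: 4.0
  bed_per_minute: 2.0
  circulating_nurse_overtime: 9.0
  circulating_nurse_regular: 2.0
  holding_nurse_overtime: 9.0
  holding_nurse_regular: 2.0
  treatment_fixed: 500.0
factor_levels:
  anesthetists:
  - 15
  - 20
  - 25
  circulating_nurses:
  - 15
  - 25
  - 35
  holding_nurses:
  - 10
  - 15
  - 20
  preoperative_beds:
  - 5
  - 10
  - 15
regimes:
- arrival_rate: 80.0
  days:
  - 1
  - 2
  - 3
  - 4
  name: weekday
  utilization: 0.85
- arrival_rate: 30.0
  days:
  - 5
  - 6
  - 7
  name: weekend
  utilization: 0.75
replicates: 1000
seed: 0
service_floor_minutes: 1.0
station_times:
  discharge:
    service_mean: 20.0
    service_sd: 5.0
    wait_mean: 5.0
    wait_sd: 2.0
  operating_room:
    service_mean: 52.0
    service_sd: 15.0
    wait_mean: 15.0
    wait_sd: 6.0
  pacu:
    service_mean: 40.0
    service_sd: 12.0
    wait_mean: 10.0
    wait_sd: 4.0
  ward:
    service_mean: 60.0
    service_sd: 20.0
    wait_mean: 20.0
    wait_sd: 8.0
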