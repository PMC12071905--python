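# Methods

## The model

`ormsim` treats one week of an elective operating-room service as a
capacity-constrained queueing network with four stations in series:

1. **ward / preoperative holding** — admission requires a free preoperative
   bed *and* a free holding nurse simultaneously (FIFO); the nurse is
   released after the preparation service, the bed is kept until OR entry;
2. **operating room** — start requires a free OR, one anesthetist and one
   circulating nurse concurrently, plus available OR minutes for the day;
3. **PACU** — a recovery bed;
4. **return / discharge** — a pure service delay, no contended resource.

Arrivals are Poisson: uniform draws θ are inverted through the exponential
CDF (gap = −ln(1−θ)/rate) and accumulated across the admission window, so
daily counts are Poisson with mean λ. Service times are normal, truncated
below at a 1-minute floor. Waiting times are *not* drawn from a
distribution: they emerge from resource contention in a discrete-event pass
(heapq event loop; ties broken by insertion order, which follows event time
then patient id). In the uncongested limit every wait is zero and the total
system time reduces to the closed-form sum-of-normals service model; a
`literal_times` mode draws the total wait directly from that closed form
(sum of per-station wait means/variances) for testing the response
definitions in isolation.

**OR-minute metering.** Day *t* offers a regular budget
`R_t = u(t) · n_OR · M` (utilization × OR count × staffed shift minutes)
and an overtime cap `O_t`. A patient's OR service consumes regular minutes
first (`y`), then overtime (`x`); a single case may straddle both, and its
regular flag `Y` is 1 only when `x = 0`. When a day's `R_t + O_t` is
exhausted the patient defers to the next day; patients left beyond the
7-day horizon are dropped from the completed count `N` (and logged). The
per-day ledgers (`Σy ≤ R_t`, `Σx ≤ O_t`) are asserted on every outcome.

**Responses.** Per replicate week,

- `TC = [Σ(no+ao+co)(X−Y)x + Σ(nr+ar+cr)·y·X + Σ b·B·X + Σ c·X] / N`,
  where `B` is preoperative-bed minutes (bed assignment → OR entry) and `c`
  the fixed treating cost;
- `ST = (ΣW + ΣS)/N`, total waiting plus service minutes per patient.

The regular-time cost term uses the regular *minutes* `y` (the symbol list
defines `y` as regular treating minutes; pairing the regular rate with the
overtime minutes would make the term vanish exactly when it should apply).

## Study design

The inner array is the standard L9(3⁴) in canonical row order, mapped to the
configured integer levels; balance and pairwise orthogonality are asserted
at construction, not assumed. Each of the 9 runs is crossed with the 2×2
outer array (utilization 0.85/0.75 × arrival rate 80/30) and replicated
(default 1000, configurable). Within a DOE cell the outer condition is held
uniform across the simulated week — otherwise the outer factors would be
confounded with day-of-week; the mixed weekday/weekend regime remains the
default for single `simulate` runs. Every cell replicate draws from its own
`SeedSequence(seed, spawn_key=(setting, signal, noise, replicate))` stream,
so any cell is independently reproducible and capacity comparisons with the
same seed are true common-random-number pairs (arrivals and all service
draws are sampled before the event pass, in patient order, independent of
contention).

## Desirability

TC and ST are smaller-the-better; both are mapped linearly onto [0,1]
against bounds taken as the global observed min/max of the full results
table (global, not per-cell, so d is comparable across settings and outer
conditions), and combined multiplicatively, `d = d1·d2`. Scoring is
per-replicate row; the per-setting robust response is the mean of
per-replicate d. No Derringer–Suich shape or weight exponents.

## Surrogate network

4 inputs (factor values min-max scaled to [0,1] per factor), one logistic
hidden layer (width 1–6), logistic output. Full-batch gradient descent on
mean squared error with momentum 0.75, 10,000 epochs, weights initialized
uniform(−0.5, 0.5) from the seed. The learning rate self-adjusts within
[0.01, 0.25] by a bold-driver rule: ×1.05 after an epoch that lowers the
loss, ×0.7 (with the momentum velocity cancelled) after one that raises it.
The adaptation scheme, activation and initialization are this package's own
choices — chosen for determinism and stability — since only the rate range,
momentum and iteration count are externally specified. Hidden width is
selected by test RMSE on a single stratified 80/20 split (every setting
appears in both partitions). Training rows are per-replicate, not 9
aggregated points: 9 points cannot support a train/test RMSE report, and
the replicate spread across outer cells is exactly the noise the fitted
response should average over. Signal and noise levels are not network
inputs.

Because the inputs take only 9 distinct values, the training loss equals a
weighted fit of the 9 per-setting means plus an irreducible constant (the
within-setting variance, dominated by the spread between outer cells,
roughly 0.2 sd on the fixture). Factor effects smaller than that spread are
therefore recovered slowly: within the 10,000-epoch budget the fitted
surface tends toward a smooth monotone compromise. With a much longer
budget (~200k epochs) the same family does carve the fixture's interior
peak in factor D; at the default budget the GA optimum typically lands on a
box boundary, which the sensitivity module handles one-sidedly. This is an
optimization-budget effect, not a representational limit, and is the main
caveat when reading the fitted optimum.

## Genetic algorithm

Chromosome = 4 integers in [level1, level3] per factor. Size-2 tournament
selection, uniform crossover on 85% of parent pairs, per-gene random-reset
mutation at 8%, 150 individuals, 1000 generations, elitism 2 (configurable;
0 gives the literal operator set, elitism makes the best-so-far history
provably non-decreasing). Selection and crossover operators are this
package's choices for integer boxes. `brute_force_optimum` enumerates boxes
up to 10⁶ points (the default box has 11·21·11·11 = 27,951) with exact
lexicographic tie-breaking, and the pipeline verifies the GA against it
whenever the box is enumerable.

## Sensitivity

For each factor, the others held at their optimal values, every integer
between the nearest configured level below the optimum and the nearest
level above is evaluated; one-sided when the optimum equals a boundary
level. `adjusted d% = 100·(d_level − d*)/d*`, exactly 0 at the optimum and
non-positive everywhere once the optimum is the verified box maximum. A
`steps` override sweeps a fixed-width window instead (the level-anchored
rule is the default because level spacings differ between factors).
Impact power = max |adjusted d%| per factor, reported per-run and never
asserted against any external ordering (it is parameter-dependent).

## The fixture scenario (non-paper values)

The source hospital's service-time, cost and capacity parameters are
unpublished, so `examples/fixture.yaml` / `default_fixture_scenario()`
substitutes a plausible high-throughput internal-medicine OR suite. These
values were chosen once, for mechanism rather than realism of any specific
hospital:

| parameter | value | why |
|---|---|---|
| station service times (min) | ward 60±20, OR 52±15, PACU 40±12, discharge 20±5 | short procedures; weekday OR demand (80·52 = 4160 min) sits just above the regular budget so overtime is routinely at stake |
| capacity | 8 ORs, shift 600 min, overtime cap 480 min, 20 PACU beds | `R_t = 0.85·8·600 = 4080` weekday; the OR suite, not the PACU, is the downstream constraint |
| admission window | 600 min/day | elective patients arrive during the working day; daily counts still average λ |
| staff rates (regular/overtime, per min) | nurse 2/9, anesthetist 4/18, circulating 2/9 | steep overtime premium: fast-flowing configurations push more minutes into overtime |
| bed rate, fixed cost | 2/min, 500 | bed-minutes price the preoperative dwell |

Under these defaults the desirability response has an **interior optimum in
factor D** (preoperative beds): the marginal mean d over the L9 peaks at
D = 10 (≈0.76) versus D = 5 (≈0.70, bed shortage starves the ORs) and
D = 15 (≈0.73, faster feed converts regular minutes into premium overtime
in the low-budget/high-demand outer cell). A seeded test asserts this
ordering. Staff factors B and C bind only weakly at these loads (the OR
count caps their useful concurrency), which mirrors how flat their printed
sensitivity ranges are in comparable studies.

What the generator does *not* emulate: surgeon-level scheduling and case
sequencing, emergency preemption, heterogeneous case mix (log-normal
operating times are a known better fit for long cases), calendar effects
beyond the 7-day week, and any per-patient variation in cost rates. Passing
tests therefore demonstrate correctness of the machinery and the stated
qualitative mechanisms, not calibration to any real hospital.

## Numerical choices and problem sizes

- Service floor 1 minute (truncation, applied as a max).
- Event ties resolved by (time, insertion order); insertion order follows
  patient id within a timestamp.
- Desirability bounds require strictly non-constant TC and ST columns.
- Brute-force ties: lexicographically smallest setting.
- Capacity-ledger assertions use a 1e-6 minute tolerance.
- Test and acceptance runs use 15–50 replicates per cell and 1.5k–10k
  training epochs; these sizes were chosen so the full suite exercises
  every stage at comfortable desk scale while the package defaults (1000
  replicates, 10,000 epochs) remain the study-scale configuration.

## Known limitations

- The surrogate's 10,000-epoch budget under-resolves factor effects much
  smaller than the outer-cell spread (see above); rerun with more epochs or
  aggregate targets when curvature matters.
- Weekly leftovers are dropped from N rather than carried to a next week,
  so severely under-capacitated settings are scored slightly optimistically
  on TC while their ST inflates — both effects push d down, which is the
  intended reading.
- `B_it` covers bed assignment to OR entry; alternative readings (whole
  preoperative stay) would raise bed costs uniformly.
- One run's 10,000-entry-scale results table (9×2×2×R rows) is held in
  memory as a DataFrame; R beyond ~10⁴ per cell would want chunked writes.
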