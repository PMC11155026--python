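# icuflow

Discrete-event simulation of intensive-care-unit (ICU) patient flow, built to
quantify the capacity trade-off between a **dedicated** ICU (the ward split
into specialism-specific units with non-shared beds) and a **non-dedicated**
(pooled) ICU (one bed pool admitting any specialism). For a calibrated ward it
reports three performance measures:

- **occupancy rate** — time-weighted % of beds occupied over the evaluation
  window;
- **rejection rate** — rejected unplanned (emergency) patients per 100
  unplanned arrivals; unplanned patients finding no eligible free bed are
  lost;
- **rescheduling rate** — rescheduling events per 100 planned (elective)
  arrivals; a bumped planned patient retries after a delay, so the rate can
  exceed 100%.

The package is aimed at ICU capacity planners and operations researchers who
want to explore bed-partition decisions with their own admission logs.

## Model

Unplanned arrivals form a Poisson process with day-type-specific daily rates
λ<sub>s,d</sub> per specialism *s* and day type *d* ∈ {weekday, weekend}
(an assumption checkable with a χ² goodness-of-fit test on daily counts).
Planned arrivals follow the empirical categorical distribution of daily
counts per (*s*, *d*). Length of stay is a positive parametric distribution
per (specialism × planned/unplanned) stratum, selected by AIC among
exponential, gamma, Weibull and lognormal maximum-likelihood fits. Each
admitted patient holds one bed for their sampled stay; eligibility is the
whole ward (pooled) or the patient's cluster unit (dedicated), with the seven
specialisms mapped onto four unit clusters (CAPU; CARD/INT/OTHER; CHIR;
NEC/NEU). The pooled design benefits from the classic resource-pooling
effect: at offered load *a* = λ·E[LOS] on *c* beds with no rescheduling, the
rejection fraction is the Erlang-B blocking probability *B*(*a*, *c*), and
the engine is verified against that closed form.

Four scenario runners compare the designs: the base case at fixed capacity,
a capacity sweep (with the dedicated partition re-optimised per capacity),
hypothetical mean-LOS reductions in the dedicated design, and surges in
unplanned inflow. A partition optimizer searches all four-way bed splits for
the one minimising overall rejection.

## Worked example

```python
import icuflow as f

log = f.generate_log(f.SyntheticSpec(seed=1))      # two-year synthetic log
arrival = f.fit_arrival_model(log)
los = f.fit_los_model(log)
reports = f.base_case(arrival, los, total_beds=28, seed=3, replications=20)
for design, report in reports.items():
    print(design, {k: round(v, 1) for k, v in report.scopes["overall"].items()})
```

prints

```
non_dedicated {'occupancy_pct': 70.6, 'rejection_pct': 2.8, 'rescheduling_pct': 3.4}
dedicated {'occupancy_pct': 63.1, 'rejection_pct': 15.8, 'rescheduling_pct': 28.0}
```

i.e. on this calibration the pooled ward keeps its 28 beds ~71% occupied and
turns away ~3% of emergencies, while the same ward partitioned 6/11/5/6
across the four clusters idles more beds (63% occupancy) yet rejects ~16% of
emergencies and bumps elective patients far more often — the pooling effect
the simulation is designed to quantify.

The same workflow is available from the shell:

```
icuflow generate --out log.csv --days 730 --seed 1
icuflow fit log.csv --out fit.json
icuflow run base --calibration fit.json --beds 28 --replications 100 --seed 1 --out results/
icuflow check --servers 28 --load 28        # engine vs Erlang-B theory
```

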