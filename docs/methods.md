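# Methods

## Model

The ward is a loss/retry system. Time is continuous, in days. Patients
arrive one by one; each belongs to one of seven admission specialisms
(CAPU, CARD, INT, CHIR, NEC, NEU, OTHER), mapped onto four unit clusters
(CAPU; CARD/INT/OTHER; CHIR; NEC/NEU). In the *non-dedicated* (pooled)
design every patient may use any of the `total_beds` beds; in the
*dedicated* design each cluster owns a fixed number of beds and patients
may only use their cluster's unit.

**Arrivals.** Unplanned (emergency) arrivals are Poisson with a daily rate
per (day type × specialism), day type ∈ {weekday, weekend}. Planned
(elective) daily counts follow the empirical categorical distribution of
the calibration log per (day type × specialism); a scenario's inflow
multiplier scales unplanned rates only. Within a day each arrival is
placed uniformly at random — calibration happens at daily resolution, and
the uniform placement is the maximum-entropy completion consistent with
it. Per-specialism unplanned rates arise by multinomial thinning of the
day-type totals, which preserves the Poisson property tested at the
aggregate level.

**Length of stay (LOS).** One positive parametric distribution per
(specialism × planned/unplanned) stratum. Fitting is by maximum likelihood
with location pinned at zero for each of four candidate families
(exponential, gamma, Weibull, lognormal); the family minimising AIC is
selected, ties broken by fewer parameters, then fixed family order. This
replaces interactive distribution-fitting tools with a reproducible,
standard selection rule. Strata with fewer than 10 admitted stays fall
back to an exponential at the stratum mean (pooled mean when empty).
A global reduction multiplier r ∈ (0, 1] rescales sampled stays, so the
sampled mean is exactly r times the unreduced mean.

**Flow mechanics.** An arriving unplanned patient with no free eligible
bed is rejected and lost — no retry, no overflow to another unit. A
planned patient with no free bed is *rescheduled*: one rescheduling event
is counted and the patient re-enters after `reschedule_delay_days`
(default 1 day), repeatedly and by default without an attempt cap
(configurable), until admitted or the horizon ends. This retry mechanism
is what lets rescheduling rates exceed 100%: one patient can be bumped
many times. Equal-time events process deterministically: departures first
(a freed bed is available to a same-instant arrival), then retries, then
new planned, then new unplanned arrivals; within a class, earlier
scheduling wins.

**Measures.** Over the evaluation window (horizon minus burn-in):
occupancy = ∫occupied dt / (beds × window) × 100; rejection = rejected /
unplanned arrivals × 100; rescheduling = rescheduling events / planned
arrivals × 100. Scopes are "overall" plus the four clusters; in the
pooled design a cluster scope counts that cluster's patients against the
whole pool's capacity — the performance of the patient group a dedicated
unit would serve. Events before burn-in do not contribute; patients
admitted during burn-in keep their beds, which is the intended warm-up
behaviour. Denominators of zero report a rate of 0 with the zero count
visible in the report; a dedicated cluster with zero beds but nonzero
demand is flagged explicitly.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| horizon_days | 3770 | simulated span (≈10.5 y) |
| burn_in_days | 120 | warm-up excluded from metrics |
| total_beds | 28 | ward capacity |
| partition | 6/11/5/6 | beds per cluster (dedicated) |
| reschedule_delay_days | 1.0 | retry delay for bumped electives |
| los_reduction | 1.0 | multiplier on sampled stays |
| inflow_multiplier | 1.0 | scales unplanned rates |
| replications | 100 | independent replications per arm |

Standard errors come from independent replications (mean ± sd/√n), not
batch means — simpler and valid for these run lengths. Replication seeds
are spawned from one master seed via `numpy.random.SeedSequence`, making
every runner bit-reproducible.

**Common random numbers (CRN).** A replication's patient stream (arrival
times, types, specialisms and *unreduced* stays) is generated once and
reused across every compared configuration — both designs, all
capacities, all LOS reductions. LOS reduction and bed configuration apply
at simulation time, so paired contrasts (pooled vs dedicated, capacity
steps) share identical demand and their differences carry far less Monte
Carlo noise. Surge levels change the generating rates and therefore get
their own streams.

## Partition optimizer

The search space of 4-way splits of c beds (min 1 per unit by default) is
enumerated exactly. Because simulating thousands of splits at useful
replication counts is wasteful, candidates are first ranked by a
closed-form proxy — the unplanned-rate-weighted Erlang-B blocking of the
cluster units at their offered loads — and a shortlist (default 40, the
uniform and proportional-to-load heuristics always added) is simulated
with CRN at a reduced replication count; the top 5 are re-simulated at
full replications and the minimiser of overall rejection returned, ties
broken lexicographically in cluster order. The proxy ignores rescheduling
feedback, so it only ranks; simulation decides. The objective is overall
rejection only — rescheduling and occupancy are reported, not optimised,
which is why optimised partitions can carry high rescheduling rates.

## Synthetic-data generator

`SyntheticSpec` emulates a two-year admission log of a large mixed
academic ICU: 5.55 arrivals/day on average, 66% unplanned, 82% of
admissions on weekdays, 9% of unplanned arrivals rejected, over 730 days.
Weekday/weekend rates are solved from the daily mean and weekday share
using the actual calendar of the span, so fitting a generated log
recovers the generating rates. Planned and unplanned streams share the
specialism mix; daily planned counts are Poisson in the generator (their
*fitted* representation is the empirical categorical pmf, per the
calibration design). Stays are lognormal (σ = 0.9) with cluster means
3.0/4.0/3.5/5.5 days and planned stays 0.75× their cluster mean — chosen
once so that a 28-bed pooled ward runs at roughly 70–80% occupancy, the
congested regime where design choices matter. These are fixtures with the
right summary statistics and regime, not claims about any hospital; in
particular the generator has no seasonality, no within-day arrival
pattern, no LOS/occupancy dependence and independent strata, so passing
tests demonstrate correct mechanics and calibrated-regime behaviour, not
fidelity to any specific ward's microstructure.

## Verification and numerical choices

- **Erlang-B equivalence.** With one unplanned stream, exponential
  stays and no planned patients, the pooled design is M/M/c/c; simulated
  blocking is checked against the stable recursion B(k) = aB(k−1)/(k +
  aB(k−1)) for c ∈ {1, 4, 28} at loads 0.5c, c, 1.5c, within 3 Monte
  Carlo SEs. Little's law (mean occupied beds = admitted rate × mean
  stay) is checked the same way.
- **χ² goodness of fit.** Daily counts vs Poisson(sample mean); adjacent
  bins pooled inward from both tails until every expected count ≥ 5
  (the textbook validity rule); df = bins − 2; fewer than 3 pooled bins
  is an error, not a silent answer.
- **Statistical test design.** Stochastic assertions use 3-SE bands with
  fixed seeds. The parameter-recovery check tests several quantities at
  once and therefore uses Bonferroni-adjusted simultaneous 95% intervals
  rather than per-quantity 95% intervals, keeping the intended joint
  coverage.
- **Degenerate inputs.** Empty arrival strata fit rate 0 / a pmf
  degenerate at 0 with a warning; zero-bed eligible pools reject all
  unplanned and endlessly reschedule planned demand, flagged in the
  report; invalid configurations fail before any event is processed.

## Problem sizes

Default runs use the full 3,770-day horizon. The test suite and the
acceptance script scale Monte Carlo effort to the precision each check
needs: verification grids run 25 replications at 700–1,200 days;
scenario-ordering checks run 8–12 replications at 500–1,500 days with
CRN (which makes the orderings sharp at small n); headline scenario
numbers use 40 replications at the full horizon. Parameter-recovery
checks use 10,000-day logs. All sizes are stated in the relevant
docstrings and are ordinary accuracy/effort trade-offs.

## Limitations

No seasonality or secular trends in arrivals; no staffing constraints,
bed closures or transfers; LOS is time- and state-independent and
identical across designs unless a reduction is imposed; rejected patients
vanish rather than overflow; the reschedule delay is a fixed constant.
The optimizer is single-objective (rejection) and static in time.
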