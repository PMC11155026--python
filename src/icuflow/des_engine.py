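"""Discrete-event simulation of ICU bed occupancy.

Patients arrive according to the fitted arrival model, request a bed in
their eligible pool — the whole ward in the non-dedicated (pooled) design,
their specialism cluster's unit in the dedicated design — and hold it for
their sampled length of stay. An unplanned patient finding no free bed is
rejected and lost; a planned patient finding no free bed is rescheduled
(one rescheduling event counted) and retries after a fixed delay,
repeatedly, until admitted or the horizon ends. Metrics accumulate only
after the burn-in period.

Event ordering at equal times is deterministic: departures first (a bed
frees up before same-time arrivals), then reschedule retries, then new
planned arrivals, then new unplanned arrivals; within a class, earlier
scheduling wins.

Performance is summarised per scope (overall plus each unit cluster) as:
the time-weighted percentage of beds occupied; rejected unplanned
patients per hundred unplanned arrivals; and rescheduling events per
hundred planned arrivals (which can exceed 100 when patients are bumped
more than once).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .stochastic_inputs import ArrivalModel, LOSFit, LOSModel
from .units import CLUSTERS, DAY_TYPES, DEFAULT_PARTITION, PATIENT_TYPES, SPECIALISMS, cluster_of

DESIGNS = ("non_dedicated", "dedicated")
METRICS = ("occupancy_pct", "rejection_pct", "rescheduling_pct")
SCOPES = ("overall",) + CLUSTERS

# event priorities at equal times
_DEP, _RETRY, _ARR_PLANNED, _ARR_UNPLANNED = 0, 1, 2, 3

EVENT_COLUMNS = ["time", "event", "patient_id", "type", "specialism", "cluster", "outcome"]


@dataclass
class ScenarioConfig:
    """Configuration of one simulated scenario arm."""

    design: str = "non_dedicated"
    total_beds: int = 28
    partition: dict[str, int] | None = None
    los_reduction: float = 1.0
    inflow_multiplier: float = 1.0
    horizon_days: float = 3770.0
    burn_in_days: float = 120.0
    reschedule_delay_days: float = 1.0
    max_reschedules: int | None = None
    seed: int = 0
    replications: int = 100
    start_weekday: int = 0  # 0 = Monday; fixes the weekday/weekend pattern

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if self.total_beds < 0:
            raise ValueError("total_beds must be non-negative")
        if not 0 < self.los_reduction <= 1:
            raise ValueError("los_reduction must be in (0, 1]")
        if self.inflow_multiplier < 0:
            raise ValueError("inflow_multiplier must be non-negative")
        if not 0 <= self.burn_in_days < self.horizon_days:
            raise ValueError("need 0 <= burn_in_days < horizon_days")
        if self.reschedule_delay_days <= 0:
            raise ValueError("reschedule_delay_days must be positive")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.design == "dedicated":
            if self.partition is None:
                raise ValueError("dedicated design requires a partition")
            if set(self.partition) != set(CLUSTERS):
                raise ValueError(f"partition must cover clusters {CLUSTERS}")
            if any(b < 0 for b in self.partition.values()):
                raise ValueError("partition entries must be non-negative")
            if sum(self.partition.values()) != self.total_beds:
                raise ValueError("partition must sum to total_beds")

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


def dedicated_config(partition: dict[str, int] | None = None, **kwargs) -> ScenarioConfig:
    """Convenience constructor for a dedicated-design configuration."""
    partition = dict(partition or DEFAULT_PARTITION)
    kwargs.setdefault("total_beds", sum(partition.values()))
    return ScenarioConfig(design="dedicated", partition=partition, **kwargs)


# ---------------------------------------------------------------------------
# Patient streams


@dataclass
class PatientStream:
    """One replication's arrivals, sorted by time.

    ``base_los`` is the unreduced sampled stay; design-specific LOS
    reduction is applied at simulation time so paired designs can share
    one stream (common random numbers).
    """

    time: np.ndarray  # days since simulation start
    planned: np.ndarray  # bool
    spec_idx: np.ndarray  # index into SPECIALISMS
    cluster_idx: np.ndarray  # index into CLUSTERS
    base_los: np.ndarray  # days

    def __len__(self) -> int:
        return self.time.size


def generate_patients(
    arrival_model: ArrivalModel,
    los_model: LOSModel,
    horizon_days: float,
    inflow_multiplier: float,
    rng: np.random.Generator,
    start_weekday: int = 0,
) -> PatientStream:
    """Sample one replication's patient stream from the fitted models.

    Daily counts follow the arrival model (unplanned rates scaled by the
    inflow multiplier, planned pmfs untouched); each arrival lands
    uniformly within its day; stays are sampled per stratum from the LOS
    model (unreduced by any scenario reduction).
    """
    if inflow_multiplier < 0:
        raise ValueError("inflow_multiplier must be non-negative")
    n_days = int(np.ceil(horizon_days))
    day_idx = np.arange(n_days)
    is_weekday = (start_weekday + day_idx) % 7 < 5
    day_types = np.where(is_weekday, "weekday", "weekend")

    times, planned, spec_idx, los = [], [], [], []
    cluster_lookup = np.array([CLUSTERS.index(cluster_of(s)) for s in SPECIALISMS])
    for si, s in enumerate(SPECIALISMS):
        counts_u = np.zeros(n_days, dtype=int)
        counts_p = np.zeros(n_days, dtype=int)
        for dt in ("weekday", "weekend"):
            mask = day_types == dt
            n_dt = int(mask.sum())
            if n_dt == 0:
                continue
            rate = arrival_model.unplanned_rate[dt][s] * inflow_multiplier
            counts_u[mask] = rng.poisson(rate, n_dt) if rate > 0 else 0
            pmf = np.asarray(arrival_model.planned_pmf[dt][s], float)
            counts_p[mask] = rng.choice(pmf.size, size=n_dt, p=pmf) if pmf.size > 1 else 0
        for is_planned, counts in ((False, counts_u), (True, counts_p)):
            n = int(counts.sum())
            if n == 0:
                continue
            t = np.repeat(day_idx, counts) + rng.random(n)
            ptype = "planned" if is_planned else "unplanned"
            stay = los_model.sample(s, ptype, n, rng)
            times.append(t)
            planned.append(np.full(n, is_planned))
            spec_idx.append(np.full(n, si))
            los.append(stay)

    if not times:
        empty = np.empty(0)
        return PatientStream(empty, empty.astype(bool), empty.astype(int), empty.astype(int), empty)
    time_all = np.concatenate(times)
    order = np.argsort(time_all, kind="stable")
    spec_all = np.concatenate(spec_idx)[order]
    return PatientStream(
        time=time_all[order],
        planned=np.concatenate(planned)[order],
        spec_idx=spec_all,
        cluster_idx=cluster_lookup[spec_all],
        base_los=np.concatenate(los)[order],
    )


def generate_streams(
    arrival_model: ArrivalModel,
    los_model: LOSModel,
    horizon_days: float,
    inflow_multiplier: float,
    seed: int,
    replications: int,
    start_weekday: int = 0,
) -> list[PatientStream]:
    """Independent patient streams for each replication (for CRN reuse)."""
    seeds = np.random.SeedSequence(seed).spawn(replications)
    return [
        generate_patients(
            arrival_model,
            los_model,
            horizon_days,
            inflow_multiplier,
            np.random.default_rng(s),
            start_weekday,
        )
        for s in seeds
    ]


# ---------------------------------------------------------------------------
# Event loop


def simulate_stream(stream: PatientStream, config: ScenarioConfig):
    """Run the event loop for one patient stream under one configuration.

    Returns ``(event_log, occupancy_trace)``; the log is a list of
    ``(time, event, patient_id, type, specialism, cluster, outcome)``
    tuples and the trace an array with columns
    ``time, occupied_total, occupied_<cluster>...`` recorded at every
    occupancy change.
    """
    config.validate()
    horizon = config.horizon_days
    pooled = config.design == "non_dedicated"
    if pooled:
        free = [config.total_beds]
        pool_of = [0] * len(CLUSTERS)
    else:
        free = [config.partition[c] for c in CLUSTERS]
        pool_of = list(range(len(CLUSTERS)))

    los = stream.base_los * config.los_reduction
    time_arr = stream.time
    planned_arr = stream.planned
    clus_arr = stream.cluster_idx
    spec_arr = stream.spec_idx

    heap: list[tuple[float, int, int, int]] = []
    for i in range(len(stream)):
        if time_arr[i] <= horizon:
            prio = _ARR_PLANNED if planned_arr[i] else _ARR_UNPLANNED
            heap.append((time_arr[i], prio, i, i))
    heapq.heapify(heap)
    seq = len(stream)

    occ = [0] * len(CLUSTERS)
    occ_total = 0
    trace_rows = [(0.0, 0, 0, 0, 0, 0)]
    log: list[tuple] = []
    attempts: dict[int, int] = {}
    max_resched = config.max_reschedules

    push = heapq.heappush
    pop = heapq.heappop
    while heap:
        t, prio, _, i = pop(heap)
        if t > horizon:
            break
        ci = clus_arr[i]
        cluster = CLUSTERS[ci]
        spec = SPECIALISMS[spec_arr[i]]
        ptype = "planned" if planned_arr[i] else "unplanned"
        if prio == _DEP:
            free[pool_of[ci]] += 1
            occ[ci] -= 1
            occ_total -= 1
            trace_rows.append((t, occ_total, *occ))
            log.append((t, "departure", i, ptype, spec, cluster, "departed"))
            continue
        kind = "retry" if prio == _RETRY else "arrival"
        if free[pool_of[ci]] > 0:
            free[pool_of[ci]] -= 1
            occ[ci] += 1
            occ_total += 1
            trace_rows.append((t, occ_total, *occ))
            log.append((t, kind, i, ptype, spec, cluster, "admitted"))
            seq += 1
            push(heap, (t + los[i], _DEP, seq, i))
        elif not planned_arr[i]:
            log.append((t, kind, i, ptype, spec, cluster, "rejected"))
        else:
            log.append((t, kind, i, ptype, spec, cluster, "rescheduled"))
            n_prev = attempts.get(i, 0) + 1
            attempts[i] = n_prev
            retry_at = t + config.reschedule_delay_days
            if retry_at <= horizon and (max_resched is None or n_prev < max_resched):
                seq += 1
                push(heap, (retry_at, _RETRY, seq, i))

    trace = np.asarray(trace_rows, dtype=float)
    return log, trace


def event_log_frame(log: Sequence[tuple]) -> pd.DataFrame:
    """Event log as a DataFrame in the exportable CSV schema."""
    return pd.DataFrame(log, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class PerformanceReport:
    """Occupancy, rejection and rescheduling rates per scope.

    ``scopes`` maps scope (``overall`` or a cluster) to metric means;
    ``ses`` holds matching Monte-Carlo standard errors across replications
    (None for a single replication); ``counts`` holds mean event counts.
    """

    scopes: dict[str, dict[str, float]]
    ses: dict[str, dict[str, float]] | None
    counts: dict[str, dict[str, float]]
    replications: int = 1
    config: ScenarioConfig | None = None
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scope, metrics in self.scopes.items():
            for metric, mean in metrics.items():
                se = self.ses[scope][metric] if self.ses is not None else np.nan
                rows.append({"scope": scope, "metric": metric, "mean": mean, "se": se})
        return pd.DataFrame(rows)

    def overall(self, metric: str) -> float:
        return self.scopes["overall"][metric]


def compute_metrics(event_log, occupancy_trace, config: ScenarioConfig) -> PerformanceReport:
    """Performance measures over the post-burn-in evaluation window.

    Occupancy is the time-weighted integral of occupied beds divided by
    capacity and window length. In the pooled design a cluster scope
    reports that cluster's patients against the whole pool's capacity —
    the performance of the patient group that a dedicated unit would
    serve. Rates use only events inside the window.
    """
    b, horizon = config.burn_in_days, config.horizon_days
    window = horizon - b
    if window <= 0:
        raise ValueError("empty evaluation window")
    trace = np.asarray(occupancy_trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 2 + len(CLUSTERS):
        raise ValueError("trace must have columns time, total, one per cluster")

    edges = np.append(trace[:, 0], horizon)
    seg = np.clip(edges[1:], b, horizon) - np.clip(edges[:-1], b, horizon)
    integrals = seg @ trace[:, 1:]  # bed-days: total then per cluster

    zero = {"arrivals": 0, "unplanned_arrivals": 0, "planned_arrivals": 0,
            "admissions": 0, "rejections": 0, "reschedules": 0}
    counts = {scope: dict(zero) for scope in SCOPES}
    for t, kind, _pid, ptype, _spec, cluster, outcome in event_log:
        if not (b < t <= horizon) or kind == "departure":
            continue
        for scope in ("overall", cluster):
            c = counts[scope]
            if kind == "arrival":
                c["arrivals"] += 1
                c["unplanned_arrivals" if ptype == "unplanned" else "planned_arrivals"] += 1
            if outcome == "admitted":
                c["admissions"] += 1
            elif outcome == "rejected":
                c["rejections"] += 1
            elif outcome == "rescheduled":
                c["reschedules"] += 1

    if config.design == "dedicated":
        denom_beds = {c: config.partition[c] for c in CLUSTERS}
    else:
        denom_beds = {c: config.total_beds for c in CLUSTERS}
    denom_beds["overall"] = config.total_beds

    scopes: dict[str, dict[str, float]] = {}
    flags = []
    for k, scope in enumerate(SCOPES):
        beds = denom_beds[scope]
        c = counts[scope]
        occupancy = 100.0 * integrals[k] / (beds * window) if beds > 0 else 0.0
        rejection = (
            100.0 * c["rejections"] / c["unplanned_arrivals"] if c["unplanned_arrivals"] else 0.0
        )
        resched = 100.0 * c["reschedules"] / c["planned_arrivals"] if c["planned_arrivals"] else 0.0
        scopes[scope] = {
            "occupancy_pct": occupancy,
            "rejection_pct": rejection,
            "rescheduling_pct": resched,
        }
        if scope != "overall" and beds == 0 and c["arrivals"] > 0:
            flags.append(f"cluster {scope} has zero beds but receives arrivals")
    return PerformanceReport(
        scopes=scopes,
        ses=None,
        counts={s: {k: float(v) for k, v in c.items()} for s, c in counts.items()},
        replications=1,
        config=config,
        flags=flags,
    )


def run_replication(
    config: ScenarioConfig,
    arrival_model: ArrivalModel,
    los_model: LOSModel,
    rng: np.random.Generator,
):
    """Generate one patient stream, simulate it and compute its metrics.

    Returns ``(report, event_log, occupancy_trace)``.
    """
    stream = generate_patients(
        arrival_model,
        los_model,
        config.horizon_days,
        config.inflow_multiplier,
        rng,
        config.start_weekday,
    )
    log, trace = simulate_stream(stream, config)
    return compute_metrics(log, trace, config), log, trace


def run_on_streams(config: ScenarioConfig, streams: Sequence[PatientStream]) -> PerformanceReport:
    """Simulate pre-generated streams under one configuration and aggregate.

    Sharing the same streams across configurations implements common
    random numbers for paired comparisons.
    """
    reports = []
    for stream in streams:
        log, trace = simulate_stream(stream, config)
        reports.append(compute_metrics(log, trace, config))
    return aggregate_reports(reports, config)


def run_scenario(
    config: ScenarioConfig, arrival_model: ArrivalModel, los_model: LOSModel
) -> PerformanceReport:
    """Run ``config.replications`` independent replications and aggregate.

    Replication seeds are spawned deterministically from ``config.seed``.
    With a single replication, means are reported and standard errors are
    unavailable (None).
    """
    streams = generate_streams(
        arrival_model,
        los_model,
        config.horizon_days,
        config.inflow_multiplier,
        config.seed,
        config.replications,
        config.start_weekday,
    )
    return run_on_streams(config, streams)


def mmcc_inputs(
    offered_load: float, mean_los: float = 1.0, specialism: str = "OTHER"
) -> tuple[ArrivalModel, LOSModel]:
    """Arrival/LOS models describing an M/M/c/c verification case.

    A single unplanned Poisson stream at rate ``offered_load / mean_los``
    per day (identical on weekdays and weekends), exponential stays with
    the given mean, and no planned patients. Running the pooled design on
    these inputs is an Erlang loss system whose blocking probability has
    the closed form :func:`icuflow.queueing.erlang_b`.
    """
    if offered_load < 0 or mean_los <= 0:
        raise ValueError("offered_load must be >= 0 and mean_los > 0")
    rate = offered_load / mean_los
    arrival = ArrivalModel(
        unplanned_rate={
            dt: {s: (rate if s == specialism else 0.0) for s in SPECIALISMS}
            for dt in DAY_TYPES
        },
        planned_pmf={dt: {s: [1.0] for s in SPECIALISMS} for dt in DAY_TYPES},
    )
    fits = {
        (s, t): LOSFit(family="exponential", params=(0.0, mean_los), n=0)
        for s in SPECIALISMS
        for t in PATIENT_TYPES
    }
    return arrival, LOSModel(fits=fits)


def aggregate_reports(
    reports: Sequence[PerformanceReport], config: ScenarioConfig | None = None
) -> PerformanceReport:
    """Combine per-replication reports into means and standard errors."""
    if not reports:
        raise ValueError("no replications to aggregate")
    n = len(reports)
    scopes: dict[str, dict[str, float]] = {}
    ses: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, float]] = {}
    for scope in SCOPES:
        scopes[scope], ses[scope], counts[scope] = {}, {}, {}
        for metric in METRICS:
            vals = np.array([r.scopes[scope][metric] for r in reports])
            scopes[scope][metric] = float(vals.mean())
            ses[scope][metric] = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        for key in reports[0].counts[scope]:
            counts[scope][key] = float(np.mean([r.counts[scope][key] for r in reports]))
    flags = sorted({f for r in reports for f in r.flags})
    return PerformanceReport(
        scopes=scopes,
        ses=ses if n > 1 else None,
        counts=counts,
        replications=n,
        config=config,
        flags=flags,
    )
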