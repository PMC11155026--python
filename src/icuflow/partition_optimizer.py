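"""Bed-partition search for the dedicated design.

Finds the four-way split of a given total capacity that minimises the
overall rejection rate. The composition space at realistic capacities is
small (a few thousand splits below 50 beds) but simulating every split at
useful replication counts is wasteful, so the search runs in three
stages: (1) every composition is scored with a closed-form proxy — the
load-weighted Erlang-B blocking of its cluster units — and a shortlist is
kept (the uniform and proportional-to-load heuristics are always
retained); (2) the shortlist is simulated with common random numbers at a
reduced replication count; (3) the top few are re-simulated at full
replications and the minimiser returned. Ties break lexicographically in
cluster order, which makes repeated runs at the same seed return the
identical partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .des_engine import PatientStream, ScenarioConfig, generate_streams, run_on_streams
from .queueing import erlang_b
from .stochastic_inputs import ArrivalModel, LOSModel
from .units import CLUSTERS, DAY_TYPES, SPECIALISMS, cluster_of


@dataclass
class SimSettings:
    """Simulation effort knobs for the partition search."""

    horizon_days: float = 1000.0
    burn_in_days: float = 120.0
    screen_keep: int = 40
    screen_replications: int = 5
    final_replications: int = 30
    top_refine: int = 5
    seed: int = 0
    los_reduction: float = 1.0
    inflow_multiplier: float = 1.0


@dataclass
class PartitionSearchResult:
    best: dict[str, int]
    objective_value: float  # overall rejection_pct of the best partition
    evaluated: list[tuple[dict[str, int], dict[str, float]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for part, metrics in self.evaluated:
            rows.append({**{c.lower(): part[c] for c in CLUSTERS}, **metrics})
        return pd.DataFrame(rows)


def compositions(total: int, parts: int = 4, minimum: int = 0) -> Iterator[tuple[int, ...]]:
    """All ordered splits of ``total`` into ``parts`` integers >= minimum."""
    if total < parts * minimum:
        return
    if parts == 1:
        yield (total,)
        return
    for head in range(minimum, total - (parts - 1) * minimum + 1):
        for tail in compositions(total - head, parts - 1, minimum):
            yield (head,) + tail


def cluster_loads(
    arrival_model: ArrivalModel, los_model: LOSModel
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-cluster mean daily arrival rates and offered loads (in beds).

    Rates average the day-type rates over a 5/2 weekday/weekend week and
    include both planned and unplanned streams; offered load multiplies
    each stream by its mean LOS.
    """
    weights = {"weekday": 5 / 7, "weekend": 2 / 7}
    rates = {c: 0.0 for c in CLUSTERS}
    loads = {c: 0.0 for c in CLUSTERS}
    for s in SPECIALISMS:
        c = cluster_of(s)
        for dt in DAY_TYPES:
            w = weights[dt]
            unpl = arrival_model.unplanned_rate[dt][s]
            plan = arrival_model.planned_mean(dt, s)
            rates[c] += w * (unpl + plan)
            loads[c] += w * (
                unpl * los_model.mean(s, "unplanned") + plan * los_model.mean(s, "planned")
            )
    return rates, loads


def erlang_rejection_proxy(
    partition: Sequence[int],
    unplanned_rates: dict[str, float],
    loads: dict[str, float],
) -> float:
    """Closed-form screening objective for a candidate partition.

    Treats each cluster unit as an independent Erlang loss system at its
    offered load and returns the unplanned-arrival-weighted blocking
    percentage. Ignores rescheduling feedback, so it is a ranking proxy
    only; the simulation stages decide the final answer.
    """
    total_rate = sum(unplanned_rates.values())
    if total_rate == 0:
        return 0.0
    blocked = sum(
        unplanned_rates[c] * erlang_b(loads[c], beds)
        for c, beds in zip(CLUSTERS, partition)
    )
    return 100.0 * blocked / total_rate


def proportional_partition(
    arrival_model: ArrivalModel, los_model: LOSModel, total_beds: int, min_beds: int = 1
) -> dict[str, int]:
    """Beds proportional to cluster offered load (largest remainder)."""
    if total_beds < len(CLUSTERS) * min_beds:
        raise ValueError("total_beds too small for the minimum per cluster")
    _, loads = cluster_loads(arrival_model, los_model)
    total_load = sum(loads.values())
    spare = total_beds - len(CLUSTERS) * min_beds
    if total_load == 0:
        shares = {c: spare / len(CLUSTERS) for c in CLUSTERS}
    else:
        shares = {c: spare * loads[c] / total_load for c in CLUSTERS}
    alloc = {c: min_beds + int(np.floor(shares[c])) for c in CLUSTERS}
    remainder = total_beds - sum(alloc.values())
    order = sorted(CLUSTERS, key=lambda c: shares[c] - np.floor(shares[c]), reverse=True)
    for c in order[:remainder]:
        alloc[c] += 1
    return alloc


def uniform_partition(total_beds: int) -> dict[str, int]:
    base, extra = divmod(total_beds, len(CLUSTERS))
    return {c: base + (1 if i < extra else 0) for i, c in enumerate(CLUSTERS)}


def _evaluate(
    partition: tuple[int, ...], streams: Sequence[PatientStream], settings: SimSettings
) -> dict[str, float]:
    config = ScenarioConfig(
        design="dedicated",
        total_beds=sum(partition),
        partition=dict(zip(CLUSTERS, partition)),
        horizon_days=settings.horizon_days,
        burn_in_days=settings.burn_in_days,
        los_reduction=settings.los_reduction,
        inflow_multiplier=settings.inflow_multiplier,
        replications=len(streams),
    )
    report = run_on_streams(config, streams)
    out = {f"{m}": report.scopes["overall"][m] for m in report.scopes["overall"]}
    if report.ses is not None:
        out.update({f"se_{m}": v for m, v in report.ses["overall"].items()})
    return out


def optimize_partition(
    total_beds: int,
    arrival_model: ArrivalModel,
    los_model: LOSModel,
    min_beds_per_cluster: int = 1,
    sim_settings: SimSettings | None = None,
) -> PartitionSearchResult:
    """Find the partition of ``total_beds`` minimising overall rejection.

    Enumerates every composition with at least ``min_beds_per_cluster``
    beds per unit, screens with the Erlang-B proxy, then simulates the
    shortlist with common random numbers (reduced replications) and the
    finalists at full replications. Deterministic given the settings seed.
    """
    settings = sim_settings or SimSettings()
    if total_beds < len(CLUSTERS) * min_beds_per_cluster:
        raise ValueError(
            f"total_beds={total_beds} infeasible with minimum "
            f"{min_beds_per_cluster} beds per cluster"
        )
    unplanned_rates = {c: 0.0 for c in CLUSTERS}
    weights = {"weekday": 5 / 7, "weekend": 2 / 7}
    for s in SPECIALISMS:
        for dt in DAY_TYPES:
            unplanned_rates[cluster_of(s)] += (
                weights[dt] * arrival_model.unplanned_rate[dt][s]
            )
    _, loads = cluster_loads(arrival_model, los_model)

    all_parts = list(compositions(total_beds, len(CLUSTERS), min_beds_per_cluster))
    proxy = [(erlang_rejection_proxy(p, unplanned_rates, loads), p) for p in all_parts]
    proxy.sort(key=lambda x: (x[0], x[1]))
    shortlist = {p for _, p in proxy[: settings.screen_keep]}
    for heuristic in (
        uniform_partition(total_beds),
        proportional_partition(arrival_model, los_model, total_beds, min_beds_per_cluster),
    ):
        tup = tuple(heuristic[c] for c in CLUSTERS)
        if min(tup) >= min_beds_per_cluster:
            shortlist.add(tup)
    shortlist = sorted(shortlist)

    screen_streams = generate_streams(
        arrival_model,
        los_model,
        settings.horizon_days,
        settings.inflow_multiplier,
        settings.seed,
        settings.screen_replications,
    )
    screened = [(p, _evaluate(p, screen_streams, settings)) for p in shortlist]
    screened.sort(key=lambda e: (e[1]["rejection_pct"], e[0]))
    finalists = [p for p, _ in screened[: settings.top_refine]]

    final_streams = generate_streams(
        arrival_model,
        los_model,
        settings.horizon_days,
        settings.inflow_multiplier,
        settings.seed + 1,
        settings.final_replications,
    )
    evaluated = [(p, _evaluate(p, final_streams, settings)) for p in finalists]
    evaluated.sort(key=lambda e: (e[1]["rejection_pct"], e[0]))
    best_tuple, best_metrics = evaluated[0]
    return PartitionSearchResult(
        best=dict(zip(CLUSTERS, best_tuple)),
        objective_value=best_metrics["rejection_pct"],
        evaluated=[(dict(zip(CLUSTERS, p)), m) for p, m in evaluated],
    )


def marginal_allocation_sweep(
    capacities: Sequence[int],
    arrival_model: ArrivalModel,
    los_model: LOSModel,
    min_beds_per_cluster: int = 1,
    sim_settings: SimSettings | None = None,
) -> pd.DataFrame:
    """Optimised partition at each capacity with bed-gain annotations.

    For every capacity in the (contiguous, increasing) range the best
    partition is computed; the ``gained`` column names the cluster(s)
    holding more beds than in the previous capacity's optimum.
    """
    caps = list(capacities)
    if caps != sorted(caps):
        raise ValueError("capacity range must be increasing")
    rows = []
    prev: dict[str, int] | None = None
    for total in caps:
        res = optimize_partition(
            total, arrival_model, los_model, min_beds_per_cluster, sim_settings
        )
        gained = (
            "" if prev is None
            else "+".join(c for c in CLUSTERS if res.best[c] > prev.get(c, 0))
        )
        row = {"total_beds": total, "gained": gained}
        row.update({c.lower(): res.best[c] for c in CLUSTERS})
        row.update(res.evaluated[0][1])
        rows.append(row)
        prev = res.best
    return pd.DataFrame(rows)
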