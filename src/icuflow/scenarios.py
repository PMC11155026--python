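"""The four decision scenarios: base case, capacity sweep, LOS reduction
and unplanned-inflow surge.

Each runner compares the pooled (non-dedicated) and partitioned
(dedicated) designs on identical replication-level arrival streams
(common random numbers), which sharpens the paired contrasts the
scenarios exist to show: pooling lowers rejection and rescheduling at the
price of higher occupancy; extra beds buy lower rejection; shorter stays
in a dedicated ward relax all three measures; surges in emergency inflow
stress the dedicated design harder.

Runners return tidy tables keyed by scope x metric with means and
Monte-Carlo standard errors, from which the scenario figures can be
re-plotted directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .des_engine import (
    PerformanceReport,
    ScenarioConfig,
    dedicated_config,
    generate_streams,
    run_on_streams,
)
from .partition_optimizer import SimSettings, optimize_partition, proportional_partition
from .stochastic_inputs import ArrivalModel, LOSModel
from .units import DEFAULT_PARTITION

#: Capacity at and partition under which the hospital's ward operates.
BASE_BEDS = 28


def report_rows(report: PerformanceReport, **keys) -> list[dict]:
    rows = []
    for row in report.to_frame().itertuples(index=False):
        rows.append({**keys, "scope": row.scope, "metric": row.metric,
                     "mean": row.mean, "se": row.se})
    return rows


def _require_models(arrival_model, los_model):
    if arrival_model is None or los_model is None:
        raise ValueError("fitted arrival and LOS models are required")


def base_case(
    arrival_model: ArrivalModel,
    los_model: LOSModel,
    total_beds: int = BASE_BEDS,
    partition: dict[str, int] | None = None,
    seed: int = 0,
    replications: int = 100,
    horizon_days: float = 3770.0,
    burn_in_days: float = 120.0,
) -> dict[str, PerformanceReport]:
    """Paired pooled-vs-dedicated comparison at a fixed capacity.

    Both designs see the same arrival streams; the dedicated arm uses the
    given partition (the ward's 6/11/5/6 split by default, scaled
    implicitly by ``total_beds`` only through the caller's choice).
    """
    _require_models(arrival_model, los_model)
    partition = dict(partition or DEFAULT_PARTITION)
    if sum(partition.values()) != total_beds:
        raise ValueError("partition must sum to total_beds")
    streams = generate_streams(
        arrival_model, los_model, horizon_days, 1.0, seed, replications
    )
    shared = dict(
        horizon_days=horizon_days, burn_in_days=burn_in_days,
        seed=seed, replications=replications,
    )
    pooled = ScenarioConfig(design="non_dedicated", total_beds=total_beds, **shared)
    dedicated = dedicated_config(partition=partition, **shared)
    return {
        "non_dedicated": run_on_streams(pooled, streams),
        "dedicated": run_on_streams(dedicated, streams),
    }


@dataclass
class CapacitySweepResult:
    table: pd.DataFrame  # columns: total_beds, design, scope, metric, mean, se
    min_beds: dict[str, int | None]  # per design: smallest capacity under target
    partitions: dict[int, dict[str, int]]  # dedicated partition per capacity
    rejection_target_pct: float


def capacity_sweep(
    arrival_model: ArrivalModel,
    los_model: LOSModel,
    bed_range=range(14, 51),
    rejection_target_pct: float = 5.0,
    partition_strategy: str = "optimize",
    seed: int = 0,
    replications: int = 30,
    horizon_days: float = 3770.0,
    burn_in_days: float = 120.0,
    optimizer_settings: SimSettings | None = None,
) -> CapacitySweepResult:
    """Both designs across a capacity range, plus the minimum capacity
    whose mean overall rejection rate is below the target.

    The dedicated partition is re-optimised at each capacity
    (``partition_strategy='optimize'``) or allocated proportionally to
    cluster offered load (``'proportional'``, much faster). One set of
    arrival streams serves every capacity and both designs.
    """
    _require_models(arrival_model, los_model)
    if partition_strategy not in ("optimize", "proportional"):
        raise ValueError("partition_strategy must be 'optimize' or 'proportional'")
    capacities = sorted(bed_range)
    streams = generate_streams(
        arrival_model, los_model, horizon_days, 1.0, seed, replications
    )
    opt_settings = optimizer_settings or SimSettings(seed=seed)
    rows: list[dict] = []
    partitions: dict[int, dict[str, int]] = {}
    overall_rejection: dict[str, dict[int, float]] = {"non_dedicated": {}, "dedicated": {}}
    shared = dict(
        horizon_days=horizon_days, burn_in_days=burn_in_days,
        seed=seed, replications=replications,
    )
    for total in capacities:
        if partition_strategy == "optimize":
            partition = optimize_partition(
                total, arrival_model, los_model, sim_settings=opt_settings
            ).best
        else:
            partition = proportional_partition(arrival_model, los_model, total)
        partitions[total] = partition
        for design, config in (
            ("non_dedicated", ScenarioConfig(design="non_dedicated", total_beds=total, **shared)),
            ("dedicated", dedicated_config(partition=partition, **shared)),
        ):
            report = run_on_streams(config, streams)
            overall_rejection[design][total] = report.overall("rejection_pct")
            rows.extend(report_rows(report, total_beds=total, design=design))
    min_beds = {
        design: next(
            (c for c in capacities if overall_rejection[design][c] < rejection_target_pct),
            None,
        )
        for design in overall_rejection
    }
    return CapacitySweepResult(
        table=pd.DataFrame(rows),
        min_beds=min_beds,
        partitions=partitions,
        rejection_target_pct=rejection_target_pct,
    )


def los_reduction_sweep(
    arrival_model: ArrivalModel,
    los_model: LOSModel,
    reductions=(0.0, 0.1, 0.2, 0.3),
    total_beds: int = BASE_BEDS,
    partition: dict[str, int] | None = None,
    seed: int = 0,
    replications: int = 100,
    horizon_days: float = 3770.0,
    burn_in_days: float = 120.0,
) -> pd.DataFrame:
    """Dedicated design under hypothetical mean-LOS reductions.

    A reduction of 0.2 multiplies every sampled stay in the dedicated arm
    by 0.8; the pooled baseline (no reduction) is reported alongside.
    The same streams serve every reduction level, so the reduction-0 row
    is exactly the base-case dedicated arm at the same seed.
    """
    _require_models(arrival_model, los_model)
    partition = dict(partition or DEFAULT_PARTITION)
    streams = generate_streams(
        arrival_model, los_model, horizon_days, 1.0, seed, replications
    )
    shared = dict(
        horizon_days=horizon_days, burn_in_days=burn_in_days,
        seed=seed, replications=replications,
    )
    rows: list[dict] = []
    pooled = ScenarioConfig(design="non_dedicated", total_beds=total_beds, **shared)
    rows.extend(
        report_rows(
            run_on_streams(pooled, streams),
            design="non_dedicated", los_reduction_pct=0.0,
        )
    )
    for r in reductions:
        if not 0 <= r < 1:
            raise ValueError("reductions must be in [0, 1)")
        config = dedicated_config(partition=partition, los_reduction=1.0 - r, **shared)
        rows.extend(
            report_rows(
                run_on_streams(config, streams),
                design="dedicated", los_reduction_pct=100.0 * r,
            )
        )
    return pd.DataFrame(rows)


def inflow_surge(
    arrival_model: ArrivalModel,
    los_model: LOSModel,
    surges=(0.0, 0.1, 0.2, 0.3),
    total_beds: int = BASE_BEDS,
    partition: dict[str, int] | None = None,
    seed: int = 0,
    replications: int = 100,
    horizon_days: float = 3770.0,
    burn_in_days: float = 120.0,
) -> pd.DataFrame:
    """Both designs under increased unplanned inflow.

    A surge of 0.2 scales every unplanned arrival rate by 1.2; planned
    arrivals are untouched. Within each surge level the two designs share
    streams; the surge-0 rows equal the base case at the same seed.
    """
    _require_models(arrival_model, los_model)
    partition = dict(partition or DEFAULT_PARTITION)
    shared = dict(
        horizon_days=horizon_days, burn_in_days=burn_in_days,
        seed=seed, replications=replications,
    )
    rows: list[dict] = []
    for surge in surges:
        if surge < 0:
            raise ValueError("surges must be non-negative")
        mult = 1.0 + surge
        streams = generate_streams(
            arrival_model, los_model, horizon_days, mult, seed, replications
        )
        for design, config in (
            (
                "non_dedicated",
                ScenarioConfig(
                    design="non_dedicated", total_beds=total_beds,
                    inflow_multiplier=mult, **shared,
                ),
            ),
            ("dedicated", dedicated_config(partition=partition, inflow_multiplier=mult, **shared)),
        ):
            report = run_on_streams(config, streams)
            rows.extend(report_rows(report, design=design, surge_pct=100.0 * surge))
    return pd.DataFrame(rows)
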