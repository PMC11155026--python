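"""Event-engine behaviour: admission/rejection/rescheduling mechanics,
metric definitions, conservation laws and queueing-theory equivalences."""

import numpy as np
import pytest

import icuflow as f
from icuflow.des_engine import (
    PatientStream,
    ScenarioConfig,
    aggregate_reports,
    compute_metrics,
    dedicated_config,
    generate_patients,
    mmcc_inputs,
    run_on_streams,
    run_replication,
    run_scenario,
    simulate_stream,
)
from icuflow.queueing import erlang_b
from icuflow.units import CLUSTERS


def stream_from_rows(rows):
    """Build a PatientStream from (time, planned, cluster_idx, los) rows."""
    t, planned, clus, los = (np.array(x) for x in zip(*rows))
    order = np.argsort(t, kind="stable")
    spec_of_cluster = {0: 0, 1: 1, 2: 3, 3: 4}  # a specialism inside each cluster
    clus = clus.astype(int)[order]
    return PatientStream(
        time=t.astype(float)[order],
        planned=planned.astype(bool)[order],
        spec_idx=np.array([spec_of_cluster[c] for c in clus]),
        cluster_idx=clus,
        base_los=los.astype(float)[order],
    )


# ---------------------------------------------------------------------------
# Configuration contract


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(design="dedicated"),  # partition missing
        dict(design="dedicated", partition={"CAPU": 28}),  # clusters missing
        dict(design="dedicated", total_beds=28,
             partition={"CAPU": 6, "CARD_INT_OTHER": 11, "CHIR": 5, "NEC_NEU": 7}),
        dict(total_beds=-1),
        dict(los_reduction=0.0),
        dict(inflow_multiplier=-0.5),
        dict(burn_in_days=400, horizon_days=300),
        dict(reschedule_delay_days=0.0),
    ],
)
def test_invalid_configs_rejected_before_simulation(kwargs):
    with pytest.raises(ValueError):
        ScenarioConfig(**kwargs)


# ---------------------------------------------------------------------------
# Deterministic micro-scenarios


def test_zero_arrivals_give_all_zero_metrics():
    arrival, los = mmcc_inputs(0.0)
    config = ScenarioConfig(total_beds=4, horizon_days=50, burn_in_days=5, replications=1)
    report, log, _ = run_replication(config, arrival, los, np.random.default_rng(0))
    assert log == []
    for scope in report.scopes.values():
        assert scope == {"occupancy_pct": 0.0, "rejection_pct": 0.0, "rescheduling_pct": 0.0}


def test_time_weighted_occupancy_definition():
    """One patient holding 1 of 2 beds for exactly half the window -> 25%."""
    config = ScenarioConfig(total_beds=2, horizon_days=10, burn_in_days=0)
    stream = stream_from_rows([(0.0, False, 0, 5.0)])
    log, trace = simulate_stream(stream, config)
    report = compute_metrics(log, trace, config)
    assert report.overall("occupancy_pct") == pytest.approx(25.0)

    full = ScenarioConfig(total_beds=1, horizon_days=10, burn_in_days=0)
    log, trace = simulate_stream(stream_from_rows([(0.0, False, 0, 10.0)]), full)
    assert compute_metrics(log, trace, full).overall("occupancy_pct") == pytest.approx(100.0)


def test_rejection_rate_matches_enumeration():
    """5 unplanned arrivals into 4 beds with long stays: 1 rejection -> 20%."""
    config = ScenarioConfig(total_beds=4, horizon_days=10, burn_in_days=0)
    rows = [(0.5 + 0.1 * i, False, 0, 100.0) for i in range(5)]
    log, trace = simulate_stream(stream_from_rows(rows), config)
    report = compute_metrics(log, trace, config)
    outcomes = [e[6] for e in log if e[1] == "arrival"]
    assert outcomes.count("rejected") == 1 and outcomes.count("admitted") == 4
    assert report.overall("rejection_pct") == pytest.approx(20.0)


def test_rescheduling_rate_can_exceed_100():
    """A planned patient bumped repeatedly counts one event per attempt."""
    config = ScenarioConfig(total_beds=1, horizon_days=30, burn_in_days=0,
                            reschedule_delay_days=1.0)
    rows = [(0.0, False, 0, 10.5), (0.25, True, 0, 1.0)]
    log, trace = simulate_stream(stream_from_rows(rows), config)
    report = compute_metrics(log, trace, config)
    reschedules = sum(1 for e in log if e[6] == "rescheduled")
    # blocked at 0.25, 1.25, ..., 10.25; admitted at the 11.25 retry
    assert reschedules == 11
    assert report.overall("rescheduling_pct") == pytest.approx(1100.0)
    admitted = [e for e in log if e[6] == "admitted" and e[3] == "planned"]
    assert len(admitted) == 1 and admitted[0][0] == pytest.approx(11.25)


def test_departure_frees_bed_before_same_time_arrival():
    config = ScenarioConfig(total_beds=1, horizon_days=10, burn_in_days=0)
    rows = [(1.0, False, 0, 1.0), (2.0, False, 0, 1.0)]  # departs exactly at 2.0
    log, _ = simulate_stream(stream_from_rows(rows), config)
    outcomes = [e[6] for e in log if e[1] == "arrival"]
    assert outcomes == ["admitted", "admitted"]


def test_dedicated_design_isolates_clusters():
    """In the dedicated design a full unit rejects even when another unit
    has free beds; the pool admits the same patient."""
    partition = {"CAPU": 1, "CARD_INT_OTHER": 1, "CHIR": 1, "NEC_NEU": 1}
    rows = [(0.0, False, 0, 50.0), (1.0, False, 0, 50.0)]
    dedicated = dedicated_config(partition=partition, horizon_days=10, burn_in_days=0)
    log, _ = simulate_stream(stream_from_rows(rows), dedicated)
    assert [e[6] for e in log if e[1] == "arrival"] == ["admitted", "rejected"]

    pooled = ScenarioConfig(total_beds=4, horizon_days=10, burn_in_days=0)
    log, _ = simulate_stream(stream_from_rows(rows), pooled)
    assert [e[6] for e in log if e[1] == "arrival"] == ["admitted", "admitted"]


def test_zero_bed_cluster_flagged_and_rejects_everything():
    partition = {"CAPU": 0, "CARD_INT_OTHER": 2, "CHIR": 1, "NEC_NEU": 1}
    config = dedicated_config(partition=partition, horizon_days=10, burn_in_days=0)
    rows = [(1.0, False, 0, 2.0), (2.0, False, 0, 2.0)]
    log, trace = simulate_stream(stream_from_rows(rows), config)
    report = compute_metrics(log, trace, config)
    assert report.scopes["CAPU"]["rejection_pct"] == 100.0
    assert any("CAPU" in flag for flag in report.flags)


# ---------------------------------------------------------------------------
# Conservation and bounds on simulated traffic


def test_conservation_and_bed_bound(models):
    arrival, los = models
    config = ScenarioConfig(total_beds=20, horizon_days=400, burn_in_days=0)
    report, log, trace = run_replication(config, arrival, los, np.random.default_rng(11))

    arrivals = [e for e in log if e[1] == "arrival"]
    rejected = {e[2] for e in log if e[6] == "rejected"}
    admitted = {e[2] for e in log if e[6] == "admitted"}
    departed = {e[2] for e in log if e[1] == "departure"}
    all_ids = {e[2] for e in arrivals}
    waiting = all_ids - rejected - admitted  # planned, still retrying at horizon
    assert len(all_ids) == len(admitted) + len(rejected) + len(waiting)
    assert all(
        e[3] == "planned" for e in arrivals if e[2] in waiting
    )
    # every admission departs exactly once or is in service at the horizon
    assert departed <= admitted
    in_service = len(admitted) - len(departed)
    assert in_service == trace[-1, 1]
    # occupancy never exceeds capacity
    assert trace[:, 1].max() <= config.total_beds
    assert (trace[:, 2:].sum(axis=1) == trace[:, 1]).all()


def test_dedicated_bed_bound_per_cluster(models):
    arrival, los = models
    config = dedicated_config(horizon_days=400, burn_in_days=0)
    _, _, trace = run_replication(config, arrival, los, np.random.default_rng(12))
    for k, cluster in enumerate(CLUSTERS):
        assert trace[:, 2 + k].max() <= config.partition[cluster]


# ---------------------------------------------------------------------------
# Queueing-theory equivalences


def test_blocking_matches_erlang_b_within_3_se():
    a, c = 4.0, 4
    arrival, los = mmcc_inputs(a)
    config = ScenarioConfig(total_beds=c, horizon_days=1000, burn_in_days=100,
                            seed=5, replications=25)
    report = run_scenario(config, arrival, los)
    sim = report.overall("rejection_pct")
    se = report.ses["overall"]["rejection_pct"]
    assert abs(sim - 100 * erlang_b(a, c)) < 3 * se


def test_littles_law_occupancy_in_loss_system():
    """Mean occupied beds = admitted rate x mean LOS (Little's law)."""
    a, c = 10.0, 28
    arrival, los = mmcc_inputs(a, mean_los=2.0)
    config = ScenarioConfig(total_beds=c, horizon_days=1000, burn_in_days=100,
                            seed=6, replications=20)
    report = run_scenario(config, arrival, los)
    lam = a / 2.0
    blocking = erlang_b(a, c)
    expected_occ = lam * (1 - blocking) * 2.0 / c * 100
    se = report.ses["overall"]["occupancy_pct"]
    assert abs(report.overall("occupancy_pct") - expected_occ) < 3 * se


def test_rejection_non_increasing_in_beds(models):
    arrival, los = models
    from icuflow.des_engine import generate_streams

    shared = generate_streams(arrival, los, 500, 1.0, seed=9, replications=8)
    rejections = []
    for beds in (14, 22, 30, 38):
        config = ScenarioConfig(total_beds=beds, horizon_days=500, burn_in_days=60,
                                replications=8)
        rep = run_on_streams(config, shared)
        rejections.append(
            (rep.overall("rejection_pct"), rep.ses["overall"]["rejection_pct"])
        )
    for (lo_r, lo_se), (hi_r, hi_se) in zip(rejections[1:], rejections[:-1]):
        assert lo_r <= hi_r + 3 * np.hypot(lo_se, hi_se)


# ---------------------------------------------------------------------------
# Replication aggregation


def test_identical_streams_give_zero_se(models):
    arrival, los = models
    from icuflow.des_engine import generate_streams

    stream = generate_streams(arrival, los, 300, 1.0, seed=2, replications=1)[0]
    config = ScenarioConfig(total_beds=20, horizon_days=300, burn_in_days=30,
                            replications=2)
    report = run_on_streams(config, [stream, stream])
    for scope in report.ses.values():
        for se in scope.values():
            assert se == 0.0


def test_single_replication_reports_means_without_se(models):
    arrival, los = models
    config = ScenarioConfig(total_beds=20, horizon_days=300, burn_in_days=30,
                            seed=1, replications=1)
    report = run_scenario(config, arrival, los)
    assert report.ses is None
    assert 0 <= report.overall("occupancy_pct") <= 100


def test_se_shrinks_with_replications_like_inverse_sqrt():
    a, c = 4.0, 4
    arrival, los = mmcc_inputs(a)
    ses = {}
    for n in (30, 120):
        config = ScenarioConfig(total_beds=c, horizon_days=250, burn_in_days=30,
                                seed=21, replications=n)
        ses[n] = run_scenario(config, arrival, los).ses["overall"]["rejection_pct"]
    ratio = ses[30] / ses[120]
    assert ratio == pytest.approx(2.0, rel=0.30)


def test_aggregate_requires_reports():
    with pytest.raises(ValueError):
        aggregate_reports([])
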