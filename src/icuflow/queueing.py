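"""Closed-form queueing results used to verify the simulation engine.

An ICU with Poisson arrivals, c beds, no waiting room and losses on
arrival is an M/G/c/c (Erlang loss) system; its blocking probability
depends on the service distribution only through the offered load
a = arrival rate x mean length of stay. These formulas are shipped in the
package so users can sanity-check custom calibrations against theory.
"""

from __future__ import annotations


def erlang_b(offered_load: float, servers: int) -> float:
    """Erlang-B blocking probability of an M/G/c/c loss system.

    Computed by the numerically stable recursion
    B(0) = 1, B(k) = a B(k-1) / (k + a B(k-1)).

    Parameters
    ----------
    offered_load:
        a = arrival rate x mean service time, in units of servers (beds).
    servers:
        Number of servers c (a non-negative integer).
    """
    if offered_load < 0:
        raise ValueError("offered load must be non-negative")
    if servers < 0 or int(servers) != servers:
        raise ValueError("servers must be a non-negative integer")
    if offered_load == 0:
        return 0.0
    b = 1.0
    for k in range(1, int(servers) + 1):
        b = offered_load * b / (k + offered_load * b)
    return b


def littles_law_occupancy(admitted_rate: float, mean_los: float, servers: int) -> float:
    """Expected occupancy fraction of a loss system via Little's law.

    L = admitted arrival rate x mean LOS is the mean number of occupied
    beds; the occupancy fraction is L / c, capped at 1.
    """
    if admitted_rate < 0 or mean_los < 0:
        raise ValueError("rate and mean LOS must be non-negative")
    if servers <= 0:
        raise ValueError("servers must be positive")
    return min(admitted_rate * mean_los / servers, 1.0)
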