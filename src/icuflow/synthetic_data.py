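"""Synthetic admission-log generator.

Generates two-year (by default) admission logs with the statistical
structure of a large mixed academic ICU: about 5.55 arrivals per day, 66%
of them unplanned, 82% of admitted patients arriving on weekdays, and 9%
of unplanned patients rejected. Weekday and weekend Poisson rates are
derived from the target daily mean and the weekday share using the actual
calendar of the generated span, so fitting an arrival model to a generated
log recovers the generating rates.

Lengths of stay are lognormal per unit cluster with means placed so a
28-bed pooled ward runs in the congested (roughly 70–80% occupancy)
regime; planned stays are somewhat shorter than unplanned ones, as
elective admissions typically are. These defaults are test fixtures
emulating published summary statistics, not measurements of any hospital.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .admission_log import COLUMNS
from .units import SPECIALISMS, cluster_of


def _default_mix() -> dict[str, float]:
    # plausible case mix for a mixed academic ICU; sums to 1
    return {
        "CAPU": 0.18,
        "CARD": 0.16,
        "INT": 0.20,
        "CHIR": 0.15,
        "NEC": 0.10,
        "NEU": 0.10,
        "OTHER": 0.11,
    }


def _default_los_means() -> dict[str, float]:
    # mean unplanned LOS in days per unit cluster
    return {"CAPU": 3.0, "CARD_INT_OTHER": 4.0, "CHIR": 3.5, "NEC_NEU": 5.5}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic admission-log generator."""

    n_days: int = 730
    start: str = "2015-01-01"
    arrivals_per_day: float = 5.55
    unplanned_frac: float = 0.66
    weekday_share: float = 0.82
    specialism_mix: dict[str, float] = field(default_factory=_default_mix)
    rejection_prob: float = 0.09
    los_mean_by_cluster: dict[str, float] = field(default_factory=_default_los_means)
    los_sigma: float = 0.9
    planned_los_factor: float = 0.75
    seed: int = 1

    def __post_init__(self):
        for name in ("unplanned_frac", "weekday_share", "rejection_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.arrivals_per_day < 0 or self.n_days < 0:
            raise ValueError("arrivals_per_day and n_days must be non-negative")
        mix_total = sum(self.specialism_mix.get(s, 0.0) for s in SPECIALISMS)
        if abs(mix_total - 1.0) > 1e-9:
            raise ValueError("specialism mix must sum to 1")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)

    def day_type_rates(self) -> dict[str, float]:
        """Weekday/weekend total arrival rates implied by the targets.

        Solves for rates such that the expected total is
        ``arrivals_per_day * n_days`` with ``weekday_share`` of it on
        weekdays, given the calendar's actual weekday/weekend day counts.
        """
        days = pd.date_range(self.start, periods=max(self.n_days, 1), freq="D")
        n_wd = int((days.dayofweek < 5).sum())
        n_we = len(days) - n_wd
        total = self.arrivals_per_day * self.n_days
        if n_we == 0 and self.weekday_share < 1 and total > 0:
            raise ValueError("span has no weekend days but weekday_share < 1")
        if n_wd == 0 and self.weekday_share > 0 and total > 0:
            raise ValueError("span has no weekdays but weekday_share > 0")
        return {
            "weekday": self.weekday_share * total / n_wd if n_wd else 0.0,
            "weekend": (1 - self.weekday_share) * total / n_we if n_we else 0.0,
        }

    def lognormal_params(self, specialism: str, patient_type: str) -> tuple[float, float]:
        """(mu, sigma) of the log-scale normal for a stratum's LOS."""
        mean = self.los_mean_by_cluster[cluster_of(specialism)]
        if patient_type == "planned":
            mean *= self.planned_los_factor
        mu = np.log(mean) - self.los_sigma**2 / 2
        return mu, self.los_sigma


def generate_log(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate a synthetic admission log; deterministic given ``spec.seed``.

    Returns a frame in the canonical admission-log dialect, sorted by
    arrival time, with parsed datetimes (write with
    :func:`icuflow.admission_log.write_log`).
    """
    rng = np.random.default_rng(spec.seed)
    days = pd.date_range(spec.start, periods=spec.n_days, freq="D")
    if spec.n_days == 0:
        return pd.DataFrame(columns=COLUMNS)
    rates = spec.day_type_rates()
    day_rate = np.where(days.dayofweek < 5, rates["weekday"], rates["weekend"])

    rows_arr, rows_type, rows_spec, rows_disc, rows_rej = [], [], [], [], []
    day_start = days.to_numpy()
    for s in SPECIALISMS:
        for ptype, frac in (("unplanned", spec.unplanned_frac), ("planned", 1 - spec.unplanned_frac)):
            lam = day_rate * frac * spec.specialism_mix.get(s, 0.0)
            counts = rng.poisson(lam)
            n = int(counts.sum())
            if n == 0:
                continue
            day_idx = np.repeat(np.arange(spec.n_days), counts)
            arrivals = day_start[day_idx] + (rng.random(n) * 86400 * 1e3).astype(
                "timedelta64[ms]"
            )
            rejected = (
                rng.random(n) < spec.rejection_prob if ptype == "unplanned" else np.zeros(n, bool)
            )
            mu, sigma = spec.lognormal_params(s, ptype)
            los_days = rng.lognormal(mu, sigma, size=n)
            discharge = arrivals + (los_days * 86400 * 1e3).astype("timedelta64[ms]")
            discharge = np.where(rejected, np.datetime64("NaT", "ms"), discharge)
            rows_arr.append(arrivals)
            rows_type.append(np.full(n, ptype, dtype=object))
            rows_spec.append(np.full(n, s, dtype=object))
            rows_disc.append(discharge)
            rows_rej.append(rejected.astype(int))

    if not rows_arr:
        return pd.DataFrame(columns=COLUMNS)
    df = pd.DataFrame(
        {
            "arrival_time": pd.to_datetime(np.concatenate(rows_arr)),
            "type": np.concatenate(rows_type),
            "specialism": np.concatenate(rows_spec),
            "discharge_time": pd.to_datetime(np.concatenate(rows_disc)),
            "rejected": np.concatenate(rows_rej),
        }
    )
    df = df.sort_values("arrival_time", kind="stable").reset_index(drop=True)
    df["los_days"] = (df["discharge_time"] - df["arrival_time"]).dt.total_seconds() / 86400.0
    return df
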