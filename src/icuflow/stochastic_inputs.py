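"""Arrival and length-of-stay models fitted from admission logs.

Unplanned (emergency) arrivals are modelled as a Poisson process whose
daily rate depends on the day type (weekday/weekend) and specialism; the
aggregate Poisson assumption can be checked with a chi-squared
goodness-of-fit test on daily counts. Planned (elective) arrivals follow
the empirical categorical distribution of daily counts per day type and
specialism. Length of stay is a parametric positive distribution per
(specialism, patient type) stratum, selected by AIC among exponential,
gamma, Weibull and lognormal maximum-likelihood fits, with an optional
global reduction multiplier on sampled durations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .units import DAY_TYPES, PATIENT_TYPES, SPECIALISMS

CANDIDATE_FAMILIES: tuple[str, ...] = ("exponential", "gamma", "weibull", "lognormal")

# scipy distribution, number of free parameters with loc pinned at 0
_FAMILY_SPEC = {
    "exponential": (stats.expon, 1),
    "gamma": (stats.gamma, 2),
    "weibull": (stats.weibull_min, 2),
    "lognormal": (stats.lognorm, 2),
}


# ---------------------------------------------------------------------------
# Arrival model


@dataclass
class ArrivalModel:
    """Day-type-stratified arrival model.

    ``unplanned_rate[day_type][specialism]`` is the Poisson mean number of
    unplanned arrivals per day; ``planned_pmf[day_type][specialism]`` is a
    probability mass function over daily planned-arrival counts 0..K.
    """

    unplanned_rate: dict[str, dict[str, float]]
    planned_pmf: dict[str, dict[str, list[float]]]

    def __post_init__(self):
        for dt in DAY_TYPES:
            for s in SPECIALISMS:
                if self.unplanned_rate[dt][s] < 0:
                    raise ValueError("arrival rates must be non-negative")
                pmf = np.asarray(self.planned_pmf[dt][s], float)
                if pmf.size == 0 or abs(pmf.sum() - 1.0) > 1e-9 or (pmf < 0).any():
                    raise ValueError("planned pmf must be a distribution summing to 1")

    def total_unplanned_rate(self, day_type: str) -> float:
        return float(sum(self.unplanned_rate[day_type].values()))

    def planned_mean(self, day_type: str, specialism: str) -> float:
        pmf = np.asarray(self.planned_pmf[day_type][specialism], float)
        return float(np.arange(pmf.size) @ pmf)

    def to_dict(self) -> dict:
        return {
            "unplanned_rate": self.unplanned_rate,
            "planned_pmf": {
                dt: {s: list(map(float, p)) for s, p in by_spec.items()}
                for dt, by_spec in self.planned_pmf.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrivalModel":
        return cls(unplanned_rate=d["unplanned_rate"], planned_pmf=d["planned_pmf"])


def fit_arrival_model(log: pd.DataFrame, day_type_col: str | None = None) -> ArrivalModel:
    """Fit the arrival model from a validated admission log.

    Every calendar day in the log's span contributes an observation, so
    days with zero arrivals count toward rates and pmfs. Day types come
    from the calendar (Mon–Fri = weekday) unless ``day_type_col`` names a
    column carrying explicit labels per row.

    Unplanned rates are the maximum-likelihood Poisson rates (mean daily
    counts per day type and specialism); planned pmfs are empirical
    daily-count frequencies.
    """
    if len(log) == 0:
        raise ValueError("admission log is empty")
    days = log["arrival_time"].dt.normalize()
    span = pd.date_range(days.min(), days.max(), freq="D")
    if day_type_col is None:
        row_dt = np.where(log["arrival_time"].dt.dayofweek < 5, "weekday", "weekend")
        span_dt = np.where(span.dayofweek < 5, "weekday", "weekend")
    else:
        row_dt = log[day_type_col].to_numpy()
        # label the full span by majority of explicit labels per calendar day
        by_day = pd.Series(row_dt, index=days).groupby(level=0).agg(lambda s: s.mode()[0])
        span_dt = by_day.reindex(span).fillna("weekday").to_numpy()
    n_days = {dt: int((span_dt == dt).sum()) for dt in DAY_TYPES}

    unplanned_rate: dict[str, dict[str, float]] = {dt: {} for dt in DAY_TYPES}
    planned_pmf: dict[str, dict[str, list[float]]] = {dt: {} for dt in DAY_TYPES}
    for dt in DAY_TYPES:
        if n_days[dt] == 0:
            warnings.warn(f"no {dt} days in log span; rates set to 0", stacklevel=2)
        for s in SPECIALISMS:
            in_stratum = (log["specialism"] == s) & (row_dt == dt)
            n_unpl = int((in_stratum & (log["type"] == "unplanned")).sum())
            unplanned_rate[dt][s] = n_unpl / n_days[dt] if n_days[dt] else 0.0
            planned_days = days[in_stratum & (log["type"] == "planned")]
            if n_days[dt] == 0 or len(planned_days) == 0:
                planned_pmf[dt][s] = [1.0]
                continue
            counts = planned_days.value_counts().to_numpy()
            kmax = int(counts.max())
            freq = np.bincount(counts, minlength=kmax + 1).astype(float)
            freq[0] = n_days[dt] - len(counts)  # days with zero planned arrivals
            planned_pmf[dt][s] = list(freq / n_days[dt])
    return ArrivalModel(unplanned_rate=unplanned_rate, planned_pmf=planned_pmf)


def poisson_gof_test(daily_counts) -> dict[str, float]:
    """Chi-squared goodness-of-fit of daily arrival counts to a Poisson law.

    Observed count frequencies are compared against Poisson(mean of the
    counts); adjacent bins are pooled from both tails until every expected
    frequency is at least 5. Degrees of freedom are (bins − 2): one for
    normalisation, one for the estimated mean.
    """
    counts = np.asarray(daily_counts, dtype=int)
    if counts.size < 30:
        raise ValueError("need at least 30 days of counts")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    lam = counts.mean()
    kmax = int(counts.max())
    observed = np.bincount(counts, minlength=kmax + 2).astype(float)
    expected = counts.size * stats.poisson.pmf(np.arange(kmax + 2), lam)
    expected[-1] = counts.size * stats.poisson.sf(kmax, lam)  # open tail bin

    # pool under-populated bins inward from both ends
    obs, exp = list(observed), list(expected)
    while len(exp) > 1 and exp[-1] < 5:
        e, o = exp.pop(), obs.pop()
        exp[-1] += e
        obs[-1] += o
    while len(exp) > 1 and exp[0] < 5:
        e, o = exp.pop(0), obs.pop(0)
        exp[0] += e
        obs[0] += o
    if len(exp) < 3:
        raise ValueError("fewer than 3 bins after pooling: insufficient data for GOF test")
    obs_a, exp_a = np.asarray(obs), np.asarray(exp)
    statistic = float(((obs_a - exp_a) ** 2 / exp_a).sum())
    df = len(exp_a) - 2
    return {"statistic": statistic, "p_value": float(stats.chi2.sf(statistic, df)), "df": df}


# ---------------------------------------------------------------------------
# Length-of-stay model


@dataclass
class LOSFit:
    """A fitted duration distribution for one (specialism, type) stratum."""

    family: str
    params: tuple[float, ...]  # scipy shape/loc/scale tuple
    n: int
    aic: float | None = None

    def _frozen(self):
        dist, _ = _FAMILY_SPEC[self.family]
        return dist(*self.params)

    @property
    def mean(self) -> float:
        return float(self._frozen().mean())

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=size, random_state=rng)


@dataclass
class LOSModel:
    """Per-stratum parametric LOS distributions with a global reduction.

    ``reduction`` in (0, 1] multiplies every sampled duration, so the
    sampled mean equals ``reduction`` times the unreduced mean.
    """

    fits: dict[tuple[str, str], LOSFit]
    reduction: float = 1.0

    def __post_init__(self):
        if not 0 < self.reduction <= 1:
            raise ValueError("reduction must be in (0, 1]")

    def with_reduction(self, reduction: float) -> "LOSModel":
        return LOSModel(fits=self.fits, reduction=reduction)

    def mean(self, specialism: str, patient_type: str, reduced: bool = True) -> float:
        m = self.fits[(specialism, patient_type)].mean
        return m * self.reduction if reduced else m

    def sample(
        self, specialism: str, patient_type: str, size: int, rng: np.random.Generator
    ) -> np.ndarray:
        draws = self.fits[(specialism, patient_type)].sample(size, rng) * self.reduction
        return np.maximum(draws, 1e-9)  # durations strictly positive

    def to_dict(self) -> dict:
        return {
            "reduction": self.reduction,
            "fits": {
                f"{s}|{t}": {"family": f.family, "params": list(f.params), "n": f.n, "aic": f.aic}
                for (s, t), f in self.fits.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LOSModel":
        fits = {}
        for key, f in d["fits"].items():
            s, t = key.split("|")
            fits[(s, t)] = LOSFit(
                family=f["family"], params=tuple(f["params"]), n=f["n"], aic=f.get("aic")
            )
        return cls(fits=fits, reduction=d.get("reduction", 1.0))


def _fit_family(family: str, data: np.ndarray) -> LOSFit | None:
    dist, k = _FAMILY_SPEC[family]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = dist.fit(data, floc=0)
            loglik = float(dist.logpdf(data, *params).sum())
    except Exception:
        return None
    if not np.isfinite(loglik):
        return None
    return LOSFit(family=family, params=tuple(params), n=data.size, aic=2 * k - 2 * loglik)


def _exponential_fallback(mean: float, n: int) -> LOSFit:
    return LOSFit(family="exponential", params=(0.0, mean), n=n, aic=None)


def fit_los_model(
    log: pd.DataFrame,
    candidate_families: tuple[str, ...] = CANDIDATE_FAMILIES,
    min_stratum: int = 10,
) -> LOSModel:
    """Fit per-(specialism, type) LOS distributions by AIC model selection.

    Strata with fewer than ``min_stratum`` admitted stays fall back to an
    exponential with the stratum mean (or the pooled mean when empty).
    Ties in AIC are broken by fewer parameters, then by the fixed family
    order of ``candidate_families``.
    """
    unknown = set(candidate_families) - set(_FAMILY_SPEC)
    if unknown:
        raise ValueError(f"unknown LOS families: {sorted(unknown)}")
    admitted = log[log["rejected"] == 0]
    durations = admitted["los_days"].to_numpy(float)
    if (durations <= 0).any():
        raise ValueError("non-positive length of stay in admitted rows")
    pooled_mean = float(durations.mean()) if durations.size else 1.0

    fits: dict[tuple[str, str], LOSFit] = {}
    for s in SPECIALISMS:
        for t in PATIENT_TYPES:
            mask = (admitted["specialism"] == s) & (admitted["type"] == t)
            data = admitted.loc[mask, "los_days"].to_numpy(float)
            if data.size == 0:
                fits[(s, t)] = _exponential_fallback(pooled_mean, 0)
                continue
            if data.size < min_stratum:
                fits[(s, t)] = _exponential_fallback(float(data.mean()), int(data.size))
                continue
            candidates = []
            for order, fam in enumerate(candidate_families):
                fit = _fit_family(fam, data)
                if fit is not None:
                    candidates.append((fit.aic, _FAMILY_SPEC[fam][1], order, fit))
            if not candidates:
                fits[(s, t)] = _exponential_fallback(float(data.mean()), int(data.size))
                continue
            fits[(s, t)] = min(candidates, key=lambda c: c[:3])[3]
    return LOSModel(fits=fits)


# ---------------------------------------------------------------------------
# Sampling and persistence


def sample_daily_arrivals(
    model: ArrivalModel,
    day_type: str,
    inflow_multiplier: float,
    rng: np.random.Generator,
) -> dict[tuple[str, str], int]:
    """Draw one day's arrival counts per (specialism, patient type).

    The inflow multiplier scales unplanned Poisson rates only; planned
    counts come from the stored categorical pmf unchanged.
    """
    if inflow_multiplier < 0:
        raise ValueError("inflow_multiplier must be non-negative")
    out: dict[tuple[str, str], int] = {}
    for s in SPECIALISMS:
        rate = model.unplanned_rate[day_type][s] * inflow_multiplier
        out[(s, "unplanned")] = int(rng.poisson(rate)) if rate > 0 else 0
        pmf = np.asarray(model.planned_pmf[day_type][s], float)
        out[(s, "planned")] = int(rng.choice(pmf.size, p=pmf)) if pmf.size > 1 else 0
    return out


def save_models(arrival: ArrivalModel, los: LOSModel, path, extra: dict | None = None) -> None:
    """Serialize fitted models (plus optional calibration metadata) to JSON."""
    doc = {"arrival": arrival.to_dict(), "los": los.to_dict()}
    if extra:
        doc["calibration"] = extra
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_models(path) -> tuple[ArrivalModel, LOSModel]:
    with open(path) as fh:
        doc = json.load(fh)
    return ArrivalModel.from_dict(doc["arrival"]), LOSModel.from_dict(doc["los"])
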