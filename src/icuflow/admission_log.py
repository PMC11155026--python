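"""Admission-log I/O, validation and summary statistics.

The admission log is a CSV with one row per arriving patient:

``arrival_time`` (ISO-8601), ``type`` (``planned``/``unplanned``),
``specialism`` (one of the seven labels), ``discharge_time`` (ISO-8601,
empty for rejected patients) and ``rejected`` (``0``/``1``).

Only unplanned patients can be rejected; rejected patients have no
discharge time and admitted patients leave strictly after they arrive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .units import PATIENT_TYPES, SPECIALISMS

COLUMNS = ["arrival_time", "type", "specialism", "discharge_time", "rejected"]


class AdmissionLogError(ValueError):
    """Raised when an admission log violates the schema.

    ``rows`` holds the offending 0-based data row numbers (when known).
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = rows or []
        if self.rows:
            shown = ", ".join(map(str, self.rows[:10]))
            more = "" if len(self.rows) <= 10 else f" (+{len(self.rows) - 10} more)"
            message = f"{message} [rows: {shown}{more}]"
        super().__init__(message)


def validate_log(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an admission-log frame.

    Returns a copy with parsed datetimes, integer ``rejected`` and a
    ``los_days`` column for admitted rows. Raises :class:`AdmissionLogError`
    on any schema violation, reporting row numbers.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise AdmissionLogError(f"missing columns: {missing}")
    out = df.loc[:, COLUMNS].copy().reset_index(drop=True)

    arrival = pd.to_datetime(out["arrival_time"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(arrival.isna().to_numpy())
    if bad.size:
        raise AdmissionLogError("unparseable arrival_time", list(bad))
    out["arrival_time"] = arrival

    raw_disc = out["discharge_time"]
    has_disc = raw_disc.notna() & (raw_disc.astype(str).str.strip() != "")
    discharge = pd.to_datetime(raw_disc.where(has_disc), errors="coerce", format="ISO8601")
    bad = np.flatnonzero((has_disc & discharge.isna()).to_numpy())
    if bad.size:
        raise AdmissionLogError("unparseable discharge_time", list(bad))
    out["discharge_time"] = discharge

    bad = np.flatnonzero(~out["type"].isin(PATIENT_TYPES).to_numpy())
    if bad.size:
        raise AdmissionLogError("type must be 'planned' or 'unplanned'", list(bad))
    bad = np.flatnonzero(~out["specialism"].isin(SPECIALISMS).to_numpy())
    if bad.size:
        raise AdmissionLogError(f"specialism must be one of {SPECIALISMS}", list(bad))

    try:
        rejected = out["rejected"].astype(int)
    except (TypeError, ValueError):
        raise AdmissionLogError("rejected must be 0 or 1") from None
    bad = np.flatnonzero(~rejected.isin([0, 1]).to_numpy())
    if bad.size:
        raise AdmissionLogError("rejected must be 0 or 1", list(bad))
    out["rejected"] = rejected

    rej = rejected.to_numpy(bool)
    bad = np.flatnonzero(rej & discharge.notna().to_numpy())
    if bad.size:
        raise AdmissionLogError("rejected rows must not have a discharge_time", list(bad))
    bad = np.flatnonzero(rej & (out["type"] == "planned").to_numpy())
    if bad.size:
        raise AdmissionLogError("only unplanned patients can be rejected", list(bad))
    admitted = ~rej
    bad = np.flatnonzero(admitted & discharge.isna().to_numpy())
    if bad.size:
        raise AdmissionLogError("admitted rows need a discharge_time", list(bad))
    los = (discharge - arrival).dt.total_seconds() / 86400.0
    bad = np.flatnonzero(admitted & (los.to_numpy() <= 0))
    if bad.size:
        raise AdmissionLogError("discharge_time must be after arrival_time", list(bad))
    out["los_days"] = los.where(admitted)
    return out


def read_log(path) -> pd.DataFrame:
    """Read and validate an admission-log CSV."""
    try:
        df = pd.read_csv(path, dtype={"arrival_time": str, "discharge_time": str})
    except Exception as exc:  # malformed CSV, missing file
        raise AdmissionLogError(f"cannot read admission log: {exc}") from exc
    return validate_log(df)


def write_log(df: pd.DataFrame, path) -> None:
    """Write an admission log in the canonical CSV dialect."""
    out = df.loc[:, COLUMNS].copy()
    for col in ("arrival_time", "discharge_time"):
        if np.issubdtype(out[col].dtype, np.datetime64):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["discharge_time"] = out["discharge_time"].fillna("")
    out.to_csv(path, index=False)


def summarize_counts(
    n_arrivals: int,
    n_days: int,
    n_unplanned: int,
    n_unplanned_rejected: int,
    n_weekday_admitted: int,
    n_weekend_admitted: int,
) -> dict[str, float]:
    """Summary-statistic panel from aggregate cohort counts.

    Pure arithmetic on counts: mean arrivals/day, percentage unplanned,
    percentage of unplanned patients rejected, and the weekday share of
    admitted patients.
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    admitted = n_weekday_admitted + n_weekend_admitted
    return {
        "arrivals_per_day": n_arrivals / n_days,
        "pct_unplanned": 100.0 * n_unplanned / n_arrivals if n_arrivals else 0.0,
        "pct_unplanned_rejected": (
            100.0 * n_unplanned_rejected / n_unplanned if n_unplanned else 0.0
        ),
        "pct_weekday_admitted": 100.0 * n_weekday_admitted / admitted if admitted else 0.0,
    }


def summarize_log(df: pd.DataFrame) -> dict[str, float]:
    """Summary-statistic panel computed from a validated admission log.

    ``n_days`` is the number of calendar days spanned by the log
    (inclusive of first and last arrival day).
    """
    if len(df) == 0:
        return {"n_arrivals": 0, "n_days": 0}
    days = df["arrival_time"].dt.normalize()
    n_days = int((days.max() - days.min()).days) + 1
    unplanned = df["type"] == "unplanned"
    admitted = df["rejected"] == 0
    weekday = df["arrival_time"].dt.dayofweek < 5
    panel = summarize_counts(
        n_arrivals=len(df),
        n_days=n_days,
        n_unplanned=int(unplanned.sum()),
        n_unplanned_rejected=int((unplanned & ~admitted).sum()),
        n_weekday_admitted=int((admitted & weekday).sum()),
        n_weekend_admitted=int((admitted & ~weekday).sum()),
    )
    panel.update(
        n_arrivals=len(df),
        n_days=n_days,
        mean_los_days=float(df["los_days"].mean()),
    )
    return panel
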