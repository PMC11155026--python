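"""Specialism labels, unit clusters and calendar helpers.

An arriving patient carries one of seven admission specialisms. In the
dedicated design the ward is split into four physical units; each specialism
maps to exactly one of them (cardiology, internal medicine and "other"
share a unit, as do neurosurgery and neurology).
"""

from __future__ import annotations

SPECIALISMS: tuple[str, ...] = ("CAPU", "CARD", "INT", "CHIR", "NEC", "NEU", "OTHER")
"""CAPU = cardiopulmonary surgery, CARD = cardiology, INT = internal medicine,
CHIR = surgery, NEC = neurosurgery, NEU = neurology, OTHER = anything else."""

CLUSTERS: tuple[str, ...] = ("CAPU", "CARD_INT_OTHER", "CHIR", "NEC_NEU")

SPECIALISM_TO_CLUSTER: dict[str, str] = {
    "CAPU": "CAPU",
    "CARD": "CARD_INT_OTHER",
    "INT": "CARD_INT_OTHER",
    "OTHER": "CARD_INT_OTHER",
    "CHIR": "CHIR",
    "NEC": "NEC_NEU",
    "NEU": "NEC_NEU",
}

CLUSTER_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLUSTERS)}
SPECIALISM_INDEX: dict[str, int] = {s: i for i, s in enumerate(SPECIALISMS)}

#: The 28-bed partition used by the hospital's four physical units.
DEFAULT_PARTITION: dict[str, int] = {
    "CAPU": 6,
    "CARD_INT_OTHER": 11,
    "CHIR": 5,
    "NEC_NEU": 6,
}

DAY_TYPES: tuple[str, str] = ("weekday", "weekend")

PATIENT_TYPES: tuple[str, str] = ("planned", "unplanned")


def cluster_of(specialism: str) -> str:
    """Unit cluster a specialism belongs to."""
    try:
        return SPECIALISM_TO_CLUSTER[specialism]
    except KeyError:
        raise ValueError(f"unknown specialism {specialism!r}") from None


def day_type_of_weekday(weekday: int) -> str:
    """Map a weekday number (0=Monday .. 6=Sunday) to 'weekday'/'weekend'."""
    return "weekend" if weekday >= 5 else "weekday"
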