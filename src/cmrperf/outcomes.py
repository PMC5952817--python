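"""Composite-endpoint adjudication and survival-table construction.

The primary endpoint is a composite of cardiovascular death, nonfatal
myocardial infarction, aborted sudden cardiac death, and late
revascularization — percutaneous coronary intervention (PCI) or bypass
surgery (CABG) more than 90 days after the scan. Revascularizations within
the 90-day blanking window are excluded from the endpoint definition (they
may be driven by the scan result itself), but the patients remain in the
risk set. When a patient has more than one qualifying event, only the first
counts; patients without events are censored at last follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ClinicalEvent",
    "EndpointResult",
    "BLANKING_DAYS",
    "HARD_EVENT_TYPES",
    "REVASC_EVENT_TYPES",
    "adjudicate_primary_endpoint",
    "cohort_filter",
    "composite_event_count",
    "survival_table",
]

#: Default post-scan blanking window for revascularization, days.
BLANKING_DAYS = 90

#: Event types that qualify at any time after the scan.
HARD_EVENT_TYPES = frozenset({"cv_death", "nonfatal_mi", "aborted_scd"})
#: Revascularization procedures, which qualify only beyond the blanking window.
REVASC_EVENT_TYPES = frozenset({"pci", "cabg"})


@dataclass(frozen=True)
class ClinicalEvent:
    """One adjudicable clinical event at a day offset from the CMR scan."""

    type: str
    day_offset: float

    def __post_init__(self) -> None:
        if self.type not in HARD_EVENT_TYPES | REVASC_EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.day_offset < 0:
            raise ValueError("day_offset must be non-negative")


@dataclass(frozen=True)
class EndpointResult:
    """Adjudicated endpoint for one patient."""

    event: bool
    time_days: float
    event_type: str  # qualifying type, or "censored"
    early_revasc: bool


def adjudicate_primary_endpoint(
    events: Iterable[ClinicalEvent],
    last_followup: float,
    blanking_days: float = BLANKING_DAYS,
) -> EndpointResult:
    """Apply the first-event rule with the revascularization blanking window.

    Hard events (cardiovascular death, nonfatal MI, aborted sudden death)
    qualify at any time; PCI/CABG qualify only strictly beyond
    ``blanking_days``. The earliest qualifying event defines the endpoint;
    without one the patient is censored at ``last_followup``. The
    ``early_revasc`` flag records any PCI/CABG within the blanking window.
    The result does not depend on the input ordering of events.
    """
    if blanking_days < 0:
        raise ValueError("blanking_days must be non-negative")
    if last_followup <= 0:
        raise ValueError("last_followup must be positive")

    events = list(events)
    for ev in events:
        if ev.day_offset > last_followup:
            raise ValueError(
                f"event {ev.type} at day {ev.day_offset} lies after "
                f"last follow-up ({last_followup})"
            )

    early = any(
        ev.type in REVASC_EVENT_TYPES and ev.day_offset <= blanking_days
        for ev in events
    )
    qualifying = [
        ev
        for ev in events
        if ev.type in HARD_EVENT_TYPES
        or (ev.type in REVASC_EVENT_TYPES and ev.day_offset > blanking_days)
    ]
    if not qualifying:
        return EndpointResult(False, float(last_followup), "censored", early)
    # earliest qualifying event; simultaneous events resolve deterministically
    # with hard events taking precedence over revascularization
    first = min(
        qualifying,
        key=lambda ev: (ev.day_offset, ev.type in REVASC_EVENT_TYPES, ev.type),
    )
    label = "late_revasc" if first.type in REVASC_EVENT_TYPES else first.type
    return EndpointResult(True, float(first.day_offset), label, early)


def cohort_filter(
    n_eligible: int, n_lost: int, n_poor_quality: int
) -> tuple[int, pd.DataFrame]:
    """Cohort accounting: eligible minus lost-to-follow-up minus poor-quality.

    Returns the final analyzed count and an exclusion log with percentages of
    the eligible cohort reported to one decimal place.
    """
    if min(n_eligible, n_lost, n_poor_quality) < 0:
        raise ValueError("counts must be non-negative")
    final = n_eligible - n_lost - n_poor_quality
    if final < 0:
        raise ValueError("exclusions exceed the eligible cohort")
    log = pd.DataFrame(
        {
            "step": ["eligible", "lost_to_followup", "poor_image_quality", "final"],
            "n": [n_eligible, n_lost, n_poor_quality, final],
            "pct_of_eligible": [
                100.0,
                round(100.0 * n_lost / n_eligible, 1) if n_eligible else 0.0,
                round(100.0 * n_poor_quality / n_eligible, 1) if n_eligible else 0.0,
                round(100.0 * final / n_eligible, 1) if n_eligible else 0.0,
            ],
        }
    )
    return final, log


def composite_event_count(results: Sequence[EndpointResult]) -> pd.Series:
    """Counts of first events by type plus the composite total."""
    counts: dict[str, int] = {}
    for res in results:
        if res.event:
            counts[res.event_type] = counts.get(res.event_type, 0) + 1
    counts["total"] = sum(counts.values())
    return pd.Series(counts, dtype=int).sort_index()


def _events_from_row(row: pd.Series) -> list[ClinicalEvent]:
    """Reconstruct the per-patient event list from cohort-table columns."""
    evs: list[ClinicalEvent] = []
    revasc = str(row.get("revasc_days", "") or "")
    for tok in revasc.split(";"):
        tok = tok.strip()
        if tok:
            evs.append(ClinicalEvent("pci", float(tok)))
    etype = row.get("event_type", "censored")
    if row.get("event", 0) and etype in HARD_EVENT_TYPES:
        evs.append(ClinicalEvent(etype, float(row["time_days"])))
    # late_revasc events are already present via revasc_days
    return evs


def survival_table(
    cohort: pd.DataFrame,
    blanking_days: float = BLANKING_DAYS,
    exclude_early_revasc_patients: bool = False,
) -> pd.DataFrame:
    """Adjudicate every patient of a cohort table.

    Reads the event columns of the synthetic cohort layout (``time_days``,
    ``event``, ``event_type``, ``revasc_days``) and returns ``patient_id,
    time_days, event, event_type, early_revasc``. By default patients with a
    blanked early revascularization stay in the risk set (only the procedure
    is excluded from the endpoint); ``exclude_early_revasc_patients=True``
    drops them entirely for sensitivity analyses.
    """
    rows = []
    for _, row in cohort.iterrows():
        res = adjudicate_primary_endpoint(
            _events_from_row(row), float(row["time_days"]), blanking_days
        )
        rows.append(
            dict(
                patient_id=row["patient_id"],
                time_days=res.time_days,
                event=int(res.event),
                event_type=res.event_type,
                early_revasc=res.early_revasc,
            )
        )
    out = pd.DataFrame(rows)
    if exclude_early_revasc_patients:
        out = out[~out["early_revasc"]].reset_index(drop=True)
    return out
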