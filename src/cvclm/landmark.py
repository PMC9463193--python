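"""Reverse landmark truncation — the simulated scheduled-removal device.

A scheduled removal at day L is simulated by ignoring all CVC days and all
CRBSI events after the landmark: a record contributes ``min(dwell, L)`` days
and keeps its event only if the onset day is on or before the landmark (a
catheter is still in situ on the landmark day itself, so an onset equal to L
is retained).  This is the opposite of a classical landmark survival
analysis, which discards events *before* a time point.  Control records are
the observed data, untruncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .randomization import ARMS, AllocationTable, CONTROL_ARM
from .registry import Cohort, CVCRecord

__all__ = [
    "DEFAULT_LANDMARKS",
    "CRBSI_DEFINITIONS",
    "TruncatedRecord",
    "EndpointResult",
    "LandmarkError",
    "truncate_record",
    "apply_landmark",
    "summarize_endpoint",
    "premature_removal_fraction",
    "endpoint_table",
]

#: Landmark day per arm; ``None`` means unbounded (no simulated removal).
DEFAULT_LANDMARKS: dict[str, Optional[int]] = {
    "D7rmv": 7,
    "D14rmv": 14,
    "D21rmv": 21,
    CONTROL_ARM: None,
}

#: Endpoint definition classes: definite only, or definite plus probable.
CRBSI_DEFINITIONS = ("dCRBSI", "dpCRBSI")


class LandmarkError(ValueError):
    """Raised for invalid landmark maps or empty endpoint groups."""


@dataclass(frozen=True)
class TruncatedRecord:
    """A record after (possibly trivial) landmark truncation."""

    record_id: str
    arm: str
    contributed_days: int
    event_definite: bool
    event_probable: bool
    premature_removal: bool  # true iff real dwell exceeded the landmark


@dataclass(frozen=True)
class EndpointResult:
    """Per-arm endpoint summary for one CRBSI definition class."""

    arm: str
    crbsi_definition: str
    n_cvc: int
    events: int
    cvc_days: int

    @property
    def rate_percent(self) -> float:
        """Events per catheter, as a percentage."""
        return 100.0 * self.events / self.n_cvc

    @property
    def incidence_per_1000(self) -> float:
        """Incidence density: events per 1000 CVC days."""
        return 1000.0 * self.events / self.cvc_days


def truncate_record(record: CVCRecord, landmark_day: Optional[int]) -> TruncatedRecord:
    """Apply the reverse-landmark rule to one record.

    ``landmark_day=None`` means unbounded (control): the record passes
    through unchanged.
    """
    if landmark_day is not None and landmark_day < 1:
        raise LandmarkError(f"landmark_day must be >= 1 or None, got {landmark_day}")
    landmark = math.inf if landmark_day is None else landmark_day
    contributed = int(min(record.dwell_days, landmark))
    has_event = (record.crbsi_class != "none"
                 and record.crbsi_onset_day is not None
                 and record.crbsi_onset_day <= landmark)
    return TruncatedRecord(
        record_id=record.record_id,
        arm="",  # filled by apply_landmark
        contributed_days=contributed,
        event_definite=has_event and record.crbsi_class == "definite",
        event_probable=has_event and record.crbsi_class == "probable",
        premature_removal=record.dwell_days > landmark,
    )


def apply_landmark(cohort: Cohort, table: AllocationTable,
                   landmarks: Mapping[str, Optional[int]] = DEFAULT_LANDMARKS,
                   ) -> list[TruncatedRecord]:
    """Truncate every allocated record at its arm's landmark.

    Records left unassigned by balance truncation are excluded; any other
    record without an allocation raises.
    """
    unknown = set(landmarks) - set(ARMS)
    if unknown:
        raise LandmarkError(f"landmark map names unknown arms: {sorted(unknown)}")
    skipped = set(table.unassigned)
    out: list[TruncatedRecord] = []
    for rec in cohort:
        if rec.record_id in skipped:
            continue
        arm = table.arm_of(rec.record_id)
        if arm not in landmarks:
            raise LandmarkError(f"no landmark defined for arm {arm!r}")
        tr = truncate_record(rec, landmarks[arm])
        out.append(TruncatedRecord(
            record_id=tr.record_id, arm=arm,
            contributed_days=tr.contributed_days,
            event_definite=tr.event_definite,
            event_probable=tr.event_probable,
            premature_removal=tr.premature_removal,
        ))
    return out


def _arm_records(truncated: Iterable[TruncatedRecord], arm: str) -> list[TruncatedRecord]:
    recs = [t for t in truncated if t.arm == arm]
    if not recs:
        raise LandmarkError(f"no records in arm {arm!r}")
    return recs


def summarize_endpoint(truncated: Iterable[TruncatedRecord], arm: str,
                       crbsi_definition: str) -> EndpointResult:
    """Events, CVC days, rate (%) and incidence (/1000 d) for one arm.

    ``dCRBSI`` counts definite events only; ``dpCRBSI`` counts definite plus
    probable.  No rounding is applied — that is presentation's job.
    """
    if crbsi_definition not in CRBSI_DEFINITIONS:
        raise LandmarkError(
            f"crbsi_definition must be one of {CRBSI_DEFINITIONS}, got {crbsi_definition!r}"
        )
    recs = _arm_records(truncated, arm)
    days = sum(t.contributed_days for t in recs)
    if days == 0:
        raise LandmarkError(f"arm {arm!r} has zero total CVC days")
    events = sum(t.event_definite for t in recs)
    if crbsi_definition == "dpCRBSI":
        events += sum(t.event_probable for t in recs)
    return EndpointResult(arm=arm, crbsi_definition=crbsi_definition,
                          n_cvc=len(recs), events=events, cvc_days=days)


def premature_removal_fraction(truncated: Iterable[TruncatedRecord], arm: str) -> float:
    """Fraction of arm records whose real dwell exceeded the landmark."""
    recs = _arm_records(truncated, arm)
    return sum(t.premature_removal for t in recs) / len(recs)


def endpoint_table(truncated: list[TruncatedRecord]) -> pd.DataFrame:
    """Per-(definition, arm) endpoint summaries as a tidy frame.

    One row per definition class and arm present in the data, in the fixed
    arm order, with the premature-removal fraction alongside.
    """
    arms = [a for a in ARMS if any(t.arm == a for t in truncated)]
    rows = []
    for definition in CRBSI_DEFINITIONS:
        for arm in arms:
            ep = summarize_endpoint(truncated, arm, definition)
            rows.append({
                "crbsi_definition": definition,
                "arm": arm,
                "n_cvc": ep.n_cvc,
                "events": ep.events,
                "cvc_days": ep.cvc_days,
                "rate_percent": ep.rate_percent,
                "incidence_per_1000": ep.incidence_per_1000,
                "premature_removal_fraction": premature_removal_fraction(truncated, arm),
            })
    return pd.DataFrame(rows)
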