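"""Survey (EMA) latency, completion, and Likert domain-score metrics.

Each prompted survey records three timestamps — delivery, first viewing,
and submission — and a set of item responses on a 0–3 Likert scale
("Not at all" = 0, "Sometimes" = 1, "Often" = 2, "Frequently" = 3).
View latency is first-view minus delivery; completion latency is
submission minus first-view.  Items are grouped into symptom domains by
a configurable :class:`DomainMap`; a domain score is the mean of the
answered items in that domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataIntegrityError, ValidationError

VALID_RESPONSES = frozenset({0, 1, 2, 3})

#: Likert anchors for the 0–3 scale.
LIKERT_ANCHORS = {0: "Not at all", 1: "Sometimes", 2: "Often", 3: "Frequently"}


@dataclass
class SurveyEvent:
    """One prompted survey with its timestamps and item responses.

    Timestamps are epoch seconds; ``first_view_ts``/``submit_ts`` are
    ``None`` when the survey was never viewed/submitted.
    """

    subject_id: str
    survey_id: str
    delivered_ts: float
    first_view_ts: float | None = None
    submit_ts: float | None = None
    responses: dict[str, int] = field(default_factory=dict)

    def validate(self) -> "SurveyEvent":
        if self.submit_ts is not None and self.first_view_ts is None:
            raise DataIntegrityError(
                f"survey {self.survey_id}: submitted but never viewed"
            )
        if self.first_view_ts is not None and self.first_view_ts < self.delivered_ts:
            raise DataIntegrityError(
                f"survey {self.survey_id}: first viewed before delivery"
            )
        if self.submit_ts is not None and self.submit_ts < self.first_view_ts:
            raise DataIntegrityError(
                f"survey {self.survey_id}: submitted before first view"
            )
        for item, value in self.responses.items():
            if value not in VALID_RESPONSES:
                raise ValidationError(
                    f"survey {self.survey_id}, item {item}: response {value!r} "
                    "outside the 0-3 Likert range"
                )
        return self


@dataclass(frozen=True)
class DomainMap:
    """Mapping from symptom-domain labels to lists of item ids."""

    domains: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for label, items in self.domains.items():
            if not items:
                raise ValidationError(f"domain {label!r} has an empty item list")

    def items_for(self, domain: str) -> tuple[str, ...]:
        try:
            return self.domains[domain]
        except KeyError:
            raise KeyError(f"unknown domain {domain!r}") from None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.domains)


def default_domain_map() -> DomainMap:
    """A synthetic 23-item instrument over the five symptom domains.

    The five domains (mood, anxiety, sleep, psychosis, medication
    adherence) match the domains the instrument covers; the item ids and
    their domain assignment are synthetic stand-ins, since the original
    question-to-domain mapping is not public.  Override via run config.
    """
    return DomainMap(
        {
            "mood": tuple(f"mood_q{i}" for i in range(1, 6)),
            "anxiety": tuple(f"anx_q{i}" for i in range(1, 6)),
            "sleep": tuple(f"sleep_q{i}" for i in range(1, 5)),
            "psychosis": tuple(f"psy_q{i}" for i in range(1, 6)),
            "adherence": tuple(f"adh_q{i}" for i in range(1, 5)),
        }
    )


def view_latency(event: SurveyEvent) -> float:
    """Seconds from delivery to first viewing; NaN if never viewed."""
    if event.first_view_ts is None:
        return math.nan
    if event.first_view_ts < event.delivered_ts:
        raise DataIntegrityError(
            f"survey {event.survey_id}: first viewed before delivery"
        )
    return event.first_view_ts - event.delivered_ts


def completion_latency(event: SurveyEvent) -> float:
    """Seconds from first viewing to submission; NaN if unsubmitted."""
    if event.submit_ts is None:
        return math.nan
    if event.first_view_ts is None:
        raise DataIntegrityError(f"survey {event.survey_id}: submitted but never viewed")
    if event.submit_ts < event.first_view_ts:
        raise DataIntegrityError(f"survey {event.survey_id}: submitted before first view")
    return event.submit_ts - event.first_view_ts


def surveys_completed(events: list[SurveyEvent], start: float, end: float) -> int:
    """Number of surveys submitted within the half-open window [start, end)."""
    return sum(
        1 for e in events if e.submit_ts is not None and start <= e.submit_ts < end
    )


def domain_score(event: SurveyEvent, domain_map: DomainMap, domain: str) -> float:
    """Mean response over the domain's answered items; NaN if none answered."""
    event.validate()
    items = domain_map.items_for(domain)
    answered = [event.responses[i] for i in items if i in event.responses]
    if not answered:
        return math.nan
    return sum(answered) / len(answered)


def survey_metrics_frame(
    events: list[SurveyEvent], domain_map: DomainMap | None = None
) -> pd.DataFrame:
    """Per-event metrics table: latencies, completion flag, domain scores."""
    domain_map = domain_map or default_domain_map()
    rows = []
    for e in events:
        e.validate()
        row = {
            "subject_id": e.subject_id,
            "survey_id": e.survey_id,
            "delivered_ts": e.delivered_ts,
            "view_latency": view_latency(e),
            "completion_latency": completion_latency(e),
            "completed": e.submit_ts is not None,
            "submit_ts": e.submit_ts if e.submit_ts is not None else math.nan,
        }
        for dom in domain_map.labels:
            row[f"Y_{dom}"] = domain_score(e, domain_map, dom) if e.submit_ts is not None else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
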