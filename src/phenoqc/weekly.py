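"""Weekly aggregation and lagged covariate tables.

Daily sensor coverage and per-survey metrics are averaged within
subject-weeks (7-day blocks anchored at each subject's start, matching
the day indexing) to produce one row per subject-week with

* ``A`` — mean daily accelerometer coverage,
* ``G`` — mean daily GPS coverage,
* ``V`` — mean view latency (s) over surveys delivered that week,
* ``C`` — mean completion latency (s) over surveys completed from that
  week's deliveries,
* ``T`` — number of surveys submitted that week, and
* ``Y_<domain>`` — mean domain score over surveys submitted that week.

``lag_table`` pairs the outcome at week ``j`` with the covariates at
week ``j - l`` within each subject (complete-case; dropped rows are
counted in ``DataFrame.attrs["n_dropped"]``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import JoinError
from .surveys import DomainMap, SurveyEvent, default_domain_map, survey_metrics_frame

SECONDS_PER_WEEK = 7 * 86_400.0

#: Covariate order used throughout the model layer.
COVARIATES = ("A", "G", "V", "C", "T")

#: Which sensor feeds which coverage covariate.
DEFAULT_SENSOR_ROLES = {"accelerometer": "A", "gps": "G"}


def _week_of(ts: pd.Series, start: pd.Series) -> pd.Series:
    return ((ts - start) // SECONDS_PER_WEEK).astype(int) + 1


def build_weekly(
    daily: pd.DataFrame,
    events: list[SurveyEvent],
    subject_starts: dict[str, float],
    domain_map: DomainMap | None = None,
    n_weeks: int | dict[str, int] | None = None,
    sensor_roles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Aggregate daily coverage and survey metrics into subject-week rows.

    ``daily`` is the concatenated per-subject daily metrics table
    (columns ``subject_id, sensor, day_index, coverage``).  ``events``
    may include subjects absent from ``daily`` only if they appear in
    ``subject_starts``; an unknown subject raises :class:`JoinError`.
    """
    domain_map = domain_map or default_domain_map()
    sensor_roles = sensor_roles or DEFAULT_SENSOR_ROLES

    daily = daily.copy()
    daily_subjects = set(daily["subject_id"].unique())
    missing = daily_subjects - set(subject_starts)
    if missing:
        raise JoinError(f"no subject start anchor for subjects: {sorted(missing)}")
    for e in events:
        if e.subject_id not in subject_starts:
            raise JoinError(f"survey subject {e.subject_id!r} has no start anchor")

    daily["week"] = (daily["day_index"] - 1) // 7 + 1

    def _weeks_for(sid: str) -> int:
        if isinstance(n_weeks, dict):
            return n_weeks[sid]
        if n_weeks is not None:
            return n_weeks
        obs = daily.loc[daily["subject_id"] == sid, "week"]
        return int(obs.max()) if len(obs) else 0

    subjects = sorted(daily_subjects | {e.subject_id for e in events})
    grid = pd.concat(
        [
            pd.DataFrame({"subject_id": sid, "week": np.arange(1, _weeks_for(sid) + 1)})
            for sid in subjects
            if _weeks_for(sid) > 0
        ],
        ignore_index=True,
    )

    # sensor coverage means -> A / G columns
    cov = (
        daily.groupby(["subject_id", "sensor", "week"], as_index=False)["coverage"]
        .mean()
        .pivot(index=["subject_id", "week"], columns="sensor", values="coverage")
        .rename(columns=sensor_roles)
        .reset_index()
    )
    out = grid.merge(cov, on=["subject_id", "week"], how="left")
    for role in sensor_roles.values():
        if role not in out:
            out[role] = np.nan

    sm = survey_metrics_frame(events, domain_map)
    if len(sm):
        start = sm["subject_id"].map(subject_starts)
        sm["delivered_week"] = _week_of(sm["delivered_ts"], start)
        submitted = sm[sm["completed"]].copy()
        submitted["submit_week"] = _week_of(submitted["submit_ts"], start[submitted.index])

        v = (
            sm.dropna(subset=["view_latency"])
            .groupby(["subject_id", "delivered_week"], as_index=False)["view_latency"]
            .mean()
            .rename(columns={"delivered_week": "week", "view_latency": "V"})
        )
        c = (
            sm.dropna(subset=["completion_latency"])
            .groupby(["subject_id", "delivered_week"], as_index=False)["completion_latency"]
            .mean()
            .rename(columns={"delivered_week": "week", "completion_latency": "C"})
        )
        t = (
            submitted.groupby(["subject_id", "submit_week"], as_index=False)
            .size()
            .rename(columns={"submit_week": "week", "size": "T"})
        )
        y_cols = [f"Y_{dom}" for dom in domain_map.labels]
        y = (
            submitted.groupby(["subject_id", "submit_week"], as_index=False)[y_cols]
            .mean()
            .rename(columns={"submit_week": "week"})
        )
        for frame in (v, c, t, y):
            out = out.merge(frame, on=["subject_id", "week"], how="left")
    else:
        out["V"] = np.nan
        out["C"] = np.nan
        out["T"] = np.nan
        for dom in domain_map.labels:
            out[f"Y_{dom}"] = np.nan

    out["T"] = out["T"].fillna(0).astype(int)
    ordered = ["subject_id", "week", "A", "G", "V", "C", "T"] + [
        f"Y_{dom}" for dom in domain_map.labels
    ]
    return out[ordered].sort_values(["subject_id", "week"], ignore_index=True)


def lag_table(
    weekly: pd.DataFrame,
    lag: int,
    outcome_domain: str,
    covariates: tuple[str, ...] = COVARIATES,
) -> pd.DataFrame:
    """Pair outcome week ``j`` with covariate week ``j - lag`` within subjects.

    Returns a complete-case table with columns ``subject_id, week, Y``
    and the lagged covariates; the number of rows dropped for
    missingness is recorded in ``attrs["n_dropped"]`` and the lag in
    ``attrs["lag"]``.
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    ycol = f"Y_{outcome_domain}"
    if ycol not in weekly:
        raise KeyError(f"outcome domain {outcome_domain!r} not in weekly table")

    left = weekly[["subject_id", "week", ycol]].rename(columns={ycol: "Y"})
    right = weekly[["subject_id", "week", *covariates]].copy()
    right["week"] = right["week"] + lag
    merged = left.merge(right, on=["subject_id", "week"], how="inner")
    complete = merged.dropna(subset=["Y", *covariates]).reset_index(drop=True)
    complete.attrs["n_dropped"] = len(merged) - len(complete)
    complete.attrs["lag"] = lag
    complete.attrs["outcome_domain"] = outcome_domain
    return complete
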