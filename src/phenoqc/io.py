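"""CSV / YAML readers and writers for the pipeline's data contracts.

Sensor ping files are one CSV per subject per sensor with an integer
``timestamp_ms`` column (epoch milliseconds, UTC) followed by payload
columns that the quality metrics carry but never use.  They routinely
run to tens of millions of rows for a 10 Hz accelerometer, so bulk I/O
goes through pyarrow.  Survey files are long-format CSV, one row per
answered item (a survey with no answered items contributes a single row
with empty item fields).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.csv as pacsv
import yaml

from .errors import DataIntegrityError
from .surveys import SurveyEvent


def write_pings_csv(
    path: str | Path,
    timestamps_ms: np.ndarray,
    payload_columns: tuple[str, ...] = ("x", "y", "z"),
    payload: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> None:
    """Write a sensor ping CSV; payload defaults to white noise."""
    cols: dict[str, pa.Array] = {"timestamp_ms": pa.array(timestamps_ms, type=pa.int64())}
    n = len(timestamps_ms)
    for name in payload_columns:
        if payload is not None and name in payload:
            values = payload[name]
        elif rng is not None:
            values = np.round(rng.standard_normal(n), 3)
        else:
            values = np.zeros(n)
        cols[name] = pa.array(values, type=pa.float64())
    pacsv.write_csv(pa.table(cols), str(path))


def read_pings_csv(path: str | Path) -> np.ndarray:
    """Read a sensor ping CSV and return sorted epoch-second timestamps."""
    table = pacsv.read_csv(
        str(path),
        convert_options=pacsv.ConvertOptions(
            include_columns=["timestamp_ms"],
            column_types={"timestamp_ms": pa.int64()},
        ),
    )
    ts = table.column("timestamp_ms").to_numpy()
    return np.sort(ts) / 1000.0


def write_surveys_csv(path: str | Path, events: list[SurveyEvent]) -> None:
    """Write survey events in long format (one row per answered item)."""
    rows = []
    for e in events:
        base = {
            "subject_id": e.subject_id,
            "survey_id": e.survey_id,
            "delivered_ts_ms": int(round(e.delivered_ts * 1000)),
            "first_view_ts_ms": (
                int(round(e.first_view_ts * 1000)) if e.first_view_ts is not None else ""
            ),
            "submit_ts_ms": int(round(e.submit_ts * 1000)) if e.submit_ts is not None else "",
        }
        if e.responses:
            for item, value in sorted(e.responses.items()):
                rows.append({**base, "item_id": item, "response": value})
        else:
            rows.append({**base, "item_id": "", "response": ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_surveys_csv(path: str | Path, validate: bool = True) -> list[SurveyEvent]:
    """Read long-format survey CSV back into validated events.

    Raises :class:`DataIntegrityError` naming the offending row group
    when timestamps are inconsistent.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "survey_id": str, "item_id": str},
        keep_default_na=True,
    )
    events = []
    for (sid, svid), grp in df.groupby(["subject_id", "survey_id"], sort=True):
        first = grp.iloc[0]

        def _ts(field):
            v = first[field]
            return None if pd.isna(v) else float(v) / 1000.0

        responses = {}
        for _, row in grp.iterrows():
            item = row.get("item_id")
            if isinstance(item, str) and item and not pd.isna(row["response"]):
                responses[item] = int(row["response"])
        event = SurveyEvent(
            subject_id=sid,
            survey_id=svid,
            delivered_ts=float(first["delivered_ts_ms"]) / 1000.0,
            first_view_ts=_ts("first_view_ts_ms"),
            submit_ts=_ts("submit_ts_ms"),
            responses=responses,
        )
        if validate:
            try:
                event.validate()
            except (DataIntegrityError, ValueError) as exc:
                raise DataIntegrityError(f"{path}: survey {svid!r}: {exc}") from exc
        events.append(event)
    return events


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    """Write an analysis table with a stable float format."""
    df.to_csv(path, index=False, float_format="%.12g")


def write_yaml_config(path: str | Path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_yaml_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
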