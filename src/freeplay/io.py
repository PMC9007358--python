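"""Readers and writers for every file format the pipeline touches.

Raw sessions use an ActiGraph-style raw CSV dialect: a 10-line header
block (device banner with the sample rate, serial number, start time/date
and filler fields, closed by a dashed line), then a column header
``Accelerometer X,Accelerometer Y,Accelerometer Z`` and one row per sample
with values in g to 4 decimal places.  An optional leading ``Timestamp``
column is accepted on read and validated for uniformity against the
declared rate.

Event logs are plain CSV: ``start_iso8601,end_iso8601,class,cars`` with an
empty cars field for OUT_OF_VIEW segments.  Epoch, feature and metric
tables are written as CSV with stable column order.
"""

from __future__ import annotations

import re
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .cutpoints import EpochMetrics
from .epochs import EpochRecord
from .features import FEATURE_NAMES
from .labels import ACTIVITY_CLASSES, OUT_OF_VIEW
from .simulate import Event, EventLog, RawSession

_BANNER = (
    "------------ Data File Created By Raw Session Writer "
    "date format yyyy-MM-dd at {rate:g} Hz  Filter Normal ------------"
)
_DASHES = "-" * 50
_COLUMNS = "Accelerometer X,Accelerometer Y,Accelerometer Z"


def write_raw_csv(
    session: RawSession, path: str | Path, include_timestamps: bool = False
) -> None:
    """Write a session in the ActiGraph-style raw CSV dialect (4 dp in g)."""
    path = Path(path)
    lines = [
        _BANNER.format(rate=session.rate_hz),
        f"Serial Number: {session.serial or 'SYN-0000'}",
        f"Start Time {session.start.strftime('%H:%M:%S')}",
        f"Start Date {session.start.strftime('%Y-%m-%d')}",
        "Epoch Period (hh:mm:ss) 00:00:00",
        f"Download Time {session.start.strftime('%H:%M:%S')}",
        f"Download Date {session.start.strftime('%Y-%m-%d')}",
        "Current Memory Address: 0",
        "Current Battery Voltage: 4.07     Mode = 12",
        _DASHES,
    ]
    header = ("Timestamp," if include_timestamps else "") + _COLUMNS
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        fh.write(header + "\n")
        step = 1.0 / session.rate_hz
        for i, (x, y, z) in enumerate(session.samples):
            if include_timestamps:
                ts = session.start + timedelta(seconds=i * step)
                fh.write(f"{ts.isoformat()},")
            fh.write(f"{x:.4f},{y:.4f},{z:.4f}\n")


def read_raw_csv(path: str | Path) -> RawSession:
    """Parse the raw CSV dialect back into a RawSession.

    Raises ValueError with the offending line number on malformed headers,
    wrong axis counts, or non-uniform timestamps.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if len(lines) < 12:
        raise ValueError(f"{path}: truncated file ({len(lines)} lines)")
    m = re.search(r"at ([0-9.]+) Hz", lines[0])
    if not m:
        raise ValueError(f"{path}: line 1: no sample rate in header banner")
    rate = float(m.group(1))
    sm = re.match(r"Serial Number:\s*(\S+)", lines[1])
    if not sm:
        raise ValueError(f"{path}: line 2: missing serial number")
    tm = re.match(r"Start Time (\d\d:\d\d:\d\d)", lines[2])
    dm = re.match(r"Start Date (\d{4}-\d{2}-\d{2})", lines[3])
    if not (tm and dm):
        raise ValueError(f"{path}: lines 3-4: missing start time/date")
    start = datetime.fromisoformat(f"{dm.group(1)}T{tm.group(1)}")
    cols_line = lines[10]
    has_ts = cols_line.startswith("Timestamp,")
    if cols_line not in (_COLUMNS, "Timestamp," + _COLUMNS):
        raise ValueError(f"{path}: line 11: unexpected column header {cols_line!r}")
    data = []
    step = 1.0 / rate
    prev_ts: datetime | None = None
    for ln, row in enumerate(lines[11:], start=12):
        if not row:
            continue
        parts = row.split(",")
        vals = parts[1:] if has_ts else parts
        if len(vals) != 3:
            raise ValueError(f"{path}: line {ln}: expected 3 axis values, got {len(vals)}")
        if has_ts:
            ts = datetime.fromisoformat(parts[0])
            if prev_ts is not None:
                gap = (ts - prev_ts).total_seconds()
                if abs(gap - step) > step / 2:
                    raise ValueError(
                        f"{path}: line {ln}: timestamp gap of {gap:.6f} s "
                        f"(expected {step:.6f} s)"
                    )
            prev_ts = ts
        data.append([float(v) for v in vals])
    serial = sm.group(1)
    placement = "wrist" if serial.upper().endswith("WRIST") else "hip"
    subject = serial.split("-")[1] if serial.count("-") >= 2 else serial
    return RawSession(
        subject_id=subject,
        placement=placement,
        rate_hz=rate,
        start=start,
        samples=np.asarray(data, float),
        serial=serial,
    )


def write_event_log(log: EventLog, path: str | Path) -> None:
    """CSV with columns start_iso8601,end_iso8601,class,cars."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("start_iso8601,end_iso8601,class,cars\n")
        for ev in log.events:
            s = log.session_start + timedelta(seconds=ev.start_s)
            e = log.session_start + timedelta(seconds=ev.end_s)
            cars = "" if ev.cars is None else str(ev.cars)
            fh.write(f"{s.isoformat()},{e.isoformat()},{ev.label},{cars}\n")


def read_event_log(path: str | Path) -> EventLog:
    path = Path(path)
    df = pd.read_csv(path, dtype={"cars": "Int64"})
    required = {"start_iso8601", "end_iso8601", "class", "cars"}
    if set(df.columns) != required:
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    starts = pd.to_datetime(df["start_iso8601"], format="ISO8601")
    ends = pd.to_datetime(df["end_iso8601"], format="ISO8601")
    t0 = starts.iloc[0].to_pydatetime()
    events = []
    for s, e, lab, cars in zip(starts, ends, df["class"], df["cars"]):
        if lab != OUT_OF_VIEW and lab not in ACTIVITY_CLASSES:
            raise ValueError(f"{path}: unknown class {lab!r}")
        events.append(
            Event(
                start_s=(s - starts.iloc[0]).total_seconds(),
                end_s=(e - starts.iloc[0]).total_seconds(),
                label=lab,
                cars=None if pd.isna(cars) else int(cars),
            )
        )
    log = EventLog(
        session_start=t0, duration_s=events[-1].end_s, events=events
    )
    log.validate()
    return log


def epoch_table(records: list[EpochRecord]) -> pd.DataFrame:
    """Labelled epoch table (no signal columns)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "placement": [r.placement for r in records],
            "epoch_index": [r.index for r in records],
            "start_s": [r.start_s for r in records],
            "true_class": [r.true_class for r in records],
            "cars_score": [r.cars_score for r in records],
            "intensity": [r.intensity for r in records],
            "valid": [r.valid for r in records],
        }
    )


def feature_table(
    records: list[EpochRecord], feats: list[dict[str, float]]
) -> pd.DataFrame:
    """Epoch table joined with the 25 features in stable column order."""
    base = epoch_table(records)
    fdf = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
    return pd.concat([base.reset_index(drop=True), fdf], axis=1)


def metrics_table(
    records: list[EpochRecord], metrics: list[EpochMetrics]
) -> pd.DataFrame:
    base = epoch_table(records)
    mdf = pd.DataFrame(
        {
            "vertical_counts": [m.vertical_counts for m in metrics],
            "vm_counts": [m.vm_counts for m in metrics],
            "enmo_mg": [m.enmo_mg for m in metrics],
            "svmg_mg": [m.svmg_mg for m in metrics],
        }
    )
    return pd.concat([base.reset_index(drop=True), mdf], axis=1)
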