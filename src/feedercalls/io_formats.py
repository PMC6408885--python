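"""Readers and writers for the project's CSV event-log dialects.

Three tabular formats are used throughout the pipeline, all comma-separated
UTF-8 with a fixed header and ISO 8601 ``YYYY-MM-DDTHH:MM:SS`` timestamps
(local clock time, timezone-naive — trials never span DST changes):

* visit logs      — ``site_id,timestamp,tag_id,species``
* call logs       — ``site_id,timestamp,call_type,n_notes``
* trial tables    — ``site_id,trial_date,time_of_day,treatment,order,start_time``

Visit and call logs are returned as :class:`pandas.DataFrame` objects whose
rows preserve file order; each row corresponds to one event. An empty
``tag_id`` denotes an untagged visitor (the RFID system reads only ringed
birds, and roughly a quarter of the wild population carries no transponder):
such rows are legal and count toward visit totals but never toward
unique-individual counts downstream.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import sys
import warnings
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "SPECIES_CODES",
    "CALL_TYPES",
    "TIMES_OF_DAY",
    "TREATMENTS",
    "LogFormatError",
    "TrialMeta",
    "read_visit_log",
    "write_visit_log",
    "read_call_log",
    "write_call_log",
    "read_trial_table",
    "write_trial_table",
    "trials_to_frame",
    "load_config",
    "log_run_header",
]

logger = logging.getLogger("feedercalls")

#: Closed vocabulary of species codes (standard ringing abbreviations for the
#: three tit species, plus UNKNOWN for untagged/unidentified visitors).
SPECIES_CODES = ("GRETI", "BLUTI", "MARTI", "UNKNOWN")

#: Closed vocabulary of annotated call types: blue/great tit chirps and the
#: chick-a-dee-like dä/D calls of marsh tits.
CALL_TYPES = ("CHIRP", "DAD")

TIMES_OF_DAY = ("AM", "PM")
TREATMENTS = ("PLAYBACK", "CONTROL")

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"

VISIT_COLUMNS = ("site_id", "timestamp", "tag_id", "species")
CALL_COLUMNS = ("site_id", "timestamp", "call_type", "n_notes")
TRIAL_COLUMNS = ("site_id", "trial_date", "time_of_day", "treatment", "order", "start_time")


class LogFormatError(ValueError):
    """A CSV log violates its declared format (bad header or row)."""


@dataclass(frozen=True)
class TrialMeta:
    """One playback trial: design condition labels plus its start time.

    A fully balanced experiment uses every site for all four conditions
    (AM/PM x playback/control) in randomised order 1-4.
    """

    site_id: str
    trial_date: date
    time_of_day: str
    treatment: str
    order: int
    start_time: datetime

    def __post_init__(self) -> None:
        if self.time_of_day not in TIMES_OF_DAY:
            raise LogFormatError(f"time_of_day {self.time_of_day!r} not in {TIMES_OF_DAY}")
        if self.treatment not in TREATMENTS:
            raise LogFormatError(f"treatment {self.treatment!r} not in {TREATMENTS}")
        if not 1 <= int(self.order) <= 4:
            raise LogFormatError(f"order must be in 1..4, got {self.order}")

    @property
    def condition(self) -> tuple[str, str]:
        return (self.time_of_day, self.treatment)


def _parse_timestamp(raw: str, lineno: int) -> datetime:
    try:
        return datetime.strptime(raw, TIMESTAMP_FORMAT)
    except ValueError as exc:
        raise LogFormatError(f"line {lineno}: unparseable timestamp {raw!r} "
                             f"(expected {TIMESTAMP_FORMAT})") from exc


def _check_header(header: Sequence[str] | None, expected: Sequence[str], path: Path) -> None:
    if header is None:
        raise LogFormatError(f"{path}: empty file, expected header {','.join(expected)}")
    missing = [c for c in expected if c not in header]
    if missing:
        raise LogFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if list(header) != list(expected):
        raise LogFormatError(f"{path}: header must be exactly {','.join(expected)}, "
                             f"got {','.join(header)}")


def read_visit_log(path: str | Path) -> pd.DataFrame:
    """Read a feeder visit log.

    Returns a DataFrame with columns ``site_id, timestamp, tag_id, species``
    in file order. Empty ``tag_id`` marks an untagged visitor. Malformed rows
    raise :class:`LogFormatError` naming the offending line.
    """
    path = Path(path)
    rows = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, VISIT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise LogFormatError(f"{path} line {lineno}: expected 4 fields, got {len(row)}")
            site_id, ts, tag_id, species = row
            if species not in SPECIES_CODES:
                raise LogFormatError(
                    f"{path} line {lineno}: unknown species code {species!r}; "
                    f"allowed codes: {', '.join(SPECIES_CODES)}")
            rows.append((site_id, _parse_timestamp(ts, lineno), tag_id, species))
    return pd.DataFrame(rows, columns=list(VISIT_COLUMNS)).astype({"timestamp": "datetime64[ns]"}) \
        if rows else _empty_frame(VISIT_COLUMNS)


def _empty_frame(columns: Sequence[str]) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
    if "timestamp" in df.columns:
        df["timestamp"] = pd.Series(dtype="datetime64[ns]")
    if "n_notes" in df.columns:
        df["n_notes"] = pd.Series(dtype="int64")
    return df


def write_visit_log(visits: pd.DataFrame, path: str | Path) -> None:
    """Write a visit-log DataFrame; inverse of :func:`read_visit_log`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(VISIT_COLUMNS)
        for row in visits.itertuples(index=False):
            ts = pd.Timestamp(row.timestamp).strftime(TIMESTAMP_FORMAT)
            writer.writerow([row.site_id, ts, row.tag_id, row.species])


def read_call_log(path: str | Path) -> pd.DataFrame:
    """Read a call-annotation log (``site_id,timestamp,call_type,n_notes``).

    ``n_notes`` is the number of notes in the call and must be >= 1.
    """
    path = Path(path)
    rows = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, CALL_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise LogFormatError(f"{path} line {lineno}: expected 4 fields, got {len(row)}")
            site_id, ts, call_type, n_notes = row
            if call_type not in CALL_TYPES:
                raise LogFormatError(
                    f"{path} line {lineno}: unknown call type {call_type!r}; "
                    f"allowed: {', '.join(CALL_TYPES)}")
            try:
                n = int(n_notes)
            except ValueError as exc:
                raise LogFormatError(f"{path} line {lineno}: n_notes {n_notes!r} "
                                     "is not an integer") from exc
            if n < 1:
                raise LogFormatError(f"{path} line {lineno}: n_notes must be >= 1, got {n}")
            rows.append((site_id, _parse_timestamp(ts, lineno), call_type, n))
    if not rows:
        return _empty_frame(CALL_COLUMNS)
    df = pd.DataFrame(rows, columns=list(CALL_COLUMNS))
    return df.astype({"timestamp": "datetime64[ns]", "n_notes": "int64"})


def write_call_log(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a call-log DataFrame; inverse of :func:`read_call_log`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CALL_COLUMNS)
        for row in calls.itertuples(index=False):
            ts = pd.Timestamp(row.timestamp).strftime(TIMESTAMP_FORMAT)
            writer.writerow([row.site_id, ts, row.call_type, int(row.n_notes)])


def read_trial_table(path: str | Path) -> list[TrialMeta]:
    """Read a playback trial table.

    Raises on duplicate (site, time-of-day, treatment) combinations — the
    balanced design uses each condition exactly once per site — and warns
    (without failing) when a site lacks some of the four conditions.
    """
    path = Path(path)
    trials: list[TrialMeta] = []
    seen: set[tuple[str, str, str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, TRIAL_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 6:
                raise LogFormatError(f"{path} line {lineno}: expected 6 fields, got {len(row)}")
            site_id, trial_date, tod, treatment, order, start = row
            try:
                order_i = int(order)
            except ValueError as exc:
                raise LogFormatError(f"{path} line {lineno}: order {order!r} "
                                     "is not an integer") from exc
            if not 1 <= order_i <= 4:
                raise LogFormatError(f"{path} line {lineno}: order must be in 1..4, got {order_i}")
            try:
                d = datetime.strptime(trial_date, "%Y-%m-%d").date()
            except ValueError as exc:
                raise LogFormatError(f"{path} line {lineno}: bad trial_date {trial_date!r}") from exc
            try:
                meta = TrialMeta(site_id, d, tod, treatment, order_i,
                                 _parse_timestamp(start, lineno))
            except LogFormatError as exc:
                raise LogFormatError(f"{path} line {lineno}: {exc}") from exc
            key = (site_id, tod, treatment)
            if key in seen:
                raise LogFormatError(f"{path} line {lineno}: duplicate condition "
                                     f"{tod}/{treatment} at site {site_id}")
            seen.add(key)
            trials.append(meta)
    _warn_unbalanced(trials)
    return trials


def _warn_unbalanced(trials: Iterable[TrialMeta]) -> None:
    all_conditions = {(t, tr) for t in TIMES_OF_DAY for tr in TREATMENTS}
    by_site: dict[str, set[tuple[str, str]]] = {}
    for t in trials:
        by_site.setdefault(t.site_id, set()).add(t.condition)
    for site, conds in by_site.items():
        missing = all_conditions - conds
        if missing:
            names = ", ".join(f"{a}/{b}" for a, b in sorted(missing))
            warnings.warn(f"site {site} lacks condition(s): {names} — design not balanced",
                          stacklevel=3)


def write_trial_table(trials: Sequence[TrialMeta], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_COLUMNS)
        for t in trials:
            writer.writerow([t.site_id, t.trial_date.isoformat(), t.time_of_day,
                             t.treatment, t.order, t.start_time.strftime(TIMESTAMP_FORMAT)])


def trials_to_frame(trials: Sequence[TrialMeta]) -> pd.DataFrame:
    """Trial metadata as a DataFrame (one row per trial)."""
    return pd.DataFrame(
        {
            "site_id": [t.site_id for t in trials],
            "trial_date": [t.trial_date for t in trials],
            "time_of_day": [t.time_of_day for t in trials],
            "treatment": [t.treatment for t in trials],
            "order": [t.order for t in trials],
            "start_time": pd.to_datetime([t.start_time for t in trials]),
        }
    )


def load_config(path: str | Path) -> dict:
    """Load a flat key-value YAML configuration file."""
    with Path(path).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise LogFormatError(f"{path}: configuration must be a flat key-value mapping")
    return cfg


def log_run_header(stage: str, seed: int | None, config: dict | None = None,
                   inputs: Sequence[str | Path] = (), stream=None) -> str:
    """Emit a reproducibility header (stage, seed, config hash, input paths).

    Every pipeline stage calls this so that a stochastic run can be re-created
    from its log alone. Returns the header string.
    """
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(config or {}, sort_keys=True).encode()).hexdigest()[:12]
    header = (f"[feedercalls:{stage}] seed={seed} config_sha256={cfg_hash} "
              f"inputs={','.join(str(p) for p in inputs) or '-'}")
    logger.info(header)
    print(header, file=stream or sys.stderr)
    return header
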