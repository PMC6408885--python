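"""From raw event streams to hourly summaries and per-trial response measures.

Hour bins are left-closed clock hours ``[h:00, h+1:00)``. Morning means
strictly before 12.00, so 12:00 itself is afternoon. Hours with zero visits
have an undefined calls-per-visit rate (NaN, not 0): a rate with a zero
denominator is not an observation and such rows are dropped before the
permutation test. Untagged visitors (empty ``tag_id``) count toward visit
totals but never toward unique-individual counts, mirroring the RFID system's
blindness to unringed birds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import TrialMeta

__all__ = [
    "HOURLY_COLUMNS",
    "bin_hourly",
    "hourly_table",
    "label_ampm",
    "profile_across_sites",
    "derive_latency",
    "initial_recruitment",
    "total_birds",
    "trial_record",
    "playback_records",
    "TrialRecord",
]

HOURLY_COLUMNS = ("site_id", "clock_hour", "n_calls", "n_visits",
                  "n_individuals", "calls_per_visit")


class AggregationError(ValueError):
    """Events violate an aggregation precondition."""


def label_ampm(clock_hour: int) -> str:
    """AM for hours strictly before 12, PM from 12:00 onward."""
    if not 0 <= clock_hour <= 23:
        raise AggregationError(f"clock_hour must be in 0..23, got {clock_hour}")
    return "AM" if clock_hour < 12 else "PM"


def _hours_of(ts: pd.Series) -> np.ndarray:
    return pd.DatetimeIndex(ts).hour.to_numpy()


def bin_hourly(
    visits: pd.DataFrame,
    calls: pd.DataFrame,
    site_id: str | None = None,
    sunrise_hour: float = 7.0,
    sunset_hour: float = 17.75,
) -> pd.DataFrame:
    """Per-clock-hour counts for one site's trial day.

    Returns one row per daylight clock hour (sunrise hour through sunset hour
    inclusive) with the number of calls, the number of feeder visits, the
    number of distinct tagged individuals, and calls-per-visit (NaN when the
    hour has no visits). Counts partition the events: each event falls in
    exactly one left-closed hour bin.
    """
    sites = set(visits["site_id"]) | set(calls["site_id"])
    if len(sites) > 1:
        raise AggregationError(f"events from multiple sites: {sorted(sites)}")
    if site_id is None:
        site_id = next(iter(sites)) if sites else "?"
    elif sites and sites != {site_id}:
        raise AggregationError(f"events belong to {sorted(sites)}, not {site_id}")

    hours = np.arange(int(math.floor(sunrise_hour)), int(math.floor(sunset_hour)) + 1)
    out = pd.DataFrame({"site_id": site_id, "clock_hour": hours})

    vh = _hours_of(visits["timestamp"]) if len(visits) else np.array([], dtype=int)
    ch = _hours_of(calls["timestamp"]) if len(calls) else np.array([], dtype=int)

    n_visits = np.array([(vh == h).sum() for h in hours])
    n_calls = np.array([(ch == h).sum() for h in hours])
    tags = visits["tag_id"].to_numpy() if len(visits) else np.array([], dtype=object)
    n_ind = np.array([
        len({t for t, h0 in zip(tags, vh) if h0 == h and t}) for h in hours
    ])

    out["n_calls"] = n_calls
    out["n_visits"] = n_visits
    out["n_individuals"] = n_ind
    with np.errstate(divide="ignore", invalid="ignore"):
        out["calls_per_visit"] = np.where(n_visits > 0, n_calls / np.maximum(n_visits, 1),
                                          np.nan)
    return out


def hourly_table(
    visits: pd.DataFrame,
    calls: pd.DataFrame,
    sunrise_hour: float = 7.0,
    sunset_hour: float = 17.75,
) -> pd.DataFrame:
    """Hourly summaries for a multi-site study, one trial per site.

    Concatenates :func:`bin_hourly` over the sites present in the event
    streams and adds an AM/PM label column. The site id doubles as the trial
    identifier for the permutation test.
    """
    frames = []
    for site in sorted(set(visits["site_id"]) | set(calls["site_id"])):
        frames.append(bin_hourly(visits[visits["site_id"] == site],
                                 calls[calls["site_id"] == site],
                                 site, sunrise_hour, sunset_hour))
    if not frames:
        raise AggregationError("no events to aggregate")
    table = pd.concat(frames, ignore_index=True)
    table["trial_id"] = table["site_id"]
    table["period"] = table["clock_hour"].map(label_ampm)
    return table


def profile_across_sites(hourly: pd.DataFrame, min_sites: int = 2) -> pd.DataFrame:
    """Across-site mean and standard error per clock hour.

    The standard error is sd/sqrt(number of contributing sites). Hours
    observed at fewer than ``min_sites`` sites are flagged (``flagged`` True)
    and get NaN standard errors rather than a misleading 0.
    """
    rows = []
    for hour, grp in hourly.groupby("clock_hour"):
        n = grp["site_id"].nunique()
        row = {"clock_hour": hour, "n_sites": n, "flagged": n < min_sites}
        for measure in ("n_calls", "n_individuals", "n_visits"):
            vals = grp[measure].to_numpy(dtype=float)
            row[f"mean_{measure}"] = vals.mean()
            row[f"se_{measure}"] = (vals.std(ddof=1) / math.sqrt(n)) if n >= min_sites else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# playback response measures
# ---------------------------------------------------------------------------

def _minutes_since(ts: pd.Series, start: datetime) -> np.ndarray:
    return (pd.DatetimeIndex(ts) - pd.Timestamp(start)).total_seconds() / 60.0


def derive_latency(
    visits: pd.DataFrame,
    trial_start: datetime,
    censor_min: float = 60.0,
) -> tuple[float, bool]:
    """Latency to feeder discovery, censored at the analysis window.

    Minutes from trial onset to the first recorded visit; when no visit falls
    within ``censor_min`` minutes the latency is set to exactly ``censor_min``
    with the censored flag raised.
    """
    if len(visits) == 0:
        return censor_min, True
    minutes = _minutes_since(visits["timestamp"], trial_start)
    if (minutes < 0).any():
        raise AggregationError("trial_start must precede all trial events")
    first = float(minutes.min())
    if first >= censor_min:  # window is closed-left, open-right
        return censor_min, True
    return first, False


def initial_recruitment(
    visits: pd.DataFrame,
    discovery_time: datetime,
    window_min: float = 2.0,
) -> int:
    """Unique tagged individuals within ``window_min`` minutes of discovery.

    The window is closed at both ends. Calling this for a trial with no
    discovery is an error; the measure is undefined without a discoverer.
    """
    if len(visits) == 0:
        raise AggregationError("initial recruitment undefined for a censored trial")
    minutes = _minutes_since(visits["timestamp"], discovery_time)
    in_window = (minutes >= 0) & (minutes <= window_min)
    tags = visits.loc[in_window, "tag_id"]
    return int(tags[tags != ""].nunique())


def total_birds(
    visits: pd.DataFrame,
    trial_start: datetime,
    window_min: float = 60.0,
) -> int:
    """Unique tagged individuals over the trial window [start, start+window).

    Returns 0 for a censored (undiscovered) trial.
    """
    if len(visits) == 0:
        return 0
    minutes = _minutes_since(visits["timestamp"], trial_start)
    in_window = (minutes >= 0) & (minutes < window_min)
    tags = visits.loc[in_window, "tag_id"]
    return int(tags[tags != ""].nunique())


@dataclass(frozen=True)
class TrialRecord:
    """One playback trial's condition labels plus derived responses.

    Count responses are None when they could not be measured (no discovery
    within the analysis window, or failed logging).
    """

    site_id: str
    time_of_day: str
    treatment: str
    order: int
    latency_min: float
    censored: bool
    initial_recruitment: int | None
    total_birds: int | None
    species: str = "ALL"


def trial_record(meta: TrialMeta, visits: pd.DataFrame,
                 censor_min: float = 60.0, recruit_window_min: float = 2.0,
                 species: str | None = None) -> TrialRecord:
    """Derive the three response measures for one trial.

    With ``species`` given, only that species' visits are considered
    (species-level analysis); untagged visitors are invisible either way to
    the count measures.
    """
    if species is not None:
        visits = visits[visits["species"] == species]
    latency, censored = derive_latency(visits, meta.start_time, censor_min)
    if censored:
        init, tot = None, None
    else:
        minutes = _minutes_since(visits["timestamp"], meta.start_time)
        discovery = pd.Timestamp(meta.start_time) + pd.Timedelta(minutes=float(minutes.min()))
        init = initial_recruitment(visits, discovery, recruit_window_min)
        tot = total_birds(visits, meta.start_time, censor_min)
    return TrialRecord(meta.site_id, meta.time_of_day, meta.treatment, meta.order,
                       latency, censored, init, tot, species or "ALL")


def playback_records(
    trials: Sequence[TrialMeta],
    visits_by_trial: Mapping[tuple[str, str, str], pd.DataFrame],
    species: str | None = None,
) -> pd.DataFrame:
    """Response table for a playback experiment (one row per trial)."""
    recs = [trial_record(t, visits_by_trial[(t.site_id, t.time_of_day, t.treatment)],
                         species=species) for t in trials]
    return pd.DataFrame({
        "site_id": [r.site_id for r in recs],
        "time_of_day": [r.time_of_day for r in recs],
        "treatment": [r.treatment for r in recs],
        "order": [r.order for r in recs],
        "latency_min": [r.latency_min for r in recs],
        "censored": [r.censored for r in recs],
        "initial_recruitment": [np.nan if r.initial_recruitment is None
                                else r.initial_recruitment for r in recs],
        "total_birds": [np.nan if r.total_birds is None else r.total_birds for r in recs],
        "species": [r.species for r in recs],
    })
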