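"""Construction of per-storm panel matrices from daily counts and exposure records.

A tropical cyclone (TC) is treated as a quasi-experiment: counties that
experienced gale-force sustained winds (>= 17.4 m/s) are "treated", nearby
counties are controls, and the outcome panel is a counties x 10 matrix of
two-week event counts ending 11 days after the storm's first US approach.
This module applies the eligibility and exclusion rules that define the
analytic set for each storm and assembles the panel the causal model consumes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GALE_FORCE_MS = 17.4
"""Gale-force sustained windspeed threshold (m/s) defining treated counties."""

N_INTERVALS = 10
INTERVAL_DAYS = 14
FINAL_INTERVAL_LEAD_DAYS = 2    # final interval begins 2 days before first approach
FINAL_INTERVAL_TAIL_DAYS = 11   # ... and ends 11 days after

EARTH_RADIUS_KM = 6371.0
MILES_PER_KM = 1.0 / 1.609344
CONTROL_RADIUS_MILES = 150.0

MIN_POPULATION = 100
MIN_EVENTS = 5          # counties with <= MIN_EVENTS of any outcome are excluded
MIN_TOTAL_COUNTIES = 20
MIN_CONTROLS = 5


class PanelConstructionError(ValueError):
    """Raised when inputs violate the panel-construction contract."""


@dataclass(frozen=True)
class ExposureRecord:
    """One county's exposure to one storm."""

    storm_id: str
    county_id: str
    first_approach_date: dt.date
    max_windspeed: float
    centroid_lat: float
    centroid_lon: float
    features: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.max_windspeed) or self.max_windspeed < 0:
            raise PanelConstructionError(
                f"max_windspeed must be finite and >= 0, got {self.max_windspeed}"
            )


@dataclass(frozen=True)
class StudyPeriod:
    """Ten contiguous two-week intervals ending 11 days after first approach."""

    start_date: dt.date
    end_date: dt.date
    interval_bounds: tuple  # of (start, end) inclusive date pairs
    treatment_interval_index: int

    @property
    def n_intervals(self) -> int:
        return len(self.interval_bounds)


@dataclass
class AnalyticSet:
    """Treated and retained control counties for one storm, with exclusion log."""

    storm_id: str
    treated_ids: list
    control_ids: list
    exclusion_log: dict  # county_id -> first triggering reason code

    def __post_init__(self) -> None:
        overlap = set(self.treated_ids) & set(self.control_ids)
        if overlap:
            raise PanelConstructionError(f"counties both treated and control: {overlap}")


@dataclass
class PanelMatrix:
    """Counties x intervals count panel with treatment mask and offsets.

    Rows are ordered treated-first then controls, each block sorted by county
    id, so construction is deterministic.  ``mask[i, t] == 1`` marks treated
    cells (treated county, t >= T0); with the single treated final interval
    used throughout, T0 is the last column.
    """

    counts: np.ndarray          # (N, T) non-negative ints
    mask: np.ndarray            # (N, T) binary
    offsets: np.ndarray         # (N, T) positive population denominators
    county_ids: list
    interval_labels: list
    t0: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mask = np.asarray(self.mask, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=float)
        n, t = self.counts.shape
        if self.mask.shape != (n, t) or self.offsets.shape != (n, t):
            raise PanelConstructionError("counts, mask and offsets shapes differ")
        if len(self.county_ids) != n or len(self.interval_labels) != t:
            raise PanelConstructionError("label lengths do not match matrix shape")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise PanelConstructionError("counts must be finite and non-negative")
        if np.any(self.counts != np.round(self.counts)):
            raise PanelConstructionError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if np.any(self.offsets <= 0) or not np.all(np.isfinite(self.offsets)):
            raise PanelConstructionError("offsets must be positive and finite")
        if not 0 <= self.t0 < t:
            raise PanelConstructionError(f"t0 out of range: {self.t0}")
        expected = np.zeros((n, t), dtype=int)
        treated_rows = self.mask[:, self.t0] == 1
        expected[treated_rows, self.t0:] = 1
        if not np.array_equal(self.mask, expected):
            raise PanelConstructionError(
                "mask must equal 1 exactly on treated rows for t >= t0"
            )

    @property
    def n_counties(self) -> int:
        return self.counts.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.counts.shape[1]

    @property
    def treated_rows(self) -> np.ndarray:
        return np.flatnonzero(self.mask[:, self.t0] == 1)

    @property
    def treated_cells(self) -> list:
        """(row, column) pairs of treated cells, row-major order."""
        rows, cols = np.nonzero(self.mask)
        return list(zip(rows.tolist(), cols.tolist()))


def classify_exposure(max_windspeed: float) -> str:
    """Classify a county's storm exposure as ``"treated"`` or ``"control"``.

    Treated means maximum sustained windspeed at the population mean center of
    at least gale force, 17.4 m/s.
    """
    w = float(max_windspeed)
    if not np.isfinite(w) or w < 0:
        raise PanelConstructionError(f"windspeed must be finite and >= 0, got {w}")
    return "treated" if w >= GALE_FORCE_MS else "control"


def define_study_period(first_approach_date: dt.date) -> StudyPeriod:
    """Build the 10-interval study period around a storm's first US approach.

    The final (treatment) interval runs from 2 days before through 11 days
    after first approach; the nine baseline intervals are anchored backwards
    from it in contiguous 14-day blocks, so the period opens 128 days before
    first approach.
    """
    if isinstance(first_approach_date, dt.datetime):
        first_approach_date = first_approach_date.date()
    if not isinstance(first_approach_date, dt.date):
        raise PanelConstructionError(f"not a date: {first_approach_date!r}")
    final_start = first_approach_date - dt.timedelta(days=FINAL_INTERVAL_LEAD_DAYS)
    bounds = []
    for j in range(N_INTERVALS):
        start = final_start - dt.timedelta(days=(N_INTERVALS - 1 - j) * INTERVAL_DAYS)
        end = start + dt.timedelta(days=INTERVAL_DAYS - 1)
        bounds.append((start, end))
    return StudyPeriod(
        start_date=bounds[0][0],
        end_date=bounds[-1][1],
        interval_bounds=tuple(bounds),
        treatment_interval_index=N_INTERVALS - 1,
    )


def aggregate_daily_to_intervals(
    daily_counts, period: StudyPeriod, missing: str = "error"
) -> np.ndarray:
    """Aggregate a daily count series into the period's two-week cumulative counts.

    Parameters
    ----------
    daily_counts : mapping or pandas Series
        date -> non-negative integer count.  Must cover every day of the
        study period unless ``missing="zero"``.
    missing : {"error", "zero"}
        Policy for days absent from the series.  The default refuses to
        aggregate, because silently zero-filling would bias baseline trends.
    """
    if isinstance(daily_counts, pd.Series):
        series = {
            (k.date() if isinstance(k, (pd.Timestamp, dt.datetime)) else k): v
            for k, v in daily_counts.items()
        }
    else:
        series = dict(daily_counts)
    if missing not in ("error", "zero"):
        raise PanelConstructionError(f"unknown missing-day policy {missing!r}")
    out = np.zeros(period.n_intervals, dtype=np.int64)
    for j, (start, end) in enumerate(period.interval_bounds):
        total = 0
        day = start
        while day <= end:
            if day in series:
                c = series[day]
                if c < 0 or c != int(c):
                    raise PanelConstructionError(
                        f"count on {day} must be a non-negative integer, got {c}"
                    )
                total += int(c)
            elif missing == "error":
                raise PanelConstructionError(f"no count for {day} in study period")
            day += dt.timedelta(days=1)
        out[j] = total
    return out


def haversine_miles(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in miles between points given in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    km = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return km * MILES_PER_KM


def select_analytic_set(
    exposures,
    populations: dict,
    event_minima: dict,
    centroids: dict | None = None,
) -> AnalyticSet:
    """Apply the per-storm eligibility rules and return the analytic set.

    Any county (treated or control) is excluded if its fee-for-service
    population is below 100 or if it experienced 5 or fewer events of any
    studied outcome during the study period (``event_minima`` carries, per
    county, the minimum study-period event count across outcomes).  Controls
    are then retained only if their centroid lies within 150 miles of at
    least one retained treated county.  ``exclusion_log`` records the first
    rule that fired for each excluded county.

    ``exposures`` is an iterable of :class:`ExposureRecord` for a single
    storm; centroids default to the records' own coordinates.
    """
    exposures = list(exposures)
    if not exposures:
        raise PanelConstructionError("no candidate counties for storm")
    storm_ids = {e.storm_id for e in exposures}
    if len(storm_ids) != 1:
        raise PanelConstructionError(f"records span several storms: {sorted(storm_ids)}")
    storm_id = exposures[0].storm_id

    if centroids is None:
        centroids = {e.county_id: (e.centroid_lat, e.centroid_lon) for e in exposures}

    log: dict = {}
    treated, controls = [], []
    for e in sorted(exposures, key=lambda r: str(r.county_id)):
        cid = e.county_id
        if cid not in populations:
            raise PanelConstructionError(f"no population for county {cid}")
        if cid not in event_minima:
            raise PanelConstructionError(f"no event counts for county {cid}")
        if populations[cid] < MIN_POPULATION:
            log[cid] = "low_population"
            continue
        if event_minima[cid] <= MIN_EVENTS:
            log[cid] = "low_event_count"
            continue
        if classify_exposure(e.max_windspeed) == "treated":
            treated.append(cid)
        else:
            controls.append(cid)

    if treated:
        tlat = np.array([centroids[c][0] for c in treated])
        tlon = np.array([centroids[c][1] for c in treated])
        kept_controls = []
        for cid in controls:
            clat, clon = centroids[cid]
            d = haversine_miles(clat, clon, tlat, tlon)
            if float(np.min(d)) <= CONTROL_RADIUS_MILES:
                kept_controls.append(cid)
            else:
                log[cid] = "beyond_control_radius"
        controls = kept_controls
    else:
        # no treated counties: the 150-mile rule removes every control
        for cid in controls:
            log[cid] = "beyond_control_radius"
        controls = []

    return AnalyticSet(
        storm_id=storm_id,
        treated_ids=sorted(treated, key=str),
        control_ids=sorted(controls, key=str),
        exclusion_log=log,
    )


def qualify_storm(analytic: AnalyticSet) -> bool:
    """Whether a storm enters the study: >=1 treated, >=20 total, >=5 controls."""
    n_t = len(analytic.treated_ids)
    n_c = len(analytic.control_ids)
    return n_t >= 1 and (n_t + n_c) >= MIN_TOTAL_COUNTIES and n_c >= MIN_CONTROLS


def build_panel(
    analytic: AnalyticSet,
    interval_counts: dict,
    offsets: dict,
    interval_labels=None,
) -> PanelMatrix:
    """Assemble the panel matrix for a qualifying storm.

    ``interval_counts`` maps county id -> length-10 count vector;
    ``offsets`` maps county id -> positive scalar population (held constant
    over the study period) or a length-10 vector of time-varying denominators.
    """
    county_ids = list(analytic.treated_ids) + list(analytic.control_ids)
    if not county_ids:
        raise PanelConstructionError("analytic set is empty")
    rows, offs = [], []
    for cid in county_ids:
        if cid not in interval_counts:
            raise PanelConstructionError(f"no interval counts for county {cid}")
        v = np.asarray(interval_counts[cid])
        if v.shape != (N_INTERVALS,):
            raise PanelConstructionError(
                f"county {cid}: expected {N_INTERVALS} interval counts, got shape {v.shape}"
            )
        rows.append(v)
        if cid not in offsets:
            raise PanelConstructionError(f"no offset for county {cid}")
        o = np.asarray(offsets[cid], dtype=float)
        offs.append(np.full(N_INTERVALS, float(o)) if o.ndim == 0 else o)
    counts = np.stack(rows)
    off = np.stack(offs)
    t0 = N_INTERVALS - 1
    mask = np.zeros_like(counts, dtype=int)
    mask[: len(analytic.treated_ids), t0:] = 1
    if interval_labels is None:
        interval_labels = [f"interval_{j + 1}" for j in range(N_INTERVALS)]
    return PanelMatrix(
        counts=counts,
        mask=mask,
        offsets=off,
        county_ids=county_ids,
        interval_labels=list(interval_labels),
        t0=t0,
    )
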