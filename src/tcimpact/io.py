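"""File formats: tidy CSV inputs, panel artifacts, run manifests."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    AnalyticSet,
    ExposureRecord,
    PanelMatrix,
    aggregate_daily_to_intervals,
    define_study_period,
)


def read_daily_counts(path) -> pd.DataFrame:
    """Tidy daily counts: columns county_id, date (ISO-8601), count."""
    df = pd.read_csv(path, dtype={"county_id": str})
    required = {"county_id", "date", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"daily counts file needs columns {sorted(required)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def read_exposures(path) -> list:
    """Exposure records CSV -> list of ExposureRecord (one storm or many)."""
    df = pd.read_csv(path, dtype={"county_id": str, "storm_id": str})
    required = {
        "storm_id",
        "county_id",
        "first_approach_date",
        "max_windspeed",
        "centroid_lat",
        "centroid_lon",
    }
    if not required.issubset(df.columns):
        raise ValueError(f"exposures file needs columns {sorted(required)}")
    extra = [c for c in df.columns if c not in required]
    records = []
    for _, row in df.iterrows():
        records.append(
            ExposureRecord(
                storm_id=row["storm_id"],
                county_id=row["county_id"],
                first_approach_date=pd.to_datetime(row["first_approach_date"]).date(),
                max_windspeed=float(row["max_windspeed"]),
                centroid_lat=float(row["centroid_lat"]),
                centroid_lon=float(row["centroid_lon"]),
                features={k: row[k] for k in extra},
            )
        )
    return records


def read_population(path) -> dict:
    """CSV with county_id, population -> dict."""
    df = pd.read_csv(path, dtype={"county_id": str})
    if not {"county_id", "population"}.issubset(df.columns):
        raise ValueError("population file needs columns county_id, population")
    return dict(zip(df["county_id"], df["population"].astype(float)))


def interval_counts_for_storm(daily: pd.DataFrame, first_approach: dt.date, missing="error"):
    """Aggregate each county's daily series over the storm's study period."""
    period = define_study_period(first_approach)
    out = {}
    for cid, grp in daily.groupby("county_id"):
        series = dict(zip(grp["date"], grp["count"]))
        out[cid] = aggregate_daily_to_intervals(series, period, missing=missing)
    return out, period


def write_panel(panel: PanelMatrix, out_dir, storm_id: str, analytic: AnalyticSet | None = None):
    """Panel as a CSV count matrix plus a JSON sidecar with mask/offsets/labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = pd.DataFrame(panel.counts, index=panel.county_ids, columns=panel.interval_labels)
    counts.index.name = "county_id"
    csv_path = out_dir / f"{storm_id}_panel.csv"
    counts.to_csv(csv_path)
    sidecar = {
        "storm_id": storm_id,
        "t0": panel.t0,
        "county_ids": list(map(str, panel.county_ids)),
        "interval_labels": list(panel.interval_labels),
        "mask": panel.mask.tolist(),
        "offsets": panel.offsets.tolist(),
        "exclusion_log": dict(analytic.exclusion_log) if analytic else {},
    }
    json_path = out_dir / f"{storm_id}_panel.json"
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_panel(out_dir, storm_id: str) -> PanelMatrix:
    out_dir = Path(out_dir)
    counts = pd.read_csv(out_dir / f"{storm_id}_panel.csv", index_col="county_id")
    side = json.loads((out_dir / f"{storm_id}_panel.json").read_text())
    return PanelMatrix(
        counts=counts.to_numpy(),
        mask=np.asarray(side["mask"]),
        offsets=np.asarray(side["offsets"]),
        county_ids=side["county_ids"],
        interval_labels=side["interval_labels"],
        t0=side["t0"],
    )


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, payload: dict):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=1, default=str))
    return path
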