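"""Georeferencing and classified-track export.

Each image is placed at the navigation fix nearest in UTC time (within a
maximum gap), classified points are summarized as per-class proportions
with before/after deltas, and tracks are exported as RFC 7946 GeoJSON or
CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_MAX_GAP_S = 30.0


def _to_epoch(ts) -> np.ndarray:
    s = pd.to_datetime(pd.Series(ts), utc=True, format="ISO8601")
    return s.astype("int64").to_numpy() / 1e9


def georeference(
    image_times: pd.Series | list,
    nav: pd.DataFrame,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> pd.DataFrame:
    """Nearest-in-time fix per image; ties go to the earlier fix.

    Returns a frame with longitude, latitude, matched_gap_s and a
    ``placed`` flag (False when no fix lies within ``max_gap_s``).
    """
    nav_t = _to_epoch(nav["timestamp_utc"])
    if np.any(np.diff(nav_t) < 0):
        raise ValueError("nav must be sorted by time")
    img_t = _to_epoch(image_times)
    lon = nav["longitude"].to_numpy(dtype=float)
    lat = nav["latitude"].to_numpy(dtype=float)

    right = np.searchsorted(nav_t, img_t, side="left")
    left = np.clip(right - 1, 0, len(nav_t) - 1)
    right = np.clip(right, 0, len(nav_t) - 1)
    d_left = np.abs(img_t - nav_t[left])
    d_right = np.abs(nav_t[right] - img_t)
    use_left = d_left <= d_right  # tie -> earlier fix
    pick = np.where(use_left, left, right)
    gap = np.where(use_left, d_left, d_right)
    placed = gap <= max_gap_s
    return pd.DataFrame(
        {
            "longitude": np.where(placed, lon[pick], np.nan),
            "latitude": np.where(placed, lat[pick], np.nan),
            "matched_gap_s": gap,
            "placed": placed,
        }
    )


def build_classified_points(
    predictions: pd.DataFrame,
    image_times: pd.DataFrame,
    nav: pd.DataFrame,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> pd.DataFrame:
    """Join predictions (image_id, pred_class, confidence) with times
    (image_id, timestamp_utc) and nav into classified track points."""
    df = predictions.merge(image_times[["image_id", "timestamp_utc"]], on="image_id", how="inner")
    geo = georeference(df["timestamp_utc"], nav, max_gap_s)
    out = pd.concat([df.reset_index(drop=True), geo], axis=1)
    return out


def class_proportions(points: pd.DataFrame) -> pd.Series:
    """Per-class fraction over placed points; fractions sum to 1."""
    placed = points[points.get("placed", True) == True] if "placed" in points else points
    if len(placed) == 0:
        raise ValueError("no placed points")
    counts = placed["pred_class"].value_counts().sort_index()
    return counts / counts.sum()


def proportion_delta(before: pd.Series, after: pd.Series) -> pd.Series:
    """Per-class change in percentage points (after - before)."""
    labels = sorted(set(before.index) | set(after.index))
    b = before.reindex(labels, fill_value=0.0)
    a = after.reindex(labels, fill_value=0.0)
    return (a - b) * 100.0


def export_track(points: pd.DataFrame, path: str | Path, fmt: str = "geojson") -> Path:
    """Write classified points as a GeoJSON FeatureCollection or CSV."""
    path = Path(path)
    placed = points[points["placed"]] if "placed" in points else points
    if fmt == "csv":
        cols = ["image_id", "timestamp_utc", "longitude", "latitude", "pred_class", "confidence"]
        placed.to_csv(path, columns=[c for c in cols if c in placed], index=False)
        return path
    if fmt != "geojson":
        raise ValueError(f"unknown format {fmt!r}")
    feats = []
    for _, row in placed.iterrows():
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row["longitude"]), float(row["latitude"])]},
                "properties": {
                    "image_id": str(row["image_id"]),
                    "class": str(row["pred_class"]),
                    "confidence": float(row.get("confidence", float("nan"))),
                    "time": str(row.get("timestamp_utc", "")),
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": feats}
    path.write_text(json.dumps(fc, indent=1))
    return path


def read_track(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for exported GeoJSON tracks."""
    fc = json.loads(Path(path).read_text())
    rows = []
    for f in fc.get("features", []):
        p = f["properties"]
        x, y = f["geometry"]["coordinates"]
        rows.append(
            {
                "image_id": p["image_id"],
                "timestamp_utc": p.get("time", ""),
                "longitude": x,
                "latitude": y,
                "pred_class": p["class"],
                "confidence": p.get("confidence", float("nan")),
            }
        )
    return pd.DataFrame(rows, columns=["image_id", "timestamp_utc", "longitude", "latitude", "pred_class", "confidence"])
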