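"""Domain types and CSV readers/writers for camera-trap tables.

Three tabular inputs drive the analysis:

* ``detections.csv`` — one row per image-level species detection
  (``camera_id,species,timestamp``, ISO 8601 local time);
* ``deployments.csv`` — one row per camera operational interval
  (``camera_id,x,y,feature,start,end``), planar coordinates in metres;
* ``covariates.csv`` — one row per (cluster, survey) with the site-level
  covariates used by the hierarchical detection models.

Timestamps are naive local clock time throughout: the diel analyses map
clock time directly onto the 24-h circle, so timezone arithmetic would only
obscure the quantity of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DetectionEvent",
    "CameraDeployment",
    "CovariateRow",
    "SpeciesConfig",
    "SchemaError",
    "ValidationError",
    "read_detections",
    "read_deployments",
    "read_covariates",
    "write_detections",
    "write_deployments",
    "write_covariates",
    "latlon_to_planar",
    "COVARIATE_RANGES",
]

FEATURES = ("waterhole", "riverbed", "track", "trail")

#: declared inclusive bounds for the ordinal site covariates
COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "visibility": (1.0, 4.0),
    "cover": (1.0, 3.5),
    "water_proximity": (0.0, 3.0),
    "human_use": (0.0, 4.0),
    "lion_longterm": (0.0, 2.0),
}


class SchemaError(ValueError):
    """A required column is missing or a file is structurally unreadable."""


class ValidationError(ValueError):
    """A row violates a declared invariant; the message names the record."""


@dataclass(frozen=True, order=True)
class DetectionEvent:
    """One species detection at one camera at one local timestamp."""

    camera_id: str
    species: str
    timestamp: datetime


@dataclass(frozen=True)
class CameraDeployment:
    """One camera with planar coordinates, site feature and active intervals."""

    camera_id: str
    x: float
    y: float
    feature: str
    active_ranges: tuple[tuple[date, date], ...]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"camera {self.camera_id}: non-finite coordinates")
        if self.feature not in FEATURES:
            raise ValidationError(
                f"camera {self.camera_id}: unknown feature {self.feature!r}"
            )
        ranges = sorted(self.active_ranges)
        for start, end in ranges:
            if end < start:
                raise ValidationError(
                    f"camera {self.camera_id}: active range end {end} before start {start}"
                )
        for (_, e0), (s1, _) in zip(ranges, ranges[1:]):
            if s1 <= e0:
                raise ValidationError(
                    f"camera {self.camera_id}: overlapping active ranges"
                )
        object.__setattr__(self, "active_ranges", tuple(ranges))


@dataclass(frozen=True)
class CovariateRow:
    """Site covariates for one (cluster, survey); bounded ordinals validated."""

    cluster_id: str
    survey_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in COVARIATE_RANGES.items():
            if name in self.values:
                v = self.values[name]
                if not (lo <= v <= hi):
                    raise ValidationError(
                        f"cluster {self.cluster_id}: covariate {name}={v} "
                        f"outside [{lo}, {hi}]"
                    )
        for name, v in self.values.items():
            if isinstance(v, float) and math.isnan(v):
                raise ValidationError(
                    f"cluster {self.cluster_id}: covariate {name} is missing"
                )


@dataclass(frozen=True)
class SpeciesConfig:
    """Focal herbivores, apex predators and co-detection species lists."""

    focal_herbivores: tuple[str, ...]
    predators: tuple[str, ...]
    co_detection_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.focal_herbivores) & set(self.predators)
        if overlap:
            raise ValidationError(
                f"species listed as both herbivore and predator: {sorted(overlap)}"
            )


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_detections(
    path, species_filter: Iterable[str] | None = None
) -> list[DetectionEvent]:
    """Read a detections CSV into sorted, de-duplicated events.

    Rows are filtered to ``species_filter`` when given, exact duplicates are
    dropped, and the result is sorted by (camera_id, species, timestamp) —
    the total order every downstream stage assumes.

    Raises :class:`ValidationError` with the 1-based data line number for an
    unparseable timestamp, :class:`SchemaError` for a missing column.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["camera_id", "species", "timestamp"], str(path))
    if species_filter is not None:
        keep = set(species_filter)
        df = df[df["species"].isin(keep)]
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            ts = datetime.fromisoformat(row.timestamp)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: line {i}: unparseable timestamp {row.timestamp!r}"
            ) from exc
        events.append(DetectionEvent(str(row.camera_id), str(row.species), ts))
    return sorted(set(events))


def read_deployments(path) -> list[CameraDeployment]:
    """Read a deployments CSV (one row per active range) into validated records."""
    df = pd.read_csv(path, dtype={"camera_id": str, "feature": str})
    _require_columns(df, ["camera_id", "x", "y", "feature", "start", "end"], str(path))
    out = []
    for cam, grp in df.groupby("camera_id", sort=True):
        xs, ys = grp["x"].astype(float), grp["y"].astype(float)
        feats = grp["feature"].unique()
        if len(feats) > 1:
            raise ValidationError(f"camera {cam}: conflicting features {list(feats)}")
        if xs.nunique() > 1 or ys.nunique() > 1:
            raise ValidationError(f"camera {cam}: conflicting coordinates")
        ranges = tuple(
            (date.fromisoformat(str(s)), date.fromisoformat(str(e)))
            for s, e in zip(grp["start"], grp["end"])
        )
        out.append(
            CameraDeployment(str(cam), float(xs.iloc[0]), float(ys.iloc[0]),
                             str(feats[0]), ranges)
        )
    return out


def read_covariates(path) -> list[CovariateRow]:
    """Read a covariates CSV into validated per-(cluster, survey) records."""
    df = pd.read_csv(path, dtype={"cluster_id": str, "survey_id": str})
    _require_columns(df, ["cluster_id", "survey_id"], str(path))
    value_cols = [c for c in df.columns if c not in ("cluster_id", "survey_id")]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        values = {}
        for c in value_cols:
            v = d[c]
            values[c] = v if isinstance(v, str) else float(v)
        out.append(CovariateRow(str(d["cluster_id"]), str(d["survey_id"]), values))
    return out


def write_detections(events: Iterable[DetectionEvent], path) -> None:
    pd.DataFrame(
        [
            {"camera_id": e.camera_id, "species": e.species,
             "timestamp": e.timestamp.isoformat()}
            for e in events
        ],
        columns=["camera_id", "species", "timestamp"],
    ).to_csv(path, index=False)


def write_deployments(deployments: Iterable[CameraDeployment], path) -> None:
    rows = []
    for d in deployments:
        for start, end in d.active_ranges:
            rows.append(
                {"camera_id": d.camera_id, "x": d.x, "y": d.y,
                 "feature": d.feature,
                 "start": start.isoformat(), "end": end.isoformat()}
            )
    pd.DataFrame(rows, columns=["camera_id", "x", "y", "feature", "start", "end"]
                 ).to_csv(path, index=False)


def write_covariates(rows: Iterable[CovariateRow], path) -> None:
    recs = [{"cluster_id": r.cluster_id, "survey_id": r.survey_id, **r.values}
            for r in rows]
    pd.DataFrame(recs).to_csv(path, index=False)


def latlon_to_planar(
    lat, lon, lat0: float, lon0: float
) -> tuple:
    """Project lat/lon (degrees) to local planar metres.

    Local equirectangular approximation about (``lat0``, ``lon0``) — adequate
    at the ~150 m scale of camera clustering, where projection error is
    sub-metre.
    """
    import numpy as np

    r_earth = 6_371_000.0
    lat, lon = np.asarray(lat, float), np.asarray(lon, float)
    x = np.radians(lon - lon0) * r_earth * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * r_earth
    return x, y
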