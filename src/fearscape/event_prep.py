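"""Camera clustering, effort accounting, independence filtering, rates.

Cameras sharing a landscape feature within ~150 m are merged into *camera
clusters*, the sampling unit for every downstream analysis; detections of
the same species at the same cluster within 30 min are collapsed to the
first one (the independence rule), limiting pseudo-replication from animals
lingering in front of a camera. Detection rates are expressed per 100
camera-nights so clusters with unequal effort are comparable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from fearscape.data_model import (
    CameraDeployment,
    DetectionEvent,
    SchemaError,
    ValidationError,
)

__all__ = [
    "CameraCluster",
    "cluster_cameras",
    "camera_nights",
    "filter_independent",
    "detection_rate",
    "prepare_covariates",
    "PreparedCovariates",
]


@dataclass(frozen=True)
class CameraCluster:
    """A group of same-feature cameras treated as one sampling unit."""

    cluster_id: str
    camera_ids: tuple[str, ...]
    centroid: tuple[float, float]
    feature: str


def cluster_cameras(
    deployments: Sequence[CameraDeployment],
    radius: float = 150.0,
    cluster_map: Mapping[str, str] | None = None,
) -> list[CameraCluster]:
    """Partition cameras into clusters of same-feature neighbours.

    Greedy agglomeration, deterministic by construction: within each feature
    class cameras are processed in ``camera_id`` order; each unassigned
    camera seeds a cluster which then absorbs any unassigned same-feature
    camera within ``radius`` metres of the running centroid, recomputing the
    centroid after every absorption.

    A user-supplied ``cluster_map`` (camera_id -> cluster_id) overrides the
    algorithm entirely, mirroring field practice where clusters are drawn by
    the deployment team.
    """
    if not deployments:
        raise ValueError("no deployments to cluster")
    by_id = {d.camera_id: d for d in deployments}

    if cluster_map is not None:
        groups: dict[str, list[CameraDeployment]] = {}
        for cam in sorted(by_id):
            cid = cluster_map.get(cam)
            if cid is None:
                raise SchemaError(f"camera {cam} missing from supplied cluster map")
            groups.setdefault(cid, []).append(by_id[cam])
        clusters = []
        for cid in sorted(groups):
            members = groups[cid]
            feats = {m.feature for m in members}
            if len(feats) > 1:
                raise ValidationError(
                    f"cluster {cid}: mixed features {sorted(feats)}"
                )
            cx = float(np.mean([m.x for m in members]))
            cy = float(np.mean([m.y for m in members]))
            clusters.append(
                CameraCluster(cid, tuple(m.camera_id for m in members),
                              (cx, cy), members[0].feature)
            )
        _warn_large(clusters)
        return clusters

    clusters = []
    assigned: set[str] = set()
    features = sorted({d.feature for d in deployments})
    idx = 0
    for feat in features:
        cams = [by_id[c] for c in sorted(by_id) if by_id[c].feature == feat]
        for seed in cams:
            if seed.camera_id in assigned:
                continue
            members = [seed]
            assigned.add(seed.camera_id)
            cx, cy = seed.x, seed.y
            # single forward pass; centroid drifts as members are absorbed
            changed = True
            while changed:
                changed = False
                for cand in cams:
                    if cand.camera_id in assigned:
                        continue
                    if math.hypot(cand.x - cx, cand.y - cy) <= radius:
                        members.append(cand)
                        assigned.add(cand.camera_id)
                        cx = float(np.mean([m.x for m in members]))
                        cy = float(np.mean([m.y for m in members]))
                        changed = True
            idx += 1
            clusters.append(
                CameraCluster(f"C{idx:03d}",
                              tuple(m.camera_id for m in members),
                              (cx, cy), feat)
            )
    _warn_large(clusters)
    return clusters


def _warn_large(clusters: Iterable[CameraCluster]) -> None:
    for c in clusters:
        if len(c.camera_ids) > 9:
            warnings.warn(
                f"cluster {c.cluster_id} has {len(c.camera_ids)} cameras "
                "(field protocol groups 1-9)",
                stacklevel=3,
            )


def camera_nights(
    cluster: CameraCluster,
    deployments: Sequence[CameraDeployment],
    window: tuple[date, date] | None = None,
) -> float:
    """Operational camera-nights for a cluster within an optional date window.

    One camera-night = one operational calendar day of one member camera;
    partial first/last days count as a full night. Summed over members.
    """
    by_id = {d.camera_id: d for d in deployments}
    total = 0
    for cam in cluster.camera_ids:
        dep = by_id.get(cam)
        if dep is None:
            raise SchemaError(f"camera {cam} of cluster {cluster.cluster_id} "
                              "has no deployment record")
        for start, end in dep.active_ranges:
            if window is not None:
                w0, w1 = window
                if w1 < w0:
                    raise ValueError("empty window")
                start, end = max(start, w0), min(end, w1)
            if end >= start:
                total += (end - start).days + 1
    return float(total)


def _camera_to_cluster(clusters: Sequence[CameraCluster]) -> dict[str, str]:
    out = {}
    for c in clusters:
        for cam in c.camera_ids:
            out[cam] = c.cluster_id
    return out


def filter_independent(
    events: Sequence[DetectionEvent],
    clusters: Sequence[CameraCluster],
    window_minutes: float = 30.0,
    group_by: str = "cluster",
) -> list[DetectionEvent]:
    """Apply the independence rule within each (group, species) stream.

    An event is retained iff it falls at least ``window_minutes`` after the
    previously *retained* event of the same species in the same group (the
    first event of a stream is always retained). ``group_by`` is ``cluster``
    (default) or ``camera`` — the latter reproduces the no-clustering
    sensitivity analysis.

    The rule is idempotent: gaps between retained events are all >= the
    window, so a second pass retains everything.
    """
    if group_by not in ("cluster", "camera"):
        raise ValueError(f"group_by must be 'cluster' or 'camera', got {group_by!r}")
    cam2clu = _camera_to_cluster(clusters)
    delta = timedelta(minutes=window_minutes)

    def key(e: DetectionEvent) -> tuple[str, str]:
        if group_by == "camera":
            return (e.camera_id, e.species)
        cid = cam2clu.get(e.camera_id)
        if cid is None:
            raise SchemaError(f"event camera {e.camera_id} not in any cluster")
        return (cid, e.species)

    streams: dict[tuple[str, str], list[DetectionEvent]] = {}
    for e in sorted(events, key=lambda e: (e.timestamp, e.camera_id, e.species)):
        streams.setdefault(key(e), []).append(e)

    kept: list[DetectionEvent] = []
    for stream in streams.values():
        last = None
        for e in stream:
            if last is None or e.timestamp - last >= delta:
                kept.append(e)
                last = e.timestamp
    return sorted(kept)


def detection_rate(
    events_after_filter: Sequence[DetectionEvent],
    effort: Mapping[str, float],
    species: str,
    clusters: Sequence[CameraCluster],
) -> pd.Series:
    """Detections per 100 camera-nights per cluster for one species.

    ``effort`` maps cluster_id -> camera-nights. Clusters with zero effort
    and zero detections report 0; zero effort with detections is an error.
    """
    cam2clu = _camera_to_cluster(clusters)
    counts: dict[str, int] = {c.cluster_id: 0 for c in clusters}
    for e in events_after_filter:
        if e.species != species:
            continue
        cid = cam2clu.get(e.camera_id)
        if cid is None:
            raise SchemaError(f"event camera {e.camera_id} not in any cluster")
        counts[cid] += 1
    rates = {}
    for cid, n in counts.items():
        nights = float(effort.get(cid, 0.0))
        if nights <= 0:
            if n > 0:
                raise ValidationError(
                    f"cluster {cid}: {n} detections but zero camera-nights"
                )
            rates[cid] = 0.0
        else:
            rates[cid] = 100.0 * n / nights
    return pd.Series(rates, name=f"{species}_rate").sort_index()


@dataclass(frozen=True)
class PreparedCovariates:
    """Transformed covariate table plus the metadata to invert the transforms."""

    data: pd.DataFrame
    log1p_columns: tuple[str, ...]
    zscore_means: dict[str, float]
    zscore_sds: dict[str, float]


def prepare_covariates(
    rows: pd.DataFrame,
    log1p_columns: Sequence[str] = (),
    zscore_columns: Sequence[str] = (),
) -> PreparedCovariates:
    """log(1+x) then z-score named numeric columns, recording the transforms.

    log1p is applied before standardisation when a column appears in both
    lists (skew is stabilised first, then the scale removed). A constant
    column requested for z-scoring is an error — it carries no information
    and would divide by zero.
    """
    df = rows.copy()
    for col in list(log1p_columns) + list(zscore_columns):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not in covariate table")
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"column {col!r} is not numeric")
    for col in log1p_columns:
        if (df[col] < 0).any():
            raise ValidationError(f"column {col!r} has negative values under log1p")
        df[col] = np.log1p(df[col].astype(float))
    means, sds = {}, {}
    for col in zscore_columns:
        sd = float(df[col].std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValidationError(f"column {col!r} is constant; cannot z-score")
        mu = float(df[col].mean())
        df[col] = (df[col].astype(float) - mu) / sd
        means[col], sds[col] = mu, sd
    return PreparedCovariates(df, tuple(log1p_columns), means, sds)
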