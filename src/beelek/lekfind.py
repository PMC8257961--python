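"""Drone congregation area (DCA) discovery.

Candidate congregation areas are found by clustering the positional fixes of
convoluted-flight sections that happened away from hives: sections whose
center of mass lies within 50 m of a hive are excluded first (drones also
perform convoluted flight in front of their own hive, which is not lekking),
then the remaining fixes are clustered by single-linkage agglomerative
clustering on Euclidean distance with an 8 m cutoff — two fixes share a
cluster iff they are connected by a chain of steps each no longer than the
cutoff.  Clusters fed by at least 10 distinct flight segments are retained
as congregations; requiring many independent visits discards the many small
clusters produced by a single bout of convoluted flight elsewhere.

The center of each congregation is the center of mass of its member fixes
(robust to a few perimeter points); the convex hull is attached for
illustration only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from .flightseg import CONVOLUTED, FlightSection
from .trackio import FlightSegment, HiveRecord

logger = logging.getLogger("beelek")

#: above this many fixes, single linkage switches to the KD-tree
#: connected-components route (identical partition, linear memory)
_LINKAGE_MATRIX_LIMIT = 4000


@dataclass(frozen=True)
class ClusterParams:
    hive_exclusion_m: float = 50.0
    linkage_cutoff_m: float = 8.0
    min_segments: int = 10
    linkage: str = "single"
    active_hives_only: bool = True

    def __post_init__(self) -> None:
        if min(self.hive_exclusion_m, self.linkage_cutoff_m, self.min_segments) <= 0:
            raise ValueError("cluster parameters must be positive")
        if self.linkage not in ("single", "complete", "average"):
            raise ValueError(f"unsupported linkage {self.linkage!r}")


@dataclass(frozen=True)
class Congregation:
    area_id: str
    center: tuple[float, float]
    hull: np.ndarray  # (k, 2) hull vertex coordinates
    members: pd.DataFrame  # segment_id, fix_index, x, y
    n_segments: int

    @property
    def n_fixes(self) -> int:
        return len(self.members)


def collect_convoluted_fixes(
    classified: Sequence[tuple[FlightSegment, Sequence[FlightSection]]],
    hives: Sequence[HiveRecord],
    params: ClusterParams | None = None,
) -> pd.DataFrame:
    """Fixes of convoluted sections whose center of mass is more than
    ``hive_exclusion_m`` from every (active) hive.

    By default only hives occupied at the flight's start time count; set
    ``active_hives_only=False`` to exclude around every hive site regardless
    of occupancy.  Segments without an absolute start time are checked
    against all hives.  Returns a frame with columns segment_id, fix_index,
    x, y.
    """
    params = params or ClusterParams()
    rows = []
    for seg, sections in classified:
        if params.active_hives_only:
            hive_pos = [h.position for h in hives if h.is_active(seg.start_time)]
        else:
            hive_pos = [h.position for h in hives]
        hp = np.asarray(hive_pos, dtype=float).reshape(-1, 2)
        for sec in sections:
            if sec.label != CONVOLUTED:
                continue
            cx, cy = sec.center_of_mass
            if hp.size and np.hypot(hp[:, 0] - cx, hp[:, 1] - cy).min() <= params.hive_exclusion_m:
                continue
            xy = seg.xy[sec.start : sec.stop]
            for k, (x, y) in enumerate(xy, start=sec.start):
                rows.append((seg.segment_id, k, float(x), float(y)))
    return pd.DataFrame(rows, columns=["segment_id", "fix_index", "x", "y"])


def cluster_fixes(points: np.ndarray, params: ClusterParams | None = None) -> np.ndarray:
    """Cluster (n, 2) points; returns integer labels of length n.

    Single linkage cut at a distance is exactly the connected components of
    the <= cutoff adjacency graph, so for large inputs it is computed with a
    KD-tree and union-find instead of the O(n^2) linkage matrix; complete
    and average linkage always go through the hierarchy.
    """
    params = params or ClusterParams()
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.zeros(1, dtype=int)
    if params.linkage == "single" and n > _LINKAGE_MATRIX_LIMIT:
        return _components_within(pts, params.linkage_cutoff_m)
    z = linkage(pts, method=params.linkage)
    return fcluster(z, t=params.linkage_cutoff_m, criterion="distance") - 1


def _components_within(pts: np.ndarray, cutoff: float) -> np.ndarray:
    tree = cKDTree(pts)
    parent = np.arange(len(pts))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(r=cutoff, output_type="ndarray"):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.fromiter((find(i) for i in range(len(pts))), dtype=int)
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def _hull_coords(xy: np.ndarray) -> np.ndarray:
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    if hull.geom_type == "Polygon":
        return np.asarray(hull.exterior.coords)
    return np.asarray(hull.coords)  # degenerate: point or collinear line


def _area_id(i: int) -> str:
    # A, B, ... Z, AA, AB, ... for overflow
    name = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        name = chr(ord("A") + rem) + name
    return name


def select_congregations(
    labels: np.ndarray, fixes: pd.DataFrame, params: ClusterParams | None = None
) -> list[Congregation]:
    """Retain clusters fed by at least ``min_segments`` distinct segments,
    ordered by contributing-segment count (descending), labelled A, B, C...
    """
    params = params or ClusterParams()
    fixes = fixes.assign(cluster=labels)
    keep = []
    for cl, grp in fixes.groupby("cluster"):
        n_seg = grp["segment_id"].nunique()
        if n_seg >= params.min_segments:
            keep.append((n_seg, len(grp), cl, grp))
    # deterministic order: by segment count desc, fix count desc, then center
    keep.sort(key=lambda item: (-item[0], -item[1], item[3]["x"].mean(), item[3]["y"].mean()))
    out = []
    for i, (n_seg, _n_fix, _cl, grp) in enumerate(keep):
        xy = grp[["x", "y"]].to_numpy()
        center = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
        out.append(
            Congregation(
                area_id=_area_id(i),
                center=center,
                hull=_hull_coords(xy),
                members=grp.drop(columns="cluster").reset_index(drop=True),
                n_segments=int(n_seg),
            )
        )
    return out


def discover_congregations(
    classified: Sequence[tuple[FlightSegment, Sequence[FlightSection]]],
    hives: Sequence[HiveRecord],
    params: ClusterParams | None = None,
) -> list[Congregation]:
    """End-to-end DCA discovery: collect qualifying convoluted fixes,
    cluster, and retain multi-segment clusters."""
    params = params or ClusterParams()
    fixes = collect_convoluted_fixes(classified, hives, params)
    if fixes.empty:
        return []
    labels = cluster_fixes(fixes[["x", "y"]].to_numpy(), params)
    return select_congregations(labels, fixes, params)


def congregations_table(areas: Sequence[Congregation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "area_id": a.area_id,
                "center_x": a.center[0],
                "center_y": a.center[1],
                "n_segments": a.n_segments,
                "n_fixes": a.n_fixes,
            }
            for a in areas
        ],
        columns=["area_id", "center_x", "center_y", "n_segments", "n_fixes"],
    )


def cluster_params_from_dict(raw: dict | None) -> ClusterParams:
    p = ClusterParams()
    if raw:
        p = replace(p, **{k: v for k, v in raw.items() if k in ClusterParams.__dataclass_fields__})
    return p
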