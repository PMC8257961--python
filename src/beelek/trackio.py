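"""Track data model, coordinate conversion, and file I/O.

Harmonic radar reports the position of a tagged insect once per antenna
rotation (~3 s) as (range, azimuth) polar coordinates about the radar dish.
This module converts those records into a planar east-north-up (ENU) frame in
meters anchored at the radar origin, groups fixes into flight segments (the
runs of fixes unambiguously attributable to one flight by one individual),
and applies the segment-level "substantial flight" filter: a segment is
substantial when it lasts at least 30 s and the bee moved at least 15 m from
its starting position.

Geographic export uses a similarity transform (translation + rotation +
scale) calibrated from two reference points of known GPS position, standing
in for the field triangulation; at <= 800 m range a planar equirectangular
frame is accurate to well under the radar's ~2 m positional error.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("beelek")

EARTH_RADIUS_M = 6_371_008.8

#: substantial-flight thresholds (inclusive: >= 30 s and >= 15 m)
MIN_SUBSTANTIAL_DURATION_S = 30.0
MIN_SUBSTANTIAL_DISPLACEMENT_M = 15.0

DEFAULT_MAX_RANGE_M = 800.0
RANGE_TOLERANCE_M = 50.0


class TrackFormatError(ValueError):
    """A track file is missing required columns or is otherwise malformed."""


class TrackValidationError(ValueError):
    """A track file parses but violates a data invariant (bad azimuth,
    non-monotone timestamps within a segment, ...)."""


# ---------------------------------------------------------------------------
# site metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HiveRecord:
    """A hive location in the local frame with its period of occupancy."""

    hive_id: str
    position: tuple[float, float]  # (x, y) meters, local ENU frame
    active_interval: tuple[datetime, datetime] | None = None

    def __post_init__(self) -> None:
        x, y = self.position
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(f"hive {self.hive_id}: non-finite position")
        if self.active_interval is not None:
            start, end = self.active_interval
            if start > end:
                raise ValueError(f"hive {self.hive_id}: active interval start > end")

    def is_active(self, when: datetime | None) -> bool:
        """True if the hive was occupied at ``when``.

        An unknown time (``None``) or an open interval counts as active: when
        we cannot rule a hive out, we keep it.
        """
        if when is None or self.active_interval is None:
            return True
        start, end = self.active_interval
        return start <= when <= end


@dataclass(frozen=True)
class ReferencePoint:
    """A calibration landmark: known GPS position and known local position."""

    lat: float
    lon: float
    x: float
    y: float


@dataclass
class SiteConfig:
    """Radar site metadata: origin, calibration points, hives, parameters.

    ``params`` carries the pipeline parameter sections (classifier, cluster,
    bridge, simulate) read from the site config file; each stage constructs
    its own parameter object from the matching section.
    """

    radar_origin: tuple[float, float]  # (lat, lon)
    reference_points: tuple[ReferencePoint, ReferencePoint]
    hives: list[HiveRecord]
    azimuth_convention: str = "cw_from_north"
    max_range_m: float = DEFAULT_MAX_RANGE_M
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.hives:
            raise ValueError("site config must declare at least one hive")
        ids = [h.hive_id for h in self.hives]
        if len(set(ids)) != len(ids):
            raise ValueError("hive_id values must be unique within a site")
        a, b = self.reference_points
        if (a.lat, a.lon) == (b.lat, b.lon):
            raise ValueError("reference points must be distinct")
        for rp in (a, b):
            if (rp.lat, rp.lon) == tuple(self.radar_origin):
                raise ValueError("reference points must differ from the radar origin")
        if self.azimuth_convention not in ("cw_from_north", "ccw_from_east"):
            raise ValueError(f"unknown azimuth convention {self.azimuth_convention!r}")

    # -- geographic calibration -------------------------------------------

    def _geo_to_enu(self, lat: float, lon: float) -> tuple[float, float]:
        """Equirectangular meters of a geographic point about the origin."""
        lat0, lon0 = self.radar_origin
        east = math.radians(lon - lon0) * EARTH_RADIUS_M * math.cos(math.radians(lat0))
        north = math.radians(lat - lat0) * EARTH_RADIUS_M
        return east, north

    @cached_property
    def _local_to_geo_transform(self) -> tuple[complex, complex, float]:
        """Similarity transform w = a*z + b mapping local (x, y) to
        geographic ENU meters, solved from the two reference points.

        Two point pairs determine the four degrees of freedom exactly, so the
        residual is zero by construction; it is still computed and reported
        so that a future fit over more landmarks surfaces miscalibration.
        """
        (p, q) = self.reference_points
        z1, z2 = complex(p.x, p.y), complex(q.x, q.y)
        w1 = complex(*self._geo_to_enu(p.lat, p.lon))
        w2 = complex(*self._geo_to_enu(q.lat, q.lon))
        if z1 == z2:
            raise ValueError("reference points coincide in the local frame")
        a = (w2 - w1) / (z2 - z1)
        b = w1 - a * z1
        residual = max(abs(a * z + b - w) for z, w in ((z1, w1), (z2, w2)))
        return a, b, residual

    @property
    def calibration_residual_m(self) -> float:
        return self._local_to_geo_transform[2]

    def local_to_geographic(self, x: float, y: float) -> tuple[float, float]:
        """Map local-frame meters to (lat, lon) WGS84 degrees."""
        a, b, _ = self._local_to_geo_transform
        w = a * complex(x, y) + b
        lat0, lon0 = self.radar_origin
        lat = lat0 + math.degrees(w.imag / EARTH_RADIUS_M)
        lon = lon0 + math.degrees(w.real / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
        return lat, lon


def load_site_config(path: str | Path) -> SiteConfig:
    """Read a YAML site config (documented schema in the README)."""
    raw = yaml.safe_load(Path(path).read_text())
    origin = (float(raw["radar_origin"]["lat"]), float(raw["radar_origin"]["lon"]))
    refs = tuple(
        ReferencePoint(float(r["lat"]), float(r["lon"]), float(r["x"]), float(r["y"]))
        for r in raw["reference_points"]
    )
    if len(refs) != 2:
        raise TrackFormatError("site config must list exactly 2 reference points")
    hives = []
    for h in raw["hives"]:
        interval = None
        if h.get("active"):
            start, end = h["active"]
            interval = (_parse_dt(start), _parse_dt(end))
        hives.append(HiveRecord(str(h["hive_id"]), (float(h["x"]), float(h["y"])), interval))
    return SiteConfig(
        radar_origin=origin,
        reference_points=refs,  # type: ignore[arg-type]
        hives=hives,
        azimuth_convention=raw.get("azimuth_convention", "cw_from_north"),
        max_range_m=float(raw.get("max_range_m", DEFAULT_MAX_RANGE_M)),
        params=raw.get("params", {}) or {},
    )


def write_site_config(site: SiteConfig, path: str | Path) -> None:
    doc = {
        "radar_origin": {"lat": site.radar_origin[0], "lon": site.radar_origin[1]},
        "reference_points": [
            {"lat": r.lat, "lon": r.lon, "x": r.x, "y": r.y} for r in site.reference_points
        ],
        "hives": [
            {
                "hive_id": h.hive_id,
                "x": h.position[0],
                "y": h.position[1],
                "active": (
                    [h.active_interval[0].isoformat(), h.active_interval[1].isoformat()]
                    if h.active_interval
                    else None
                ),
            }
            for h in site.hives
        ],
        "azimuth_convention": site.azimuth_convention,
        "max_range_m": site.max_range_m,
        "params": site.params,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _parse_dt(value) -> datetime:
    if isinstance(value, datetime):
        return value
    return datetime.fromisoformat(str(value))


# ---------------------------------------------------------------------------
# fixes and segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadarFix:
    """One positional detection.

    ``t`` is seconds relative to the segment start; polar coordinates are
    kept when the record arrived polar, and (x, y) local meters are always
    present after conversion.
    """

    t: float
    x: float
    y: float
    range_m: float | None = None
    azimuth_deg: float | None = None


@dataclass
class FlightSegment:
    """An ordered run of fixes attributable to one flight by one individual."""

    segment_id: str
    fixes: list[RadarFix]
    drone_id: str | None = None
    hive_id: str | None = None
    year: int | None = None
    start_time: datetime | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.fixes) < 2:
            raise TrackValidationError(
                f"segment {self.segment_id!r}: needs >= 2 fixes, got {len(self.fixes)}"
            )
        t = np.asarray([f.t for f in self.fixes])
        if not np.all(np.diff(t) > 0):
            raise TrackValidationError(
                f"segment {self.segment_id!r}: timestamps not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.fixes)

    @cached_property
    def times(self) -> np.ndarray:
        return np.asarray([f.t for f in self.fixes], dtype=float)

    @cached_property
    def xy(self) -> np.ndarray:
        return np.asarray([(f.x, f.y) for f in self.fixes], dtype=float)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class SegmentSummary:
    duration_s: float
    max_displacement_m: float
    mean_speed_ms: float
    substantial: bool


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def polar_to_local(
    range_m,
    azimuth_deg,
    site: SiteConfig | None = None,
    convention: str | None = None,
):
    """Convert radar (range, azimuth) to local ENU meters.

    The default convention is azimuth in degrees clockwise from true north
    (the radar/navigation convention): x = r sin(az), y = r cos(az).  Accepts
    scalars or arrays.
    """
    conv = convention or (site.azimuth_convention if site else "cw_from_north")
    r = np.asarray(range_m, dtype=float)
    az = np.asarray(azimuth_deg, dtype=float)
    if np.any(r < 0):
        raise ValueError("range must be non-negative")
    theta = np.deg2rad(az)
    if conv == "cw_from_north":
        x, y = r * np.sin(theta), r * np.cos(theta)
    elif conv == "ccw_from_east":
        x, y = r * np.cos(theta), r * np.sin(theta)
    else:
        raise ValueError(f"unknown azimuth convention {conv!r}")
    if np.ndim(range_m) == 0 and np.ndim(azimuth_deg) == 0:
        return float(x), float(y)
    return x, y


def local_to_polar(x, y, convention: str = "cw_from_north"):
    """Inverse of :func:`polar_to_local` (azimuth wrapped to [0, 360))."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    r = np.hypot(xa, ya)
    if convention == "cw_from_north":
        az = np.rad2deg(np.arctan2(xa, ya)) % 360.0
    elif convention == "ccw_from_east":
        az = np.rad2deg(np.arctan2(ya, xa)) % 360.0
    else:
        raise ValueError(f"unknown azimuth convention {convention!r}")
    if np.ndim(x) == 0 and np.ndim(y) == 0:
        return float(r), float(az)
    return r, az


# ---------------------------------------------------------------------------
# track file I/O
# ---------------------------------------------------------------------------

_IDENTITY_COLS = ("drone_id", "hive_id", "year", "start_time")


def read_tracks(path: str | Path, site: SiteConfig | None = None) -> list[FlightSegment]:
    """Read a delimited track file into flight segments.

    Required columns: ``segment_id``, ``t``, and either (``range_m``,
    ``azimuth_deg``) or (``x``, ``y``).  Optional identity columns
    (``drone_id``, ``hive_id``, ``year``, ``start_time``) are constant per
    segment.  Polar records are converted via :func:`polar_to_local`; rows
    are sorted by ``t`` within each segment.
    """
    df = pd.read_csv(path)
    if "segment_id" not in df.columns or "t" not in df.columns:
        raise TrackFormatError("track file needs 'segment_id' and 't' columns")
    has_polar = {"range_m", "azimuth_deg"}.issubset(df.columns)
    has_xy = {"x", "y"}.issubset(df.columns)
    if not (has_polar or has_xy):
        raise TrackFormatError(
            "track file needs either ('range_m', 'azimuth_deg') or ('x', 'y') columns"
        )
    if has_polar:
        az = df["azimuth_deg"].to_numpy(dtype=float)
        if np.any((az < 0) | (az >= 360)):
            raise TrackValidationError("azimuth_deg must lie in [0, 360)")
        if np.any(df["range_m"].to_numpy(dtype=float) < 0):
            raise TrackValidationError("range_m must be non-negative")

    max_range = site.max_range_m if site else DEFAULT_MAX_RANGE_M
    segments: list[FlightSegment] = []
    for seg_id, grp in df.groupby("segment_id", sort=True):
        grp = grp.sort_values("t", kind="stable")
        t = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TrackValidationError(
                f"segment {seg_id!r}: duplicate or non-monotone timestamps"
            )
        if has_polar:
            r = grp["range_m"].to_numpy(dtype=float)
            az = grp["azimuth_deg"].to_numpy(dtype=float)
            x, y = polar_to_local(r, az, site)
            fixes = [
                RadarFix(float(ti), float(xi), float(yi), float(ri), float(azi))
                for ti, xi, yi, ri, azi in zip(t, x, y, r, az)
            ]
        else:
            x = grp["x"].to_numpy(dtype=float)
            y = grp["y"].to_numpy(dtype=float)
            fixes = [RadarFix(float(ti), float(xi), float(yi)) for ti, xi, yi in zip(t, x, y)]
        rr = np.hypot([f.x for f in fixes], [f.y for f in fixes])
        if np.any(rr > max_range + RANGE_TOLERANCE_M):
            raise TrackValidationError(
                f"segment {seg_id!r}: fix beyond max range {max_range:.0f} m"
            )
        kwargs = {}
        for col in _IDENTITY_COLS:
            if col in grp.columns:
                val = grp[col].iloc[0]
                if pd.isna(val):
                    continue
                if col == "year":
                    kwargs[col] = int(val)
                elif col == "start_time":
                    kwargs[col] = _parse_dt(val)
                else:
                    kwargs[col] = str(val)
        segments.append(FlightSegment(str(seg_id), fixes, **kwargs))
    return segments


def write_tracks(segments: Iterable[FlightSegment], path: str | Path) -> None:
    """Write segments as a track CSV in local Cartesian coordinates."""
    rows = []
    for seg in segments:
        for f in seg.fixes:
            rows.append(
                {
                    "segment_id": seg.segment_id,
                    "t": f.t,
                    "x": f.x,
                    "y": f.y,
                    "drone_id": seg.drone_id,
                    "hive_id": seg.hive_id,
                    "year": seg.year,
                    "start_time": seg.start_time.isoformat() if seg.start_time else None,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_geojson(segments: Iterable[FlightSegment], site: SiteConfig, path: str | Path) -> None:
    """Export segments as WGS84 GeoJSON LineStrings (lon-lat order)."""
    features = []
    for seg in segments:
        coords = []
        for f in seg.fixes:
            lat, lon = site.local_to_geographic(f.x, f.y)
            coords.append([round(lon, 7), round(lat, 7)])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {
                    "segment_id": seg.segment_id,
                    "drone_id": seg.drone_id,
                    "hive_id": seg.hive_id,
                    "year": seg.year,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


# ---------------------------------------------------------------------------
# segment summaries and filtering
# ---------------------------------------------------------------------------

def summarize_segment(seg: FlightSegment) -> SegmentSummary:
    """Duration, maximum displacement from the first fix, mean speed, and the
    substantial-flight verdict for one segment."""
    t = seg.times
    xy = seg.xy
    duration = float(t[-1] - t[0])
    disp = np.hypot(*(xy - xy[0]).T)
    max_disp = float(disp.max())
    steps = np.hypot(*np.diff(xy, axis=0).T)
    speeds = steps / np.diff(t)
    mean_speed = float(speeds.mean())
    substantial = (
        duration >= MIN_SUBSTANTIAL_DURATION_S
        and max_disp >= MIN_SUBSTANTIAL_DISPLACEMENT_M
    )
    return SegmentSummary(duration, max_disp, mean_speed, substantial)


def filter_substantial(
    segments: Sequence[FlightSegment],
) -> tuple[list[FlightSegment], list[FlightSegment]]:
    """Partition segments into (substantial, rejected).

    Rejected segments are returned, not discarded: too-short segments still
    carry evidence of where drones flew and feed the occupancy heat maps.
    """
    kept, rejected = [], []
    for seg in segments:
        (kept if summarize_segment(seg).substantial else rejected).append(seg)
    return kept, rejected
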