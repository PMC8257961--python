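"""Swarm-cohesion dynamics at congregation areas and hives.

Convoluted flight near a congregation center behaves like flight in an
effective elastic potential well: the mean acceleration conditioned on
position points back toward the center and grows linearly with distance,
while the overall (unconditional) mean acceleration is ~0 at stationarity.
This module builds the kinematic samples (finite-difference velocities and
accelerations relative to a reference center), fits the well by ordinary
least squares of acceleration on position — the fitted slope is minus the
well stiffness, and the x-intercept -intercept/slope locates the point of
zero mean acceleration — and computes the companion diagnostics: 5 m binned
acceleration profiles, Pearson kurtosis of position/velocity distributions
(Gaussian reference 3; mating-swarm cores are near-Gaussian, hive flight is
heavier-tailed), and normal-probability points for the Gaussian-core check.

It also detects lek visits: a flight visits an area when a convoluted
section's center of mass is within 50 m of the area center, or when the bee
dwells within 50 m for at least 21 s, bridging radar-signal losses whose
flanking fixes are both inside the disc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .flightseg import CONVOLUTED, FlightSection
from .lekfind import Congregation
from .trackio import FlightSegment, HiveRecord

logger = logging.getLogger("beelek")

ASSIGN_RADIUS_M = 50.0
DWELL_MIN_S = 21.0
#: gap-severing thresholds shared with the classifier
SEVER_GAP_S = 12.0
SEVER_STEP_M = 40.0

_SAMPLE_COLUMNS = ["t", "x_rel", "y_rel", "vx", "vy", "ax", "ay", "segment_id", "location_id"]


@dataclass(frozen=True)
class WellFit:
    """OLS fit of one acceleration component on the matching position
    component; slope has units 1/s^2 (minus the effective stiffness)."""

    axis: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    p_value: float
    n: int

    @property
    def x_intercept(self) -> float:
        """Position of zero mean acceleration, -intercept/slope (m)."""
        if self.slope == 0:
            return float("nan")
        return -self.intercept / self.slope


@dataclass(frozen=True)
class BinnedProfile:
    axis: str
    bin_edges: np.ndarray
    mean_accel: np.ndarray  # nan for empty bins
    se: np.ndarray
    n: np.ndarray

    @property
    def empty_bins(self) -> np.ndarray:
        return self.n == 0


@dataclass(frozen=True)
class Visit:
    segment_id: str
    area_id: str
    basis: str  # "convoluted_com" | "dwell"
    t_start: float
    t_end: float


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def kinematics(
    seg: FlightSegment,
    section: FlightSection,
    center: tuple[float, float],
    location_id: str = "",
    dt_mode: str = "trailing",
) -> pd.DataFrame:
    """Finite-difference kinematic samples for one section.

    Velocities are per-transition displacements over the time difference;
    accelerations difference consecutive velocities over the trailing
    transition interval (``dt_mode="mean"`` divides by the mean of the two
    intervals instead).  Each sample sits at the fix shared by its two
    transitions, with position expressed relative to ``center``.  Samples
    whose flanking transitions span a severed gap (> 12 s and > 40 m) are
    dropped.  Sections with fewer than 3 fixes yield no samples.
    """
    if dt_mode not in ("trailing", "mean"):
        raise ValueError(f"unknown dt_mode {dt_mode!r}")
    sl = slice(section.start, section.stop)
    t = seg.times[sl]
    xy = seg.xy[sl]
    if len(t) < 3:
        return pd.DataFrame(columns=_SAMPLE_COLUMNS)
    dt = np.diff(t)
    step = np.diff(xy, axis=0)
    v = step / dt[:, None]
    if dt_mode == "trailing":
        denom = dt[1:]
    else:
        denom = 0.5 * (dt[:-1] + dt[1:])
    a = np.diff(v, axis=0) / denom[:, None]
    # sample i sits at fix i+1, shared by transitions i and i+1
    severed = (dt > SEVER_GAP_S) & (np.hypot(step[:, 0], step[:, 1]) > SEVER_STEP_M)
    ok = ~(severed[:-1] | severed[1:])
    ok &= np.all(np.isfinite(a), axis=1)
    idx = np.arange(1, len(t) - 1)[ok]
    # velocity attributed to a sample is that of its incoming transition
    # (the one ending at the shared fix)
    df = pd.DataFrame(
        {
            "t": t[idx],
            "x_rel": xy[idx, 0] - center[0],
            "y_rel": xy[idx, 1] - center[1],
            "vx": v[idx - 1, 0],
            "vy": v[idx - 1, 1],
            "ax": a[idx - 1, 0],
            "ay": a[idx - 1, 1],
        }
    )
    df["segment_id"] = seg.segment_id
    df["location_id"] = location_id
    return df[_SAMPLE_COLUMNS]


def fit_well(samples: pd.DataFrame, axis: str) -> WellFit:
    """OLS of the ``axis`` acceleration component on the matching relative
    position, pooled over all sections at one location."""
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    pos = samples[f"{axis}_rel"].to_numpy(dtype=float)
    acc = samples[f"a{axis}"].to_numpy(dtype=float)
    if len(pos) < 3:
        raise ValueError(f"need >= 3 samples, got {len(pos)}")
    if np.ptp(pos) == 0:
        raise ValueError("degenerate fit: constant position")
    model = sm.OLS(acc, sm.add_constant(pos)).fit()
    intercept, slope = model.params
    intercept_se, slope_se = model.bse
    return WellFit(
        axis=axis,
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        p_value=float(model.pvalues[1]),
        n=int(model.nobs),
    )


def binned_profile(
    samples: pd.DataFrame, axis: str, bin_m: float = 5.0, span_m: float = 50.0
) -> BinnedProfile:
    """Mean acceleration (with SE and counts) over position bins of width
    ``bin_m`` spanning +/- ``span_m`` around the center; empty bins are
    flagged (nan mean), not zero-filled."""
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    edges = np.arange(-span_m, span_m + bin_m / 2, bin_m)
    pos = samples[f"{axis}_rel"].to_numpy(dtype=float)
    acc = samples[f"a{axis}"].to_numpy(dtype=float)
    which = np.digitize(pos, edges) - 1
    nb = len(edges) - 1
    mean = np.full(nb, np.nan)
    se = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=int)
    for b in range(nb):
        vals = acc[which == b]
        n[b] = vals.size
        if vals.size:
            mean[b] = vals.mean()
            if vals.size > 1:
                se[b] = vals.std(ddof=1) / np.sqrt(vals.size)
    return BinnedProfile(axis, edges, mean, se, n)


# ---------------------------------------------------------------------------
# distribution diagnostics
# ---------------------------------------------------------------------------

def kurtosis(values) -> float:
    """Pearson (non-excess) kurtosis m4/m2^2; 3 for a Gaussian."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError(f"kurtosis needs >= 4 values, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("kurtosis undefined for zero-variance input")
    return float(scipy.stats.kurtosis(v, fisher=False, bias=True))


def gaussian_core_points(values) -> np.ndarray:
    """Normal-probability-plot pairs for the Gaussian-core diagnostic.

    Returns an (n, 2) array of (theoretical, empirical) standard quantiles:
    the sorted values standardized by sample mean/sd against
    Phi^-1((i - 0.5)/n).  A Gaussian sample falls on the identity line; a
    heavy-tailed one departs in the tails while the core stays linear.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 10:
        raise ValueError(f"need >= 10 values, got {v.size}")
    z = (v - v.mean()) / v.std(ddof=0)
    p = (np.arange(1, v.size + 1) - 0.5) / v.size
    theo = scipy.stats.norm.ppf(p)
    return np.column_stack([theo, z])


# ---------------------------------------------------------------------------
# visits
# ---------------------------------------------------------------------------

def detect_visits(
    seg: FlightSegment,
    sections: Sequence[FlightSection],
    areas: Sequence[Congregation],
    radius_m: float = ASSIGN_RADIUS_M,
    dwell_s: float = DWELL_MIN_S,
) -> list[Visit]:
    """Visits of one flight to each congregation area.

    Clause (a): any convoluted section whose center of mass lies within
    ``radius_m`` of the area center.  Clause (b): the bee stays within
    ``radius_m`` of the center for at least ``dwell_s`` seconds; runs of
    consecutive inside fixes bridge signal-loss gaps automatically, since a
    missing period whose flanking fixes are both inside extends the run.
    """
    visits: list[Visit] = []
    t = seg.times
    xy = seg.xy
    for area in areas:
        cx, cy = area.center
        for sec in sections:
            if sec.label != CONVOLUTED:
                continue
            if np.hypot(sec.center_of_mass[0] - cx, sec.center_of_mass[1] - cy) <= radius_m:
                ts, te = seg.times[sec.start], seg.times[sec.stop - 1]
                visits.append(Visit(seg.segment_id, area.area_id, "convoluted_com", float(ts), float(te)))
        inside = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) <= radius_m
        i = 0
        n = len(inside)
        while i < n:
            if not inside[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and inside[j + 1]:
                j += 1
            if t[j] - t[i] >= dwell_s:
                visits.append(Visit(seg.segment_id, area.area_id, "dwell", float(t[i]), float(t[j])))
            i = j + 1
    return visits


def count_areas_visited(visits: Sequence[Visit]) -> int:
    """Distinct congregation areas visited (either basis counts)."""
    return len({v.area_id for v in visits})


def visits_table(
    classified: Sequence[tuple[FlightSegment, Sequence[FlightSection]]],
    areas: Sequence[Congregation],
    radius_m: float = ASSIGN_RADIUS_M,
    dwell_s: float = DWELL_MIN_S,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All visits plus the per-flight distinct-area counts."""
    rows = []
    per_flight = []
    for seg, sections in classified:
        vis = detect_visits(seg, sections, areas, radius_m, dwell_s)
        rows.extend(
            {
                "segment_id": v.segment_id,
                "area_id": v.area_id,
                "basis": v.basis,
                "t_start": v.t_start,
                "t_end": v.t_end,
            }
            for v in vis
        )
        per_flight.append({"segment_id": seg.segment_id, "n_areas_visited": count_areas_visited(vis)})
    return (
        pd.DataFrame(rows, columns=["segment_id", "area_id", "basis", "t_start", "t_end"]),
        pd.DataFrame(per_flight, columns=["segment_id", "n_areas_visited"]),
    )


# ---------------------------------------------------------------------------
# per-location summaries
# ---------------------------------------------------------------------------

def assign_section_location(
    section: FlightSection,
    areas: Sequence[Congregation],
    hives: Sequence[HiveRecord],
    when=None,
    radius_m: float = ASSIGN_RADIUS_M,
) -> tuple[str, str, tuple[float, float]] | None:
    """(location_id, kind, center) of the nearest area/active-hive center
    within ``radius_m`` of the section's center of mass, or None.

    Ties at exactly equal distance go to the congregation (fixed rule).
    """
    cx, cy = section.center_of_mass
    candidates: list[tuple[float, int, str, str, tuple[float, float]]] = []
    for a in areas:
        d = float(np.hypot(a.center[0] - cx, a.center[1] - cy))
        if d <= radius_m:
            candidates.append((d, 0, a.area_id, "congregation", a.center))
    for h in hives:
        if not h.is_active(when):
            continue
        d = float(np.hypot(h.position[0] - cx, h.position[1] - cy))
        if d <= radius_m:
            candidates.append((d, 1, h.hive_id, "hive", h.position))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    d, _, loc_id, kind, center = candidates[0]
    return loc_id, kind, center


def location_summary(
    classified: Sequence[tuple[FlightSegment, Sequence[FlightSection]]],
    areas: Sequence[Congregation],
    hives: Sequence[HiveRecord],
    radius_m: float = ASSIGN_RADIUS_M,
    dt_mode: str = "trailing",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-section assignments and per-location distribution statistics.

    Returns ``(sections_df, locations_df, samples_df)``: one row per
    convoluted section assigned to a location (duration, mean speed — the
    table the downstream location ANOVAs consume); one row per location with
    pooled Pearson kurtosis of relative x/y position and velocity plus mean
    duration/speed; and the pooled kinematic samples themselves.
    """
    sec_rows = []
    sample_frames = []
    for seg, sections in classified:
        for k, sec in enumerate(sections):
            if sec.label != CONVOLUTED:
                continue
            assignment = assign_section_location(sec, areas, hives, seg.start_time, radius_m)
            if assignment is None:
                continue
            loc_id, kind, center = assignment
            sec_rows.append(
                {
                    "segment_id": seg.segment_id,
                    "section_index": k,
                    "location_id": loc_id,
                    "location_kind": kind,
                    "duration_s": sec.duration_s,
                    "mean_speed_ms": sec.mean_speed_ms,
                }
            )
            samp = kinematics(seg, sec, center, location_id=loc_id, dt_mode=dt_mode)
            if len(samp):
                sample_frames.append(samp.assign(location_kind=kind))
    sections_df = pd.DataFrame(
        sec_rows,
        columns=["segment_id", "section_index", "location_id", "location_kind",
                 "duration_s", "mean_speed_ms"],
    )
    samples_df = (
        pd.concat(sample_frames, ignore_index=True)
        if sample_frames
        else pd.DataFrame(columns=_SAMPLE_COLUMNS + ["location_kind"])
    )
    loc_rows = []
    for loc_id, grp in samples_df.groupby("location_id"):
        secs = sections_df[sections_df["location_id"] == loc_id]
        row = {
            "location_id": loc_id,
            "location_kind": grp["location_kind"].iloc[0],
            "n_sections": len(secs),
            "n_samples": len(grp),
            "mean_duration_s": float(secs["duration_s"].mean()),
            "mean_speed_ms": float(secs["mean_speed_ms"].mean()),
        }
        for col, name in (("x_rel", "kurt_x"), ("y_rel", "kurt_y"), ("vx", "kurt_vx"), ("vy", "kurt_vy")):
            vals = grp[col].to_numpy(dtype=float)
            row[name] = kurtosis(vals) if vals.size >= 4 and np.ptp(vals) > 0 else float("nan")
        loc_rows.append(row)
    locations_df = pd.DataFrame(
        loc_rows,
        columns=["location_id", "location_kind", "n_sections", "n_samples",
                 "mean_duration_s", "mean_speed_ms", "kurt_x", "kurt_y", "kurt_vx", "kurt_vy"],
    )
    return sections_df, locations_df, samples_df


def well_fits_table(samples_df: pd.DataFrame) -> pd.DataFrame:
    """Per-location, per-axis well fits over pooled kinematic samples."""
    rows = []
    for loc_id, grp in samples_df.groupby("location_id"):
        for axis in ("x", "y"):
            try:
                fit = fit_well(grp, axis)
            except ValueError:
                continue
            rows.append(
                {
                    "location_id": loc_id,
                    "axis": axis,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "x_intercept": fit.x_intercept,
                    "slope_se": fit.slope_se,
                    "intercept_se": fit.intercept_se,
                    "p_value": fit.p_value,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["location_id", "axis", "slope", "intercept", "x_intercept",
                 "slope_se", "intercept_se", "p_value", "n"],
    )
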