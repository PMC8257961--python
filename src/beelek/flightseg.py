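"""Straight / convoluted flight classification.

Drone flights alternate between straight commuting legs and tightly looping
"convoluted" flight (the swarming mode at congregation areas and near hives).
The classifier works on transition bearings: the bearing of every consecutive
fix pair is a unit vector, and the resultant vector length R of the bearings
falling inside a moving 21 s window (seven radar rotations at the nominal 3 s
sampling) measures directional persistence — R = 1 for perfectly aligned
bearings, R -> 0 for balanced dispersion.

A fix is a straight candidate iff at least one window containing it has
R above the threshold (default 0.7); every other fix is a convoluted
candidate.  Two corrections handle radar dropouts: a transition with a gap
longer than 12 s over which the bee moved more than 40 m cannot be interior
to a convoluted section (it severs candidate runs), and convoluted sections
must contain at least 7 temporally consecutive fixes — shorter runs are
relabelled straight.  The algorithm is otherwise scale free: it assumes only
that a bee in convoluted flight does not keep flying in one direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .trackio import FlightSegment

logger = logging.getLogger("beelek")


@dataclass(frozen=True)
class ClassifierParams:
    """Tuning knobs of the windowed-resultant classifier (defaults are the
    analysis defaults: 21 s window, R > 0.7, 12 s / 40 m gap rule, 7-fix
    minimum run)."""

    window_s: float = 21.0
    r_threshold: float = 0.7
    max_gap_s: float = 12.0
    max_gap_m: float = 40.0
    min_run: int = 7

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not 0.0 <= self.r_threshold <= 1.0:
            raise ValueError("r_threshold must lie in [0, 1]")
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")


class Transition(NamedTuple):
    """One consecutive-fix transition: window-midpoint time, bearing in
    radians clockwise from north (nan when the displacement is zero), the
    time gap and the step length."""

    t_mid: float
    bearing: float
    gap_s: float
    step_m: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.bearing)


STRAIGHT = "straight"
CONVOLUTED = "convoluted"


@dataclass(frozen=True)
class FlightSection:
    """A maximal run of equally-labelled fixes within one segment.

    ``start``/``stop`` index the parent segment's fix list (stop exclusive).
    ``mean_speed_ms`` is nan for single-fix sections.
    """

    segment_id: str
    label: str
    start: int
    stop: int
    center_of_mass: tuple[float, float]
    duration_s: float
    mean_speed_ms: float

    @property
    def n_fixes(self) -> int:
        return self.stop - self.start


def transition_bearings(seg: FlightSegment) -> list[Transition]:
    """Bearing record for every consecutive fix pair of a segment.

    Bearings use atan2(dx, dy): radians clockwise from true north, matching
    the radar azimuth convention.  Zero-displacement transitions get a nan
    bearing and are excluded from window statistics.
    """
    t = seg.times
    xy = seg.xy
    d = np.diff(xy, axis=0)
    step = np.hypot(d[:, 0], d[:, 1])
    with np.errstate(invalid="ignore"):
        bearing = np.arctan2(d[:, 0], d[:, 1])
    bearing = np.where(step > 0, bearing, np.nan)
    t_mid = 0.5 * (t[:-1] + t[1:])
    gap = np.diff(t)
    return [
        Transition(float(m), float(b), float(g), float(s))
        for m, b, g, s in zip(t_mid, bearing, gap, step)
    ]


def window_resultant(
    transitions: Sequence[Transition], t_anchor: float, params: ClassifierParams
) -> float | None:
    """Resultant vector length of the defined bearings whose transition
    midpoint falls in the closed window [t_anchor - w/2, t_anchor + w/2].

    Returns None (undefined) when fewer than two defined bearings fall in
    the window: a single bearing always has R = 1 and certifies nothing.
    """
    half = params.window_s / 2.0
    th = np.asarray(
        [
            tr.bearing
            for tr in transitions
            if tr.defined and t_anchor - half <= tr.t_mid <= t_anchor + half
        ]
    )
    if th.size < 2:
        return None
    return float(np.hypot(np.sin(th).sum(), np.cos(th).sum()) / th.size)


def _window_resultants(
    t_mid: np.ndarray, bearing: np.ndarray, anchors: np.ndarray, window_s: float
) -> np.ndarray:
    """R for windows centered at each anchor time (nan where undefined)."""
    half = window_s / 2.0
    ok = ~np.isnan(bearing)
    tm, th = t_mid[ok], bearing[ok]
    order = np.argsort(tm, kind="stable")
    tm, th = tm[order], th[order]
    s, c = np.sin(th), np.cos(th)
    cs = np.concatenate([[0.0], np.cumsum(s)])
    cc = np.concatenate([[0.0], np.cumsum(c)])
    lo = np.searchsorted(tm, anchors - half, side="left")
    hi = np.searchsorted(tm, anchors + half, side="right")
    n = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.hypot(cs[hi] - cs[lo], cc[hi] - cc[lo]) / n
    r[n < 2] = np.nan
    return r


def classify_fixes(seg: FlightSegment, params: ClassifierParams) -> np.ndarray:
    """Per-fix labels (STRAIGHT / CONVOLUTED) for one segment.

    Windows are anchored at every fix time; a fix falls within a window when
    either of its incident transitions has its midpoint inside the window
    interval.  A fix is straight iff some window containing it has R above
    threshold; convoluted-candidate runs are severed at long-gap long-step
    transitions, and runs shorter than ``min_run`` are relabelled straight.
    """
    n = len(seg)
    labels = np.full(n, STRAIGHT, dtype=object)
    if seg.duration_s < params.window_s:
        warnings.warn(
            f"segment {seg.segment_id!r} shorter than one window "
            f"({seg.duration_s:.1f} s < {params.window_s:.1f} s); labelling straight",
            stacklevel=2,
        )
        return labels

    trans = transition_bearings(seg)
    t_mid = np.asarray([tr.t_mid for tr in trans])
    bearing = np.asarray([tr.bearing for tr in trans])
    gap = np.asarray([tr.gap_s for tr in trans])
    step = np.asarray([tr.step_m for tr in trans])

    anchors = seg.times
    r = _window_resultants(t_mid, bearing, anchors, params.window_s)
    good = np.flatnonzero(~np.isnan(r) & (r > params.r_threshold))

    # transition k is covered by a good window iff its midpoint lies within
    # window_s/2 of a good anchor
    half = params.window_s / 2.0
    covered = np.zeros(len(trans), dtype=bool)
    if good.size:
        ga = np.sort(anchors[good])
        idx = np.searchsorted(ga, t_mid)
        left = np.full(len(trans), np.inf)
        right = np.full(len(trans), np.inf)
        has_left = idx > 0
        left[has_left] = t_mid[has_left] - ga[idx[has_left] - 1]
        has_right = idx < ga.size
        right[has_right] = ga[idx[has_right]] - t_mid[has_right]
        covered = np.minimum(left, right) <= half

    straight_cand = np.zeros(n, dtype=bool)
    straight_cand[:-1] |= covered  # transition k is incident to fix k ...
    straight_cand[1:] |= covered  # ... and fix k+1
    conv_cand = ~straight_cand

    severed = (gap > params.max_gap_s) & (step > params.max_gap_m)

    # maximal convoluted-candidate runs, split at severed transitions
    i = 0
    while i < n:
        if not conv_cand[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and conv_cand[j + 1] and not severed[j]:
            j += 1
        if j - i + 1 >= params.min_run:
            labels[i : j + 1] = CONVOLUTED
        i = j + 1
    return labels


def _section_from_run(seg: FlightSegment, label: str, start: int, stop: int) -> FlightSection:
    t = seg.times[start:stop]
    xy = seg.xy[start:stop]
    com = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
    duration = float(t[-1] - t[0])
    if stop - start >= 2:
        speeds = np.hypot(*np.diff(xy, axis=0).T) / np.diff(t)
        mean_speed = float(speeds.mean())
    else:
        mean_speed = float("nan")
    return FlightSection(seg.segment_id, label, start, stop, com, duration, mean_speed)


def classify_sections(seg: FlightSegment, params: ClassifierParams | None = None) -> list[FlightSection]:
    """Split a segment into ordered straight / convoluted sections that
    jointly cover every fix.

    A severed transition (gap > max_gap_s and step > max_gap_m) additionally
    splits adjacent convoluted runs into separate sections — it can never be
    interior to a convoluted section.  Straight sections are simply the
    maximal leftover runs.
    """
    params = params or ClassifierParams()
    labels = classify_fixes(seg, params)
    dt = np.diff(seg.times)
    step = np.hypot(*np.diff(seg.xy, axis=0).T)
    severed = (dt > params.max_gap_s) & (step > params.max_gap_m)
    sections: list[FlightSection] = []
    start = 0
    for i in range(1, len(labels) + 1):
        split = i == len(labels) or labels[i] != labels[start]
        if not split and labels[start] == CONVOLUTED and severed[i - 1]:
            split = True
        if split:
            sections.append(_section_from_run(seg, labels[start], start, i))
            start = i
    return sections


def classify_dataset(
    segments: Sequence[FlightSegment], params: ClassifierParams | None = None
) -> list[tuple[FlightSegment, list[FlightSection]]]:
    params = params or ClassifierParams()
    return [(seg, classify_sections(seg, params)) for seg in segments]


def sections_table(
    classified: Sequence[tuple[FlightSegment, Sequence[FlightSection]]],
) -> tuple[pd.DataFrame, dict]:
    """Per-section summary table plus dataset-level aggregates.

    Aggregates: number of convoluted sections, number of flights with >= 1
    and >= 2 convoluted sections, mean convoluted-section duration, and the
    mean fraction of flight time spent convoluted among flights that contain
    convoluted flight.
    """
    rows = []
    frac_conv = []
    n_flights_conv = 0
    n_flights_multi = 0
    for seg, sections in classified:
        n_conv = 0
        t_conv = 0.0
        for k, sec in enumerate(sections):
            rows.append(
                {
                    "segment_id": seg.segment_id,
                    "section_index": k,
                    "label": sec.label,
                    "start": sec.start,
                    "stop": sec.stop,
                    "n_fixes": sec.n_fixes,
                    "duration_s": sec.duration_s,
                    "mean_speed_ms": sec.mean_speed_ms,
                    "com_x": sec.center_of_mass[0],
                    "com_y": sec.center_of_mass[1],
                }
            )
            if sec.label == CONVOLUTED:
                n_conv += 1
                t_conv += sec.duration_s
        if n_conv >= 1:
            n_flights_conv += 1
            if seg.duration_s > 0:
                frac_conv.append(t_conv / seg.duration_s)
        if n_conv >= 2:
            n_flights_multi += 1

    df = pd.DataFrame(
        rows,
        columns=[
            "segment_id", "section_index", "label", "start", "stop",
            "n_fixes", "duration_s", "mean_speed_ms", "com_x", "com_y",
        ],
    )
    conv = df[df["label"] == CONVOLUTED] if len(df) else df
    aggregates = {
        "n_sections": len(df),
        "n_convoluted_sections": int(len(conv)),
        "n_flights_with_convoluted": n_flights_conv,
        "n_flights_multi_convoluted": n_flights_multi,
        "mean_convoluted_duration_s": float(conv["duration_s"].mean()) if len(conv) else float("nan"),
        "mean_convoluted_fraction": float(np.mean(frac_conv)) if frac_conv else float("nan"),
    }
    return df, aggregates


def sections_from_params_dict(raw: dict | None) -> ClassifierParams:
    """Build classifier params from a site-config ``params.classifier`` dict."""
    p = ClassifierParams()
    if raw:
        p = replace(p, **{k: v for k, v in raw.items() if k in ClassifierParams.__dataclass_fields__})
    return p
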