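"""Synthetic radar-track generator with known ground truth.

Every pipeline stage is testable without field data against tracks whose
behavioral state is known fix by fix.  A simulated flight alternates:

* a hover phase in front of the home hive — a mixture of a tight and a wide
  harmonic well, producing the slow, heavy-tailed (kurtosis > 3) position
  distributions seen near hives;
* straight commuting legs at ~4.8 m/s (the observed mean straight-section
  speed) with a weakly autocorrelated heading perturbation;
* swarm bouts at one to three congregation areas, simulated as a damped
  harmonic (elastic) potential well driven by velocity noise — per axis
  dv = (-k (x - c) - gamma v) dt + sigma dW, integrated by Euler-Maruyama.
  The stationary position and velocity distributions are Gaussian with
  variances sigma^2/(2 gamma k) and sigma^2/(2 gamma), and the conditional
  mean acceleration is -k (x - c): exactly the swarm-cohesion signature the
  analysis stages are built to recover.  Bout durations are exponential
  with mean 134 s (the observed mean convoluted-section duration),
  truncated at 21 s so every bout is long enough to be detectable.

The radar model samples the continuous path once per 3 s antenna rotation,
drops sweeps with probability 1 - detection_prob, adds 2 m Gaussian
measurement noise per axis, and discards fixes beyond the 800 m detection
radius.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .trackio import FlightSegment, HiveRecord, RadarFix, ReferencePoint, SiteConfig

logger = logging.getLogger("beelek")

LABEL_COMMUTE = "commute"
LABEL_SWARM = "swarm"
LABEL_HOVER = "hover"

#: classifier label a behavioral state should map to (commuting is straight
#: flight; swarming and hovering are convoluted)
EXPECTED_CLASSIFIER_LABEL = {
    LABEL_COMMUTE: "straight",
    LABEL_SWARM: "convoluted",
    LABEL_HOVER: "convoluted",
}


@dataclass(frozen=True)
class AreaSpec:
    """One planted congregation area: center and well parameters."""

    center: tuple[float, float]
    stiffness_k: float = 0.05  # 1/s^2
    damping_gamma: float = 1.0  # 1/s
    noise_sigma: float = 5.66  # m / s^1.5

    def __post_init__(self) -> None:
        if min(self.stiffness_k, self.damping_gamma, self.noise_sigma) <= 0:
            raise ValueError("well parameters must be positive")

    @property
    def position_var(self) -> float:
        """Stationary per-axis position variance sigma^2 / (2 gamma k)."""
        return self.noise_sigma**2 / (2 * self.damping_gamma * self.stiffness_k)

    @property
    def velocity_var(self) -> float:
        """Stationary per-axis velocity variance sigma^2 / (2 gamma)."""
        return self.noise_sigma**2 / (2 * self.damping_gamma)


#: hive hover mixture components (tight core + wide loops): heavier-tailed
#: than any single well, giving the hive-vs-congregation kurtosis contrast
HOVER_COMPONENTS = (
    AreaSpec((0.0, 0.0), stiffness_k=0.5, damping_gamma=1.0, noise_sigma=3.0),
    AreaSpec((0.0, 0.0), stiffness_k=0.05, damping_gamma=0.6, noise_sigma=2.0),
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    hives: tuple[tuple[float, float], ...] = ((0.0, 0.0), (55.0, -25.0), (-45.0, 45.0))
    areas: tuple[AreaSpec, ...] = (
        AreaSpec((250.0, -180.0)),
        AreaSpec((430.0, -40.0)),
        AreaSpec((290.0, 160.0)),
        AreaSpec((-270.0, -230.0)),
    )
    # dwell means reproduce the observed convoluted-section durations
    # (134 s overall for swarms, ~140 s for hive-front flight)
    n_drones: int = 30
    flights_per_drone: int = 2
    commute_speed_ms: float = 4.8
    heading_noise_sd: float = 0.1  # rad, stationary sd of heading perturbation
    swarm_dwell_s: float = 134.0
    swarm_dwell_min_s: float = 21.0
    hover_dwell_s: float = 140.0
    hover_dwell_min_s: float = 24.0
    bouts_min: int = 1
    bouts_max: int = 3
    radar_interval_s: float = 3.0
    detection_prob: float = 0.9
    measurement_sd_m: float = 2.0
    max_range_m: float = 800.0
    dt: float = 0.1  # integration step (30 substeps per radar rotation)

    def __post_init__(self) -> None:
        if not 0 < self.detection_prob <= 1:
            raise ValueError("detection_prob must lie in (0, 1]")
        if self.bouts_min < 0 or self.bouts_max < self.bouts_min:
            raise ValueError("invalid bout count range")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class Path:
    """A continuous path sampled on the integration grid, with per-sample
    behavioral labels."""

    dt: float
    xy: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) object

    @property
    def duration_s(self) -> float:
        return (len(self.xy) - 1) * self.dt

    @staticmethod
    def concatenate(pieces: list["Path"]) -> "Path":
        if not pieces:
            raise ValueError("no path pieces")
        dt = pieces[0].dt
        xy = [pieces[0].xy]
        labels = [pieces[0].labels]
        for p in pieces[1:]:
            if p.dt != dt:
                raise ValueError("mixed integration steps")
            # drop the duplicated joint sample
            xy.append(p.xy[1:])
            labels.append(p.labels[1:])
        return Path(dt, np.concatenate(xy), np.concatenate(labels))


@dataclass
class GroundTruth:
    """Per-fix behavioral labels and planted structure for one dataset."""

    labels: dict[str, np.ndarray]  # segment_id -> per-fix labels
    bouts: pd.DataFrame  # segment_id, area_index, t_start, t_end
    true_centers: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# path generators
# ---------------------------------------------------------------------------

def simulate_swarm_bout(
    center: tuple[float, float],
    k: float,
    gamma: float,
    sigma: float,
    duration_s: float,
    dt: float,
    rng: np.random.Generator,
    start_xy: tuple[float, float] | None = None,
    start_v: tuple[float, float] | None = None,
) -> np.ndarray:
    """Damped-harmonic-well path, (n, 2) positions on the dt grid.

    Starts from the stationary distribution unless a start state is given,
    so short bouts are immediately representative of the well.
    """
    if dt * gamma >= 1.0:
        raise ValueError(f"unstable integration: dt*gamma = {dt * gamma:.2f} >= 1")
    n = max(int(round(duration_s / dt)), 1)
    c = np.asarray(center, dtype=float)
    sd_x = sigma / math.sqrt(2 * gamma * k)
    sd_v = sigma / math.sqrt(2 * gamma)
    x = np.array(start_xy, dtype=float) if start_xy is not None else c + rng.normal(0, sd_x, 2)
    v = np.array(start_v, dtype=float) if start_v is not None else rng.normal(0, sd_v, 2)
    out = np.empty((n + 1, 2))
    out[0] = x
    if sigma > 0:
        dw = rng.normal(0.0, sigma * math.sqrt(dt), size=(n, 2))
    else:
        dw = np.zeros((n, 2))
    for i in range(n):
        v = v + (-k * (x - c) - gamma * v) * dt + dw[i]
        x = x + v * dt
        out[i + 1] = x
    return out


def simulate_commute(
    p_start: tuple[float, float],
    p_end: tuple[float, float],
    speed: float,
    heading_noise_sd: float,
    dt: float,
    rng: np.random.Generator,
    arrive_m: float = 5.0,
) -> np.ndarray:
    """Steered correlated walk from p_start toward p_end at constant speed.

    The heading each step is the bearing to the target plus an AR(1)
    perturbation with stationary sd ``heading_noise_sd``; the walk stops on
    entering the ``arrive_m`` disc around the target.
    """
    p = np.array(p_start, dtype=float)
    target = np.array(p_end, dtype=float)
    dist = float(np.hypot(*(target - p)))
    if dist == 0:
        raise ValueError("commute endpoints must be distinct")
    phi = 0.9  # per-step heading persistence
    innov_sd = heading_noise_sd * math.sqrt(1 - phi**2)
    eps = rng.normal(0, heading_noise_sd) if heading_noise_sd > 0 else 0.0
    pts = [p.copy()]
    max_steps = int(10 * dist / (speed * dt)) + 100
    for _ in range(max_steps):
        if np.hypot(*(target - p)) <= arrive_m:
            break
        to_target = math.atan2(target[0] - p[0], target[1] - p[1])
        if heading_noise_sd > 0:
            eps = phi * eps + rng.normal(0, innov_sd)
        heading = to_target + eps
        p = p + speed * dt * np.array([math.sin(heading), math.cos(heading)])
        pts.append(p.copy())
    return np.asarray(pts)


def simulate_hover_bout(
    hive: tuple[float, float],
    duration_s: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hive-front hover: sub-bouts alternating between a tight and a wide
    well, a stand-in that makes hive flight slow and heavy-tailed."""
    pieces = []
    remaining = duration_s
    start_xy = None
    while remaining > 0:
        comp = HOVER_COMPONENTS[rng.integers(len(HOVER_COMPONENTS))]
        sub = min(remaining, float(rng.exponential(15.0)) + 3.0)
        path = simulate_swarm_bout(
            hive, comp.stiffness_k, comp.damping_gamma, comp.noise_sigma,
            sub, dt, rng, start_xy=start_xy,
        )
        pieces.append(path if not pieces else path[1:])
        start_xy = tuple(path[-1])
        remaining -= sub
    return np.concatenate(pieces)


# ---------------------------------------------------------------------------
# radar sampling
# ---------------------------------------------------------------------------

def radar_sample(
    path: Path,
    config: SimConfig,
    rng: np.random.Generator,
    segment_id: str = "sim",
    **segment_kwargs,
) -> tuple[FlightSegment | None, np.ndarray]:
    """Sample a continuous path the way the radar would.

    Positions are read every ``radar_interval_s``; each is retained with
    probability ``detection_prob``, perturbed by per-axis Gaussian noise,
    and dropped if beyond ``max_range_m``.  Returns the segment (None when
    fewer than 2 fixes survive) and the per-fix ground-truth labels.
    """
    t_total = path.duration_s
    times = np.arange(0.0, t_total + path.dt / 2, config.radar_interval_s)
    idx = np.clip(np.round(times / path.dt).astype(int), 0, len(path.xy) - 1)
    detected = rng.random(len(times)) < config.detection_prob
    noise = rng.normal(0.0, config.measurement_sd_m, size=(len(times), 2))
    fixes = []
    labels = []
    for ti, ii, keep, nz in zip(times, idx, detected, noise):
        if not keep:
            continue
        x, y = path.xy[ii] + nz
        if math.hypot(x, y) > config.max_range_m:
            continue
        fixes.append(RadarFix(float(ti), float(x), float(y)))
        labels.append(path.labels[ii])
    if len(fixes) < 2:
        return None, np.asarray(labels, dtype=object)
    return (
        FlightSegment(segment_id, fixes, **segment_kwargs),
        np.asarray(labels, dtype=object),
    )


# ---------------------------------------------------------------------------
# whole-dataset generator
# ---------------------------------------------------------------------------

def _labelled(xy: np.ndarray, label: str, dt: float) -> Path:
    return Path(dt, xy, np.full(len(xy), label, dtype=object))


def simulate_flight(
    config: SimConfig,
    hive: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[Path, list[tuple[int, float, float]]]:
    """One flight path: hover, commutes, swarm bouts, return.

    Returns the path and the swarm-bout log [(area_index, t_start, t_end)]
    in path time.
    """
    dt = config.dt
    pieces: list[Path] = []
    bout_log: list[tuple[int, float, float]] = []

    hover_s = min(
        config.hover_dwell_min_s
        + float(rng.exponential(max(config.hover_dwell_s - config.hover_dwell_min_s, 1.0))),
        420.0,
    )
    pieces.append(_labelled(simulate_hover_bout(hive, hover_s, dt, rng), LABEL_HOVER, dt))

    n_bouts = int(rng.integers(config.bouts_min, config.bouts_max + 1)) if config.areas else 0
    if n_bouts > 0:
        order = rng.permutation(len(config.areas))[:n_bouts]
        itinerary = [config.areas[i] for i in order]
    else:
        order, itinerary = [], []

    def elapsed() -> float:
        return sum(p.duration_s for p in pieces)

    pos = pieces[-1].xy[-1]
    if not itinerary:
        # flight with no swarm bouts: out-and-back commute to a waypoint
        theta = rng.uniform(0, 2 * math.pi)
        way = pos + rng.uniform(150, 350) * np.array([math.sin(theta), math.cos(theta)])
        out = simulate_commute(tuple(pos), tuple(way), config.commute_speed_ms,
                               config.heading_noise_sd, dt, rng)
        back = simulate_commute(tuple(out[-1]), tuple(hive), config.commute_speed_ms,
                                config.heading_noise_sd, dt, rng)
        pieces.append(_labelled(out, LABEL_COMMUTE, dt))
        pieces.append(_labelled(back, LABEL_COMMUTE, dt))
        return Path.concatenate(pieces), bout_log

    for area_index, area in zip(order, itinerary):
        leg = simulate_commute(tuple(pos), area.center, config.commute_speed_ms,
                               config.heading_noise_sd, dt, rng)
        pieces.append(_labelled(leg, LABEL_COMMUTE, dt))
        # shifted exponential: realized mean equals swarm_dwell_s with a
        # hard floor at the 7-rotation detectability limit
        dwell = config.swarm_dwell_min_s + float(
            rng.exponential(max(config.swarm_dwell_s - config.swarm_dwell_min_s, 1.0))
        )
        dwell = min(dwell, 420.0)
        t0 = elapsed()
        bout = simulate_swarm_bout(
            area.center, area.stiffness_k, area.damping_gamma, area.noise_sigma,
            dwell, dt, rng, start_xy=tuple(leg[-1]),
        )
        pieces.append(_labelled(bout, LABEL_SWARM, dt))
        bout_log.append((int(area_index), t0, elapsed()))
        pos = bout[-1]

    home = simulate_commute(tuple(pos), tuple(hive), config.commute_speed_ms,
                            config.heading_noise_sd, dt, rng)
    pieces.append(_labelled(home, LABEL_COMMUTE, dt))
    return Path.concatenate(pieces), bout_log


def default_site(config: SimConfig) -> SiteConfig:
    """Site metadata matching a simulated dataset (synthetic anchor point)."""
    lat0, lon0 = 51.807, -0.356
    from .trackio import EARTH_RADIUS_M

    def geo(x: float, y: float) -> tuple[float, float]:
        lat = lat0 + math.degrees(y / EARTH_RADIUS_M)
        lon = lon0 + math.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
        return lat, lon

    refs = []
    for x, y in ((500.0, 0.0), (0.0, 500.0)):
        lat, lon = geo(x, y)
        refs.append(ReferencePoint(lat, lon, x, y))
    season = (datetime(2016, 6, 1), datetime(2016, 9, 30))
    hives = [
        HiveRecord(str(i + 1), pos, season) for i, pos in enumerate(config.hives)
    ]
    return SiteConfig(
        radar_origin=(lat0, lon0),
        reference_points=tuple(refs),  # type: ignore[arg-type]
        hives=hives,
        max_range_m=config.max_range_m,
    )


def simulate_dataset(
    config: SimConfig | None = None,
) -> tuple[list[FlightSegment], GroundTruth, SiteConfig]:
    """Generate a full synthetic dataset: segments, ground truth, site.

    Deterministic under a fixed ``config.seed``.  Each drone is assigned a
    home hive and flies ``flights_per_drone`` flights on consecutive days.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    site = default_site(config)
    base = datetime(2016, 7, 1, 10, 0)
    segments: list[FlightSegment] = []
    labels: dict[str, np.ndarray] = {}
    bout_rows = []
    for d in range(config.n_drones):
        hive_idx = int(rng.integers(len(config.hives)))
        hive = config.hives[hive_idx]
        for f in range(config.flights_per_drone):
            seg_id = f"d{d:03d}f{f}"
            path, bout_log = simulate_flight(config, hive, rng)
            seg, fix_labels = radar_sample(
                path, config, rng,
                segment_id=seg_id,
                drone_id=f"drone{d:03d}",
                hive_id=str(hive_idx + 1),
                year=2016,
                start_time=base + timedelta(days=f, minutes=7 * d),
            )
            if seg is None:
                continue
            segments.append(seg)
            labels[seg_id] = fix_labels
            bout_rows.extend(
                {"segment_id": seg_id, "area_index": ai, "t_start": t0, "t_end": t1}
                for ai, t0, t1 in bout_log
            )
    truth = GroundTruth(
        labels=labels,
        bouts=pd.DataFrame(bout_rows, columns=["segment_id", "area_index", "t_start", "t_end"]),
        true_centers=[a.center for a in config.areas],
    )
    return segments, truth, site


def truth_table(truth: GroundTruth, segments: list[FlightSegment]) -> pd.DataFrame:
    """Per-fix ground-truth labels as a flat frame (for CSV export)."""
    rows = []
    for seg in segments:
        labs = truth.labels.get(seg.segment_id)
        if labs is None:
            continue
        for k, (fix, lab) in enumerate(zip(seg.fixes, labs)):
            rows.append(
                {"segment_id": seg.segment_id, "fix_index": k, "t": fix.t, "label": lab}
            )
    return pd.DataFrame(rows, columns=["segment_id", "fix_index", "t", "label"])
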