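import numpy as np
import pytest

from beelek.simulate import SimConfig, simulate_dataset
from beelek.trackio import FlightSegment, RadarFix


def make_segment(ts, xs, ys, segment_id="test", **kwargs) -> FlightSegment:
    fixes = [RadarFix(float(t), float(x), float(y)) for t, x, y in zip(ts, xs, ys)]
    return FlightSegment(segment_id, fixes, **kwargs)


def zigzag_segment(n, t0=0.0, start=(0.0, 0.0), spacing=3.0, step=8.0, segment_id="zig"):
    """Tightly turning path with low directional persistence at any window."""
    bearings = np.deg2rad([0, 170, 10, 180, 350, 160, 20, 190])
    ts, xs, ys = [t0], [start[0]], [start[1]]
    for i in range(n - 1):
        b = bearings[i % len(bearings)]
        xs.append(xs[-1] + step * np.sin(b))
        ys.append(ys[-1] + step * np.cos(b))
        ts.append(ts[-1] + spacing)
    return ts, xs, ys


@pytest.fixture(scope="session")
def sim_dataset():
    """One full synthetic dataset (default conditions, seed 1)."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_pipeline(sim_dataset):
    from beelek.pipeline import run_pipeline

    segments, truth, site = sim_dataset
    return run_pipeline(segments, site, build_heatmap=False)
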