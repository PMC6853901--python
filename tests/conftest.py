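import numpy as np
import pytest

import rotortrack as rt


@pytest.fixture(scope="session")
def small_spec():
    """Small stationary rotor: 40x40 grid, 5 rotations at 100 ms."""
    return rt.SpiralSpec(
        grid_height=40, grid_width=40, sampling_rate=1000.0,
        duration=500.0, rotation_period=100.0, seed=7,
    )


@pytest.fixture(scope="session")
def spiral_phase(small_spec):
    return rt.make_phase_spiral(small_spec)


@pytest.fixture(scope="session")
def noisy_movie():
    """Meandering noisy rotor through the full pipeline conditions."""
    spec = rt.SpiralSpec(
        grid_height=48, grid_width=48, sampling_rate=1000.0,
        duration=1000.0, rotation_period=100.0, noise_sd=0.05,
        meander_radius=2.0, seed=11,
    )
    return spec, rt.make_voltage_movie(spec)


@pytest.fixture(scope="session")
def pipeline_result(noisy_movie):
    _, movie = noisy_movie
    return rt.run_pipeline(movie)


def boundary_winding(phase_frame):
    """Winding number of phase along the frame boundary (test oracle)."""
    h, w = phase_frame.shape
    path = (
        [phase_frame[0, j] for j in range(w)]
        + [phase_frame[i, w - 1] for i in range(1, h)]
        + [phase_frame[h - 1, j] for j in range(w - 2, -1, -1)]
        + [phase_frame[i, 0] for i in range(h - 2, 0, -1)]
    )
    path.append(path[0])
    diffs = rt.wrap_phase(np.diff(np.asarray(path)))
    return int(np.rint(diffs.sum() / (2 * np.pi)))
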