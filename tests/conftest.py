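import numpy as np
import pytest

from owsmap.segmentation import WindowSpec
from owsmap.stackio import ImageStack, Trace
from owsmap.synthetic import ModelSpec, NoiseSpec, make_movie, simulate_ap_train


@pytest.fixture(scope="session")
def gp_template_train() -> Trace:
    """Regular guinea-pig-like template train, 10 beats at 400 ms / 500 Hz."""
    return simulate_ap_train(
        ModelSpec(species="guineapig", backend="template",
                  n_beats_total=10, n_beats_analysed=10)
    )


@pytest.fixture(scope="session")
def gp_template_alternans() -> Trace:
    """Template train with odd-beat APD modulation (alternans-like)."""
    return simulate_ap_train(
        ModelSpec.alternans("guineapig", backend="template",
                            n_beats_total=10, n_beats_analysed=10)
    )


@pytest.fixture(scope="session")
def uniform_movie(gp_template_train):
    """8x8 plane-wave movie, one regular train everywhere, no noise."""
    stack, truth = make_movie(8, 8, gp_template_train, conduction_velocity=2.0)
    return stack, truth


@pytest.fixture(scope="session")
def two_region_movie(gp_template_train, gp_template_alternans):
    """10x10 movie: alternans train in the left half, regular in the right."""
    region = np.zeros((10, 10), dtype=int)
    region[:, :5] = 1
    stack, truth = make_movie(
        10, 10, gp_template_train, conduction_velocity=2.0,
        region_map=region, region_trains={1: gp_template_alternans},
    )
    return stack, truth


@pytest.fixture()
def gp_window() -> WindowSpec:
    return WindowSpec(pre_ms=50.0, post_ms=150.0, minima_trim=False)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def pulse_train(
    n_pulses: int = 10,
    pcl_ms: float = 170.0,
    rate: float = 500.0,
    width_ms: float = 40.0,
    lead_ms: float = 60.0,
    tail_ms: float = 120.0,
) -> Trace:
    """Train of smooth positive pulses on a zero baseline (module-level helper)."""
    total_ms = lead_ms + n_pulses * pcl_ms + tail_ms
    t = np.arange(int(round(total_ms * rate / 1000.0))) * (1000.0 / rate)
    v = np.zeros(t.size)
    for k in range(n_pulses):
        centre = lead_ms + k * pcl_ms
        v += np.exp(-0.5 * ((t - centre) / (width_ms / 4.0)) ** 2)
    return Trace(values=v, sampling_rate=rate)


@pytest.fixture()
def clean_pulse_train() -> Trace:
    return pulse_train()


def stack_from_trace(trace: Trace, rows: int = 4, cols: int = 4) -> ImageStack:
    """Movie in which every pixel replays the same trace exactly."""
    frames = np.repeat(trace.values[:, None, None], rows, axis=1)
    frames = np.repeat(frames, cols, axis=2)
    return ImageStack(frames=frames, sampling_rate=trace.sampling_rate)
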