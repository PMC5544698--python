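import numpy as np
import pytest

from kymoflow import (
    FlowParams,
    Kymograph,
    LineBenchmarkSpec,
    NeuriteSimSpec,
    run_benchmark,
    simulate_neurite_kymograph,
)


@pytest.fixture(scope="session")
def default_params():
    return FlowParams()


@pytest.fixture(scope="session")
def bench_results():
    """Noise-free default benchmark for both estimators (shared: it is the
    most expensive fixture in the suite)."""
    return {algo: run_benchmark(algo) for algo in ("lk", "kymoflow")}


@pytest.fixture(scope="session")
def noisy_bench_results():
    spec = LineBenchmarkSpec(noise_sd=0.1, seed=7)
    return {algo: run_benchmark(algo, spec=spec) for algo in ("lk", "kymoflow")}


@pytest.fixture(scope="session")
def sim_cell():
    """One simulated growing neurite without fast events (bulk-flow recovery)."""
    spec = NeuriteSimSpec(seed=3, fast_event_rate_antero=0.0, fast_event_rate_retro=0.0)
    kymo, truth = simulate_neurite_kymograph(spec)
    return spec, kymo, truth


@pytest.fixture()
def line45():
    """Noise-free 1 p/f diagonal line kymograph with its ground truth."""
    from kymoflow import make_line_kymograph

    return make_line_kymograph(-45.0)


@pytest.fixture()
def calib_json(tmp_path):
    path = tmp_path / "calib.json"
    path.write_text('{"pixel_size_um": 0.1, "frame_interval_s": 5.0}')
    return path
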