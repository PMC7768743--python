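import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_protocol():
    from daplast.plasticity import StimulusProtocol

    return StimulusProtocol()


@pytest.fixture(scope="session")
def wt_pipeline_results():
    """Full WT pipeline (pool -> movie -> extraction), shared across tests.

    Expensive (~10 s), hence session-scoped; seeds fixed.
    """
    from daplast.plasticity import StimulusProtocol, analyze_sweeps
    from daplast.poolmodel import WT_PRESET, simulate_release
    from daplast.synthetic import gen_da_concentration, gen_fscv_movie
    from daplast.voltammetry import default_baseline_scans, extract_trace

    proto = StimulusProtocol()
    sim = simulate_release(proto, WT_PRESET)
    trace = gen_da_concentration(proto, pool_release=sim.released * WT_PRESET.q, tail=30.0)
    movie = gen_fscv_movie(trace, seed=20)
    extracted = extract_trace(movie, default_baseline_scans(movie, stim_onset=0.0))
    return sim, trace, extracted, analyze_sweeps(extracted, proto)
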