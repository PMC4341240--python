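import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    from taprootmir.sim_data import SimConfig, make_reference

    return make_reference(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One complete synthetic run (three 20k-read stage libraries, seed 1)
    shared by the integration and acceptance tests."""
    from taprootmir.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("full_run")
    return run_pipeline(outdir, seed=1)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A fast three-library simulation (1k reads/stage) for unit-level tests."""
    from taprootmir import sim_data

    cfg = sim_data.SimConfig(target_clean_reads=1000)
    bundle = sim_data.make_reference(cfg, seed=5)
    outdir = tmp_path_factory.mktemp("small_sim")
    result = sim_data.simulate_libraries(bundle, sim_data.default_profiles(cfg),
                                         seed=6, outdir=outdir)
    return cfg, bundle, result
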