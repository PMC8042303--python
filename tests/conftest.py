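import pytest

from crelink.pipeline import run_pipeline
from crelink.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic study: planted folds 8/10/8, fixed seed."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_default(sim_default):
    return run_pipeline(sim_default, seed=7)


@pytest.fixture(scope="session")
def null_sim():
    """No planted structure anywhere: all fold changes at 1."""
    cfg = SimConfig(
        seed=2,
        specific_fold=1.0,
        loop_fold=1.0,
        expr_fold=1.0,
        genome=(("chrS1", 4_000_000), ("chrS2", 4_000_000)),
        n_cres=200,
    )
    return simulate(cfg)
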