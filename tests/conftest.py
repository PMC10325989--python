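import numpy as np
import pytest

from limbgrn import pipeline as pl
from limbgrn import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_cfg():
    return sim.SimConfig(seed=0)


@pytest.fixture(scope="session")
def layout(sim_cfg):
    return sim.gen_genome(sim_cfg)


@pytest.fixture(scope="session")
def sim_dir(sim_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim") / "inputs"
    sim.simulate_to_dir(sim_cfg, out)
    return out


@pytest.fixture(scope="session")
def pipeline_result(sim_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run") / "out"
    cfg = pl.RunConfig(input_dir=str(sim_dir), output_dir=str(out), seed=0)
    report = pl.run_pipeline(cfg)
    return report, out
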