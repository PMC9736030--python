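import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bzipscan.synthetic_data import SimConfig, generate_proteome, simulate


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_proteins=40)


@pytest.fixture(scope="session")
def small_proteome(small_cfg):
    return generate_proteome(small_cfg)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A full synthetic input bundle written to disk (seeded)."""
    cfg = SimConfig(seed=7, n_proteins=200)
    outdir = tmp_path_factory.mktemp("bundle")
    data = simulate(cfg, outdir)
    data["cfg"] = cfg
    data["outdir"] = outdir
    return data
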