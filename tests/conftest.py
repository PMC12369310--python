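import numpy as np
import pytest

from synergy_state.io_core import EMGRecording, PipelineConfig, SpikeTrain, Trial
from synergy_state.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_sim_config():
    """Scaled-down simulation for fast end-to-end tests."""
    return SimConfig(n_loci=5, trials_per_locus=3)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_sim_config):
    """One synthetic animal's dataset bundle plus its ground truth."""
    out = tmp_path_factory.mktemp("bundle")
    gt = generate_dataset(small_sim_config, seed=11, out_dir=out)
    return out, gt


@pytest.fixture()
def toy_recording():
    rng = np.random.default_rng(0)
    sig = np.abs(rng.normal(1.0, 0.3, size=(3, 5000)))
    return EMGRecording(sig, fs=1000.0, muscles=("TA", "VL", "VM"))


@pytest.fixture()
def toy_trials():
    return [
        Trial("t0", "SST", 0.0, 1.0, 1.0, 1.2),
        Trial("t1", "SST", 200.0, 1.0, 2.2, 2.4),
        Trial("t2", "SSAT", 0.0, 1.3, 3.4, 3.6),
    ]
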