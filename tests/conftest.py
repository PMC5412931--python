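import numpy as np
import pytest

import ivimfit as iv
from ivimfit.fitting import MethodSpec


@pytest.fixture(scope="session")
def scheme():
    return iv.DEFAULT_SCHEME


@pytest.fixture(scope="session")
def gm_curve(scheme):
    """Noiseless gray-matter signal curve."""
    return iv.ivim_signal(iv.GM_PARAMS, scheme)


@pytest.fixture(scope="session")
def tumor_curve(scheme):
    """Noiseless low-perfused tumor signal curve."""
    return iv.ivim_signal(iv.TUMOR_PARAMS, scheme)


@pytest.fixture(scope="session")
def methods():
    return {mid: MethodSpec(mid) for mid in
            ("one_parameter", "two_parameter", "three_parameter")}


@pytest.fixture(scope="session")
def gm40_ensemble():
    """200 noisy gray-matter curves at SNR 40 (fixed seed)."""
    cfg = iv.SimulationConfig(
        model_params=iv.GM_PARAMS, snr_levels=(40.0,), n_iterations=200,
        seed=11, model_name="gray_matter",
    )
    return iv.generate_ensemble(cfg)


@pytest.fixture(scope="session")
def tumor40_ensemble():
    """200 noisy tumor curves at SNR 40 (fixed seed)."""
    cfg = iv.SimulationConfig(
        model_params=iv.TUMOR_PARAMS, snr_levels=(40.0,), n_iterations=200,
        seed=11, model_name="tumor",
    )
    return iv.generate_ensemble(cfg)
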