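import numpy as np
import pytest

from myorelax import build_labelmap, simulate_dual_echo, study


@pytest.fixture(scope="session")
def steam_acq():
    return study.STEAM_ACQ


@pytest.fixture(scope="session")
def dual_echo_acq():
    return study.DUAL_ECHO_ACQ


@pytest.fixture(scope="session")
def wt_phantom():
    """Noise-free healthy-muscle phantom with its label map and echoes."""
    spec = study.default_phantom(muscle_t2=study.T2_WT_MS, seed=11)
    lm = build_labelmap(spec)
    vol = simulate_dual_echo(
        lm, spec.tissues, study.DUAL_ECHO_ACQ, snr_te14=np.inf
    )
    return spec, lm, vol


@pytest.fixture(scope="session")
def lesion_phantom():
    """Noise-free fibrotic-muscle phantom with 20% lesion burden."""
    spec = study.default_phantom(
        muscle_t2=study.T2_DYW_MUSCLE_ONLY_MS, lesion_fraction=0.2, seed=7
    )
    lm = build_labelmap(spec)
    vol = simulate_dual_echo(
        lm, spec.tissues, study.DUAL_ECHO_ACQ, snr_te14=np.inf
    )
    return spec, lm, vol
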