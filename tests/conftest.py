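import numpy as np
import pytest

from trainrattle import synthetic
from trainrattle.datatypes import SWEEP_PRESETS


@pytest.fixture
def eyespot_profile():
    """Noise-free long display-feather profile (longest measured class)."""
    spec = synthetic.FeatherSpec("eyespot", L_R=1.12, jitter=0.0, seed=1)
    return synthetic.gen_rachis_profile(spec), spec


@pytest.fixture
def single_mode_sweep():
    """Noise-free swept-sine pair for one resonance at 25 Hz, Q = 5."""
    bank = synthetic.OscillatorBank(modes=((25.0, 5.0, 1.0),))
    drive, resp = synthetic.gen_swept_sine_pair(
        bank, SWEEP_PRESETS["high"], noise_sd=0.0, seed=0
    )
    return bank, SWEEP_PRESETS["high"], drive, resp


def lorentzian_tf(f0=25.0, Q=5.0, gain=1.0, f_lo=5.0, f_hi=60.0, df=0.02):
    """Analytic transfer function on a dense grid (no pipeline involved)."""
    from trainrattle.datatypes import TransferFunction

    f = np.arange(f_lo, f_hi, df)
    return TransferFunction(f, synthetic.lorentzian_magnitude(f, f0, Q, gain))
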