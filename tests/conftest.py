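import numpy as np
import pytest

from stimloop import calibration as cal
from stimloop import virtual_rig as rig


@pytest.fixture(scope="session")
def calibrated_rig():
    """A distorted optics model with a fitted degree-3 calibration map."""
    rng = np.random.default_rng(20240601)
    optics = rig.make_distorted_optics(rng)
    (vx, vy) = optics.voltage_bounds

    def inset(b, frac=0.03):
        lo, hi = b
        pad = frac * (hi - lo)
        return (lo + pad, hi - pad)

    raster = cal.make_raster(60, 60, (inset(vx), inset(vy)))
    obs = rig.acquire_raster_observations(raster, optics, rng)
    cmap = cal.fit_map(obs, degree=3)
    return optics, cmap


@pytest.fixture()
def identity_optics():
    """Noiseless, distortion-free optics: pixel = voltage / gain."""
    return rig.OpticsModel(gain_v_per_px=(0.01, 0.01), noise_sd_px=0.0)
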