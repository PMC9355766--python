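import numpy as np
import pytest

from dentinemp import (ChannelRenderParams, MPImage, TubuleFieldParams,
                       generate_tubule_field, render_channel_pair)


@pytest.fixture
def stripe_params():
    """Default small stripe field: 5 µm period, 256 px over 90 µm."""
    return TubuleFieldParams(period_um=5.0, n_px=256, field_um=90.0)


def make_pair(ratio: float, seed: int = 0, n_px: int = 128,
              noiseless: bool = True, photon_gain: float = 0.0):
    """Render a small co-registered (TPEF, SHG) pair at a given mean ratio."""
    params = TubuleFieldParams(period_um=5.0, n_px=n_px, field_um=45.0)
    pattern = generate_tubule_field(params, seed=seed)
    cp = ChannelRenderParams(shg_tpef_ratio=ratio,
                             photon_gain=0.0 if noiseless else photon_gain,
                             read_noise_sd=0.0)
    return render_channel_pair(pattern, cp, seed=seed,
                               pixel_size_um=params.pixel_size_um)


def make_image(data, pixel_size_um=0.35, channel="SHG", **kw):
    return MPImage(np.asarray(data, dtype=float), channel, pixel_size_um, **kw)
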