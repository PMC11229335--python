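import numpy as np
import pytest

from curtainkit import (
    MotorParams,
    OpticsParams,
    SegmentationThresholds,
)


@pytest.fixture
def optics():
    return OpticsParams()


@pytest.fixture
def quiet_optics():
    """Noise-free camera for exact round-trip checks."""
    return OpticsParams(background_sd=0.0, n_frames=120)


@pytest.fixture
def thresholds():
    return SegmentationThresholds()


@pytest.fixture
def single_component_motor():
    return MotorParams(
        mixture_weights=(1.0,),
        mixture_means_bp_s=(394.0,),
        mixture_sds_bp_s=(0.0,),
        track_len_weights=(1.0,),
        track_len_means_kb=(6.0,),
        track_len_sds_kb=(0.0,),
        pause_prob_per_frame=0.0,
        binding_rate=0.05,
    )


def make_spike_kymograph(pixel_series, optics=None, amplitude=500.0):
    """Build a noise-free kymograph with one emitter pixel per frame.

    pixel_series: sequence of pixel indices (the emitter position per
    frame). Intensity is a narrow PSF-free spike, background flat.
    """
    from curtainkit import KymographTriplet

    optics = optics or OpticsParams(background_sd=0.0, n_frames=len(pixel_series))
    n_frames = len(pixel_series)
    shape = (n_frames, optics.n_pixels)
    bg = optics.background_mean
    img = np.full(shape, bg)
    for t, p in enumerate(pixel_series):
        img[t, int(p)] += amplitude
    zeros = np.full(shape, bg)
    return KymographTriplet(
        green=img, blue=zeros.copy(), magenta=zeros.copy(), optics=optics
    )
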