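import numpy as np
import pytest

from ripsensors import ChannelKind, ChannelSignal, CleaningConfig, Recording


@pytest.fixture
def cleaning():
    return CleaningConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_signal(kind=ChannelKind.AB, fs=200.0, duration_s=60.0, freq_hz=0.25,
                amplitude=1.0, offset=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return ChannelSignal(
        kind=kind,
        samples=offset + amplitude * np.sin(2 * np.pi * freq_hz * t),
        sampling_rate_hz=fs,
    )


@pytest.fixture
def two_channel_recording():
    return Recording(
        subject_id="fix01",
        channels={
            ChannelKind.AB: make_signal(ChannelKind.AB),
            ChannelKind.TH: make_signal(ChannelKind.TH, amplitude=0.8),
        },
    )
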