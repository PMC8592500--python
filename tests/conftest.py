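import numpy as np
import pytest

from eeggan import preprocess as pp
from eeggan import synthetic as sy


@pytest.fixture(scope="session")
def desk_cfg() -> sy.SimConfig:
    return sy.PRESETS["desk"].replace(seed=7)


@pytest.fixture(scope="session")
def desk_dataset(desk_cfg):
    """60 labeled desk-preset segments (30 per class)."""
    return sy.simulate_dataset(desk_cfg, 30)


@pytest.fixture(scope="session")
def desk_images(desk_dataset):
    """64x64 spectrogram images of the desk dataset."""
    return pp.preprocess_dataset(desk_dataset, pp.DESK_PREPROCESS)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def band_log_power(seg: sy.EEGSegment, lo: float, hi: float) -> float:
    """Welch log band power averaged over channels (independent oracle)."""
    from scipy.signal import welch

    f, p = welch(seg.samples, fs=seg.fs, nperseg=min(512, seg.samples.shape[1]))
    sel = (f >= lo) & (f <= hi)
    return float(np.log(p[:, sel].mean()))
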