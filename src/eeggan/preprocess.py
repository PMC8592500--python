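"""EEG segments -> normalized spectrogram images.

The pipeline per segment: Butterworth band-stop removal of mains noise (the
fundamental and its first harmonic), a per-channel short-time Fourier
transform with non-overlapping windows, vertical concatenation of the channel
spectrograms along the frequency axis, optional log(1+m) compression, bilinear
resize to a square, per-image min-max normalization to [-1, 1], and
replication to 3 identical channels so the result is RGB-shaped.  The output
shape is fixed regardless of channel count or sampling rate, which is what
lets one generator/classifier architecture serve different recording setups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from skimage.transform import resize as sk_resize

from .synthetic import EEGSegment

log = logging.getLogger(__name__)


def default_notch_bands(line_freq: float) -> tuple:
    """Stop bands around the mains fundamental and first harmonic (+/- 3 Hz)."""
    return ((line_freq - 3.0, line_freq + 3.0),
            (2 * line_freq - 3.0, 2 * line_freq + 3.0))


@dataclass(frozen=True)
class PreprocessConfig:
    window_len: float = 60.0      # STFT window (s); 1 min, no overlap
    overlap: float = 0.0          # fraction of window overlapped
    out_size: int = 256           # S: output image side
    line_freq: float = 50.0
    notch_bands: tuple | None = None  # None -> derived from line_freq
    filter_order: int = 4
    log_transform: bool = True
    normalize: str = "per-image-minmax"

    def __post_init__(self):
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if self.out_size < 8:
            raise ValueError("out_size must be >= 8")

    def bands(self) -> tuple:
        return self.notch_bands if self.notch_bands is not None \
            else default_notch_bands(self.line_freq)


@dataclass
class SpectrogramImage:
    """An (S, S, 3) image in [-1, 1] with label and provenance."""

    pixels: np.ndarray
    label: str
    source: str = "real"          # "real" | "generated"
    subject_id: str = "sim"
    t_start: float = 0.0
    accepted: bool | None = None  # set by the one-class-SVM selector

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 \
                or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"pixels must be (S, S, 3), got {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels contain NaN/Inf")
        if self.pixels.min() < -1.0 - 1e-6 or self.pixels.max() > 1.0 + 1e-6:
            raise ValueError("pixels must lie in [-1, 1]")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


#: small fast configuration matched to the "desk" simulation preset:
#: 1 s windows over 8 s segments -> 8 columns per channel, 64x64 images
DESK_PREPROCESS = PreprocessConfig(window_len=1.0, out_size=64, line_freq=60.0)


def remove_line_noise(seg: EEGSegment, cfg: PreprocessConfig) -> EEGSegment:
    """Zero-phase Butterworth band-stop filtering of the configured mains bands.

    Bands whose upper edge reaches Nyquist are skipped with a log message
    (harmonics of 60 Hz at fs=256, for instance).  If the fundamental band
    itself is infeasible, that is an error.
    """
    nyq = seg.fs / 2.0
    x = seg.samples
    usable = []
    for i, (lo, hi) in enumerate(cfg.bands()):
        if lo <= 0 or hi >= nyq:
            if i == 0:
                raise ValueError(
                    f"fundamental stop band ({lo}-{hi} Hz) not inside (0, {nyq}) Hz")
            log.info("skipping stop band %.0f-%.0f Hz (Nyquist %.0f Hz)", lo, hi, nyq)
            continue
        usable.append((lo, hi))
    for lo, hi in usable:
        sos = sps.butter(cfg.filter_order, [lo, hi], btype="bandstop",
                         fs=seg.fs, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=-1)
    return EEGSegment(x, seg.fs, seg.channel_names, seg.label,
                      seg.subject_id, seg.t_start)


def stft_channel(x: np.ndarray, fs: float, cfg: PreprocessConfig) -> np.ndarray:
    """Magnitude STFT of one channel, Hann window, FFT length = window length.

    Returns (n_freq_bins, n_windows) with
    ``n_windows = floor((len/fs - W) / (W * (1 - overlap))) + 1``; phase is
    discarded.  Only complete windows are used (no edge padding), so the
    window count is exactly the formula above.
    """
    x = np.asarray(x, dtype=np.float64)
    nper = int(round(cfg.window_len * fs))
    if x.size < nper:
        raise ValueError(f"signal of {x.size} samples shorter than one "
                         f"{nper}-sample window")
    hop = max(int(round(nper * (1.0 - cfg.overlap))), 1)
    n_win = (x.size - nper) // hop + 1
    idx = np.arange(nper)[None, :] + hop * np.arange(n_win)[:, None]
    frames = x[idx] * sps.windows.hann(nper, sym=False)
    return np.abs(np.fft.rfft(frames, axis=1)).T


def assemble_image(per_channel: list[np.ndarray], cfg: PreprocessConfig,
                   label: str = "interictal", source: str = "real",
                   subject_id: str = "sim", t_start: float = 0.0) -> SpectrogramImage:
    """Stack channel spectrograms vertically and normalize into an (S, S, 3) image.

    Channels are stacked along the frequency axis in channel order, optionally
    log(1+m)-compressed, bilinearly resized to (S, S), then min-max normalized
    to [-1, 1] and replicated to 3 identical channels.  A constant image maps
    to -1 everywhere by convention.
    """
    if not per_channel:
        raise ValueError("no channel matrices given")
    n_win = per_channel[0].shape[1]
    for i, m in enumerate(per_channel):
        if m.ndim != 2 or m.shape[1] != n_win:
            raise ValueError(f"channel {i} has window count {m.shape[1]}, "
                             f"expected {n_win}")
    stack = np.vstack(per_channel)
    if cfg.log_transform:
        stack = np.log1p(stack)
    img = sk_resize(stack, (cfg.out_size, cfg.out_size), order=1,
                    mode="edge", anti_aliasing=True, preserve_range=True)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        img = np.full_like(img, -1.0)
    else:
        img = 2.0 * (img - lo) / (hi - lo) - 1.0
    pixels = np.repeat(img[:, :, None], 3, axis=2).astype(np.float32)
    return SpectrogramImage(pixels, label, source, subject_id, t_start)


def preprocess_segment(seg: EEGSegment, cfg: PreprocessConfig,
                       source: str = "real") -> SpectrogramImage:
    clean = remove_line_noise(seg, cfg)
    mats = [stft_channel(clean.samples[ch], clean.fs, cfg)
            for ch in range(clean.n_channels)]
    return assemble_image(mats, cfg, label=seg.label, source=source,
                          subject_id=seg.subject_id, t_start=seg.t_start)


def preprocess_dataset(segments: list[EEGSegment], cfg: PreprocessConfig,
                       source: str = "real") -> list[SpectrogramImage]:
    """Map segments to images, preserving labels, provenance and timestamps."""
    images = []
    for i, seg in enumerate(segments):
        try:
            images.append(preprocess_segment(seg, cfg, source=source))
        except Exception as exc:
            raise RuntimeError(f"preprocessing failed on segment {i}: {exc}") from exc
    counts: dict[str, int] = {}
    for im in images:
        counts[im.label] = counts.get(im.label, 0) + 1
    log.info("preprocessed %d segments: %s", len(images), counts)
    return images


def images_to_array(images: list[SpectrogramImage]) -> np.ndarray:
    """Stack images into an (N, S, S, 3) float32 array."""
    return np.stack([im.pixels for im in images]).astype(np.float32)
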