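"""Seeded synthetic EEG generator.

Produces labeled multichannel segments and continuous seizure timelines with
the statistical structure the prediction pipeline assumes: a 1/f^alpha
background, class-dependent narrowband oscillations (the pre-ictal and
interictal classes differ only in their band parameters), mains-frequency line
noise and white sensor noise.  This is a test-bench signal model, not a
physiological one: it makes the two classes learnably separable through band
power, which is the minimal structure the spectrogram/GAN/classifier chain
needs to be exercised end to end.

Every draw is derived from ``SimConfig.seed`` through per-segment
``SeedSequence`` substreams, so segment *i* of a dataset is reproducible in
isolation and identical configs give bit-identical data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PREICTAL = "preictal"
INTERICTAL = "interictal"
LABELS = (INTERICTAL, PREICTAL)

#: minimum distance (hours) from any seizure onset for interictal segments
INTERICTAL_GAP_H = 4.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic EEG signal model.

    Band specs are ``(center_hz, bandwidth_hz, amplitude)`` triples; each
    segment draws one sinusoid per band with frequency uniform in
    ``center +/- bandwidth/2`` and a random phase per channel.
    """

    n_channels: int = 8
    fs: float = 256.0
    segment_len: float = 8.0
    preictal_bands: tuple = ((21.0, 4.0, 2.5), (36.0, 6.0, 2.0))
    interictal_bands: tuple = ((9.0, 3.0, 2.5), (14.0, 3.0, 1.5))
    background_exponent: float = 1.0
    background_amp: float = 1.0
    line_noise_freq: float = 60.0
    line_noise_amp: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.segment_len <= 0:
            raise ValueError("segment_len must be positive")
        centers = [b[0] for b in self.preictal_bands + self.interictal_bands]
        if centers and self.fs <= 2 * max(centers):
            raise ValueError(
                f"fs={self.fs} violates Nyquist for band center {max(centers)} Hz")

    @property
    def n_samples(self) -> int:
        return int(round(self.segment_len * self.fs))

    def bands_for(self, label: str) -> tuple:
        _check_label(label)
        return self.preictal_bands if label == PREICTAL else self.interictal_bands

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _check_label(label: str) -> None:
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; allowed labels: {list(LABELS)}")


#: built-in presets: intracranial-like, scalp-like, and a small fast preset
PRESETS: dict[str, SimConfig] = {
    "ieeg-like": SimConfig(n_channels=16, fs=400.0, segment_len=600.0,
                           line_noise_freq=50.0),
    "scalp-like": SimConfig(n_channels=22, fs=256.0, segment_len=600.0,
                            line_noise_freq=60.0),
    "desk": SimConfig(n_channels=8, fs=256.0, segment_len=8.0,
                      line_noise_freq=60.0),
}


@dataclass
class EEGSegment:
    """One labeled multichannel window of raw signal."""

    samples: np.ndarray  # (n_channels, n_timepoints)
    fs: float
    channel_names: list[str]
    label: str
    subject_id: str = "sim"
    t_start: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x timepoints)")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain NaN/Inf")
        _check_label(self.label)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class SeizureTimeline:
    """A continuous recording description with ground-truth seizure onsets."""

    duration_h: float
    seizure_onsets: list[float]  # seconds, strictly increasing
    segment_index: list[tuple[float, str]]  # (t_start seconds, label)

    def __post_init__(self):
        on = np.asarray(self.seizure_onsets, dtype=float)
        if on.size and (np.any(np.diff(on) <= 0) or on[0] < 0
                        or on[-1] > self.duration_h * 3600):
            raise ValueError("onsets must be strictly increasing within [0, duration]")


def _segment_rng(seed: int, index: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index, LABELS.index(label))))


def _one_over_f(rng: np.random.Generator, n: int, fs: float, alpha: float,
                amp: float) -> np.ndarray:
    """1/f^alpha shaped Gaussian noise, unit-free amplitude scaling."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-alpha / 2.0)
    shaping[0] = 0.0
    sig = np.fft.irfft(spec * shaping, n=n)
    sd = sig.std()
    return amp * sig / sd if sd > 0 else sig


def simulate_segment(cfg: SimConfig, label: str, subject_id: str = "sim",
                     segment_index: int = 0, t_start: float = 0.0) -> EEGSegment:
    """Draw one segment: background + class-band sinusoids + line noise + white noise."""
    _check_label(label)
    rng = _segment_rng(cfg.seed, segment_index, label)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    x = np.zeros((cfg.n_channels, n))
    line_phase = rng.uniform(0, 2 * np.pi)
    for ch in range(cfg.n_channels):
        if cfg.background_amp > 0:
            x[ch] += _one_over_f(rng, n, cfg.fs, cfg.background_exponent,
                                 cfg.background_amp)
        for center, bw, amp in cfg.bands_for(label):
            f = rng.uniform(center - bw / 2.0, center + bw / 2.0)
            x[ch] += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if cfg.line_noise_amp > 0:
            x[ch] += cfg.line_noise_amp * np.sin(
                2 * np.pi * cfg.line_noise_freq * t + line_phase)
        if cfg.noise_sd > 0:
            x[ch] += cfg.noise_sd * rng.standard_normal(n)
    names = [f"ch{i:02d}" for i in range(cfg.n_channels)]
    return EEGSegment(x, cfg.fs, names, label, subject_id, t_start)


def simulate_dataset(cfg: SimConfig, n_per_class: int,
                     subject_id: str = "sim") -> list[EEGSegment]:
    """Balanced dataset of ``2 * n_per_class`` segments, interictal first.

    Segment *i* of each class uses substream ``(seed, i, class)``, so any
    segment can be regenerated in isolation.  Segments are given synthetic,
    non-overlapping ``t_start`` stamps in draw order so that time-disjoint
    train/test splits are well defined downstream.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    segments = []
    step = cfg.segment_len
    for label in LABELS:
        for i in range(n_per_class):
            # interleave class timestamps so any time-based split stays balanced
            t0 = (2 * i + LABELS.index(label)) * step
            segments.append(simulate_segment(cfg, label, subject_id,
                                             segment_index=i, t_start=t0))
    return segments


def simulate_timeline(cfg: SimConfig, duration_h: float, n_seizures: int,
                      sph: float, sop: float,
                      interictal_gap_h: float = INTERICTAL_GAP_H,
                      max_preictal_per_seizure: int = 8,
                      max_interictal: int = 64) -> SeizureTimeline:
    """Lay out a continuous recording with seizure onsets and labeled segments.

    ``sph`` and ``sop`` are in minutes.  Onsets are placed in the tail of the
    recording, spaced by more than ``sph + sop``; pre-ictal segments are tiled
    backwards from ``onset - sph`` and interictal segments from regions at
    least ``interictal_gap_h`` hours from every onset.  Raises if the requested
    number of seizures cannot be packed into the duration.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    if sph <= 0 or sop <= 0:
        raise ValueError("sph and sop must be positive (minutes)")
    dur_s = duration_h * 3600.0
    seg = cfg.segment_len
    sph_s, sop_s = sph * 60.0, sop * 60.0
    if n_seizures == 0:
        onsets: list[float] = []
    else:
        spacing = (sph_s + sop_s) * 1.25 + seg
        lead = interictal_gap_h * 3600.0 * 0.5 + sph_s + max_preictal_per_seizure * seg
        first = dur_s - (n_seizures - 1) * spacing - seg
        if first < lead or first < sph_s + seg:
            raise ValueError(
                f"cannot pack {n_seizures} seizures separated by >SPH+SOP into "
                f"{duration_h} h (need more than "
                f"{(lead + (n_seizures - 1) * spacing + seg) / 3600:.2f} h)")
        onsets = [first + i * spacing for i in range(n_seizures)]
    index: list[tuple[float, str]] = []
    for onset in onsets:
        end = onset - sph_s
        for j in range(max_preictal_per_seizure):
            t0 = end - (j + 1) * seg
            if t0 < 0 or any(abs(t0 - o) < 1e-9 for o, _ in index):
                break
            # pre-ictal windows must not bleed into another seizure's SPH
            index.append((t0, PREICTAL))
    gap_s = interictal_gap_h * 3600.0
    t0 = 0.0
    n_inter = 0
    while t0 + seg <= dur_s and n_inter < max_interictal:
        if all(t0 + seg <= o - gap_s or t0 >= o + gap_s for o in onsets):
            index.append((t0, INTERICTAL))
            n_inter += 1
        t0 += seg
    index.sort(key=lambda p: p[0])
    return SeizureTimeline(duration_h, list(onsets), index)


def timeline_segments(cfg: SimConfig, timeline: SeizureTimeline,
                      subject_id: str = "sim") -> list[EEGSegment]:
    """Materialize the EEG segments listed in a timeline's segment index."""
    out = []
    for i, (t0, label) in enumerate(timeline.segment_index):
        out.append(simulate_segment(cfg, label, subject_id, segment_index=i,
                                    t_start=t0))
    return out


# ---------------------------------------------------------------------------
# dataset persistence: flat .npy arrays + JSON manifest


def save_dataset(segments: list[EEGSegment], out_dir: str | Path,
                 cfg: SimConfig | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, seg in enumerate(segments):
        fname = f"segment_{i:05d}.npy"
        np.save(out / fname, seg.samples)
        entries.append({"file": fname, "label": seg.label, "fs": seg.fs,
                        "channel_names": seg.channel_names,
                        "subject_id": seg.subject_id, "t_start": seg.t_start})
    manifest = {"format": "eeggan-dataset-v1", "segments": entries,
                "config": dataclasses.asdict(cfg) if cfg else None}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_dataset(in_dir: str | Path) -> list[EEGSegment]:
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    segments = []
    for e in manifest["segments"]:
        segments.append(EEGSegment(np.load(root / e["file"]), e["fs"],
                                   e["channel_names"], e["label"],
                                   e["subject_id"], e["t_start"]))
    return segments


def load_edf(path: str | Path, label: str, segment_len: float,
             subject_id: str = "edf") -> list[EEGSegment]:
    """Cut a real EDF recording into fixed-length labeled segments (needs mne)."""
    import mne  # optional dependency

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    fs = float(raw.info["sfreq"])
    n = int(round(segment_len * fs))
    out = []
    for k in range(data.shape[1] // n):
        out.append(EEGSegment(data[:, k * n:(k + 1) * n], fs,
                              list(raw.ch_names), label, subject_id,
                              t_start=k * segment_len))
    return out
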