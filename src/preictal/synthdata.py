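"""Seeded synthetic EEG recordings, annotations, and loss trajectories.

The generator emulates the statistical structure the pipeline assumes of
scalp EEG: 22 channels sampled at 256 Hz, additive 60 Hz mains
contamination, a sub-1 Hz drift component, 1/f-shaped background noise,
and — the feature the classifier learns — a class-dependent low-frequency
(1-4 Hz) sinusoid bank whose amplitude is higher during inter-ictal spans
than during pre-ictal spans. Class spans are derived from the seizure
annotations with the same segmentation rules the pipeline itself uses, so
the generator and the segmenter cross-validate each other.

It does not attempt physiologically realistic seizure morphology or
artifact simulation (blinks, EMG); see the methods note for what that
implies about test coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import data_io
from .data_io import SeizureEvent
from .segmentation import SegmentationConfig, label_states

__all__ = [
    "SynthConfig",
    "LossCurveSpec",
    "generate_recording",
    "generate_loss_curve",
    "generate_dataset",
    "band_power",
]

#: Frequencies (Hz) of the class-modulated low-frequency sinusoid bank.
_LOWFREQ_BANK = (1.5, 2.5, 3.5)
_DRIFT_HZ = 0.3


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.

    Amplitudes are relative units; the class gains multiply the amplitude
    of the 1-4 Hz bank inside pre-ictal and inter-ictal spans respectively
    (elsewhere their mean applies). The inter-ictal gain must exceed the
    pre-ictal gain, encoding the observed low-frequency energy contrast.
    """

    duration: float
    n_channels: int = 22
    fs: float = 256.0
    seizure_events: tuple[tuple[float, float], ...] = ()
    line_noise_hz: float = 60.0
    line_noise_amp: float = 1.0
    drift_amp: float = 1.0
    preictal_lowfreq_gain: float = 1.0
    interictal_lowfreq_gain: float = 4.0
    noise_sd: float = 0.5
    seed: int = 0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_channels <= 0:
            raise ValueError("n_channels must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.interictal_lowfreq_gain > self.preictal_lowfreq_gain:
            raise ValueError(
                "interictal_lowfreq_gain must exceed preictal_lowfreq_gain "
                "(the low-frequency energy contrast)"
            )
        last_end = 0.0
        for start, end in self.seizure_events:
            if not 0 <= start < end <= self.duration:
                raise ValueError(
                    f"seizure ({start}, {end}) must lie within [0, {self.duration}]"
                )
            if start < last_end:
                raise ValueError("seizure events must be sorted and non-overlapping")
            last_end = end


@dataclass(frozen=True)
class LossCurveSpec:
    """Template + noise description of a validation-loss trajectory."""

    kind: Literal["decreasing", "plateau", "increasing", "v_shaped"]
    length: int
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("decreasing", "plateau", "increasing", "v_shaped"):
            raise ValueError(f"unknown loss-curve kind {self.kind!r}")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def _gain_envelope(config: SynthConfig, n: int) -> np.ndarray:
    """Per-sample low-frequency gain derived from the state segmentation."""
    other = 0.5 * (config.preictal_lowfreq_gain + config.interictal_lowfreq_gain)
    env = np.full(n, other)
    events = [SeizureEvent("synth", s, e) for s, e in config.seizure_events]
    intervals = label_states(events, config.duration, config.segmentation, file_id="synth")
    for iv in intervals:
        a = int(np.floor(iv.start_s * config.fs))
        b = int(np.floor(iv.end_s * config.fs))
        if iv.state == "preictal":
            env[a:b] = config.preictal_lowfreq_gain
        elif iv.state == "interictal":
            env[a:b] = config.interictal_lowfreq_gain
    return env


def generate_recording(config: SynthConfig) -> tuple[np.ndarray, list[SeizureEvent]]:
    """Synthesize one recording: ([n_channels x n_samples] array, annotations).

    Deterministic for a fixed (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    env = _gain_envelope(config, n)

    signal = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        x = np.zeros(n)
        for f in _LOWFREQ_BANK:
            phase = rng.uniform(0, 2 * np.pi)
            x += env * np.sin(2 * np.pi * f * t + phase)
        x += config.line_noise_amp * np.sin(
            2 * np.pi * config.line_noise_hz * t + rng.uniform(0, 2 * np.pi)
        )
        x += config.drift_amp * np.sin(2 * np.pi * _DRIFT_HZ * t + rng.uniform(0, 2 * np.pi))
        if config.noise_sd > 0:
            x += config.noise_sd * _pink_noise(rng, n)
            x += config.noise_sd * rng.standard_normal(n)
        else:
            # keep the draw count identical so the deterministic part of the
            # signal does not depend on noise_sd
            pass
        signal[ch] = x

    annotations = [SeizureEvent("synth", s, e) for s, e in config.seizure_events]
    return signal, annotations


def generate_loss_curve(spec: LossCurveSpec) -> np.ndarray:
    """Validation-loss trajectory following the requested template."""
    rng = np.random.default_rng(spec.seed)
    i = np.arange(spec.length, dtype=np.float64)
    if spec.kind == "decreasing":
        base = 0.5 + 1.5 * np.exp(-3.0 * i / spec.length)
    elif spec.kind == "increasing":
        base = 0.5 + 1.5 * (1.0 - np.exp(-3.0 * i / spec.length))
    elif spec.kind == "plateau":
        base = np.full(spec.length, 1.0)
    else:  # v_shaped, minimum at length // 2
        mid = spec.length // 2
        base = 0.5 + np.abs(i - mid) / spec.length
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, spec.length)
    return base


def generate_dataset(
    config: SynthConfig,
    n_recordings: int,
    seed: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write ``n_recordings`` EDF files + annotation summary + TSV manifest.

    Recording i reuses ``config`` with seed ``seed + i``. Returns the
    manifest (columns: file, n_seizures, duration_s); the summary text is
    written as ``summary.txt`` and the manifest as ``manifest.tsv``.
    """
    if n_recordings < 1:
        raise ValueError("n_recordings must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    events_by_file: dict[str, list[SeizureEvent]] = {}
    for i in range(n_recordings):
        cfg = replace(config, seed=seed + i)
        signal, _ = generate_recording(cfg)
        fname = f"rec{i:02d}.edf"
        data_io.write_recording(out_dir / fname, signal, cfg.fs)
        events_by_file[fname] = [
            SeizureEvent(fname, s, e) for s, e in cfg.seizure_events
        ]
        rows.append((fname, len(cfg.seizure_events), cfg.duration))

    (out_dir / "summary.txt").write_text(data_io.format_annotations(events_by_file))
    manifest = pd.DataFrame(rows, columns=["file", "n_seizures", "duration_s"])
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def band_power(
    x: np.ndarray, fs: float, f_lo: float = 1.0, f_hi: float = 4.0
) -> float:
    """Mean Welch power spectral density of ``x`` within [f_lo, f_hi] Hz."""
    x = np.asarray(x)
    nper = min(x.shape[-1], int(4 * fs))
    freqs, psd = sps.welch(x, fs=fs, nperseg=nper, axis=-1)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    return float(psd[..., band].mean())
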