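"""End-to-end helpers wiring the stages into the two study pipelines.

The canonical flow is: filter the raw recording (notch + high-pass),
derive state intervals from the seizure annotations, extract the
pre-ictal and inter-ictal slices, min-max scale each channel of each
slice, window both classes (50% overlap for the minority class), and
reshape every 10-s epoch into the [channels x 10 x 256] grid.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data_io import SeizureEvent, WindowStore
from .preprocessing import (
    WindowConfig,
    apply_filters,
    balance_classes,
    scale_per_channel,
)
from .segmentation import SegmentationConfig, extract_state, label_states
from .synthdata import SynthConfig, generate_recording

__all__ = ["recording_to_slices", "prepare_windows", "build_synthetic_store"]


def recording_to_slices(
    signal: np.ndarray,
    events: Sequence[SeizureEvent],
    fs: float,
    seg_config: SegmentationConfig | None = None,
    file_id: str = "",
    filter_kwargs: dict | None = None,
) -> dict[str, tuple[list[np.ndarray], list[tuple[str, int]]]]:
    """Filter a recording and extract its scaled pre-/inter-ictal slices.

    Returns ``{"preictal": (slices, provenance), "interictal": ...}`` where
    each slice is per-channel min-max scaled to [0, 1] and provenance holds
    (file_id, start_sample) of every slice.
    """
    cfg = seg_config or SegmentationConfig()
    filtered = apply_filters(signal, fs, **(filter_kwargs or {}))
    duration = signal.shape[-1] / fs
    intervals = label_states(events, duration, cfg, file_id=file_id)
    out: dict[str, tuple[list[np.ndarray], list[tuple[str, int]]]] = {}
    for state in ("preictal", "interictal"):
        ivs = [iv for iv in intervals if iv.state == state]
        slices = [scale_per_channel(s) for s in extract_state(filtered, intervals, state, fs)]
        prov = [(file_id, int(np.floor(iv.start_s * fs))) for iv in ivs]
        out[state] = (slices, prov)
    return out


def prepare_windows(
    recordings: Sequence[tuple[np.ndarray, list[SeizureEvent], str]],
    fs: float,
    window_config: WindowConfig | None = None,
    seg_config: SegmentationConfig | None = None,
) -> WindowStore:
    """Full preprocessing of several recordings into one balanced store."""
    pre_slices: list[np.ndarray] = []
    pre_prov: list[tuple[str, int]] = []
    int_slices: list[np.ndarray] = []
    int_prov: list[tuple[str, int]] = []
    for signal, events, file_id in recordings:
        parts = recording_to_slices(signal, events, fs, seg_config, file_id)
        s, p = parts["preictal"]
        pre_slices += s
        pre_prov += p
        s, p = parts["interictal"]
        int_slices += s
        int_prov += p
    return balance_classes(pre_slices, int_slices, window_config,
                           preictal_provenance=pre_prov,
                           interictal_provenance=int_prov)


def build_synthetic_store(
    seed: int = 0,
    preictal_gain: float = 1.0,
    interictal_gain: float = 4.0,
    n_channels: int = 22,
    fs: float = 256.0,
    shuffle_labels: bool = False,
) -> WindowStore:
    """The reduced-scale synthetic study dataset (~440 windows).

    Two recordings: one with two seizures spaced so both full 10-min
    pre-ictal periods survive (238 pre-ictal windows at 50% overlap), and
    one seizure-free recording treated as inter-ictal under the no-seizure
    convention (205 non-overlapping windows). ``shuffle_labels=True``
    returns the label-permuted control used for chance-level checks.
    """
    seizure_cfg = SynthConfig(
        duration=3900.0,
        n_channels=n_channels,
        fs=fs,
        seizure_events=((1000.0, 1050.0), (3850.0, 3890.0)),
        preictal_lowfreq_gain=preictal_gain,
        interictal_lowfreq_gain=interictal_gain,
        seed=seed,
    )
    baseline_cfg = SynthConfig(
        duration=2050.0,
        n_channels=n_channels,
        fs=fs,
        seizure_events=(),
        preictal_lowfreq_gain=preictal_gain,
        interictal_lowfreq_gain=interictal_gain,
        seed=seed + 1,
    )
    sig_a, ev_a = generate_recording(seizure_cfg)
    sig_b, ev_b = generate_recording(baseline_cfg)
    store = prepare_windows(
        [(sig_a, ev_a, "synth-seizure"), (sig_b, ev_b, "synth-baseline")], fs=fs
    )
    if shuffle_labels:
        rng = np.random.default_rng(seed + 99)
        store.labels = rng.permutation(store.labels)
    return store
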