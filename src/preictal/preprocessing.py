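"""Signal conditioning and window preparation.

Order of operations in the pipeline: notch + high-pass filtering on the raw
recording, state extraction, per-channel min-max scaling, sliding-window
epoching (with 50% overlap for the minority class to balance the two
classes), and reshaping each 10-s epoch into a [channels x 10 x 256] grid.

The window count for a slice of N samples is ``n = floor((N - w) / hop) + 1``
with window length ``w = window_s * fs`` samples and hop ``overlap * w``
(or ``w`` when the overlap is zero), i.e. 1280 samples at the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data_io import CLASS_MAP, WindowStore

__all__ = [
    "WindowConfig",
    "ScaleParams",
    "SplitSpec",
    "minmax_scale",
    "count_windows",
    "slide_windows",
    "reshape_epoch",
    "flatten_grid",
    "apply_filters",
    "balance_classes",
    "partition",
]


@dataclass(frozen=True)
class WindowConfig:
    """Epoching geometry: 10-s windows at 256 Hz, overlap as a fraction."""

    window_s: float = 10.0
    fs: float = 256.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        ws = self.window_s * self.fs
        if ws <= 0 or abs(ws - round(ws)) > 1e-9:
            raise ValueError("window_s * fs must be a positive integer")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def hop(self) -> int:
        """Hop in samples; overlap fractions that give a fractional hop are rounded."""
        if self.overlap == 0.0:
            return self.window_samples
        hop = int(round(self.overlap * self.window_samples))
        if hop <= 0:
            raise ValueError("overlap too small: hop rounds to zero samples")
        return hop


@dataclass(frozen=True)
class ScaleParams:
    x_min: float
    x_max: float
    target_min: float = 0.0
    target_max: float = 1.0

    def __post_init__(self) -> None:
        if self.x_max < self.x_min:
            raise ValueError("x_max must be >= x_min")
        if self.target_max <= self.target_min:
            raise ValueError("target_max must be > target_min")


@dataclass(frozen=True)
class SplitSpec:
    """6:2:2 stratified train/validation/test split."""

    mode: str = "multi_patient"
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.mode not in ("multi_patient", "independent_patient"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def minmax_scale(x: np.ndarray, params: ScaleParams | None = None) -> np.ndarray:
    """Affine map of ``x`` from [x_min, x_max] onto [target_min, target_max].

    With ``params=None`` the bounds are taken from the data itself. A
    constant input maps everywhere to ``target_min`` (the usual library
    convention), never raising.
    """
    x = np.asarray(x, dtype=np.float64)
    p = params or ScaleParams(float(np.min(x)), float(np.max(x)))
    span = p.x_max - p.x_min
    if span == 0.0:
        return np.full_like(x, p.target_min)
    return (x - p.x_min) / span * (p.target_max - p.target_min) + p.target_min


def scale_per_channel(signal: np.ndarray, target: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Min-max scale each channel of a [channels x samples] signal independently."""
    out = np.empty_like(signal, dtype=np.float64)
    for ch in range(signal.shape[0]):
        out[ch] = minmax_scale(
            signal[ch],
            ScaleParams(float(signal[ch].min()), float(signal[ch].max()),
                        target[0], target[1]),
        )
    return out


def count_windows(n_samples: int, config: WindowConfig | None = None) -> int:
    """Number of full windows that fit in a slice of ``n_samples`` samples."""
    cfg = config or WindowConfig()
    w = cfg.window_samples
    if n_samples < w:
        return 0
    return (n_samples - w) // cfg.hop + 1


def slide_windows(signal_slice: np.ndarray, config: WindowConfig | None = None) -> np.ndarray:
    """Cut a [channels x samples] slice into [n x channels x window] epochs."""
    cfg = config or WindowConfig()
    signal_slice = np.atleast_2d(signal_slice)
    n = count_windows(signal_slice.shape[1], cfg)
    w, hop = cfg.window_samples, cfg.hop
    if n == 0:
        return np.empty((0, signal_slice.shape[0], w), dtype=signal_slice.dtype)
    return np.stack([signal_slice[:, i * hop:i * hop + w] for i in range(n)])


def reshape_epoch(epoch: np.ndarray, rows: int = 10, cols: int = 256) -> np.ndarray:
    """Reshape a [channels x rows*cols] epoch to a [channels x rows x cols] grid.

    Row i holds samples [cols*i, cols*(i+1)); the inverse reshape restores
    the epoch exactly.
    """
    epoch = np.asarray(epoch)
    if epoch.shape[-1] != rows * cols:
        raise ValueError(
            f"epoch length {epoch.shape[-1]} != {rows}*{cols} = {rows * cols}"
        )
    return epoch.reshape(*epoch.shape[:-1], rows, cols)


def flatten_grid(grid: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reshape_epoch`."""
    return np.asarray(grid).reshape(*grid.shape[:-2], -1)


def apply_filters(
    signal: np.ndarray,
    fs: float,
    notch_hz: float = 60.0,
    highpass_hz: float = 1.0,
    notch_q: float = 30.0,
    highpass_order: int = 4,
) -> np.ndarray:
    """Zero-phase 60 Hz notch plus 1 Hz high-pass along the last axis.

    Both filters run forward-backward (``sosfiltfilt``), so passband tones
    keep their phase; the notch removes mains interference and the
    high-pass removes sub-1 Hz drift.
    """
    if fs <= 2 * notch_hz:
        raise ValueError(f"fs={fs} too low to notch at {notch_hz} Hz")
    b, a = sps.iirnotch(notch_hz, Q=notch_q, fs=fs)
    sos_notch = sps.tf2sos(b, a)
    sos_hp = sps.butter(highpass_order, highpass_hz, btype="highpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos_notch, np.asarray(signal, dtype=np.float64), axis=-1)
    return sps.sosfiltfilt(sos_hp, out, axis=-1)


def _window_class(
    slices: list[np.ndarray],
    overlap: float,
    label: int,
    provenance: list[tuple[str, int]] | None,
    base: WindowConfig,
) -> tuple[list[np.ndarray], list[int], list[tuple[str, int]]]:
    cfg = WindowConfig(base.window_s, base.fs, overlap)
    epochs, labels, prov = [], [], []
    for j, sl in enumerate(slices):
        wins = slide_windows(sl, cfg)
        fid = provenance[j][0] if provenance else f"slice{j}"
        off = provenance[j][1] if provenance else 0
        for i in range(wins.shape[0]):
            epochs.append(wins[i])
            labels.append(label)
            prov.append((fid, off + i * cfg.hop))
    return epochs, labels, prov


def balance_classes(
    preictal_slices: list[np.ndarray],
    interictal_slices: list[np.ndarray],
    config: WindowConfig | None = None,
    preictal_provenance: list[tuple[str, int]] | None = None,
    interictal_provenance: list[tuple[str, int]] | None = None,
    grid_rows: int = 10,
) -> WindowStore:
    """Window both classes, upsampling the minority one by 50% overlap.

    The class with the smaller total duration is slid with the configured
    overlap (default 0.5); the majority class is tiled without overlap.
    Epochs are reshaped to grids and labeled 0 = pre-ictal, 1 = inter-ictal.
    """
    cfg = config or WindowConfig()
    if not preictal_slices:
        raise ValueError("pre-ictal class has no data")
    if not interictal_slices:
        raise ValueError("inter-ictal class has no data")
    dur_pre = sum(s.shape[-1] for s in preictal_slices)
    dur_int = sum(s.shape[-1] for s in interictal_slices)
    pre_overlap = cfg.overlap if dur_pre <= dur_int else 0.0
    int_overlap = cfg.overlap if dur_int < dur_pre else 0.0

    ep_p, lb_p, pv_p = _window_class(preictal_slices, pre_overlap, 0,
                                     preictal_provenance, cfg)
    ep_i, lb_i, pv_i = _window_class(interictal_slices, int_overlap, 1,
                                     interictal_provenance, cfg)
    if not ep_p or not ep_i:
        missing = "pre-ictal" if not ep_p else "inter-ictal"
        raise ValueError(f"{missing} class yields zero windows at this window length")

    cols = cfg.window_samples // grid_rows
    data = np.stack([reshape_epoch(e, grid_rows, cols) for e in ep_p + ep_i])
    labels = np.array(lb_p + lb_i, dtype=np.int64)
    return WindowStore(data=data.astype(np.float32), labels=labels,
                       provenance=pv_p + pv_i, class_map=dict(CLASS_MAP))


def partition(
    store: WindowStore,
    spec: SplitSpec | None = None,
) -> tuple[WindowStore, WindowStore, WindowStore]:
    """Stratified, seeded 6:2:2 split into (train, val, test) stores.

    Mirrors the two-stage protocol: hold out the test fraction first, then
    carve the validation fraction out of the remainder. Both stages are
    stratified by class label.
    """
    from sklearn.model_selection import train_test_split

    spec = spec or SplitSpec()
    n = len(store)
    if n < 5:
        raise ValueError(f"need at least 5 windows to partition, got {n}")
    f_train, f_val, f_test = spec.fractions
    idx = np.arange(n)
    strat = store.labels if len(np.unique(store.labels)) > 1 else None
    rest, test_idx = train_test_split(
        idx, test_size=f_test, random_state=spec.seed, stratify=strat
    )
    strat_rest = store.labels[rest] if strat is not None else None
    val_share = f_val / (f_train + f_val)
    train_idx, val_idx = train_test_split(
        rest, test_size=val_share, random_state=spec.seed, stratify=strat_rest
    )
    return store.subset(train_idx), store.subset(val_idx), store.subset(test_idx)
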