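"""Scaling, windowing, filtering, reshaping, balancing and partitioning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from preictal.preprocessing import (
    ScaleParams,
    SplitSpec,
    WindowConfig,
    apply_filters,
    balance_classes,
    count_windows,
    flatten_grid,
    minmax_scale,
    partition,
    reshape_epoch,
    slide_windows,
)


def enumerate_starts(n_samples, cfg):
    """Brute-force oracle: count valid window start positions."""
    w, hop = cfg.window_samples, cfg.hop
    return len([s for s in range(0, max(n_samples - w + 1, 0), hop)]) \
        if n_samples >= w else 0


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


# -- scaling ----------------------------------------------------------------

def test_minmax_worked_examples():
    np.testing.assert_allclose(minmax_scale([-2, 0, 2]), [0, 0.5, 1])
    np.testing.assert_allclose(minmax_scale([5, 5, 5]), [0, 0, 0])
    np.testing.assert_allclose(
        minmax_scale([0, 10], ScaleParams(0, 10, -1, 1)), [-1, 1])


@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
def test_minmax_output_within_target_range(xs):
    out = minmax_scale(np.array(xs))
    assert np.all(out >= -1e-9) and np.all(out <= 1 + 1e-9)


def test_scale_params_validation():
    with pytest.raises(ValueError):
        ScaleParams(1.0, 0.5)
    with pytest.raises(ValueError):
        ScaleParams(0.0, 1.0, target_min=1.0, target_max=0.0)


# -- window counting --------------------------------------------------------

@pytest.mark.parametrize("n,overlap,expected", [
    (2560, 0.5, 1),
    (12800, 0.5, 9),
    (2559, 0.5, 0),
    (5120, 0.0, 2),
    (3840, 0.5, 2),
])
def test_window_count_examples(n, overlap, expected):
    assert count_windows(n, WindowConfig(overlap=overlap)) == expected


def test_window_count_matches_enumeration_sweep():
    rng = np.random.default_rng(0)
    for _ in range(500):
        cfg = WindowConfig(
            window_s=float(rng.integers(1, 20)),
            fs=float(rng.choice([64, 128, 256])),
            overlap=float(rng.choice([0.0, 0.25, 0.5, 0.75])),
        )
        n = int(rng.integers(0, 100000))
        assert count_windows(n, cfg) == enumerate_starts(n, cfg)


def test_slide_windows_layout():
    cfg = WindowConfig(overlap=0.5)
    x = np.arange(3840, dtype=float)[None, :]
    wins = slide_windows(x, cfg)
    assert wins.shape == (2, 1, 2560)
    assert wins[0, 0, 0] == 0 and wins[1, 0, 0] == 1280
    single = slide_windows(np.arange(2560.0)[None, :], cfg)
    np.testing.assert_array_equal(single[0, 0], np.arange(2560.0))
    tiles = slide_windows(np.arange(5120.0)[None, :], WindowConfig(overlap=0.0))
    assert tiles.shape == (2, 1, 2560)
    assert tiles[1, 0, 0] == 2560


# -- epoch reshaping --------------------------------------------------------

def test_reshape_row_major_grid():
    epoch = np.arange(2560.0)[None, :]
    grid = reshape_epoch(epoch)
    assert grid.shape == (1, 10, 256)
    assert grid[0][1][0] == 256
    np.testing.assert_array_equal(flatten_grid(grid), epoch)
    with pytest.raises(ValueError):
        reshape_epoch(np.zeros((1, 2559)))


@given(st.integers(0, 2**31 - 1))
def test_reshape_roundtrip_identity(seed):
    rng = np.random.default_rng(seed)
    epoch = rng.standard_normal((3, 2560))
    np.testing.assert_array_equal(flatten_grid(reshape_epoch(epoch)), epoch)


# -- filtering --------------------------------------------------------------

def test_filter_attenuates_mains_and_drift_preserves_band():
    fs = 256.0
    t = np.arange(int(fs * 20)) / fs
    for freq, low in ((60.0, True), (0.3, True), (10.0, False)):
        tone = np.sin(2 * np.pi * freq * t)[None, :]
        out = apply_filters(tone, fs)
        ratio = rms(out) / rms(tone)
        if low:
            assert ratio <= 0.10
        else:
            assert ratio >= 0.90


def test_filter_is_zero_phase_at_10hz():
    fs = 256.0
    t = np.arange(int(fs * 20)) / fs
    tone = np.sin(2 * np.pi * 10.0 * t)
    out = apply_filters(tone[None, :], fs)[0]
    # cross-correlation lag over the interior (edges see transients)
    interior = slice(int(fs * 5), int(fs * 15))
    a, b = tone[interior], out[interior]
    xc = np.correlate(b, a, mode="full")
    lag = int(np.argmax(xc)) - (len(a) - 1)
    assert abs(lag) <= 1


def test_filter_linearity_on_zero_signal():
    out = apply_filters(np.zeros((2, 1024)), 256.0)
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_filter_rejects_low_sampling_rate():
    with pytest.raises(ValueError):
        apply_filters(np.zeros((1, 100)), fs=100.0)


# -- class balancing --------------------------------------------------------

def _slices(total_samples, n_channels=2, seed=0):
    rng = np.random.default_rng(seed)
    return [rng.standard_normal((n_channels, total_samples))]


def test_balancing_upsamples_minority_with_overlap():
    # minority (pre-ictal) duration half of majority
    pre = _slices(12800)       # 5 windows at 50% -> 9
    inter = _slices(25600, seed=1)  # 10 windows at 0% overlap
    store = balance_classes(pre, inter)
    n_pre = int((store.labels == 0).sum())
    n_int = int((store.labels == 1).sum())
    assert n_pre == 9 and n_int == 10
    assert 0.8 <= n_pre / n_int <= 1.25
    assert store.data.shape[1:] == (2, 10, 256)
    assert len(store.provenance) == len(store)


def test_balancing_equal_durations_keeps_ratio_at_most_two():
    pre = _slices(25600)
    inter = _slices(25600, seed=1)
    store = balance_classes(pre, inter)
    n_pre = int((store.labels == 0).sum())
    n_int = int((store.labels == 1).sum())
    assert n_int == 10 and n_pre == 19  # 50% overlap nearly doubles
    assert n_pre / n_int <= 2


def test_balancing_rejects_empty_class():
    with pytest.raises(ValueError, match="inter-ictal"):
        balance_classes(_slices(5120), [])


# -- partitioning -----------------------------------------------------------

def _store(n, seed=0):
    from preictal.data_io import WindowStore

    rng = np.random.default_rng(seed)
    return WindowStore(
        data=rng.standard_normal((n, 1, 10, 256)).astype(np.float32),
        labels=np.tile([0, 1], n // 2 + 1)[:n],
        provenance=[("f", i) for i in range(n)],
    )


@pytest.mark.parametrize("n,sizes", [(1000, (600, 200, 200)), (10, (6, 2, 2))])
def test_partition_sizes(n, sizes):
    train, val, test = partition(_store(n), SplitSpec(seed=1))
    assert (len(train), len(val), len(test)) == sizes


def test_partition_is_deterministic_and_disjoint():
    store = _store(100)
    a = partition(store, SplitSpec(seed=7))
    b = partition(store, SplitSpec(seed=7))
    for pa, pb in zip(a, b):
        np.testing.assert_array_equal(pa.data, pb.data)
    ids = [prov for part in a for prov in part.provenance]
    assert len(ids) == 100 and len(set(ids)) == 100


def test_partition_stratifies_labels():
    train, val, test = partition(_store(100), SplitSpec(seed=3))
    for part in (train, val, test):
        frac = np.mean(part.labels == 0)
        assert 0.4 <= frac <= 0.6


def test_partition_rejects_tiny_store():
    with pytest.raises(ValueError):
        partition(_store(4))
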