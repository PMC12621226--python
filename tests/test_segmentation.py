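"""State segmentation against an independent per-second label sweep."""

import numpy as np
import pytest

from preictal.data_io import SeizureEvent
from preictal.segmentation import (
    STATE_PRECEDENCE,
    SegmentationConfig,
    StateInterval,
    extract_state,
    label_states,
)


def sweep_oracle(events, length_s, cfg=None):
    """Label each integer second independently by the state rules (ictal,
    then SPH, then post-ictal, then pre-ictal, then inter-ictal) and merge
    runs into intervals."""
    cfg = cfg or SegmentationConfig()
    labels = []
    for s in range(int(length_s)):
        label = None
        for ev in events:
            if ev.start_s <= s < ev.end_s:
                label = "ictal"
                break
        if label is None:
            for ev in events:
                if ev.start_s - cfg.sph_s <= s < ev.start_s:
                    label = "sph"
                    break
        if label is None:
            for ev in events:
                if ev.end_s <= s < ev.end_s + cfg.postictal_len_s:
                    label = "postictal"
                    break
        if label is None:
            for ev in events:
                if ev.start_s - cfg.sph_s - cfg.preictal_len_s <= s < ev.start_s - cfg.sph_s:
                    label = "preictal"
                    break
        if label is None:
            far = all(
                s < ev.start_s - cfg.interictal_gap_s or s >= ev.end_s + cfg.interictal_gap_s
                for ev in events
            )
            if far:
                label = "interictal"
        labels.append(label)
    # merge runs
    out = []
    start = None
    for s, lab in enumerate(labels + [None]):
        prev = labels[s - 1] if s else None
        if lab != prev:
            if prev is not None and start is not None:
                out.append((prev, start, s))
            start = s if lab is not None else None
    return sorted(out, key=lambda t: (t[1], t[2]))


def as_tuples(intervals):
    return sorted(
        [(iv.state, iv.start_s, iv.end_s) for iv in intervals],
        key=lambda t: (t[1], t[2]),
    )


def test_single_seizure_worked_example():
    """One seizure at (3600, 3660) in an 18000-s recording."""
    ivs = label_states([SeizureEvent("f", 3600, 3660)], 18000)
    assert as_tuples(ivs) == [
        ("preictal", 2700.0, 3300.0),
        ("sph", 3300.0, 3600.0),
        ("ictal", 3600.0, 3660.0),
        ("postictal", 3660.0, 5460.0),
        ("interictal", 10860.0, 18000.0),
    ]


def test_early_seizure_clips_preictal():
    ivs = label_states([SeizureEvent("f", 600, 660)], 18000)
    pre = [iv for iv in ivs if iv.state == "preictal"]
    assert len(pre) == 1
    assert (pre[0].start_s, pre[0].end_s) == (0.0, 300.0)


def test_no_seizures_is_all_interictal():
    ivs = label_states([], 5000, file_id="quiet")
    assert as_tuples(ivs) == [("interictal", 0.0, 5000.0)]


def test_close_seizures_truncate_preictal_by_precedence():
    # second seizure 1000 s after the first ends: its pre-ictal candidate
    # collides with the first's post-ictal period and keeps the remainder
    ivs = label_states([SeizureEvent("f", 8000, 8050), SeizureEvent("f", 9050, 9100)], 20000)
    pre2 = [iv for iv in ivs if iv.state == "preictal" and iv.start_s > 8050]
    # post-ictal of seizure 1 covers [8050, 9850); sph2 covers [8750, 9050)
    # pre-ictal candidate [8150, 8750) is fully inside post-ictal -> dropped
    assert pre2 == []
    post1 = [iv for iv in ivs if iv.state == "postictal"]
    assert post1[0].start_s == 8050.0


def test_overlapping_events_rejected():
    with pytest.raises(ValueError):
        label_states([SeizureEvent("f", 100, 200), SeizureEvent("f", 150, 300)], 1000)


@pytest.mark.parametrize("seed", range(40))
def test_intervals_match_per_second_sweep(seed):
    """Randomized seizure layouts agree with the independent sweep oracle."""
    rng = np.random.default_rng(seed)
    length = int(rng.integers(4000, 30000))
    n_seiz = int(rng.integers(0, 4))
    starts = np.sort(rng.uniform(0, length - 100, n_seiz)).astype(int).astype(float)
    events = []
    last_end = 0.0
    for s in starts:
        s = max(s, last_end + 1)
        if s >= length:
            continue
        e = min(s + float(rng.integers(10, 120)), length)
        events.append(SeizureEvent("f", s, e))
        last_end = e
    ivs = label_states(events, length)
    assert as_tuples(ivs) == sweep_oracle(events, length)


def test_no_state_overlap_and_no_empty_intervals():
    rng = np.random.default_rng(123)
    for _ in range(50):
        length = int(rng.integers(3000, 25000))
        s = float(rng.integers(0, length - 200))
        e = s + float(rng.integers(10, 100))
        ivs = label_states([SeizureEvent("f", s, e)], length)
        for iv in ivs:
            assert iv.start_s < iv.end_s
        for a in ivs:
            for b in ivs:
                if a is b:
                    continue
                assert a.end_s <= b.start_s or b.end_s <= a.start_s


def test_training_classes_disjoint():
    """No second can belong to both the pre-ictal and inter-ictal class."""
    ivs = label_states([SeizureEvent("f", 9000, 9100)], 30000)
    pre = {(iv.start_s, iv.end_s) for iv in ivs if iv.state == "preictal"}
    inter = {(iv.start_s, iv.end_s) for iv in ivs if iv.state == "interictal"}
    for p0, p1 in pre:
        for i0, i1 in inter:
            assert p1 <= i0 or i1 <= p0


def test_extract_state_slices():
    fs = 256.0
    signal = np.arange(2, dtype=np.float64)[:, None] * np.zeros(30 * 256) \
        + np.arange(30 * 256)[None, :]
    ivs = [
        StateInterval("f", "interictal", 10.0, 20.0),
        StateInterval("f", "preictal", 0.0, 5.0),
        StateInterval("f", "preictal", 20.0, 25.0),
    ]
    inter = extract_state(signal, ivs, "interictal", fs)
    assert len(inter) == 1 and inter[0].shape == (2, 2560)
    assert inter[0][0, 0] == 10 * 256
    pre = extract_state(signal, ivs, "preictal", fs)
    assert len(pre) == 2
    assert pre[0][0, 0] < pre[1][0, 0]  # temporal order
    assert extract_state(signal, ivs, "ictal", fs) == []
    with pytest.raises(ValueError):
        extract_state(signal, [StateInterval("f", "ictal", 0.0, 31.0)], "ictal", fs)


def test_precedence_order_is_documented():
    assert STATE_PRECEDENCE == ("ictal", "sph", "postictal", "preictal", "interictal")
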