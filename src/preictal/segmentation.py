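"""Seizure-state segmentation of annotated recordings.

Each seizure with onset t0 and offset t1 induces, under the defaults:

* pre-ictal  ``[t0 - 900, t0 - 300)`` — the 10 min ending at the SPH,
* SPH        ``[t0 - 300, t0)`` — the 5 min seizure-prediction horizon,
* ictal      ``[t0, t1)``,
* post-ictal ``[t1, t1 + 1800)`` — 30 min after offset,

while inter-ictal time must lie at least 2 h (7200 s) from every seizure
boundary. Overlaps between states from closely spaced seizures are
resolved by precedence: ictal and SPH always win, and a pre-ictal window
truncated by the preceding seizure's post-ictal period keeps only its
non-overlapping remainder (post-ictal and pre-ictal can only collide in
that one configuration). Inter-ictal ranks last. All intervals are
clipped to the recording and empty remnants are dropped. A recording with
no seizures is entirely inter-ictal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .data_io import SeizureEvent

State = Literal["preictal", "sph", "ictal", "postictal", "interictal"]

#: Precedence order, highest first, used to resolve overlaps. Post-ictal
#: precedes pre-ictal so that a pre-ictal window colliding with an earlier
#: seizure's post-ictal period keeps only its non-overlapping remainder.
STATE_PRECEDENCE: tuple[State, ...] = ("ictal", "sph", "postictal", "preictal", "interictal")

__all__ = [
    "SegmentationConfig",
    "StateInterval",
    "STATE_PRECEDENCE",
    "label_states",
    "extract_state",
    "intervals_to_table",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """State-segmentation time constants, all in seconds."""

    sph_s: float = 300.0
    preictal_len_s: float = 600.0
    postictal_len_s: float = 1800.0
    interictal_gap_s: float = 7200.0

    def __post_init__(self) -> None:
        for name in ("sph_s", "preictal_len_s", "postictal_len_s", "interictal_gap_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class StateInterval:
    file_id: str
    state: State
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"empty interval [{self.start_s}, {self.end_s})")


Ivl = tuple[float, float]


def _subtract(base: list[Ivl], cut: list[Ivl]) -> list[Ivl]:
    """Set-difference of half-open interval lists (both sorted, disjoint)."""
    out: list[Ivl] = []
    for b0, b1 in base:
        pieces = [(b0, b1)]
        for c0, c1 in cut:
            nxt: list[Ivl] = []
            for p0, p1 in pieces:
                if c1 <= p0 or c0 >= p1:
                    nxt.append((p0, p1))
                    continue
                if p0 < c0:
                    nxt.append((p0, c0))
                if c1 < p1:
                    nxt.append((c1, p1))
            pieces = nxt
        out.extend(pieces)
    return sorted(out)


def _merge(ivls: list[Ivl]) -> list[Ivl]:
    """Union of possibly overlapping intervals (e.g. post-ictal periods of
    closely spaced seizures)."""
    out: list[Ivl] = []
    for a, b in sorted(ivls):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _clip(ivls: list[Ivl], lo: float, hi: float) -> list[Ivl]:
    out = []
    for a, b in ivls:
        a, b = max(a, lo), min(b, hi)
        if a < b:
            out.append((a, b))
    return out


def label_states(
    events: Sequence[SeizureEvent],
    recording_len_s: float,
    config: SegmentationConfig | None = None,
    file_id: str | None = None,
) -> list[StateInterval]:
    """Derive labeled state intervals from seizure annotations.

    ``events`` must be sorted and non-overlapping; every event must start
    inside the recording.
    """
    cfg = config or SegmentationConfig()
    if recording_len_s <= 0:
        raise ValueError("recording_len_s must be positive")
    fid = file_id if file_id is not None else (events[0].file_id if events else "")
    for prev, cur in zip(events, events[1:]):
        if cur.start_s < prev.end_s:
            raise ValueError(
                f"seizure events must be sorted and non-overlapping: "
                f"({prev.start_s}, {prev.end_s}) then ({cur.start_s}, {cur.end_s})"
            )
    for ev in events:
        if ev.start_s >= recording_len_s or ev.start_s < 0:
            raise ValueError(f"seizure at {ev.start_s}s outside recording of {recording_len_s}s")

    gap = cfg.interictal_gap_s
    candidates: dict[State, list[Ivl]] = {
        "ictal": [(ev.start_s, ev.end_s) for ev in events],
        "sph": [(ev.start_s - cfg.sph_s, ev.start_s) for ev in events],
        "preictal": [
            (ev.start_s - cfg.sph_s - cfg.preictal_len_s, ev.start_s - cfg.sph_s)
            for ev in events
        ],
        "postictal": [(ev.end_s, ev.end_s + cfg.postictal_len_s) for ev in events],
    }
    exclusion = [(ev.start_s - gap, ev.end_s + gap) for ev in events]
    candidates["interictal"] = _subtract([(0.0, recording_len_s)], exclusion)

    out: list[StateInterval] = []
    claimed: list[Ivl] = []
    for state in STATE_PRECEDENCE:
        ivls = _clip(_merge(candidates[state]), 0.0, recording_len_s)
        ivls = _subtract(ivls, claimed)
        for a, b in ivls:
            out.append(StateInterval(file_id=fid, state=state, start_s=a, end_s=b))
        claimed = sorted(claimed + ivls)
    out.sort(key=lambda iv: (iv.start_s, iv.end_s))
    return out


def extract_state(
    signal: np.ndarray,
    intervals: Sequence[StateInterval],
    state: State,
    fs: float,
) -> list[np.ndarray]:
    """Slice out every interval of ``state`` as [floor(start*fs), floor(end*fs))."""
    n_samples = signal.shape[-1]
    slices: list[np.ndarray] = []
    for iv in sorted(intervals, key=lambda iv: iv.start_s):
        if iv.state != state:
            continue
        a = int(np.floor(iv.start_s * fs))
        b = int(np.floor(iv.end_s * fs))
        if b > n_samples:
            raise ValueError(
                f"interval [{iv.start_s}, {iv.end_s})s exceeds signal length "
                f"{n_samples / fs}s"
            )
        slices.append(signal[..., a:b])
    return slices


def intervals_to_table(intervals: Sequence[StateInterval]):
    """Interval list as a tidy DataFrame (file_id, state, start_s, end_s)."""
    import pandas as pd

    return pd.DataFrame(
        [(iv.file_id, iv.state, iv.start_s, iv.end_s) for iv in intervals],
        columns=["file_id", "state", "start_s", "end_s"],
    )
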