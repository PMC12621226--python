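"""Cox-Stuart trend test and the validation-loss early-stopping controller.

The Cox-Stuart test is a distribution-free sign test for monotone trend:
the sequence is split into a first and second half, the element-wise
differences ``d_i = x[c+i] - x[i]`` are formed (the middle element is
dropped when the length is odd), and the smaller of the positive/negative
sign counts is referred to a symmetric Binomial(m, 1/2) tail.

The controller watches a training run's validation-loss history and stops
once the recent window no longer trends downward: a verdict of
``increasing`` or ``no_trend`` casts a stop vote, a ``decreasing`` verdict
or a new best loss resets the vote counter, and the run halts after
``window_wp`` consecutive votes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Sequence

Verdict = Literal["increasing", "decreasing", "no_trend"]

__all__ = [
    "TrendResult",
    "EarlyStopConfig",
    "EarlyStopState",
    "compute_c",
    "binomial_tail",
    "trend_test",
    "early_stop_update",
    "CoxStuartStopper",
]


@dataclass(frozen=True)
class TrendResult:
    """Outcome of one Cox-Stuart test."""

    c: int
    num_pos: int
    num_neg: int
    k: int
    m: int
    p_value: float
    verdict: Verdict


@dataclass(frozen=True)
class EarlyStopConfig:
    """Controller settings.

    window_wp : int
        Length of the loss window tested each epoch, and the number of
        consecutive stop votes required to halt (W_p). Must be >= 3.
    alpha : float
        One-sided significance level for the trend test (default 0.1).
    stop_on : tuple of verdicts
        Verdicts that count as stop votes.
    """

    window_wp: int = 10
    alpha: float = 0.1
    stop_on: tuple[Verdict, ...] = ("increasing", "no_trend")

    def __post_init__(self) -> None:
        if self.window_wp < 3:
            raise ValueError("window_wp must be >= 3")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class EarlyStopState:
    """Mutable controller state carried across epochs."""

    history: list[float] = field(default_factory=list)
    best_val_loss: float = math.inf
    consec_stop_votes: int = 0
    # Raw per-verdict counters kept for logging parity even though the stop
    # rule only needs their sum.
    num_inc_votes: int = 0
    num_flat_votes: int = 0
    stopped_at: int | None = None


def compute_c(n: int) -> int:
    """Half-length c of an n-element sequence: n/2 (even), (n+1)/2 - 1 (odd)."""
    if n < 2:
        raise ValueError(f"sequence length must be >= 2, got {n}")
    return n // 2


def binomial_tail(k: int, m: int) -> float:
    """Exact lower tail P(X <= k) for X ~ Binomial(m, 1/2).

    Computed with integer binomial coefficients and an exact rational
    division, so it is stable for m up to ~10^4 (no 2**m float overflow).
    """
    if k < 0 or m < 0 or k > m:
        raise ValueError(f"need 0 <= k <= m, got k={k}, m={m}")
    if m == 0:
        return 1.0
    total = sum(math.comb(m, j) for j in range(k + 1))
    return float(Fraction(total, 1 << m))


def trend_test(x: Sequence[float], alpha: float = 0.1) -> TrendResult:
    """Cox-Stuart sign test for monotone trend.

    Pairs ``x[i]`` with ``x[i + c]`` for ``i = 0..c-1`` where
    ``c = floor(n/2)`` (middle element dropped when n is odd). Zero
    differences are discarded from the effective trial count m, the
    standard sign-test treatment of ties. The one-sided p-value is the
    Binomial(m, 1/2) tail over ``k = min(num_pos, num_neg)``.
    """
    n = len(x)
    c = compute_c(n)
    offset = n - c  # == ceil(n/2); skips the middle element for odd n
    num_pos = 0
    num_neg = 0
    for i in range(c):
        d = x[offset + i] - x[i]
        if d > 0:
            num_pos += 1
        elif d < 0:
            num_neg += 1
    m = num_pos + num_neg
    k = min(num_pos, num_neg)
    p = 1.0 if m == 0 else binomial_tail(k, m)
    verdict: Verdict = "no_trend"
    if p <= alpha:
        if num_pos > num_neg:
            verdict = "increasing"
        elif num_neg > num_pos:
            verdict = "decreasing"
    return TrendResult(c=c, num_pos=num_pos, num_neg=num_neg, k=k, m=m,
                       p_value=p, verdict=verdict)


def early_stop_update(
    state: EarlyStopState,
    config: EarlyStopConfig,
    epoch: int,
    val_loss: float,
) -> tuple[EarlyStopState, Literal["continue", "stop"]]:
    """Advance the controller by one epoch.

    ``epoch`` is 1-based and must increase by one per call. The trend test
    runs on the last ``window_wp`` losses once ``epoch > window_wp``.
    """
    if not math.isfinite(val_loss):
        raise ValueError(f"non-finite validation loss at epoch {epoch}: {val_loss}")
    if epoch != len(state.history) + 1:
        raise ValueError(
            f"epochs must be consecutive: expected {len(state.history) + 1}, got {epoch}"
        )
    state.history.append(float(val_loss))
    if val_loss < state.best_val_loss:
        state.best_val_loss = float(val_loss)
        state.consec_stop_votes = 0

    if epoch > config.window_wp:
        window = state.history[-config.window_wp:]
        result = trend_test(window, alpha=config.alpha)
        if result.verdict in config.stop_on:
            state.consec_stop_votes += 1
            if result.verdict == "increasing":
                state.num_inc_votes += 1
            else:
                state.num_flat_votes += 1
        elif result.verdict == "decreasing":
            state.consec_stop_votes = 0

    if state.consec_stop_votes >= config.window_wp:
        state.stopped_at = epoch
        return state, "stop"
    return state, "continue"


class CoxStuartStopper:
    """Framework-agnostic callback wrapper around the controller.

    Call :meth:`on_epoch_end` once per epoch; it returns ``"continue"`` or
    ``"stop"``.
    """

    def __init__(self, config: EarlyStopConfig | None = None) -> None:
        self.config = config or EarlyStopConfig()
        self.state = EarlyStopState()
        self._epoch = 0

    def on_epoch_end(self, epoch: int, val_loss: float) -> Literal["continue", "stop"]:
        self._epoch = epoch
        self.state, decision = early_stop_update(self.state, self.config, epoch, val_loss)
        return decision

    @property
    def stopped_at(self) -> int | None:
        return self.state.stopped_at
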