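"""Physiological preprocessing filters: insulin-on-board and carbs-on-board.

The p-LSTM variant does not see raw insulin/CHO rates; it sees IOB(t) and
COB(t), obtained by causally convolving the delivery/intake channels with
decay curves that mimic the remaining-activity profiles of rapid-acting
insulin and of ingested carbohydrate.  The curve family is

    r(t) = (1 + t/tau) * exp(-t/tau)

the integral of a biexponential activity profile: it starts at 1, decreases
monotonically and has a single shape parameter.  ``tau`` is chosen so the
remaining fraction at the stated action duration is 1%, and the curve is
truncated to exactly zero from the duration onward.

The convolution outputs are *amounts*: taps multiply rate x step, so a
5 U bolus contributes exactly 5 U to IOB in its own bin (h[0] = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

#: remaining fraction defining the end of action
_RESIDUAL_AT_DURATION = 0.01

CHO_CURVE_DURATIONS = {"slow": 360, "fast": 240}  # minutes of support


@dataclass(frozen=True)
class ActionCurve:
    """Remaining-fraction taps on the grid: h[0] = 1, non-increasing, finite support."""

    taps: np.ndarray
    step: int
    kind: str        # 'insulin' | 'cho'
    duration: int    # minutes; taps are 0 from here on

    def __post_init__(self) -> None:
        h = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", h)
        if h[0] != 1.0:
            raise ValueError("action curve must start at 1")
        if np.any(np.diff(h) > 1e-12) or np.any(h < 0):
            raise ValueError("action curve taps must be non-increasing and >= 0")


def _remaining_fraction(t: np.ndarray, tau: float) -> np.ndarray:
    return (1.0 + t / tau) * np.exp(-t / tau)


def _solve_tau(duration: float) -> float:
    """tau such that the remaining fraction at ``duration`` equals 1%."""
    f = lambda tau: _remaining_fraction(np.array(duration), tau) - _RESIDUAL_AT_DURATION
    return brentq(f, duration / 100.0, duration)


def _build_curve(duration: int, step: int, kind: str) -> ActionCurve:
    if duration <= 0:
        raise ValueError("curve duration must be positive")
    if step > duration:
        raise ValueError("grid step exceeds curve duration")
    tau = _solve_tau(float(duration))
    t = np.arange(0, duration + step, step, dtype=float)
    h = _remaining_fraction(t, tau)
    h[t >= duration] = 0.0
    return ActionCurve(h, step, kind, duration)


def insulin_action_curve(duration: int = 360, step: int = 5) -> ActionCurve:
    """Insulin decay curve; default 6-hour action duration."""
    return _build_curve(duration, step, "insulin")


def cho_action_curve(speed: str = "slow", step: int = 5) -> ActionCurve:
    """CHO absorption decay curve: 'slow' (6 h support) or 'fast' (4 h)."""
    if speed not in CHO_CURVE_DURATIONS:
        raise ValueError(f"unknown CHO absorption speed {speed!r}; "
                         f"expected one of {sorted(CHO_CURVE_DURATIONS)}")
    return _build_curve(CHO_CURVE_DURATIONS[speed], step, "cho")


def _causal_filter(channel: np.ndarray, curve: ActionCurve, step: int,
                   warmup_value: float) -> np.ndarray:
    """out[t] = sum_k channel[t-k] * step * h[k], with constant pre-history."""
    if step != curve.step:
        raise ValueError(f"channel step {step} != curve step {curve.step}")
    h = curve.taps
    x = np.concatenate([np.full(len(h) - 1, warmup_value), np.asarray(channel, float)])
    return np.convolve(x, h, mode="valid") * step


def iob(insulin: np.ndarray, curve: ActionCurve, step: int = 5,
        warmup: float | None = None) -> np.ndarray:
    """Insulin-on-board (U) from a U/min delivery channel.

    Pre-history is warm-started with ``warmup`` (U/min), defaulting to the
    series' first value (the running basal rate), so a series that begins
    mid-stream does not show a spurious IOB ramp-up.  Pass the basal rate
    explicitly when the series happens to start on a bolus bin.
    """
    insulin = np.asarray(insulin, dtype=float)
    if warmup is None:
        warmup = float(insulin[0]) if len(insulin) else 0.0
    return _causal_filter(insulin, curve, step, float(warmup))


def cob(cho: np.ndarray, curve: ActionCurve, step: int = 5) -> np.ndarray:
    """Carbs-on-board (g) from a g/min intake channel; pre-history is zero."""
    return _causal_filter(np.asarray(cho, dtype=float), curve, step, 0.0)


def curve_to_csv(curve: ActionCurve, path) -> None:
    """Export a curve as two columns (minutes, remaining fraction)."""
    t = np.arange(len(curve.taps)) * curve.step
    np.savetxt(path, np.column_stack([t, curve.taps]), delimiter=",",
               header="minutes,fraction", comments="", fmt="%.10g")
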