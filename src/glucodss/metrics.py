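"""Forecast-accuracy and glycemic-range outcome metrics.

Accuracy metrics compare the target glucose ``g(t+PH)`` with the forecast
``ghat(t+PH|t)`` over the anchors where both exist: MAE, RMSE, the forecast
delay (the temporal shift j in [0, PH] that minimizes the mean squared
distance between the shifted forecast and the target) and the time gain
TG = PH - delay.  Range metrics are the standard consensus percentages:
TBR (< 70 mg/dl), TIR (70-180 inclusive) and TAR (> 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HYPO_MGDL = 70.0
HYPER_MGDL = 180.0


@dataclass(frozen=True)
class AccuracyReport:
    mae: float     # mg/dl
    rmse: float    # mg/dl
    delay: float   # minutes
    tg: float      # minutes
    n: int


@dataclass(frozen=True)
class RangeReport:
    tbr: float     # percent < 70
    tir: float     # percent in [70, 180]
    tar: float     # percent > 180
    n: int


def _paired(g, ghat) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(g, dtype=float)
    ghat = np.asarray(ghat, dtype=float)
    if g.shape != ghat.shape:
        raise ValueError("target and forecast series must have equal length")
    ok = np.isfinite(g) & np.isfinite(ghat)
    if not np.any(ok):
        raise ValueError("no common anchors between target and forecast")
    return g[ok], ghat[ok]


def mae(g, ghat) -> float:
    """Mean absolute error (mg/dl) over common anchors."""
    a, b = _paired(g, ghat)
    return float(np.mean(np.abs(a - b)))


def rmse(g, ghat) -> float:
    """Root mean squared error (mg/dl) over common anchors."""
    a, b = _paired(g, ghat)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def delay(g, ghat, ph: int, step: int) -> float:
    """Forecast delay in minutes.

    Both inputs are indexed by anchor: ``g[t]`` is the realized glucose at
    ``t+PH`` and ``ghat[t]`` the forecast for it.  For each shift
    ``j in {0, step, ..., PH}`` the forecast series advanced by ``j``
    minutes (``ghat[(t+PH|t)+j]``) is scored against the target
    ``g(t+PH)`` on the overlapping anchors; the minimizing shift is the
    delay (ties break toward the smallest j).  A lagging forecast such as
    persistence on a ramp therefore gets delay = PH and zero time gain.  NaNs mark
    anchors without a value; a shift with empty overlap is skipped.
    """
    if ph % step != 0:
        raise ValueError("PH must be a multiple of the grid step")
    g = np.asarray(g, dtype=float)
    ghat = np.asarray(ghat, dtype=float)
    if g.shape != ghat.shape:
        raise ValueError("target and forecast series must have equal length")
    best_j, best_mse = None, np.inf
    for j_steps in range(ph // step + 1):
        if j_steps == 0:
            a, b = g, ghat
        else:
            # pair the forecast made j minutes later with the same target:
            # ghat[(t+PH|t)+j] vs g(t+PH)
            a, b = g[:-j_steps], ghat[j_steps:]
        ok = np.isfinite(a) & np.isfinite(b)
        if not np.any(ok):
            continue
        m = float(np.mean((a[ok] - b[ok]) ** 2))
        if m < best_mse:
            best_mse, best_j = m, j_steps
    if best_j is None:
        raise ValueError("no shift has any overlapping anchors")
    return float(best_j * step)


def time_gain(g, ghat, ph: int, step: int) -> float:
    """TG = PH - delay (minutes of useful anticipation)."""
    return float(ph - delay(g, ghat, ph, step))


def accuracy_report(g, ghat, ph: int, step: int) -> AccuracyReport:
    a, _ = _paired(g, ghat)
    d = delay(g, ghat, ph, step)
    return AccuracyReport(mae=mae(g, ghat), rmse=rmse(g, ghat),
                          delay=d, tg=float(ph - d), n=int(len(a)))


def time_in_ranges(cgm) -> RangeReport:
    """TBR/TIR/TAR percentages; missing (NaN) samples are excluded entirely.

    Boundaries are inclusive for TIR: 70 and 180 mg/dl both count in range.
    """
    x = np.asarray(cgm, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("all CGM samples are missing")
    n = len(x)
    tbr = 100.0 * np.sum(x < HYPO_MGDL) / n
    tar = 100.0 * np.sum(x > HYPER_MGDL) / n
    tir = 100.0 - tbr - tar
    return RangeReport(tbr=float(tbr), tir=float(tir), tar=float(tar), n=n)
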