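"""The two LSTM glucose forecasters: np-LSTM (raw channels) and p-LSTM.

Both variants share one architecture — a single LSTM layer (64 units by
default) over a 60-minute lookback window of three channels, followed by a
linear read-out predicting glucose PH minutes ahead — and one training
procedure (Adam on MSE, chronological validation tail, early stopping).
The *only* difference is the non-learnable preprocessing of the p variant:
its insulin and CHO channels are passed through the physiological IOB/COB
filters before windowing, so the network sees remaining-active amounts
instead of instantaneous delivery rates.

Windows never straddle an (un-interpolated) CGM gap, targets are strictly
future, and channels are z-scored with statistics computed on training
data only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from ._lstm import LSTMRegressor
from .core_io import GlucoseTimeSeries
from .physio import ActionCurve, cho_action_curve, cob, insulin_action_curve, iob

MIN_TRAIN_WINDOWS = 100
CHANNEL_NAMES = ("cgm", "insulin", "cho")


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "p"            # 'np' (raw channels) | 'p' (IOB/COB)
    ph: int = 30                  # prediction horizon, minutes
    lookback: int = 12            # input window length, samples
    hidden: int = 64              # LSTM units
    epochs: int = 60
    batch_size: int = 256
    lr: float = 1e-2
    val_fraction: float = 0.2     # chronological tail held out
    patience: int = 10
    seed: int = 0
    step: int = 5                 # grid step, minutes
    insulin_curve_duration: int = 360
    cho_curve_speed: str = "slow"

    def __post_init__(self) -> None:
        if self.variant not in ("np", "p"):
            raise ValueError("variant must be 'np' or 'p'")
        if self.ph % self.step != 0:
            raise ValueError("PH must be a multiple of the grid step")
        if self.lookback < 1:
            raise ValueError("lookback must be >= 1")

    @property
    def ph_steps(self) -> int:
        return self.ph // self.step


@dataclass(frozen=True)
class NormStats:
    """Per-channel z-score statistics (training data only)."""

    mean: np.ndarray  # (3,)
    sd: np.ndarray    # (3,)

    def standardize(self, channels: np.ndarray) -> np.ndarray:
        return (channels - self.mean) / self.sd

    def destandardize_target(self, y: np.ndarray) -> np.ndarray:
        return y * self.sd[0] + self.mean[0]

    def standardize_target(self, g: np.ndarray) -> np.ndarray:
        return (g - self.mean[0]) / self.sd[0]


@dataclass
class WindowedDataset:
    windows: np.ndarray   # (n, L, 3)
    targets: np.ndarray   # (n,)
    anchors: np.ndarray   # (n,) sample index t of each window's last input


@dataclass
class PredictionSeries:
    """Forecasts ghat(t+PH|t) emitted at admissible anchors t."""

    anchors: np.ndarray   # (n,) int
    values: np.ndarray    # (n,) mg/dl
    ph: int
    step: int


def _build_curves(config: ModelConfig) -> tuple[ActionCurve, ActionCurve] | None:
    if config.variant != "p":
        return None
    return (insulin_action_curve(config.insulin_curve_duration, config.step),
            cho_action_curve(config.cho_curve_speed, config.step))


def feature_channels(cgm: np.ndarray, insulin: np.ndarray, cho: np.ndarray,
                     curves, step: int,
                     insulin_warmup: float | None = None) -> np.ndarray:
    """Stack the model's input channels as an (n, 3) matrix.

    With ``curves`` set (p variant) the insulin/CHO columns are the IOB/COB
    filter outputs computed on the *full* series, so windows sliced later
    still reflect deliveries older than the lookback.  ``insulin_warmup``
    (U/min) sets the IOB pre-history rate; by default the series' first
    value (assumed basal) is used.
    """
    if curves is None:
        a, b = insulin, cho
    else:
        ins_curve, cho_curve = curves
        a = iob(insulin, ins_curve, step, warmup=insulin_warmup)
        b = cob(cho, cho_curve, step)
    return np.column_stack([cgm, a, b]).astype(float)


def compute_norm_stats(channels: np.ndarray) -> NormStats:
    mean = np.nanmean(channels, axis=0)
    sd = np.nanstd(channels, axis=0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    return NormStats(mean, sd)


def admissible_anchors(channels: np.ndarray, config: ModelConfig,
                       require_target: bool) -> np.ndarray:
    """Anchors t whose input window (and optionally target) is gap-free."""
    n, L, k = len(channels), config.lookback, config.ph_steps
    cgm_ok = np.isfinite(channels[:, 0])
    win_ok = np.ones(n, dtype=bool)
    # window [t-L+1, t] fully present
    csum = np.cumsum(np.concatenate([[0], cgm_ok.astype(int)]))
    t = np.arange(n)
    win_ok = (t >= L - 1)
    full = np.zeros(n, dtype=bool)
    valid = t[win_ok]
    full[valid] = (csum[valid + 1] - csum[valid - L + 1]) == L
    if require_target:
        tgt = np.zeros(n, dtype=bool)
        in_range = t + k < n
        tgt[t[in_range]] = cgm_ok[t[in_range] + k]
        full &= tgt
    else:
        full &= (t + k < n) | True  # forecasts may extend past observed targets
    return np.flatnonzero(full)


def make_windows(s: GlucoseTimeSeries, config: ModelConfig,
                 stats: NormStats | None = None) -> WindowedDataset:
    """Slice a series into (window, target) training pairs.

    One pair per anchor t whose L-sample input window and t+PH target are
    all present (interpolated training gaps count as present; raw missing
    samples exclude every window touching them).
    """
    L, k = config.lookback, config.ph_steps
    if s.n < L + k:
        raise ValueError("series shorter than lookback + prediction horizon")
    curves = _build_curves(config)
    ch = feature_channels(s.cgm, s.insulin, s.cho, curves, config.step)
    anchors = admissible_anchors(ch, config, require_target=True)
    anchors = anchors[anchors + k < s.n]
    windows = np.stack([ch[t - L + 1:t + 1] for t in anchors]) if len(anchors) \
        else np.empty((0, L, 3))
    targets = s.cgm[anchors + k] if len(anchors) else np.empty(0)
    if stats is not None:
        windows = stats.standardize(windows)
        targets = stats.standardize_target(targets)
    return WindowedDataset(windows, targets, anchors)


@dataclass
class TrainedPredictor:
    """An LSTM variant with its preprocessing and normalization state."""

    config: ModelConfig
    stats: NormStats
    net: LSTMRegressor
    curves: tuple[ActionCurve, ActionCurve] | None
    history: dict = field(default_factory=dict)

    # -- feature plumbing (shared with the explainer and the DSS) ---------

    def channels(self, cgm, insulin, cho,
                 insulin_warmup: float | None = None) -> np.ndarray:
        return feature_channels(np.asarray(cgm, float), np.asarray(insulin, float),
                                np.asarray(cho, float), self.curves, self.config.step,
                                insulin_warmup=insulin_warmup)

    def forecast_at_anchors(self, channels: np.ndarray,
                            anchors: np.ndarray) -> np.ndarray:
        """De-standardized forecasts (mg/dl) for given anchors of a channel matrix."""
        L = self.config.lookback
        anchors = np.asarray(anchors, dtype=int)
        if np.any(anchors < L - 1) or np.any(anchors >= len(channels)):
            raise ValueError("anchor without a complete input window")
        X = np.stack([channels[t - L + 1:t + 1] for t in anchors])
        if not np.all(np.isfinite(X)):
            raise ValueError("input window overlaps a CGM gap")
        y = self.net.forward(self.stats.standardize(X))
        return self.stats.destandardize_target(y)


def train(train_split: GlucoseTimeSeries, config: ModelConfig) -> TrainedPredictor:
    """Fit one predictor on a (gap-interpolated) training series.

    The chronological tail (``val_fraction``) of the training windows is
    held out for early stopping; normalization statistics come from the
    training portion only.  A fixed seed reproduces the loss trajectory.
    """
    curves = _build_curves(config)
    ch = feature_channels(train_split.cgm, train_split.insulin, train_split.cho,
                          curves, config.step)
    stats = compute_norm_stats(ch)
    data = make_windows(train_split, config, stats=stats)
    n = len(data.targets)
    if n < MIN_TRAIN_WINDOWS:
        raise ValueError(f"only {n} training windows; need >= {MIN_TRAIN_WINDOWS}")
    n_val = int(round(n * config.val_fraction))
    X_tr, y_tr = data.windows[:n - n_val], data.targets[:n - n_val]
    X_val, y_val = data.windows[n - n_val:], data.targets[n - n_val:]

    net = LSTMRegressor(3, config.hidden, seed=config.seed)
    history = {}
    if config.epochs > 0:
        history = net.fit(X_tr, y_tr, X_val, y_val, epochs=config.epochs,
                          batch_size=config.batch_size, lr=config.lr,
                          patience=config.patience, seed=config.seed + 1)
    return TrainedPredictor(config, stats, net, curves, history)


def predict_series(m: TrainedPredictor, s: GlucoseTimeSeries) -> PredictionSeries:
    """Strictly causal rolling forecasts over a (non-imputed) series.

    A forecast is emitted at every anchor whose input window is complete;
    anchors touching a gap emit nothing.  Appending future samples never
    changes earlier forecasts.
    """
    ch = m.channels(s.cgm, s.insulin, s.cho)
    anchors = admissible_anchors(ch, m.config, require_target=False)
    values = m.forecast_at_anchors(ch, anchors) if len(anchors) else np.empty(0)
    return PredictionSeries(anchors, values, m.config.ph, m.config.step)


def predict_counterfactual(m: TrainedPredictor, s: GlucoseTimeSeries,
                           t: int, extra_bolus: float,
                           insulin_warmup: float | None = None) -> float:
    """Forecast at anchor t with an extra bolus injected into bin t.

    The bolus is added to the insulin channel as ``U/step`` U/min; for the
    p variant the IOB filter is re-applied, so IOB at the anchor rises by
    exactly the bolus size.  The original series is not modified.
    """
    if extra_bolus < 0:
        raise ValueError("extra bolus must be non-negative")
    insulin = s.insulin.copy()
    insulin[t] += extra_bolus / m.config.step
    ch = m.channels(s.cgm, insulin, s.cho, insulin_warmup=insulin_warmup)
    return float(m.forecast_at_anchors(ch, np.array([t]))[0])


def forecast_pairs(m: TrainedPredictor, s: GlucoseTimeSeries,
                   pred: PredictionSeries | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(target, forecast) arrays over anchors where both exist."""
    pred = predict_series(m, s) if pred is None else pred
    k = m.config.ph_steps
    keep = pred.anchors + k < s.n
    anchors = pred.anchors[keep]
    g = s.cgm[anchors + k]
    ghat = pred.values[keep]
    ok = np.isfinite(g)
    return g[ok], ghat[ok]


# ---------------------------------------------------------------------------
# model bundle persistence
# ---------------------------------------------------------------------------

def save_predictor(m: TrainedPredictor, directory) -> None:
    """Save config + normalization + weights under a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {"config": asdict(m.config),
            "stats": {"mean": m.stats.mean.tolist(), "sd": m.stats.sd.tolist()},
            "history": {k: v for k, v in m.history.items() if k == "best_val"}}
    (d / "metadata.json").write_text(json.dumps(meta, indent=2))
    np.savez(d / "weights.npz", **m.net.state_dict())


def load_predictor(directory) -> TrainedPredictor:
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text())
    config = ModelConfig(**meta["config"])
    stats = NormStats(np.array(meta["stats"]["mean"]), np.array(meta["stats"]["sd"]))
    net = LSTMRegressor(3, config.hidden, seed=config.seed)
    with np.load(d / "weights.npz") as z:
        net.load_state_dict({k: z[k] for k in z.files})
    return TrainedPredictor(config, stats, net, _build_curves(config),
                            meta.get("history", {}))
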