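"""Shapley-value attribution of forecasts to the three input channels.

Each forecast is treated as a 3-player cooperative game: the players are
the CGM, insulin and CHO channels, and the value of a coalition S is the
model's forecast when the channels *not* in S are replaced, over the whole
history up to the anchor, by their training-set mean (the background).
With 3 players all 8 coalitions are enumerated, so the attributions are
exact Shapley values and the efficiency identity

    base + sum_j phi_j = prediction

holds to machine precision.  A kernel-weighted least-squares estimator is
kept for cross-checks and for >3-player extensions.

For the p variant, masking is applied to the RAW insulin/CHO channels
before the IOB/COB filters, so attributions refer to the same physical
inputs in both model variants.

Corpus-level summaries operationalize the usual summary-plot reading:
per-channel importance (mean |phi|), an importance ranking, and a
sign-consistency score (Spearman rank correlation between the channel's
physiological exposure at the anchor — CGM value, insulin-on-board,
carbs-on-board — and its Shapley value across instances).  A model that
has learnt glucose-insulin physiology shows negative insulin
sign-consistency (insulin lowers future glucose) and positive CHO
sign-consistency.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .core_io import GlucoseTimeSeries
from .physio import cho_action_curve, cob, insulin_action_curve, iob
from .predictors import TrainedPredictor, admissible_anchors

CHANNELS = ("cgm", "insulin", "cho")


# ---------------------------------------------------------------------------
# the game-theoretic core
# ---------------------------------------------------------------------------

@dataclass
class CoalitionalGame:
    """A value function on subsets of {0, ..., n_players-1}."""

    n_players: int
    value: dict  # frozenset -> float

    def v(self, coalition) -> float:
        key = frozenset(coalition)
        if key not in self.value:
            raise KeyError(f"value map is missing coalition {sorted(key)}")
        return self.value[key]


def shapley_exact(game: CoalitionalGame) -> np.ndarray:
    """Exact Shapley values by enumeration of all coalitions.

    phi_j = sum over S not containing j of
            |S|! (M - |S| - 1)! / M!  *  [v(S + j) - v(S)].
    """
    M = game.n_players
    if M > 12:
        raise ValueError("exact enumeration limited to 12 players")
    players = range(M)
    fact = [math.factorial(i) for i in range(M + 1)]
    phi = np.zeros(M)
    for j in players:
        others = [p for p in players if p != j]
        for r in range(M):
            w = fact[r] * fact[M - r - 1] / fact[M]
            for S in itertools.combinations(others, r):
                phi[j] += w * (game.v(set(S) | {j}) - game.v(S))
    return phi


def _kernel_weight(M: int, s: int) -> float:
    """Shapley kernel weight for a coalition of size s (0 < s < M)."""
    return (M - 1) / (math.comb(M, s) * s * (M - s))


def shapley_kernel(game: CoalitionalGame, n_coalition_samples: int | None = None,
                   seed: int = 0) -> np.ndarray:
    """Kernel-weighted least-squares Shapley estimator.

    Solves the weighted regression of v(S) - v(empty) on coalition
    indicator vectors under the efficiency constraint
    sum phi = v(full) - v(empty).  With no sampling cap (or a cap at least
    the number of proper coalitions) every proper coalition enters once and
    the estimate equals the exact values.
    """
    M = game.n_players
    if M < 2:
        raise ValueError("kernel estimator needs at least 2 players")
    all_proper = [frozenset(c) for r in range(1, M)
                  for c in itertools.combinations(range(M), r)]
    if n_coalition_samples is None or n_coalition_samples >= len(all_proper):
        # full enumeration: every proper coalition once, kernel-weighted
        coalitions = all_proper
        w = np.array([_kernel_weight(M, len(c)) for c in coalitions])
    else:
        # coalitions drawn with probability proportional to the kernel
        # weight, so the regression itself is unweighted
        rng = np.random.default_rng(seed)
        p = np.array([_kernel_weight(M, len(c)) for c in all_proper])
        idx = rng.choice(len(all_proper), size=n_coalition_samples,
                         replace=True, p=p / p.sum())
        coalitions = [all_proper[i] for i in idx]
        w = np.ones(len(coalitions))
    if len({frozenset(c) for c in coalitions}) < M:
        raise ValueError("too few distinct coalitions for a well-posed fit")

    v0 = game.v(())
    v_full = game.v(range(M))
    Z = np.array([[1.0 if j in c else 0.0 for j in range(M)] for c in coalitions])
    y = np.array([game.v(c) - v0 for c in coalitions])

    # impose efficiency by eliminating the last coefficient:
    # phi_M = (v_full - v0) - sum_{j<M} phi_j
    total = v_full - v0
    A = Z[:, :-1] - Z[:, -1:]
    b = y - Z[:, -1] * total
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(A * sw[:, None], b * sw, rcond=None)
    phi = np.empty(M)
    phi[:-1] = beta
    phi[-1] = total - beta.sum()
    return phi


def linear_shap_closed_form(beta: np.ndarray, x: np.ndarray,
                            means: np.ndarray) -> np.ndarray:
    """Closed-form Shapley values of a linear model: phi_j = beta_j (x_j - E[x_j])."""
    beta, x, means = (np.asarray(a, dtype=float) for a in (beta, x, means))
    if not (len(beta) == len(x) == len(means)):
        raise ValueError("beta, x and means must have equal length")
    return beta * (x - means)


# ---------------------------------------------------------------------------
# explaining predictor forecasts
# ---------------------------------------------------------------------------

@dataclass
class Explanation:
    anchor: int
    phi: np.ndarray            # per-channel Shapley value, mg/dl of forecast
    base: float                # v(empty): forecast with all channels at background
    prediction: float          # v(full): the actual forecast
    feature_values: np.ndarray  # raw channel values at the anchor
    exposures: np.ndarray = None  # (CGM, IOB, COB) at the anchor


def _masked_channel_sets(m: TrainedPredictor, s: GlucoseTimeSeries,
                         background: np.ndarray) -> dict:
    """Feature-channel matrices for every coalition, masking raw channels.

    Masking replaces a raw channel by its background value over the whole
    series before any filtering, so the p variant's IOB/COB are recomputed
    consistently.  Returns {coalition frozenset -> (n, 3) channel matrix}.
    """
    n = s.n
    raw = {
        "cgm": (s.cgm, np.full(n, background[0])),
        "insulin": (s.insulin, np.full(n, background[1])),
        "cho": (s.cho, np.full(n, background[2])),
    }
    out = {}
    for bits in itertools.product((0, 1), repeat=3):
        coalition = frozenset(j for j in range(3) if bits[j])
        chans = [raw[name][0] if bits[j] else raw[name][1]
                 for j, name in enumerate(CHANNELS)]
        out[coalition] = m.channels(*chans)
    return out


def explain_anchors(m: TrainedPredictor, s: GlucoseTimeSeries,
                    anchors: np.ndarray,
                    background: np.ndarray) -> list[Explanation]:
    """Exact channel-level Shapley explanations at many anchors at once.

    ``background`` holds the per-channel training means of the raw
    channels (CGM mg/dl, insulin U/min, CHO g/min).
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (3,):
        raise ValueError("background must provide one value per channel")
    anchors = np.asarray(anchors, dtype=int)
    sets = _masked_channel_sets(m, s, background)
    # one batched forward pass per coalition
    v = {c: m.forecast_at_anchors(ch, anchors) for c, ch in sets.items()}
    exp_iob, exp_cob = _channel_exposures(m, s)
    explanations = []
    for i, t in enumerate(anchors):
        game = CoalitionalGame(3, {c: float(vals[i]) for c, vals in v.items()})
        phi = shapley_exact(game)
        explanations.append(Explanation(
            anchor=int(t), phi=phi,
            base=float(v[frozenset()][i]),
            prediction=float(v[frozenset(range(3))][i]),
            feature_values=np.array([s.cgm[t], s.insulin[t], s.cho[t]]),
            exposures=np.array([s.cgm[t], exp_iob[t], exp_cob[t]])))
    return explanations


def _channel_exposures(m: TrainedPredictor, s: GlucoseTimeSeries):
    """Physiological exposure summaries used for summary-plot coloring.

    The scalar "value" of a channel instance is the amount still on board
    at the anchor (IOB for insulin, COB for CHO), computed with the
    standard action curves for both variants; raw impulse values at a
    single bin are basal/zero at almost every anchor and do not summarize
    the channel history that masking perturbs.
    """
    if m.curves is not None:
        ins_curve, cho_curve = m.curves
    else:
        ins_curve = insulin_action_curve(step=m.config.step)
        cho_curve = cho_action_curve(step=m.config.step)
    return (iob(s.insulin, ins_curve, m.config.step),
            cob(s.cho, cho_curve, m.config.step))


def explain_instance(m: TrainedPredictor, s: GlucoseTimeSeries, t: int,
                     background: np.ndarray) -> Explanation:
    """Explain a single forecast (see :func:`explain_anchors`)."""
    return explain_anchors(m, s, np.array([t]), background)[0]


# ---------------------------------------------------------------------------
# corpus-level summaries
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Summary-plot statistics over a corpus of explanations."""

    importance: dict            # channel -> mean |phi|
    rank: dict                  # channel -> 1 = most important
    sign_consistency: dict      # channel -> Spearman(feature value, phi) or None
    high_value_counts: dict     # channel -> (n_positive_phi, n_negative_phi)
    table: np.ndarray = field(repr=False, default=None)  # (n, 6): values + phis


def summarize(explanations: list[Explanation], min_instances: int = 30,
              value_source: str = "exposure") -> SummaryStats:
    """Aggregate per-instance attributions into summary-plot statistics.

    Sign-consistency is the Spearman rank correlation between a channel's
    value and its Shapley value across instances (undefined — reported as
    None — for a constant channel).  With ``value_source="exposure"`` (the
    default) the channel value is its physiological exposure at the anchor
    (CGM level, insulin-on-board, carbs-on-board), the scalar summary of
    the history that masking perturbs; ``"raw"`` uses the raw channel
    value at the anchor bin instead.  The high-value counts tally
    positive/negative attributions among the instances in the channel's
    top value quartile.
    """
    if len(explanations) < min_instances:
        raise ValueError(f"need >= {min_instances} explanations, "
                         f"got {len(explanations)}")
    if value_source not in ("exposure", "raw"):
        raise ValueError("value_source must be 'exposure' or 'raw'")
    if value_source == "exposure":
        values = np.array([e.exposures if e.exposures is not None
                           else e.feature_values for e in explanations])
    else:
        values = np.array([e.feature_values for e in explanations])  # (n, 3)
    phis = np.array([e.phi for e in explanations])               # (n, 3)
    importance, sign, counts = {}, {}, {}
    for j, name in enumerate(CHANNELS):
        importance[name] = float(np.mean(np.abs(phis[:, j])))
        col = values[:, j]
        finite = np.isfinite(col)
        if np.ptp(col[finite]) < 1e-12 or np.ptp(phis[finite, j]) < 1e-12:
            sign[name] = None  # constant input or attribution: undefined
        else:
            rho = spearmanr(col[finite], phis[finite, j]).statistic
            sign[name] = None if np.isnan(rho) else float(rho)
        hi = col >= np.nanquantile(col, 0.75)
        counts[name] = (int(np.sum(phis[hi & finite, j] > 0)),
                        int(np.sum(phis[hi & finite, j] < 0)))
    order = sorted(CHANNELS, key=lambda c: -importance[c])
    rank = {name: order.index(name) + 1 for name in CHANNELS}
    return SummaryStats(importance, rank, sign, counts,
                        table=np.hstack([values, phis]))


def default_summary_anchors(m: TrainedPredictor, s: GlucoseTimeSeries,
                            max_anchors: int = 2000, seed: int = 0) -> np.ndarray:
    """All admissible anchors, subsampled deterministically if too many."""
    ch = m.channels(s.cgm, s.insulin, s.cho)
    anchors = admissible_anchors(ch, m.config, require_target=False)
    if len(anchors) > max_anchors:
        rng = np.random.default_rng(seed)
        anchors = np.sort(rng.choice(anchors, size=max_anchors, replace=False))
    return anchors
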