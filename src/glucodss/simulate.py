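"""Glucose-insulin minimal-model simulator and synthetic corpus generator.

The physiological core is the Bergman minimal model of plasma-insulin
action on glucose, extended with a two-compartment subcutaneous insulin
absorption chain and a three-compartment oral glucose absorption chain:

    dG/dt     = -(SG + X) G + SG Gb + Ra / (VG BW)
    dX/dt     = -p2 [X - SI (Ip - Ipb)]
    dIsc1/dt  = -kd Isc1 + u(t) c_i        c_i = 1e6 uU/U / (VI BW 1000 ml/l)
    dIsc2/dt  =  kd Isc1 - ka2 Isc2
    dIp/dt    =  ka2 Isc2 - ke Ip
    dQsto1/dt = -kgri Qsto1 + 1000 CHO(t)
    dQsto2/dt =  kgri Qsto1 - kempt Qsto2
    dQgut/dt  =  kempt Qsto2 - kabs Qgut
    Ra        =  fabs kabs Qgut            [mg/min]

with G in mg/dl, insulin compartments in uU/ml, gut compartments in mg,
u(t) in U/min and CHO(t) in g/min.  Inputs are piecewise constant on the
sampling grid, so integration uses fixed-step RK4 substeps aligned to bin
boundaries (default 1-min substep); the refinement contract (halving the
substep moves glucose by < 0.1 mg/dl) is part of the test suite.

The same engine serves two roles: generating synthetic CGM corpora that
emulate the statistical structure of real single-patient data (meal-time
boluses nearly proportional to announced carbs, suboptimal prandial
dosing, sensor noise, short gaps) and acting as the forward model for
identify-then-replay evaluation of decision-support policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import (Bolus, DataSplit, EventList, GlucoseTimeSeries, Meal,
                      TimeGrid, interpolate_short_gaps)

DEFAULT_START = pd.Timestamp("2024-01-01 00:00")
CGM_FLOOR = 40.0  # mg/dl, sensor lower reporting limit


# ---------------------------------------------------------------------------
# parameters and scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinimalModelParams:
    """Population-default physiological parameters (70 kg adult with T1D)."""

    SG: float = 0.02       # 1/min, glucose effectiveness
    SI: float = 7.0e-4     # ml/uU/min, insulin sensitivity
    p2: float = 0.012      # 1/min, insulin-action rate
    Gb: float = 120.0      # mg/dl, basal glucose
    VG: float = 1.6        # dl/kg, glucose distribution volume
    kd: float = 0.026      # 1/min, sc insulin transfer
    ka2: float = 0.014     # 1/min, sc -> plasma absorption
    ke: float = 0.127      # 1/min, plasma insulin clearance
    VI: float = 0.126      # l/kg, insulin distribution volume
    kgri: float = 0.065    # 1/min, grinding (stomach solid -> liquid)
    kempt: float = 0.065   # 1/min, gastric emptying
    kabs: float = 0.018    # 1/min, intestinal absorption
    fabs: float = 0.9      # dimensionless bioavailability
    BW: float = 70.0       # kg

    def __post_init__(self) -> None:
        rates = ("SG", "SI", "p2", "VG", "kd", "ka2", "ke", "VI",
                 "kgri", "kempt", "kabs", "BW")
        for name in rates:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if not 0 < self.fabs <= 1:
            raise ValueError("fabs must be in (0, 1]")
        if not 70 <= self.Gb <= 300:
            raise ValueError("Gb must lie in [70, 300] mg/dl")


@dataclass
class Scenario:
    """Event schedule driving one simulation run.

    Times are minutes from the scenario start; ``gap_spec`` lists
    (start_min, length_min) runs of missing CGM.
    """

    duration: int                         # minutes
    basal: float                          # U/min
    meals: list[tuple[float, float, bool]] = field(default_factory=list)   # (t, grams, announced)
    boluses: list[tuple[float, float]] = field(default_factory=list)       # (t, units)
    cgm_noise_sd: float = 0.0             # mg/dl
    gap_spec: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0
    start: pd.Timestamp = DEFAULT_START

    def __post_init__(self) -> None:
        if self.cgm_noise_sd < 0:
            raise ValueError("CGM noise sd must be >= 0")
        for t, g, _ in self.meals:
            if not 0 <= t < self.duration:
                raise ValueError(f"meal at {t} min outside scenario duration")
            if g <= 0:
                raise ValueError("meal grams must be positive")
        for t, u in self.boluses:
            if not 0 <= t < self.duration:
                raise ValueError(f"bolus at {t} min outside scenario duration")
            if u < 0:
                raise ValueError("bolus units must be >= 0")


@dataclass
class SimulationResult:
    series: GlucoseTimeSeries       # noisy CGM + inputs, with gaps applied
    true_glucose: np.ndarray        # mg/dl, noise-free
    states: dict                    # full state trajectories, per sample


# state vector indices
_G, _X, _ISC1, _ISC2, _IP, _QSTO1, _QSTO2, _QGUT = range(8)
STATE_NAMES = ("G", "X", "Isc1", "Isc2", "Ip", "Qsto1", "Qsto2", "Qgut")


class Simulator:
    """Stateful bin-by-bin integrator used by both simulate() and replay."""

    def __init__(self, params: MinimalModelParams, basal: float,
                 step: int = 5, substep: float = 1.0, g0: float | None = None):
        self.p = params
        self.basal = float(basal)
        self.step = int(step)
        self.n_sub = max(1, int(round(step / substep)))
        self.h = step / self.n_sub
        self.ci = 1000.0 / (params.VI * params.BW)   # (uU/ml) per U
        self.Ipb = basal * self.ci / params.ke
        self.y = self._steady_state(g0)
        self.t_min = 0.0

    def _steady_state(self, g0: float | None) -> np.ndarray:
        p, ub, ci = self.p, self.basal, self.ci
        y = np.zeros(8)
        y[_G] = p.Gb if g0 is None else float(g0)
        y[_ISC1] = ub * ci / p.kd
        y[_ISC2] = ub * ci / p.ka2
        y[_IP] = ub * ci / p.ke
        return y

    def _rhs(self, y: np.ndarray, u: float, cho: float) -> np.ndarray:
        p = self.p
        d = np.empty(8)
        Ra = p.fabs * p.kabs * y[_QGUT]
        d[_G] = -(p.SG + y[_X]) * y[_G] + p.SG * p.Gb + Ra / (p.VG * p.BW)
        d[_X] = -p.p2 * (y[_X] - p.SI * (y[_IP] - self.Ipb))
        d[_ISC1] = -p.kd * y[_ISC1] + u * self.ci
        d[_ISC2] = p.kd * y[_ISC1] - p.ka2 * y[_ISC2]
        d[_IP] = p.ka2 * y[_ISC2] - p.ke * y[_IP]
        d[_QSTO1] = -p.kgri * y[_QSTO1] + 1000.0 * cho
        d[_QSTO2] = p.kgri * y[_QSTO1] - p.kempt * y[_QSTO2]
        d[_QGUT] = p.kempt * y[_QSTO2] - p.kabs * y[_QGUT]
        return d

    def advance_bin(self, u_umin: float, cho_gmin: float) -> np.ndarray:
        """Integrate one grid bin with constant inputs; returns end state."""
        y, h = self.y, self.h
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(self.n_sub):
                k1 = self._rhs(y, u_umin, cho_gmin)
                k2 = self._rhs(y + 0.5 * h * k1, u_umin, cho_gmin)
                k3 = self._rhs(y + 0.5 * h * k2, u_umin, cho_gmin)
                k4 = self._rhs(y + h * k3, u_umin, cho_gmin)
                y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        self.t_min += self.step
        if not np.all(np.isfinite(y)) or y[_G] <= 0:
            raise RuntimeError(
                f"simulation state became non-physical at t = {self.t_min:.0f} min "
                f"(parameter blow-up?)")
        self.y = y
        return y


def _events_to_channels(scenario: Scenario, step: int) -> tuple[np.ndarray, np.ndarray, int]:
    import math
    n = int(math.ceil(scenario.duration / step))
    insulin = np.full(n, scenario.basal, dtype=float)
    cho = np.zeros(n, dtype=float)
    for t, units in scenario.boluses:
        k = min(int(math.ceil(t / step - 0.5)), n - 1)
        insulin[k] += units / step
    for t, grams, _ in scenario.meals:
        k = min(int(math.ceil(t / step - 0.5)), n - 1)
        cho[k] += grams / step
    return insulin, cho, n


def simulate(params: MinimalModelParams, scenario: Scenario, step: int = 5,
             substep: float = 1.0, g0: float | None = None) -> SimulationResult:
    """Run the minimal model over a scenario.

    The initial state is the steady state at basal insulin (so with no
    meals and zero noise the glucose trace sits exactly at ``Gb``); ``g0``
    optionally overrides the initial glucose, leaving the other
    compartments at their basal equilibrium (used when replaying a window
    that starts away from basal).  CGM = true glucose + iid Gaussian noise,
    clipped below at 40 mg/dl, with gaps masked per ``gap_spec``.  With a
    fixed scenario seed the result is bit-reproducible.
    """
    insulin, cho, n = _events_to_channels(scenario, step)
    sim = Simulator(params, scenario.basal, step=step, substep=substep, g0=g0)
    states = np.empty((n, 8))
    states[0] = sim.y
    for k in range(n - 1):
        states[k + 1] = sim.advance_bin(insulin[k], cho[k])

    true_glucose = states[:, _G].copy()
    rng = np.random.default_rng(scenario.seed)
    cgm = true_glucose + rng.normal(0.0, scenario.cgm_noise_sd, size=n) \
        if scenario.cgm_noise_sd > 0 else true_glucose.copy()
    cgm = np.maximum(cgm, CGM_FLOOR)

    mask = np.zeros(n, dtype=bool)
    for start_min, length_min in scenario.gap_spec:
        a = max(int(start_min // step), 0)
        b = min(int(np.ceil((start_min + length_min) / step)), n)
        mask[a:b] = True
    cgm_masked = cgm.copy()
    cgm_masked[mask] = np.nan

    grid = TimeGrid(scenario.start, step, n)
    series = GlucoseTimeSeries(grid, cgm_masked, insulin, cho, mask)
    return SimulationResult(series, true_glucose,
                            {name: states[:, i] for i, name in enumerate(STATE_NAMES)})


def simulate_from_channels(params: MinimalModelParams, insulin: np.ndarray,
                           cho: np.ndarray, basal: float, step: int = 5,
                           substep: float = 1.0,
                           g0: float | None = None) -> np.ndarray:
    """Noise-free glucose trajectory driven directly by gridded channels.

    Initial state: basal steady state with glucose optionally overridden
    by ``g0``.  Used by identification (fit to a window's CGM) and replay.
    Returns true glucose (mg/dl), one value per input bin.
    """
    n = len(insulin)
    sim = Simulator(params, basal, step=step, substep=substep, g0=g0)
    g = np.empty(n)
    g[0] = sim.y[_G]
    for k in range(n - 1):
        g[k + 1] = sim.advance_bin(insulin[k], cho[k])[_G]
    return g


# ---------------------------------------------------------------------------
# scenario generation: emulating a real single-patient corpus
# ---------------------------------------------------------------------------

@dataclass
class CorpusConfig:
    """Statistical structure of the emulated patient corpus.

    The defaults encode a compliant but suboptimally controlled patient:
    three announced meals per day, prandial boluses nearly proportional to
    carbs (carb ratio ``carb_ratio`` g/U with multiplicative dosing noise
    ``bolus_error_sd``), a constant 40% under-bolusing factor, elevated
    fasting glucose and slow meal absorption producing prolonged
    postprandial hyperglycemia, 5 mg/dl CGM noise and about one short
    sensor gap per day.
    """

    train_days: int = 21
    test_days: int = 7
    basal: float = 1.0 / 60.0                       # U/min (1 U/hr)
    meal_hours: tuple = (7.5, 12.5, 19.0)           # breakfast, lunch, dinner
    meal_time_jitter_sd: float = 20.0               # minutes
    cho_range: tuple = (40.0, 100.0)                # grams
    carb_ratio: float = 3.5                         # g/U (insulin-resistant)
    bolus_error_sd: float = 0.15                    # relative dosing noise
    under_bolus: float = 0.6                        # <= 1, suboptimal dosing
    announce_prob: float = 1.0                      # compliant reporter
    cgm_noise_sd: float = 5.0                       # mg/dl
    gaps_per_day: float = 1.0
    gap_len_range: tuple = (10.0, 45.0)             # minutes
    #: occasional self-administered corrective boluses (insulin without a
    #: meal), as real patient diaries contain: probability per meal of a
    #: late partial catch-up correction, and its timing window after the meal
    correction_prob: float = 0.3
    correction_delay_range: tuple = (90.0, 180.0)   # minutes after the meal
    #: the emulated patient: elevated basal glucose, low glucose
    #: effectiveness, marked insulin resistance and slow mixed-meal
    #: absorption (prolonged postprandial hyperglycemia, large boluses)
    params: MinimalModelParams = field(default_factory=lambda: MinimalModelParams(
        Gb=150.0, SG=0.012, SI=2.0e-4, kabs=0.012, kempt=0.05))

    @property
    def total_days(self) -> int:
        return self.train_days + self.test_days


def generate_scenario(config: CorpusConfig, seed: int,
                      days: int | None = None) -> Scenario:
    """Draw a meal/bolus/gap schedule with the configured collinearity.

    Each bolus is ``(grams / CR) * (1 + eps) * u`` with
    ``eps ~ N(0, bolus_error_sd)`` and under-bolusing factor ``u <= 1``,
    floored at zero and delivered in the meal's bin.
    """
    if config.carb_ratio <= 0:
        raise ValueError("carb ratio must be positive")
    if config.under_bolus > 1:
        raise ValueError("under-bolusing factor must be <= 1")
    rng = np.random.default_rng(seed)
    days = config.total_days if days is None else days
    duration = days * 1440

    meals: list[tuple[float, float, bool]] = []
    boluses: list[tuple[float, float]] = []
    for day in range(days):
        for hour in config.meal_hours:
            t = day * 1440 + hour * 60 + rng.normal(0, config.meal_time_jitter_sd)
            t = float(np.clip(t, day * 1440, (day + 1) * 1440 - 30))
            grams = float(rng.uniform(*config.cho_range))
            announced = bool(rng.random() < config.announce_prob)
            meals.append((t, grams, announced))
            nominal = grams / config.carb_ratio
            eps = rng.normal(0.0, config.bolus_error_sd)
            units = max(nominal * (1.0 + eps) * config.under_bolus, 0.0)
            if units > 0:
                boluses.append((t, units))
            # occasional late partial catch-up correction (no meal attached)
            if rng.random() < config.correction_prob:
                delay = rng.uniform(*config.correction_delay_range)
                t_corr = t + delay
                if t_corr < duration - 30:
                    deficit = nominal * (1.0 - config.under_bolus)
                    corr = deficit * rng.uniform(0.5, 1.0)
                    if corr > 0:
                        boluses.append((t_corr, corr))

    gaps: list[tuple[float, float]] = []
    for day in range(days):
        for _ in range(rng.poisson(config.gaps_per_day)):
            length = float(rng.uniform(*config.gap_len_range))
            start = float(rng.uniform(day * 1440, (day + 1) * 1440 - length))
            gaps.append((start, length))

    return Scenario(duration=duration, basal=config.basal, meals=meals,
                    boluses=boluses, cgm_noise_sd=config.cgm_noise_sd,
                    gap_spec=gaps, seed=int(rng.integers(2**31 - 1)))


def scenario_events(scenario: Scenario) -> EventList:
    """Diary-event view of a scenario (timestamps anchored at its start)."""
    events = EventList()
    for t, grams, announced in scenario.meals:
        events.meals.append(Meal(scenario.start + pd.Timedelta(minutes=t),
                                 grams, announced))
    for t, units in scenario.boluses:
        events.boluses.append(Bolus(scenario.start + pd.Timedelta(minutes=t), units))
    from .core_io import BasalSegment
    events.basal_segments.append(BasalSegment(
        scenario.start, scenario.start + pd.Timedelta(minutes=scenario.duration),
        scenario.basal))
    return events


@dataclass
class CorpusBundle:
    """A synthesized corpus plus everything needed to audit or replay it."""

    split: DataSplit
    scenario: Scenario
    events: EventList
    result: SimulationResult
    config: CorpusConfig


def make_training_corpus(config: CorpusConfig, seed: int,
                         step: int = 5) -> CorpusBundle:
    """Simulate one continuous stretch and split it chronologically.

    Training-set CGM gaps shorter than 30 min are linearly interpolated;
    the test portion is left untouched (no test-set imputation).
    """
    if config.test_days <= 0 or config.train_days <= 0:
        raise ValueError("train_days and test_days must both be positive")
    scenario = generate_scenario(config, seed)
    result = simulate(config.params, scenario, step=step)
    series = result.series
    split_at = config.train_days * 1440 // step
    if split_at >= series.n:
        raise ValueError("split point is at or beyond the simulated duration")
    train = interpolate_short_gaps(series.slice(0, split_at))
    test = series.slice(split_at, series.n)
    return CorpusBundle(DataSplit(train, test), scenario,
                        scenario_events(scenario), result, config)
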