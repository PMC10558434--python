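# Methods

This note documents the models, parameter choices and numerical decisions
behind `glucodss`, and what the synthetic-data experiments do and do not
demonstrate about real CGM data.

## Data model and preprocessing

All signals live on a uniform grid (default 5 min): CGM in mg/dl with a
missingness mask, insulin delivery in U/min, CHO intake in g/min.  Diary
events are rasterized conservatively: a bolus of U units (or meal of G
grams) becomes a one-bin rate of `U/step` (`G/step`), and basal segments
are prorated over partially covered bins, so channel sums times the step
equal delivered totals exactly.  CGM readings snap to the nearest grid
point (exact halves snap earlier; if two readings collide the nearer in
time wins).  CGM gaps strictly shorter than 30 min are linearly
interpolated on *training* data only; the test set is never imputed, and
every window that touches an un-interpolated gap is simply dropped.  The
canonical CSV schema is `timestamp, cgm_mgdl, insulin_Umin, cho_gmin`
plus optional `bolus_U, meal_g, meal_announced` columns so that event
lists round-trip through files; an OhioT1DM-style XML adapter converts
basal rates from U/hr and runs the same alignment.

## The glucose–insulin minimal model

The simulator is the Bergman minimal model of plasma-insulin action
extended with a two-compartment subcutaneous insulin chain and a
three-compartment oral absorption chain (states: G, X, Isc1, Isc2, Ip,
Qsto1, Qsto2, Qgut; equations in `simulate.py`).  Units: G mg/dl, insulin
compartments µU/ml, gut compartments mg; insulin input converts via
`1e6 / (VI·BW·1000)` µU/ml per U.  Population defaults (70 kg adult):
SG = 0.02 min⁻¹, SI = 7·10⁻⁴ ml/µU/min, p2 = 0.012 min⁻¹, Gb = 120 mg/dl,
VG = 1.6 dl/kg, kd = 0.026, ka2 = 0.014, ke = 0.127 min⁻¹, VI = 0.126 l/kg,
kgri = kempt = 0.065, kabs = 0.018 min⁻¹, fabs = 0.9.

The initial state is the exact basal steady state (Ipb = ub·ci/ke, X = 0,
G = Gb), so a meal-free simulation sits at Gb to solver precision — the
contract the test suite asserts, along with gut mass balance
(`fabs·ingested = ∫Ra dt + fabs·remaining`), monotone dose- and
meal-responses, and solver-refinement stability.

**Integration.** Inputs are piecewise constant per grid bin, so the ODEs
are integrated with fixed-step RK4 sub-steps aligned to bin boundaries
(default 1 min).  An adaptive stepper would have to be restarted at every
input discontinuity to retain its order; fixed steps aligned to the bins
are simpler, bit-reproducible, and the refinement test (halving the
sub-step moves glucose by < 0.1 mg/dl sup-norm over a day with a large
meal and bolus) bounds the discretization error well below CGM noise.

## The emulated patient and corpus

`CorpusConfig` encodes the statistical structure of a compliant but
suboptimally controlled, insulin-resistant patient — the regime in which
a corrective-bolus DSS is clinically interesting:

| parameter | default | rationale |
|---|---|---|
| corpus length | 28 d (21 train / 7 test) | a scaled-down version of a 6-week/10-day single-patient split |
| meals | 3/day at 07:30, 12:30, 19:00 ± 20 min, 40–100 g | typical adult diet, fully announced (a compliant reporter) |
| carb ratio | 3.5 g/U | consistent with the low insulin sensitivity below |
| dosing noise | ±15 % (multiplicative, s.d.) | carb-counting error; keeps meal–bolus correlation ≈ 0.9 (strong collinearity) |
| under-bolusing | ×0.6 | consistent suboptimal prandial dosing → prolonged hyperglycemia |
| corrections | p = 0.3 per meal, 90–180 min later, 50–100 % of the dosing deficit | real diaries contain standalone corrective boluses; without any insulin-without-meal events the dose counterfactual a DSS relies on is unidentifiable from data |
| patient physiology | Gb = 150 mg/dl, SG = 0.012 min⁻¹, SI = 2·10⁻⁴ ml/µU/min, kabs = 0.012, kempt = 0.05 min⁻¹ | elevated fasting glucose, slow glucose effectiveness and marked insulin resistance: a 5 U bolus lowers glucose ≈ 30 mg/dl, so corrections are useful but cannot reach hypoglycemia from > 180 mg/dl |
| CGM noise | iid N(0, 5 mg/dl), floor 40 | typical sensor error; no autocorrelation (see limitations) |
| gaps | ≈ 1/day, 10–45 min | ≈ 2–3 % missing, as in a well-behaved sensor record |

With these settings the corpus runs ≈ 31 % TAR with zero TBR and glucose
peaks ≈ 315 mg/dl, and a typical test week yields about five 8-hour
postprandial windows satisfying the selection rules — the same order as
the case study this emulates.  The under-controlled patient in the
original setting spends even more time above range (≈ 46 %); the minimal
model relaxes to Gb between meals, so matching that level exactly would
require an unphysiologically high Gb, and the package settles for the
same qualitative structure (long postprandial excursions, no hypos)
rather than the exact percentage.

## Predictors

Both variants share one architecture — a single LSTM layer (default 64
units) over a 12-sample (60 min) lookback of 3 channels, a linear
read-out, z-scored inputs/targets — and one training procedure: Adam on
MSE (lr 10⁻², batch 256, max 60 epochs), early stopping with patience 10
on the chronological last 20 % of training windows, best weights
restored.  The lookback, optimizer and normalization are package choices
(config-exposed); the variants differ *only* in the preprocessing flag,
which the test suite asserts structurally.  The LSTM forward/backward
pass and Adam are implemented in numpy (`_lstm.py`): the networks are
small, the implementation is checked against central-difference gradients
to 10⁻⁵, and training is bit-reproducible from a seed on a fixed
platform (cross-platform bit-exactness is not promised).

IOB/COB filters are computed over the full series before windowing
(their 6-hour support exceeds the lookback), with the pre-history
warm-started at the series' first basal rate so a mid-stream start shows
no spurious IOB ramp.  When a replay window begins on a bolus bin, the
basal rate is passed explicitly.

`predict_counterfactual` adds a candidate bolus to the insulin channel at
the anchor bin (raising IOB there by exactly the dose, since h[0] = 1)
and re-runs the forward pass; it is the bridge between the predictors and
the DSS.

## Shapley interpretation

Forecasts are explained as 3-player games over whole channels: v(S) is
the forecast with channels outside S replaced, over the whole history up
to the anchor, by their training-set means.  Masking acts on the *raw*
channels before the IOB/COB filters so attributions refer to the same
physical inputs in both variants, and it covers the full history (not
just the lookback window) because the filters propagate pre-window
insulin into the window.  All 8 coalitions are evaluated in one batched
forward pass per coalition, and φ comes from exact enumeration, so the
axioms hold to machine precision; the kernel-weighted least-squares
estimator is retained as a cross-check and for >3-player extensions.  On
a linear model this construction reduces analytically to
φ_j = β_j (x_j − E[x_j]), which the suite verifies against the
implementation on random instances.

**Sign-consistency.** Summary statistics correlate φ with the channel's
*physiological exposure* at the anchor — the CGM value, IOB, and COB
(standard curves for both variants) — rather than the raw impulse value
at the single anchor bin.  With impulse-coded channels the anchor-bin
value is the basal rate at > 95 % of instances, so instances shortly
after a bolus pair a strongly negative φ with a *low* raw value and can
push the rank correlation positive even for a physiologically correct
model; the exposure is the natural scalar summary of the channel history
that masking actually perturbs.  Raw anchor values are still recorded on
every explanation, and `summarize(..., value_source="raw")` reproduces
the raw-value statistic.

## Identification and replay

Postprandial windows are 8-hour slices starting at an announced meal with
no further CHO in the window and no non-prandial bolus (a bolus more than
15 min from the meal counts as corrective).  Per window, the free subset
{SI, SG, p2, kabs, kempt} is identified by MAP: independent log-normal
priors centered at the population (pipeline: corpus-patient) values with
log-s.d. 0.5 for SI and 0.3 for the rest, a Gaussian CGM likelihood with
the known sensor s.d., L-BFGS-B in log-parameter space within ±3 prior
s.d., best of 3 seeded starts.  The window's initial glucose is its first
CGM reading; the other compartments start at basal equilibrium, which
ignores residual IOB/COB from before the window — acceptable because the
selection rules keep the preceding meal ≥ 5 h away, and the fit residual
is reported as a diagnostic.  On self-generated windows, SI is recovered
to well under 10 % noise-free and a few percent median error under
5 mg/dl CGM noise.

Replay runs the identified model bin by bin.  Every 5 min, starting 2 h
after the meal and outside a 120-min post-bolus lockout, the DSS reads
the *simulated* (noise-free) CGM history; if it exceeds 180 mg/dl the CIB
cost J is scanned over the 0–10 U grid in 0.1-U steps and a non-zero
minimizer is delivered into the current bin.  A minimizer of exactly 0 U
counts as "no bolus".  The cadence and lockout are package choices
(config-exposed); the cost, target, trigger rule and grid resolution
follow the DSS definition.  Outcomes per window are TBR/TIR/TAR of the
replayed trace plus correction insulin and bolus counts, aggregated as
median [IQR] across windows.

## What the experiments show — and what they cannot

On this synthetic corpus (5-seed majority at PH = 30): the two variants'
test RMSE differs by < 2 mg/dl; p-LSTM's insulin sign-consistency is
negative and CHO positive while np-LSTM's insulin sign is not reliably
negative; and in replay the p-LSTM DSS strictly raises median TIR with
zero TBR, while any predictor whose forecast does not decrease with dose
provably never suggests a bolus (boundary-minimum argument, also checked
with randomized stubs).

Limitations to keep in mind when transferring conclusions to real data:
the CGM noise is white (real sensor error is autocorrelated and
drift-prone), there is no plasma–interstitial sensor lag, no exercise,
stress, alcohol or intra-day parameter variation, meals are always
announced, and the replay virtual patient shares its functional form with
the data generator — so identification here is easier than against real
physiology, and absolute error levels (RMSE ≈ 6 mg/dl, time gain = PH)
are optimistic relative to published CGM forecasting results.  The
*contrast between the variants*, which is the object of study, does not
depend on these simplifications: it is produced by the meal–bolus
collinearity, which the generator reproduces faithfully.

## Problem sizes

Default experiment scale, chosen to keep a full run at minutes on one
CPU: 28-day corpus (8 064 samples), ≈ 5 300 training windows per model,
1 500 explained anchors per model, ≈ 5 replay windows with 3-start
identification each.  The acceptance tests run 5 seeds of the PH = 30
study plus 20 identification seeds; `scripts/acceptance.py` runs one full
seed including both horizons.
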