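# Methods

## Signal model

A fuel-cell breath analyzer produces a voltage transient when ethanol in
the sampled breath oxidizes at the platinum anode. The device digitizes
the amplified voltage every 50 ms with a 10-bit ADC (reference 4.94 V,
codes 0–1023, one count = 1000·4.94/1024 = 4.8242 mV). The sensor's
amplified sensitivity is 13 mV per mcg/100 mL and its ceiling is
300 mcg/100 mL, so a concentration `c` maps to a noiseless peak of
`round(13·c / 4.8242)` counts — e.g. 135 counts at 50 mcg/100 mL.

No raw traces from such devices are publicly deposited, so the package
simulates them. The simulated response rises from baseline as a
saturating exponential, reaches its quantized peak at
`t_peak = 200 + 4·c` ms (snapped to the 50 ms sampling grid), and then
decays exponentially toward baseline:

* the rise time constant is `t_peak / 5`, so the signal plateaus near the
  peak well inside the first ten readings — the qualitative behaviour of
  real fuel cells (immediate reaction within ~200 ms, slower approach to
  the peak at higher concentrations) and a precondition for the
  mode-to-peak classifier rule to pass genuine responses;
* the decay rate is 3·10⁻⁴ per ms (≈1.5 % per sample), a slow downtrend
  consistent with a response that is still near its peak throughout the
  1.5 s area of interest;
* quantization rounds half-up to integer counts; additive integer noise
  of amplitude ±1 count models electrical noise; everything is clipped to
  [0, 1023].

Clean (zero-concentration) samples receive only a pump-actuation
transient: a 2-count bump decaying with a 60 ms time constant, i.e.
[2, 1, 0, …] after quantization, plus the same ±1-count noise. The
physical rationale is the Nernst open-circuit potential
`E = E0 + (R·T)/(n·F)·ln(Pr/Pp)` (provided as `nernst_ocp`, with n = 4
for the dominant ethanol→acetic-acid oxidation): pump actuation perturbs
the reactant/product partial-pressure balance and nudges the cell voltage
slightly above baseline even without alcohol.

With this transient shape the zero classifier below *provably* fires on
every clean sample under default settings: at most two readings can reach
2 counts, so the mode of the first ten readings can never be the peak
value unless that peak is 0 or 1, and each such configuration is caught
by one of the four rules. The test suite verifies this over hundreds of
seeds.

The wet-bath calibration design simulated by default is ten
concentrations {0, 4, 10, 20, 30, 40, 50, 100, 150, 200} mcg/100 mL with
twenty trials each (200 traces), 60 readings (3 s) per trace. The 5 s
chamber feed and 0.35 mL pump draw of the physical protocol are
represented only by the trace's time origin (first reading = pump
release); no fluidics are modelled.

### What the simulator does not emulate

Sensor drift and electrode degradation, inter-device variation,
temperature and humidity effects, non-Gaussian noise bursts, and any
mechanistic electrochemistry. Tests passing on synthetic traces therefore
demonstrate that the *algorithmic* pipeline is correct and
self-consistent, not that a physical device meets these accuracy figures.

## Features

All decisions operate on the first 30 readings (0–1500 ms): Mode10 (mode
of readings 1–10), Max30, Min30, Avg20, Avg30, Max30−Avg20, Max30−Avg30.
Averages are kept at full float precision. When several values are
equally frequent in the first ten readings the *largest* is taken as the
mode: the classifier uses Mode10/Max30 closeness to detect a genuine peak
plateau, and the largest modal value is the most conservative against
falsely classifying a real response as zero. Readings beyond the window
never influence the features.

## Zero-threshold classification

Four rules, applied in order, first match wins:

1. Max30 = 0 — the signal never moved;
2. Mode10 = 0 — no sustained early response;
3. Mode10/Max30 < 0.8 — the peak is an isolated spike rather than a
   plateau the early readings fluctuate around (the ratio is taken
   mode-over-peak, the only direction in which "below 0.8" flags an
   unsupported peak);
4. Max30 − Avg20 < 1 count — an insufficient peak followed by a genuine
   downtrend, i.e. noise.

Comparisons are strict: a ratio of exactly 0.8, or a distance of exactly
1, falls through to the next stage. Both thresholds are configurable
(`ThresholdParams`); defaults are 0.8 (dimensionless) and 1 (counts).

## Calibration and quantification

`BreathAlcoholModel` fits concentration (y) on per-concentration averaged
Max30 peaks (x) by ordinary least squares; averaging the twenty trial
peaks per level before fitting avoids the bias of a single-point
calibration. The zero point is excluded by default — the classifier, not
the line, owns zero, and the clean-sample bump would otherwise bias the
intercept (`exclude_zero=False` reproduces the rejected single-line
alternative for comparison). The fit is delegated to
`scipy.stats.linregress`; the tests check it against an explicit
normal-equations solution. `fit()` returns `BreathAlcoholResults` with
the slope (mcg/100 mL per count), intercept, their standard errors (NaN
for a two-point fit, where residual variance is undefined), the R² of the
calibration fit, `summary()`, JSON persistence and plotting.

Predictions are `slope·Max30 + intercept` clamped to the physical range
[0, 300] mcg/100 mL. `quantify(trace)` composes the stages: extract
features, classify, and either return 0 (zero-flagged, with the rule that
fired recorded for diagnostics) or predict from the peak.

On noiseless synthetic data the round trip (simulate → calibrate →
quantify) recovers every true concentration to within one ADC
quantization step mapped through the slope (≈0.37 mcg/100 mL); the
residual error is the integer quantization of the peak.

## Evaluation

Metrics per concentration group: mean prediction, average accuracy, MSE,
MAE, RMSE, sample standard deviation (M−1 denominator) and
RSD = 100·σ/mean. Accuracy uses the absolute relative error,
`100 − 100·|actual − predicted|/actual`, so the group average equals
`100 − 100·MAE/actual`; the signed variant would exceed 100 % for
over-predictions and does not reproduce consistent tables. At an actual
of zero the ratio is undefined; a trial counts 100 % when predicted
exactly zero and 0 % otherwise, which makes the zero row a direct report
of classifier specificity.

The overall row aggregates groups unweighted: overall accuracy, MSE and
MAE are means of the group values and overall RMSE = √(overall MSE). R²
is always pooled over all pairs, `1 − Σ(a−p)² / Σ(a−ā)²`, and is
undefined (reported NaN) for constant actuals. Internal computation is
full precision; tables round half-up to two decimals only at
presentation. Groups with one prediction report NaN standard deviation
and RSD rather than failing, so small validation splits still evaluate.

`split_dataset` partitions traces 90/10 by default with the training size
rounded half up; with the 200-trace design that is exactly 180/20. All
randomness in the pipeline flows from one seed through a spawned
`SeedSequence`, and the report's provenance header records the seed,
config hash and package version.

## IoT gateway mock

The physical device confirms a participant's identity and uploads the
measured BrAC over cellular HTTP GET requests to two server-side scripts.
The mock reproduces that protocol shape — `get_name?id=<ID>` and
`insert?id=<ID>&brac=<value>`, URL-encoded, plain-text responses —
against a pluggable transport: an in-process dispatcher for tests and an
optional local HTTP server (stdlib `http.server`) used to exercise the
stateless-protocol property (a server restart between the lookup and the
upload changes nothing). Timestamps originate at the store on insert.
The session state machine enforces that no upload happens without a
successful lookup and explicit confirmation, and transport failures
abort with a retryable error and persist nothing. Authentication,
encryption and the cellular AT-command dialogue are out of scope.

## Numerical choices and degenerate inputs

* Rounding of simulated counts and of presented table cells is half-up
  (`util.round_half_up`), fixed rather than platform banker's rounding.
* ADC step divisor is 1024 (the quantization-step convention,
  reproducing the 4.82 mV step); the 1023 code-span variant (4.83 mV) is
  available as an override on `adc_step_mv` for comparison.
* Calibration requires ≥ 2 points with distinct peaks; identical peaks
  or a single point raise immediately.
* `SimulationParams` rejects configurations whose peak at the sensor
  ceiling would overflow the ADC.
* Traces must have ≥ 30 readings; shorter inputs raise before any
  feature is computed.
* The breath-to-blood ratio is configurable everywhere it appears
  (default 2300); conversions reject negative concentrations.

## Problem sizes

Default simulations are small by construction — 200 traces of 60 integer
readings — so the full test suite (including 1000-trace oracle sweeps and
property suites) runs in seconds, and the acceptance script's 100-trace
zero-classification check in well under a second.

## Known limitations

At the smallest nonzero design concentration (4 mcg/100 mL, an ≈11-count
peak) the ±1-count noise makes the mode-to-peak ratio rule marginal and
roughly 2 % of simulated traces are zero-classified, which depresses that
group's accuracy; this mirrors the general pattern that relative error is
largest at the bottom of the range. The simulator's amplitude scale is
derived from the stated 13 mV sensitivity and ADC constants; a real
amplification chain may scale differently, which would change slopes but
not the pipeline's logic.
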