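# breathcal

Calibration and validation toolkit for fuel-cell breath analyzers.

A fuel-cell breath analyzer draws a fixed breath sample onto a platinum
anode, where ethanol oxidation produces a voltage proportional to the
breath alcohol content (BrAC, mcg ethanol / 100 mL breath). The amplified
voltage is digitized by a 10-bit ADC (4.94 V reference, so one count is
4.82 mV) at 50 ms intervals, and the device must turn that short integer
time series into a concentration. `breathcal` implements the complete
device logic in software — with a trace simulator standing in for the
wet-bath calibration bench — so the whole pipeline is testable without
hardware. It is aimed at instrumentation engineers and analytical
chemists prototyping or validating this class of sensor.

## Method

From the first 30 readings (0–1500 ms, the area of interest) seven
features are extracted: the mode of the first ten readings (Mode10), the
maximum, minimum and means of the window (Max30, Min30, Avg20, Avg30) and
the peak-to-mean distances (Max30−Avg20, Max30−Avg30).

Quantification is two-staged:

1. **Zero-threshold classifier.** Clean samples still show a slight
   above-baseline transient (electrical noise, pump actuation perturbing
   the Nernst partial-pressure balance), so a regression line alone would
   report false positives at zero. Four rules, applied in order, classify
   a trace as alcohol-free: Max30 = 0; Mode10 = 0; Mode10/Max30 < 0.8;
   Max30 − Avg20 < 1 count.
2. **Linear calibration.** Surviving traces are quantified with an
   ordinary-least-squares line of concentration on Max30, fitted to
   per-concentration *averaged* peaks with the zero point excluded, and
   clamped to the sensor's physical range [0, 300] mcg/100 mL.

Performance is reported per concentration group and overall with the
standard analytical metrics: accuracy% (100 − 100·MAE/actual), MSE, MAE,
RMSE = √MSE, pooled R², sample standard deviation and RSD% =
100·σ/mean. BrAC converts to blood alcohol content via the
breath-to-blood ratio (BAC = BrAC·BBR/1000; BBR = 2300 in Malaysia). A
mock IoT gateway reproduces the device's cloud protocol (GET-style
identity lookup, confirmation, measurement upload) against an in-process
or local-HTTP transport.

## Worked example

Simulate the wet-bath design (ten concentrations 0–200 mcg/100 mL, twenty
trials each), split 90/10, calibrate on the training set and evaluate the
validation set:

```python
import breathcal as bc

report, results = bc.run_pipeline(seed=1)
print(results.summary())
```

```
Breath alcohol linear calibration (OLS)
===============================================
calibration points        9  (zero excluded)
peak range (counts)       11.95 - 538.78
slope  (mcg/100mL/count)  0.371950  (se 0.00027)
intercept (mcg/100mL)     -0.248293  (se 0.068)
R^2 of calibration fit    0.999996
zero rules                ratio < 0.8, peak - avg20 < 1.0
prediction clamp          [0, 300.0] mcg/100 mL
```

The slope says one ADC count corresponds to ≈0.372 mcg/100 mL — the
inverse of the sensor's 13 mV sensitivity divided by the 4.82 mV
quantization step — and the near-zero intercept shows the averaged-peak
calibration is essentially proportional. `print(report.summary())` gives
the grouped validation table (values in mcg/100 mL, rounded at
presentation):

```
ActualConcentration  N  AveragePredicted  AverageAccuracy  MSE  MAE  RMSE  R2  StandardDeviation  RSD
                0.0  1              0.00           100.00 0.00 0.00  0.00   -                  -    -
                4.0  1              4.22            94.62 0.05 0.22  0.22   -                  -    -
               10.0  3             10.04            98.21 0.03 0.18  0.18   -               0.21 2.14
               20.0  4             19.93            98.61 0.10 0.28  0.32   -               0.36 1.79
               30.0  2             29.88            99.60 0.01 0.12  0.12   -               0.00 0.00
              100.0  4             99.90            99.72 0.11 0.28  0.32   -               0.36 0.36
              150.0  3            150.14            99.90 0.05 0.14  0.23   -               0.21 0.14
              200.0  2            200.42            99.79 0.21 0.42  0.46   -               0.26 0.13
            Overall 20                 -            98.81 0.07 0.20  0.26 1.0                  -    -
```

The zero row is perfect — the threshold classifier rejects every clean
sample — and accuracy is lowest at the smallest nonzero concentration,
where ±1-count noise is largest relative to the ~11-count peak. Overall
accuracy is the unweighted mean of the group accuracies. Converting the
200 mcg/100 mL training ceiling to blood alcohol:
`bc.brac_to_bac(200, 2300)` → `460.0` mg/100 mL.

The same flow is available from the shell:

```sh
breathcal simulate --seed 1 --out traces.csv
breathcal calibrate --traces traces.csv --out model.json
breathcal quantify --traces traces.csv --model model.json --out readings.csv
breathcal evaluate --readings readings.csv --out report.csv
breathcal convert 200            # -> 460 mg/100 mL BAC
```

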