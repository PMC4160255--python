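# ewdclim

Dendroclimatology toolkit for building tree-ring **earlywood density (EWD)
chronologies** and turning them into calibrated, verified **spring
temperature reconstructions**.

In warm, semi-humid monsoon-margin forests, the density of the first-formed
(earlywood) portion of an annual ring responds to moisture stress early in
the growing season: warm, dry springs narrow the tracheids, raise the cell-
wall fraction and hence the density. A multi-core EWD chronology can
therefore serve as a proxy for May–June maximum temperature where latewood
density (the classic cool-site temperature proxy) carries little signal.
`ewdclim` implements that full analysis chain for anyone working with
Tucson/RWL or CSV measurement files and monthly station climate tables:

1. **Standardization** — each core series is divided by a fitted growth
   curve, by a deterministic cascade: modified negative exponential
   `y(t) = a·e^(−bt) + d` (a, b > 0, curve > 0), else a non-positive-slope
   line, else the horizontal mean. Indices are dimensionless ratios.
2. **Chronology** — per-year Tukey biweight robust mean of the index
   series, with gliding-window (30 yr / 15 yr step) mean inter-series
   correlation `rbar` and expressed population signal
   `EPS = N·rbar / (N·rbar + (1 − rbar))`; the chronology is truncated to
   the earliest year from which EPS > 0.80 (override: EPS ≥ 0.75 with ≥ 4
   trees) and depth ≥ 4 trees / 6 cores hold through the present.
3. **Climate response** — bootstrapped correlation functions and
   principal-component response functions over a monthly window from July
   of the prior year to September of the growth year, plus first-order
   partial correlations.
4. **Calibration & verification** — OLS transfer function
   `T = β₀ + β₁·index`, leave-one-out cross-validation, reduction of error
   `RE = 1 − SSE/SSM`, sign test on departures from the calibration mean,
   and the product-means *t* (Fritts' PMT).
5. **Reconstruction** — transfer applied over the reliable span; warm/cold
   years classified against mean ± 1σ; a zero-phase 10-yr low-pass
   (second-order Butterworth, forward–backward) exposes decadal warm/cold
   periods (runs ≥ 5 yr above/below the mean).
6. **Field diagnostics** — detrended spatial correlation maps against any
   annual gridded field, and composite anomaly maps over the k warmest /
   coldest reconstructed years.
7. **Synthetic data** — a generator producing multi-core density datasets
   and monthly climate with *known* truth (growth curves, signal
   coefficients, common-variance fraction), so the whole pipeline is
   testable end to end without any data download.

## Worked example

```sh
python examples/03_calibrate_reconstruct.py
```

prints (seed 1):

```
Calibration / leave-one-out verification
  n years        : 56
  R              : 0.667
  r^2            : 0.445
  F              : 43.312
  sign test      : 41+/15-  (p=0.0006856)
  RE             : 0.385
  PMT            : 2.693  (p=0.009416)
  r (cross-val)  : 0.623

reconstruction 1666-2008 (343 years): mean 25.6 degC, sd 0.46 degC
event shares: {'warm': 14, 'cold': 15, 'normal': 71}
28 decadal warm/cold periods; first three: 1668-1672 warm, 1673-1685 cold, 1686-1692 warm
correlation with the generator's true temperature: 0.62 (true slope 1.89, estimated 2.09 +- 0.32)
```

Reading this: the chronology explains 44.5% of May–June maximum temperature
variance over the 56 calibration years; RE = 0.385 > 0 means the model beats
the climatology benchmark out of sample; 41 of 56 leave-one-out predictions
fall on the correct side of the calibration mean; and because the data are
synthetic, the recovered transfer slope can be compared with the generating
one (2.09 ± 0.32 vs 1.89). The other examples cover chronology building,
response functions, and gridded-field composites; each prints a line or two
explaining its numbers.

The same pipeline runs from the shell:

```sh
ewdclim simulate --seed 1 --out bench/
ewdclim chronology --measurements bench/measurements.csv --out chron.csv
ewdclim calibrate --chronology chron.csv --tmax bench/tmax.csv --out table1.csv
ewdclim run-all --config run.yaml          # whole study from a YAML config
```

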