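# heatacc

Behaviour classification and heat-response analysis for collar-mounted
tri-axial accelerometers on savanna antelope.

Biologging collars record short accelerometer *bursts* (here 3.3 s at
33.3 Hz — 110 samples per axis — every 5 minutes). From these, `heatacc`
reconstructs what the animal was doing and how its time budget and
movement intensity respond to heat:

1. **Features** — per burst, 19 descriptors: mean, variance, SD, max, min,
   range, main frequency, main amplitude and spectral entropy for the
   surge (x) axis and for the collar-rotation-invariant yz-plane magnitude
   `a_yz = sqrt(a_y² + a_z²)`, plus overall dynamic body acceleration
   (ODBA, a 22-sample running-mean static split summed over all three
   axes) as an energy-expenditure proxy.
2. **Classification** — correlation-filtered stepwise forward selection
   (|r| < 0.9, five features) feeding a gradient-boosted decision-tree
   classifier (XGBoost; nrounds = 10, max_depth = 6, eta = 0.3), evaluated
   with a pooled 5-fold cross-validated confusion matrix with per-class
   precision/recall and a Wilson 95% CI on accuracy.
3. **Time budgets** — the 12 ethogram behaviours consolidate into 5
   analysis categories (browsing, grazing, walking, ruminating, resting;
   five rare behaviours excluded, ~2% of records). Records join a
   blackglobe heat index computed from air temperature, solar radiation
   and humidity; afternoon (12:00–17:59) proportions and mean-ODBA cells
   aggregate per blackglobe °C × hour × month × individual, with
   mean-ODBA cells kept only when backed by ≥ 30 recordings.
4. **Smooth models** — penalized-spline mixed models (logit-link
   quasi-binomial for proportions, weights = cell size; identity link for
   ODBA; individual random intercepts; REML smoothing) estimate

   `logit E[p] = β₀ + s(blackglobe) + s(hour) + month + b_individual`

   for each behaviour, and, for the 10 hottest vs 10 coolest days of the
   hot season (October–December, by daily maximum air temperature), cyclic
   diel models

   `logit E[p] = β₀ + hot·δ + s_c(hour) + s_c(hour)·hot + b_individual`

   where a significant interaction smooth means the diel pattern differs
   and a significant δ means the 24-h mean activity differs, quantified as
   the percentage difference of 24-h means. Worst-case concurvity is
   reported per smooth (flagged at ≥ 0.8); α = .05 throughout.

A synthetic-data module generates labelled bursts (posture + gait
periodicity + noise per behaviour), multi-day behaviour timelines with
temperature-dependent allocation, and matching weather series, so the
whole pipeline is testable without field data.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data:

```bash
python analysis/01_simulate.py        # writes scratch/data/
python analysis/02_train_classifier.py
python analysis/03_heat_response.py
python analysis/04_diel_comparison.py
```

`02_train_classifier.py` prints, for the 2,040-burst training fixture:

```
cross-validated accuracy: 100.0% (95% CI 99.8%-100.0%) on 2040 bursts
selected features and accuracy contributions:
  x_freqamp: +0.852
  yz_mean: +0.063
  x_max: +0.001
  ...
```

meaning the surge-axis spectral amplitude alone lifts accuracy 85 points
over the majority-class baseline — the synthetic behaviours differ mainly
in gait periodicity, and the remaining features add small refinements.
`03_heat_response.py` then classifies the 11,520-burst deployment
(~1.8% of predictions excluded as rare behaviours) and fits the heat
models; with the generator's planted grazing suppression the blackglobe
smooth for grazing comes out significant (p ≈ 0.002) while unplanted
behaviours stay null. `04_diel_comparison.py` summarises the hot/cool
contrast per behaviour: for grazing it reports a significant intercept
contrast with a −22% difference of 24-h means, matching the planted
all-day temperature effect.

## Command-line interface

The same stages are available as a CLI for real collar files
(CSV dialects: three per-axis columns, or one interleaved
`x y z x y z ...` column):

```bash
heatacc simulate --out data/ --seed 0
heatacc train --training data/training_bursts.csv --out model/
heatacc analyze --model-dir model/ --bursts data/scenario_bursts.csv \
    --weather data/weather.csv --out analysis/
```

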