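# ordtrial

Autoregressive transitional ordinal modelling and Monte-Carlo power studies
for multivariate ordinal trial endpoints (ten upper-extremity key muscles,
each scored 0–5, five cervical segments per body side).

The follow-up score of each key muscle *below* a side's motor level is
modelled with a cumulative-logit proportional-odds regression on

* a 10-level motor-level × distance factor,
* the muscle's own baseline score (ordered factor, dummy coded),
* the follow-up score of the muscle just rostral (the autoregressive term),
* optionally a treatment-arm indicator whose exponentiated coefficient is a
  conditional odds ratio (OR > 1 ⇒ better recovery under treatment).

On top of the model the package provides:

* `population` — synthetic reference populations (motor-level constellation
  frequencies, baseline score pools, at-level follow-up frequencies, model
  coefficients), plus estimation of all of these from a wide-format cohort
  CSV;
* `simulate` — a two-arm RCT simulator: multinomial constellation draws,
  baseline resampling with replacement, exactly balanced 1:1 allocation,
  at-level multinomial follow-up draws, and sequential rostral→caudal
  sampling of below-level scores from the transitional model;
* `battery` — six treatment-effect tests run on each trial: Welch t-test on
  the follow-up total, Welch t-test on the change from baseline, their
  motor-level-stratified conditional independence-test counterparts,
  baseline-adjusted ANCOVA, and the transitional model with
  participant-level permutation inference (default B = 1000);
* `power` — scenario grids (default: sizes 50–200 × odds ratios 1.0–1.5,
  42 scenarios), rejection fractions with 95 % Wilson score intervals, CSV
  export, and probability-shift / power-curve figures.

## CLI

```sh
# one simulated trial (wide CSV; optional long format)
ordtrial simulate --n 100 --beta-trt 0.2624 --seed 7 --out trial.csv

# the six-test battery on a trial file
ordtrial analyze --data trial.csv --permutations 1000 --seed 1 --out report.json

# power study over a grid (use --fast for 300 replicates / B=199)
ordtrial power --sizes 50,100,150 --effects 0.0,0.2624 --fast --seed 7 \
    --out table.csv --manifest manifest.json

# probability-shift figure (control vs treatment panels)
ordtrial plot-shift --beta-trt 0.2624 --lev C5.-3 --y-base 1 --y-auto 3 --out shift.png

# power curves from a saved table
ordtrial plot-power --table table.csv --out power.png
```

Population configuration is a YAML file with keys `constellation_weights`
(map like `"C5/C6": 0.1`), `segment_weights`, `at_ml_weights`,
`coefficients`, `baseline_pool_size`; see
`ordtrial.population.DEFAULT_CONFIG` for the defaults and pass it via
`--pop pop.yaml`.

## Data formats

* Wide cohort/trial CSV: `id, arm, left_ml, right_ml, base_L_C5..base_R_T1,
  fu_L_C5..fu_R_T1` (one row per participant).
* Long CSV: `participant_id, side, segment, motor_level, y_base, y_auto,
  y_out, arm` (one row per below-level muscle).
* Coefficients: JSON with labelled entries (`"lev:C6.-2"`, `"base:3"`,
  `"auto:1"`, `"trt"`, `"cutpoints"`).
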