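# icval

Validation of landmark event-status predictions when the validation sample
is **interval-censored**.

## The problem

Clinical registries of chronic disease (the motivating example is
radiological joint damage in psoriatic arthritis) observe disease status
only at clinic visits.  A prognostic model built on such a registry
predicts whether a patient will still be event-free at a landmark time
`t0`; validating that prediction needs the true status
`Y = I(T > t0)` — but with intermittent assessment the event time `T` is
only known to lie between the last event-free visit `a-` and the first
post-event visit `a+` (case-K interval censoring).  `Y` is determined only
for patients with `a+ <= t0` (known failed) or `a- >= t0` (known
event-free); restricting validation to those patients selects on outcome
and visit behaviour jointly and biases both the mean prediction error

    PE(t0) = E | Y - Yhat(X; theta_hat) |,    Yhat = I(S(t0 | X; theta_hat) > c),

and the landmark AUC
`P(S(t0|X_i) > S(t0|X_j) | T_i > t0, T_j <= t0)`.

`icval` implements four estimators of PE and AUC for this setting:

* **unweighted** — the biased complete-case comparator;
* **imputation** — unknown losses replaced by their conditional expectation
  given the censoring interval under the fitted event model;
* **IPW** — classified subjects weighted by `1/pi` where
  `pi = P(Y is determined | Y, X)` is computed by numerical integration
  over a joint model of the event, recurrent-assessment and
  loss-to-follow-up processes (time-homogeneous Poisson or semiparametric
  Andersen–Gill visit intensities);
* **AIPW** — IPW plus a model-based augmentation term for stability and
  efficiency.

It also ships the full Monte-Carlo study apparatus: a synthetic-data
engine (Weibull proportional-hazards event times; Poisson or gamma-renewal
visit processes; calibrated administrative censoring) and a study driver
reporting empirical bias (EBIAS) and empirical SE (ESE) of every estimator
against replicate-specific truths.  See `docs/methods.md` for the model
details and numerical choices.

## Worked example

```python
from icval import (SimulationConfig, resolve_design, generate_dataset,
                   WeibullPH, AccuracyEvaluator, fit_th_poisson)

design = resolve_design(SimulationConfig())   # calibrates lambda, B, gamma0; t0 = 1
data = generate_dataset(design, seed=7)       # 500 training + 500 validation subjects

event = WeibullPH.from_sample(data.train, covariate_indices=(0, 1)).fit()
print(event.summary())

visit = fit_th_poisson(data.valid, covariate_indices=(0, 2))
evaluator = AccuracyEvaluator(data.valid, event, t0=design.t0, B=design.B)
print(evaluator.fit("unweighted").summary())
print(evaluator.fit("aipw", visit_model=visit).summary())
```

prints

```
Weibull PH model, interval-censored MLE
n = 500, log-likelihood = -787.6202
            estimate  std_err        z
log_lambda   -0.3219   0.0389  -8.2723
log_kappa     0.2856   0.0456   6.2644
beta_1        0.6787   0.0593  11.4417
beta_2        0.4269   0.0553   7.7233
lambda = 0.7247, kappa = 1.3305
Predictive accuracy at t0 = 1 (unweighted)
  prediction error (|Y - Yhat|, c = 0.5): 0.2598
  AUC: 0.8044
  subjects used: 381
Predictive accuracy at t0 = 1 (aipw)
  prediction error (|Y - Yhat|, c = 0.5): 0.3067
  AUC: 0.7514
  subjects used: 500
  sum delta/pi = 529.2, truncated weights: 0
```

The training fit recovers the generating parameters
(`beta = (log 2, log 1.5) = (0.693, 0.405)`, `kappa = 1.25`) within two
standard errors.  Only 381 of 500 validation subjects can be classified at
`t0 = 1`, and they are a favourable subset: the complete-case estimate
understates the prediction error (0.260) and overstates the AUC (0.804)
relative to the weighted estimates (0.307 / 0.751), which are close to this
replicate's population truth.  `sum delta/pi ≈ 529 ≈ n` shows the weights
are calibrated.

The same pipeline is scriptable from the shell:

```bash
icval simulate --config cfg.yaml --seed 3 --out data/
icval fit-event --subjects data/train_subjects.csv --visits data/train_visits.csv --out model.json
icval evaluate  --subjects data/valid_subjects.csv --visits data/valid_visits.csv \
                --event-model model.json --t0 1.0 --method aipw-th
icval study     --config cfg.yaml --seed 1 --out study/
```

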