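# Methods

## Setting

`icval` assesses how well a fitted event-time model predicts event-free
status at a landmark time `t0` when the validation sample is under
intermittent observation.  Each validation subject is examined at a baseline
visit (time 0) and at irregular follow-up visits up to the end of follow-up
`C = min(R, B)` (administrative end `B`, optional random loss to follow-up
`R`).  The binary disease status `Z(a) = I(T <= a)` is recorded at each
visit, so the event time `T` is case-K interval-censored: it is known only
to lie in `(a-, a+]`, the gap between the last event-free and the first
post-event assessment.

The target of validation is `Y = I(T > t0)` with predictor
`Yhat = I(S(t0 | X; theta_hat) > c)`, `c = 0.5` by default, where
`S(t | X; theta)` is the survivor function of a Weibull proportional-hazards
model fitted to a separate training sample.  Two accuracy summaries are
estimated: the mean absolute prediction error `PE = E|Y - Yhat|` and the
AUC, the probability that a randomly chosen event-free subject has a higher
predicted survival probability than a randomly chosen failed subject (ties
on the score get half credit).

## Why naive estimators fail, and the estimator suite

`Y` is determined by the visit history (`delta = 1`) only when a post-event
visit occurred by `t0` or an event-free visit occurred at/after `t0`.
Restricting to classified subjects selects on outcomes and visit patterns
jointly, so the complete-case ("unweighted") estimator is biased; it is kept
as the comparator.  Three corrections are implemented:

* **Imputation** — replace the unknown loss for `delta = 0` subjects by its
  conditional expectation under the fitted event model given the censoring
  interval, `E{|Y - Yhat| | T in (a-, a+], X} = Yhat (1 - p) + (1 - Yhat) p`
  with `p = P(T > t0 | T in (a-, a+], X; theta_hat)`.
* **IPW** — restrict to classified subjects and weight each by
  `1 / pi`, `pi = P(delta = 1 | Y, X)` computed from a joint model of the
  event, assessment and drop-out processes (below); the estimator divides
  by the full sample size `n`.
* **AIPW** — add the augmentation `(1 - delta/pi) E{|Y - Yhat| | X}` with
  `E{Y | X} = S(t0 | X; theta_hat)`.  Because `pi` itself involves the
  event model, the usual double-robustness argument does not apply here;
  the augmentation buys efficiency and robustness to a misspecified visit
  model when the event model is right.

ROC/TPR/FPR and the AUC use one shared representation: per-subject
"positive mass" `Psi_i` estimating `Y_i` and "negative mass" `Phi_j`
estimating `1 - Y_j` (complete-case, imputed, IPW or AIPW versions).  The
AUC is the tie-corrected rank statistic
`sum_ij [I(s_i > s_j) + 0.5 I(s_i = s_j)] Psi_i Phi_j / sum_ij Psi_i Phi_j`,
computed in `O(n log n)` by grouped prefix sums; ties are defined on risk
scores rounded to 12 digits (with continuous covariates any covariate tie
implies a score tie, so score ties are the ones that matter).

## Classification probabilities (weights)

Conditioning on `(Y, X)`:

* `Y = 0`: classification requires a post-event visit in `(T, t0]` before
  drop-out, averaged over the conditional failure density
  `f(t | T <= t0, X)`.  For any visit intensity the inner integral
  collapses via `int lam e^{-int lam} = 1 - e^{-int lam}`, leaving a single
  outer integral.
* `Y = 1`: classification requires the first visit after `t0` to precede
  the event, drop-out and `B`:
  `pi1 = int_{t0}^{B} lam_a(u) exp{-int_{t0}^{u}(lam_a + h) dv - int_0^u lam_c dv} du`.

With a constant (time-homogeneous Poisson) visit rate these are evaluated
by adaptive Gauss–Kronrod quadrature (`scipy.integrate.quad`, absolute
tolerance 1e-10); with a constant rate and constant event hazard `pi1` has
the closed form `a/(a+h) (1 - e^{-(a+h)(B-t0)})` used as a test oracle.
For the Andersen–Gill fit the cumulative baseline is a pure-jump (Breslow)
measure; the integrals are evaluated *exactly* as piecewise sums between
jump times, with `P(no visit in (s1, s2]) = exp{-e^{X'g}(L(s2) - L(s1))}`
and per-jump visit probability `1 - exp{-e^{X'g} dL_k}` (this converges to
the continuous-time expressions as the jumps refine; no smoothing is
applied).  A brute-force Monte-Carlo oracle that simulates the entire
observation scheme validates both paths.

Weights below `eps = 0.01` are truncated to `eps` (configurable, flagged in
the output).  Near-zero probabilities are rare under the default designs;
truncation only guards finite-sample instability of `1/pi`.

## Fitted component models

* **Event model** — Weibull PH, `S(t|X) = exp{-(lambda t)^kappa e^{X'beta}}`;
  `lambda` a rate (1/time), `kappa` the shape, `beta` log hazard ratios.
  The interval-censored log likelihood `sum log{S(a-|X) - S(a+|X)}` (valid
  when the visit process is conditionally independent of the event process
  given `X`) is maximised on the unconstrained scale
  `(log lambda, log kappa, beta)` by multi-start BFGS with a Nelder–Mead
  polish; an optimum is accepted when the polish cannot improve the
  objective beyond float noise.  Standard errors come from the numerically
  differentiated observed information.  Interval differences use
  `log(-expm1(-(H+ - H-)))` for accuracy with tight intervals.
* **Visit models** — (i) time-homogeneous Poisson with rate
  `exp(gamma0 + X'gamma)`, fitted as a Poisson GLM on the post-baseline
  visit count with offset `log C` (exposure is `C`, since visits may occur
  up to `C` by construction); (ii) semiparametric Andersen–Gill on calendar
  time with at-risk indicator `I(s <= C)`, `gamma` from the Cox partial
  likelihood and Breslow baseline increments
  `(# visits at u) / sum_{C_j >= u} e^{X_j'gamma}`.  Both are fitted to all
  visits regardless of event status, matching intensities that depend on
  covariates and time only.
* **Drop-out model** — Weibull PH on `(C, delta_dropout)`; when no subject
  drops out the model degenerates to `lambda_c = 0` and the simplified
  weight expressions apply (the two code paths agree exactly, which is
  tested).

## Synthetic-data engine

The generator reproduces the study conditions used throughout the empirical
evaluation: three covariates (standard normal with `corr(X2, X3)` in
{0, 0.5}, or Bernoulli(0.5) with the correlation induced by median
dichotomisation of Gaussians with tetrachoric correlation
`r = sin(pi rho / 2)`); Weibull PH event times with
`beta = (log 2, log 1.5)` on `(X1, X2)` and `kappa = 1.25`; visit gap times
`Gamma(eta, rate = exp(gamma0 + X1 g1 + X3 g2))` with
`(g1, g2) = (log 1.1, log 1.5)` (normal) or `(log 2, log 2.5)` (binary);
`eta = 1` gives a homogeneous Poisson assessment process, `eta > 1` a
renewal process used to study visit-model misspecification.  `C = B` and
`delta_dropout = 0` throughout (drop-out is a model capability, not a
generated condition).  Visit intensities do not depend on event status, so
assessments continue at the same rate after the event.

Three deterministic calibrations pin the free scale parameters:

* `lambda`: marginal `P(T > 1) = 0.5` (so the landmark `t0 = 1` is the
  marginal median), solved by Brent's method with the expectation over the
  linear predictor taken by 80-node Gauss–Hermite quadrature (normal) or
  exact 4-cell enumeration (binary);
* `B`: marginal `P(T <= B) = 0.9`;
* `gamma0`: mean number of post-baseline visits over `(0, B)` equal to 10.
  For `eta = 1` this is closed-form; for renewal gaps the expected count is
  the convergent series `E N(B) = sum_n P(Gamma(n eta, rate) <= B)`,
  averaged over covariates and solved by Brent's method — chosen over
  stochastic root-finding because it is exact and reproducible (it is
  verified against large-sample simulation in the tests).

The generator emulates clean registry data: exact visit times, error-free
status readings, no missing covariates, no death, and visit intensities
depending only on fixed covariates.  Passing tests therefore demonstrate
correctness of the estimators under these conditions, not robustness to
misclassified statuses, outcome-dependent visit behaviour beyond the
modelled form, or competing risks.

## Monte-Carlo study driver

One replicate: generate a training/validation pair (each `n = 500` by
default), fit the event model to the training sample, fit the TH and/or AG
visit models to the validation sample, and compute all requested estimators
at `t0`.  Truth is replicate-specific — the population PE and AUC of *that
replicate's* fitted predictor — evaluated on a fresh Monte-Carlo covariate
population (default 1e5) with `Y` integrated out analytically via
`P(Y = 1 | X) = S_true(t0 | X)`, which removes one layer of simulation
noise.  EBIAS is the mean of (estimate − truth) over replicates, ESE the
SD of the estimates; the default study size is 100 replicates.
Per-replicate seeds derive from the master seed via
`SeedSequence.spawn`, so results are reproducible and order-independent.
Replicates whose fits fail are excluded with a logged count; the study
aborts if more than 10% fail (none fail under the default designs).

## Design choices and conventions

* Boundary ties at the landmark: an event-free visit exactly at `t0` gives
  `Y = 1`; a post-event visit exactly at `t0` gives `Y = 0`.  Intervals are
  `(a-, a+]`; right censoring is `a+ = +inf` in memory and an empty field
  in CSV.
* The "unweighted" comparator normalises by the number of classified
  subjects (a genuine complete-case mean); the IPW/AIPW estimators
  normalise by the full `n`.
* The risk score is the survivor probability: larger `S(t0|X)` means a
  "positive" (event-free) prediction, and the AUC orders subjects by it.
* The default threshold grid for ROC curves is 101 equispaced points in
  (0, 1); the AUC is computed from the rank statistic directly, not by
  trapezoidal integration of the gridded curve.
* Conditional probabilities are clipped to [0, 1] with a 1e-12 floor on
  denominators before ratios are formed.

## Known limitations

* No variance or confidence-interval estimation for PE/AUC (the study
  driver reports empirical SEs across replicates instead).
* Weights condition on covariates and time only, not on richer observed
  histories (prior visit counts or times).
* No gap-time (renewal) fitting of the visit process: the misspecification
  study deliberately fits Poisson-type models to renewal data.
* The AIPW estimator is not doubly robust here, because the weights depend
  on the event model; a wrong event model breaks both terms.
* Exact (uncensored) event times are supported only as arbitrarily tight
  intervals; piecewise-constant or penalised baseline hazards and frailty
  terms are out of scope.
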