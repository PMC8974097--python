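"""Synthetic-data engine for the simulation designs.

Generates paired training/validation samples under the study conditions
used throughout the package's empirical evaluation:

* three covariates; Scenario "normal": standard normal marginals with
  X1 independent of (X2, X3) and corr(X2, X3) in {0, 0.5}; Scenario
  "binary": Bernoulli(0.5) marginals, the X2-X3 correlation induced by
  dichotomising correlated Gaussians at their medians (tetrachoric
  correlation r = sin(pi * rho / 2));
* Weibull PH event times with beta = (log 2, log 1.5) on (X1, X2) and
  shape kappa = 1.25, the rate lambda calibrated so the marginal
  P(T > 1) = 0.5 (hence the landmark t0 = 1 is the marginal median);
* administrative censoring at B, calibrated so the marginal CDF of T at B
  is 0.9; no random loss to follow-up (C = B, delta = 0);
* an assessment process with per-subject rate exp(gamma0 + X1 g1 + X3 g2);
  gap times between consecutive visits are Gamma(shape eta) with that rate,
  so eta = 1 is a time-homogeneous Poisson process and eta > 1 a
  (misspecifying) renewal process; gamma0 is calibrated so the expected
  number of post-baseline visits over (0, B) is mu = 10.

All calibrations are deterministic: expectations over covariates use
Gauss-Hermite quadrature (normal) or exact 4-cell enumeration (binary), and
the expected renewal count uses the series E N(B) = sum_n P(S_n <= B) with
S_n ~ Gamma(n * eta, rate).  Latent event times are returned in a side
channel for truth evaluation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, special

from .data import SubjectRecord, VisitRecord
from .event import WeibullPHParams

__all__ = [
    "SimulationConfig",
    "Design",
    "resolve_design",
    "draw_covariates",
    "calibrate_lambda",
    "calibrate_B",
    "calibrate_gamma0",
    "draw_event_time",
    "draw_visit_times",
    "generate_dataset",
    "Dataset",
]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)

DEFAULT_GAMMA = {
    "normal": (math.log(1.1), math.log(1.5)),
    "binary": (math.log(2.0), math.log(2.5)),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions; the defaults are the conditions of the main design."""

    scenario: str = "normal"  # "normal" | "binary"
    corr23: float = 0.0  # corr(X2, X3), 0 or 0.5
    beta: tuple = (math.log(2.0), math.log(1.5))  # event-model effects on (X1, X2)
    kappa: float = 1.25  # Weibull shape
    gamma: tuple | None = None  # visit effects on (X1, X3); scenario default if None
    eta: float = 1.0  # gap-time Gamma shape (1 = Poisson)
    mu_visits: float = 10.0  # mean post-baseline visits over (0, B)
    surv_time: float = 1.0  # marginal survival target: P(T > surv_time) = surv_prob
    surv_prob: float = 0.5
    B_cdf: float = 0.9  # administrative end: marginal P(T <= B)
    n_train: int = 500
    n_valid: int = 500
    nsim: int = 100
    seed: int | None = None

    def resolved_gamma(self) -> tuple:
        return self.gamma if self.gamma is not None else DEFAULT_GAMMA[self.scenario]

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("beta", "gamma"):
            if key in d and d[key] is not None:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)


@dataclass(frozen=True)
class Design:
    """A config with its calibrated quantities attached."""

    config: SimulationConfig
    lam: float
    B: float
    gamma0: float
    t0: float

    @property
    def event_params(self) -> WeibullPHParams:
        return WeibullPHParams(
            lam=self.lam, kappa=self.config.kappa, beta=np.array(self.config.beta)
        )


# ---------------------------------------------------------------------------
# Expectations over the covariate distribution
# ---------------------------------------------------------------------------


def _lp_expectation(fn, coefs, scenario: str) -> float:
    """E[fn(W)] for the linear predictor W of two independent covariates.

    In both scenarios the two covariates entering a given linear predictor
    (X1, X2 for the event model; X1, X3 for the visit model) are mutually
    independent, so W ~ N(0, c1^2 + c2^2) in the normal scenario and takes
    four equiprobable values in the binary one.
    """
    c1, c2 = coefs
    if scenario == "normal":
        sigma = math.hypot(c1, c2)
        vals = fn(math.sqrt(2.0) * sigma * _GH_NODES)
        return float(np.sum(_GH_WEIGHTS * vals) / math.sqrt(math.pi))
    if scenario == "binary":
        cells = np.array([0.0, c1, c2, c1 + c2])
        return float(np.mean(fn(cells)))
    raise ValueError(f"unknown scenario {scenario!r}")


def marginal_survival(t, lam, kappa, beta, scenario) -> float:
    """Marginal S(t) = E_X[S(t | X1, X2)]."""
    if t == 0:
        return 1.0
    return _lp_expectation(
        lambda w: np.exp(-((lam * t) ** kappa) * np.exp(w)), beta, scenario
    )


def calibrate_lambda(beta, kappa, scenario, corr23=0.0, t=1.0, p=0.5) -> float:
    """Rate lambda such that the marginal P(T > t) equals p.

    ``corr23`` is accepted for interface symmetry; the event model involves
    (X1, X2) which are independent in every scenario, so it does not enter.
    """

    def g(loglam):
        return marginal_survival(t, math.exp(loglam), kappa, beta, scenario) - p

    lo, hi = -20.0, 20.0
    return math.exp(optimize.brentq(g, lo, hi, xtol=1e-13))


def calibrate_B(lam, kappa, beta, scenario, corr23=0.0, q=0.9) -> float:
    """Administrative end B with marginal P(T <= B) = q."""

    def g(logB):
        return marginal_survival(math.exp(logB), lam, kappa, beta, scenario) - (1.0 - q)

    return math.exp(optimize.brentq(g, -20.0, 20.0, xtol=1e-13))


def expected_renewal_count(B, rate, eta, tol=1e-12, nmax=1000):
    """E N(B) for a renewal process with Gamma(eta, rate) gap times.

    N(B) counts renewals in (0, B]; E N(B) = sum_{n>=1} P(Gamma(n eta, rate) <= B),
    a rapidly converging series (for eta = 1 it sums to rate * B exactly).
    """
    rate = np.asarray(rate, dtype=float)
    total = np.zeros_like(rate)
    x = rate * B
    for n in range(1, nmax + 1):
        term = special.gammainc(n * eta, x)
        total += term
        if np.max(term) < tol:
            break
    return total if total.ndim else float(total)


def calibrate_gamma0(gamma, eta, B, scenario, corr23=0.0, mu=10.0) -> float:
    """Intercept gamma0 giving mean ``mu`` post-baseline visits over (0, B).

    Poisson case (eta = 1): closed form gamma0 = log(mu / B) - log E[e^W].
    Renewal case: deterministic root-finding on the exact expected renewal
    count averaged over the covariate distribution.
    """
    if eta == 1.0:
        m1 = _lp_expectation(np.exp, gamma, scenario)
        return math.log(mu / B) - math.log(m1)

    def g(g0):
        mean = _lp_expectation(
            lambda w: expected_renewal_count(B, np.exp(g0 + w), eta), gamma, scenario
        )
        return mean - mu

    center = math.log(mu * eta / B)
    return optimize.brentq(g, center - 6.0, center + 6.0, xtol=1e-12)


def resolve_design(config: SimulationConfig) -> Design:
    """Run all calibrations; the landmark t0 is the marginal median of T."""
    lam = calibrate_lambda(
        config.beta, config.kappa, config.scenario, config.corr23,
        t=config.surv_time, p=config.surv_prob,
    )
    B = calibrate_B(
        lam, config.kappa, config.beta, config.scenario, config.corr23, q=config.B_cdf
    )
    gamma0 = calibrate_gamma0(
        config.resolved_gamma(), config.eta, B, config.scenario, config.corr23,
        mu=config.mu_visits,
    )
    # with surv_prob = 0.5 the marginal median of T is surv_time by construction
    return Design(config=config, lam=lam, B=B, gamma0=gamma0, t0=config.surv_time)


# ---------------------------------------------------------------------------
# Random draws
# ---------------------------------------------------------------------------


def draw_covariates(scenario, corr23, n, rng) -> np.ndarray:
    """n x 3 covariate matrix under the stated scenario."""
    if not 0 <= corr23 < 1:
        raise ValueError("corr23 must lie in [0, 1)")
    if scenario == "normal":
        x1 = rng.standard_normal(n)
        z = rng.standard_normal((n, 2))
        x2 = z[:, 0]
        x3 = corr23 * z[:, 0] + math.sqrt(1.0 - corr23**2) * z[:, 1]
        return np.column_stack([x1, x2, x3])
    if scenario == "binary":
        x1 = (rng.uniform(size=n) < 0.5).astype(float)
        # dichotomise correlated Gaussians at 0: phi coefficient rho needs
        # latent (tetrachoric) correlation r = sin(pi rho / 2)
        r = math.sin(math.pi * corr23 / 2.0)
        z = rng.standard_normal((n, 2))
        z3 = r * z[:, 0] + math.sqrt(1.0 - r**2) * z[:, 1]
        return np.column_stack([x1, (z[:, 0] > 0).astype(float), (z3 > 0).astype(float)])
    raise ValueError(f"unknown scenario {scenario!r}")


def draw_event_time(X, lam, kappa, beta, rng) -> np.ndarray:
    """Inverse-CDF draw: T = (1/lambda) (-log U / e^{X'beta})^(1/kappa)."""
    params = WeibullPHParams(lam=lam, kappa=kappa, beta=np.asarray(beta))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    u = rng.uniform(size=X.shape[0])
    return params.inverse_survival(u, X)


def draw_visit_times(rates, eta, B, rng) -> list[np.ndarray]:
    """Per-subject visit times in (0, B]: cumulated Gamma(eta, rate) gaps.

    ``rates`` is the per-subject gap-time rate exp(gamma0 + X1 g1 + X3 g2);
    for eta = 1 this is a homogeneous Poisson process given X.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    n = len(rates)
    mean_count = float(np.max(expected_renewal_count(B, rates, eta))) if n else 0.0
    ncol = max(10, int(mean_count + 10.0 * math.sqrt(mean_count + 1.0) + 10))
    scale = 1.0 / rates  # gap ~ Gamma(shape=eta, scale=1/rate), mean eta/rate
    gaps = rng.gamma(eta, scale[:, None], size=(n, ncol))
    times = np.cumsum(gaps, axis=1)
    incomplete = times[:, -1] <= B
    while np.any(incomplete):
        idx = np.where(incomplete)[0]
        extra = rng.gamma(eta, np.repeat(scale[idx, None], ncol, axis=1))
        times[idx] = times[idx, -1][:, None] + np.cumsum(extra, axis=1)
        incomplete[idx] = times[idx, -1] <= B
    return [t[t <= B] for t in times]


class Dataset(NamedTuple):
    """A generated training/validation pair plus the latent event times."""

    train: list[SubjectRecord]
    valid: list[SubjectRecord]
    latent: pd.DataFrame  # columns: sample, id, T


def _make_sample(prefix, n, design: Design, rng) -> tuple[list[SubjectRecord], pd.DataFrame]:
    cfg = design.config
    X = draw_covariates(cfg.scenario, cfg.corr23, n, rng)
    T = draw_event_time(X[:, :2], design.lam, cfg.kappa, cfg.beta, rng)
    g1, g2 = cfg.resolved_gamma()
    rates = np.exp(design.gamma0 + X[:, 0] * g1 + X[:, 2] * g2)
    visit_lists = draw_visit_times(rates, cfg.eta, design.B, rng)
    width = len(str(n))
    subjects = []
    for i in range(n):
        visits = [VisitRecord(0.0, 0)]
        visits += [VisitRecord(float(a), int(T[i] <= a)) for a in visit_lists[i]]
        subjects.append(
            SubjectRecord(
                id=f"{prefix}{i + 1:0{width}d}",
                x=X[i],
                visits=visits,
                C=design.B,
                delta_dropout=0,
            )
        )
    latent = pd.DataFrame({"id": [s.id for s in subjects], "T": T})
    return subjects, latent


def generate_dataset(design: Design | SimulationConfig, seed=None) -> Dataset:
    """Generate a (training, validation) pair under ``design``.

    ``seed`` may be an int, a SeedSequence or a Generator.  Latent event
    times are returned only in the side-channel frame, never encoded in the
    subject records.
    """
    if isinstance(design, SimulationConfig):
        design = resolve_design(design)
    rng = np.random.default_rng(seed)
    train, lat_tr = _make_sample("tr", design.config.n_train, design, rng)
    valid, lat_va = _make_sample("va", design.config.n_valid, design, rng)
    lat_tr.insert(0, "sample", "train")
    lat_va.insert(0, "sample", "valid")
    return Dataset(train=train, valid=valid, latent=pd.concat([lat_tr, lat_va], ignore_index=True))
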