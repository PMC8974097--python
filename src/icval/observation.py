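"""Models for the recurrent assessment process and loss to follow-up.

The probability that a subject can be definitively classified at the
landmark depends on how often they are seen and for how long, so the weight
integrals need fitted intensity models for

* the assessment (visit) counting process, with multiplicative intensity
  ``lambda_a(s | X) = rho0(s) * exp(X' gamma)`` -- either a
  time-homogeneous Poisson model (constant baseline, fitted as a Poisson
  log-linear model with offset log C) or a semiparametric Andersen-Gill
  model (unspecified step baseline, Breslow estimate); and
* the loss-to-follow-up time R, a parametric Weibull PH model on (C, delta),
  or the trivial "no drop-out" model when every subject runs to the
  administrative end B.

Visit-model fitting uses all visits up to C regardless of event status: the
intensities considered here depend on covariates and time only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import SubjectRecord
from .event import WeibullPHParams

__all__ = [
    "PoissonVisitModel",
    "StepBaselineVisitModel",
    "DropoutModel",
    "fit_th_poisson",
    "fit_ag",
    "fit_dropout",
    "visit_intensity",
    "cumulative_visit_intensity",
]


@dataclass
class PoissonVisitModel:
    """Time-homogeneous Poisson visit intensity exp(gamma0 + X'gamma)."""

    gamma0: float
    gamma: np.ndarray
    bse: np.ndarray | None = None  # (gamma0, gamma) standard errors
    llf: float | None = None
    covariate_indices: tuple | None = None

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))

    def rate(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if len(self.gamma) == 0:
            return np.full(max(X.shape[0], 1), math.exp(self.gamma0))
        if self.covariate_indices is not None and X.shape[1] != len(self.gamma):
            X = X[:, list(self.covariate_indices)]
        return np.exp(self.gamma0 + X @ self.gamma)

    def intensity(self, s, X) -> np.ndarray:
        return self.rate(X) * np.ones_like(np.asarray(s, dtype=float))

    def cumulative(self, s1, s2, X) -> np.ndarray:
        if np.any(np.asarray(s2) < np.asarray(s1)):
            raise ValueError("need s1 <= s2")
        return (np.asarray(s2, dtype=float) - np.asarray(s1, dtype=float)) * self.rate(X)

    def summary(self) -> str:
        names = ["gamma0"] + [f"gamma_{j + 1}" for j in range(len(self.gamma))]
        est = np.r_[self.gamma0, self.gamma]
        se = self.bse if self.bse is not None else np.full(len(est), np.nan)
        df = pd.DataFrame({"estimate": est, "std_err": se}, index=names)
        return "Time-homogeneous Poisson visit model\n" + df.to_string(
            float_format=lambda v: f"{v: .4f}"
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "th_poisson",
                "gamma0": self.gamma0,
                "gamma": self.gamma.tolist(),
            }
        )


@dataclass
class StepBaselineVisitModel:
    """Andersen-Gill visit model: step cumulative baseline + exp(X'gamma).

    ``baseline_times`` / ``baseline_increments`` are the Breslow jumps of the
    cumulative baseline intensity at the observed visit times; the cumulative
    intensity over (s1, s2] for a subject is the sum of increments in that
    window times exp(X'gamma).
    """

    gamma: np.ndarray
    baseline_times: np.ndarray
    baseline_increments: np.ndarray
    bse: np.ndarray | None = None
    covariate_indices: tuple | None = None

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.baseline_times = np.asarray(self.baseline_times, dtype=float)
        self.baseline_increments = np.asarray(self.baseline_increments, dtype=float)
        if np.any(np.diff(self.baseline_times) <= 0):
            raise ValueError("baseline jump times must be strictly increasing")
        if np.any(self.baseline_increments < 0):
            raise ValueError("baseline increments must be nonnegative")

    def multiplier(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if len(self.gamma) == 0:
            return np.ones(max(X.shape[0], 1))
        if self.covariate_indices is not None and X.shape[1] != len(self.gamma):
            X = X[:, list(self.covariate_indices)]
        return np.exp(X @ self.gamma)

    def intensity(self, s, X) -> np.ndarray:
        # pure-jump baseline: the absolutely continuous part is 0 a.e.
        return np.zeros_like(np.asarray(s, dtype=float)) * self.multiplier(X)

    def cumulative_baseline(self, s) -> np.ndarray:
        """Lambda0(s) = sum of increments at jump times <= s."""
        idx = np.searchsorted(self.baseline_times, np.asarray(s, dtype=float), "right")
        csum = np.r_[0.0, np.cumsum(self.baseline_increments)]
        return csum[idx]

    def cumulative(self, s1, s2, X) -> np.ndarray:
        if np.any(np.asarray(s2) < np.asarray(s1)):
            raise ValueError("need s1 <= s2")
        return (self.cumulative_baseline(s2) - self.cumulative_baseline(s1)) * self.multiplier(X)

    def jumps_in(self, s1, s2) -> tuple[np.ndarray, np.ndarray]:
        """Jump times and increments in (s1, s2]."""
        i = np.searchsorted(self.baseline_times, s1, "right")
        j = np.searchsorted(self.baseline_times, s2, "right")
        return self.baseline_times[i:j], self.baseline_increments[i:j]

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "andersen_gill",
                "gamma": self.gamma.tolist(),
                "baseline_times": self.baseline_times.tolist(),
                "baseline_increments": self.baseline_increments.tolist(),
            }
        )


@dataclass
class DropoutModel:
    """Loss-to-follow-up hazard: Weibull PH on covariates, or none.

    ``params is None`` encodes administrative censoring only
    (lambda_c identically 0).
    """

    params: WeibullPHParams | None = None
    covariate_indices: tuple | None = None
    note: str = ""

    @property
    def is_none(self) -> bool:
        return self.params is None

    def _x(self, X):
        X = np.atleast_1d(np.asarray(X, dtype=float))
        if self.covariate_indices is not None:
            X = X[list(self.covariate_indices)]
        return X

    def hazard(self, s, X) -> np.ndarray:
        if self.is_none:
            return np.zeros_like(np.asarray(s, dtype=float))
        return self.params.hazard(s, self._x(X))

    def cumulative_hazard(self, s, X) -> np.ndarray:
        if self.is_none:
            return np.zeros_like(np.asarray(s, dtype=float))
        return self.params.cumulative_hazard(s, self._x(X))

    def survival(self, s, X) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(s, X))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _design(sample: list[SubjectRecord], covariate_indices) -> np.ndarray:
    X = np.array([s.x for s in sample], dtype=float)
    if covariate_indices is not None:
        X = X[:, list(covariate_indices)]
    return X


def fit_th_poisson(
    sample: list[SubjectRecord], covariate_indices=None
) -> PoissonVisitModel:
    """Fit the time-homogeneous Poisson visit model.

    The post-baseline visit count m_i over exposure (0, C_i] is Poisson with
    mean C_i * exp(gamma0 + X_i' gamma); the MLE is a Poisson GLM with
    offset log C_i.
    """
    counts = np.array([s.n_post_baseline for s in sample], dtype=float)
    expo = np.array([s.C for s in sample], dtype=float)
    if counts.sum() == 0:
        raise RuntimeError("no post-baseline visits: visit rate not identifiable")
    X = _design(sample, covariate_indices)
    exog = sm.add_constant(X, has_constant="add")
    res = sm.GLM(
        counts, exog, family=sm.families.Poisson(), offset=np.log(expo)
    ).fit()
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(f"Poisson visit fit failed: params={res.params}")
    return PoissonVisitModel(
        gamma0=float(res.params[0]),
        gamma=res.params[1:],
        bse=np.asarray(res.bse),
        llf=float(res.llf),
        covariate_indices=tuple(covariate_indices) if covariate_indices is not None else None,
    )


def fit_ag(
    sample: list[SubjectRecord], covariate_indices=None
) -> StepBaselineVisitModel:
    """Fit the semiparametric Andersen-Gill visit model on calendar time.

    gamma is estimated by the Cox partial likelihood with each post-baseline
    visit as a recurrent event and at-risk indicator I(s <= C_i)
    (via lifelines' CoxTimeVaryingFitter); the cumulative baseline is the
    Breslow estimator dLambda0(u) = (# visits at u) / sum_{j at risk} e^{X_j'gamma}.
    """
    from lifelines import CoxTimeVaryingFitter

    X = _design(sample, covariate_indices)
    q = X.shape[1]
    rows = []
    for i, s in enumerate(sample):
        times = [v.time for v in s.visits[1:]]
        prev = 0.0
        for t in times:
            rows.append((i, prev, t, 1, *X[i]))
            prev = t
        if prev < s.C:
            rows.append((i, prev, s.C, 0, *X[i]))
    df = pd.DataFrame(
        rows, columns=["id", "start", "stop", "event", *[f"x{j}" for j in range(q)]]
    )
    if df["event"].sum() == 0:
        raise RuntimeError("no post-baseline visits: visit model not identifiable")
    if q > 0:
        ctv = CoxTimeVaryingFitter(penalizer=0.0)
        ctv.fit(df, id_col="id", event_col="event", start_col="start", stop_col="stop")
        gamma = ctv.params_.to_numpy()
        bse = ctv.standard_errors_.to_numpy()
    else:
        gamma = np.zeros(0)
        bse = np.zeros(0)

    # Breslow baseline increments at distinct visit times
    event_times = np.sort(df.loc[df["event"] == 1, "stop"].to_numpy())
    uniq, counts = np.unique(event_times, return_counts=True)
    C = np.array([s.C for s in sample], dtype=float)
    mult = np.exp(X @ gamma) if q else np.ones(len(sample))
    # risk set at u: subjects with C_i >= u (all subjects enter at 0)
    order = np.argsort(C)
    C_sorted = C[order]
    mult_sorted = mult[order]
    suffix = np.r_[np.cumsum(mult_sorted[::-1])[::-1], 0.0]
    risk = suffix[np.searchsorted(C_sorted, uniq, "left")]
    increments = counts / risk
    return StepBaselineVisitModel(
        gamma=gamma,
        baseline_times=uniq,
        baseline_increments=increments,
        bse=bse,
        covariate_indices=tuple(covariate_indices) if covariate_indices is not None else None,
    )


def fit_dropout(sample: list[SubjectRecord], covariate_indices=None) -> DropoutModel:
    """Fit a Weibull PH model for the loss-to-follow-up time R.

    Treats administrative ends (delta = 0) as right-censored at C = B.
    Returns the "none" model (lambda_c = 0) when no drop-outs occurred.
    """
    delta = np.array([s.delta_dropout for s in sample], dtype=int)
    C = np.array([s.C for s in sample], dtype=float)
    if delta.sum() == 0:
        return DropoutModel(None, note="no drop-outs observed; lambda_c = 0")
    B = C[delta == 0].max() if np.any(delta == 0) else np.inf
    if np.any(C[delta == 1] >= B):
        raise ValueError("drop-out recorded at or after the administrative end B")
    from lifelines import WeibullAFTFitter

    X = _design(sample, covariate_indices)
    q = X.shape[1]
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(q)])
    df["duration"] = C
    df["observed"] = delta
    aft = WeibullAFTFitter()
    aft.fit(df, duration_col="duration", event_col="observed")
    # AFT: S(t|X) = exp{-(t / exp(b0 + X'b))^rho}; PH: lam = e^{-b0},
    # kappa = rho, beta = -rho * b.
    lam_params = aft.params_["lambda_"]
    b0 = float(lam_params["Intercept"])
    b = np.array([lam_params.get(f"x{j}", 0.0) for j in range(q)])
    rho = float(np.exp(aft.params_["rho_"]["Intercept"]))
    params = WeibullPHParams(lam=float(np.exp(-b0)), kappa=rho, beta=-rho * b)
    return DropoutModel(params, covariate_indices=covariate_indices)


# ---------------------------------------------------------------------------
# Intensity evaluation helpers (functional interface)
# ---------------------------------------------------------------------------


def visit_intensity(s, X, model) -> np.ndarray:
    """Pointwise visit intensity lambda_a(s | X)."""
    return model.intensity(s, X) if hasattr(model, "intensity") else model.rate(X)


def cumulative_visit_intensity(s1, s2, X, model) -> np.ndarray:
    """Integrated visit intensity over (s1, s2]."""
    return model.cumulative(s1, s2, X)
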