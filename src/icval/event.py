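"""Weibull proportional-hazards event-time model for interval-censored data.

The event time T given a covariate vector X follows

    S(t | X) = exp{ -(lambda * t)^kappa * exp(X' beta) },

i.e. a Weibull baseline hazard h0(t) = kappa * lambda^kappa * t^(kappa-1)
multiplied by exp(X' beta).  ``lambda`` is a rate (1/time), ``kappa`` the
shape, ``beta`` log hazard ratios.

Fitting uses the interval-censored likelihood: a subject whose event is known
only to lie in (a-, a+] contributes S(a- | X) - S(a+ | X) (with S(+inf) = 0
for right-censored subjects).  This is the partial likelihood that is valid
when the visit process is conditionally independent of the event process
given X.  Optimisation is on the unconstrained scale
(log lambda, log kappa, beta) with multiple starts.

The model class/results pair follows the statsmodels idiom:
``WeibullPH(left, right, X).fit()`` returns :class:`WeibullPHResults` with
parameter estimates, standard errors, a ``summary()`` table and the
predictive quantities needed downstream (survival probabilities, conditional
probabilities given a censoring interval, conditional densities given
failure by a landmark).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess1

from .data import SubjectRecord, censoring_interval

__all__ = [
    "WeibullPHParams",
    "WeibullPH",
    "WeibullPHResults",
    "FitError",
    "survival",
    "hazard",
    "fit_interval_censored",
    "predict_binary",
    "interval_conditional_survival",
    "conditional_density_given_failure",
]

_PROB_FLOOR = 1e-12  # floor applied before forming conditional ratios


def _scalar(x) -> float:
    """First element of a size-1 array as a Python float."""
    return float(np.asarray(x).reshape(-1)[0])


class FitError(RuntimeError):
    """Maximum likelihood estimation failed; message carries diagnostics."""


@dataclass
class WeibullPHParams:
    """Parameter container; also the 'true model' object used in simulation.

    ``covariate_indices``, when set, records which columns of a wider
    covariate matrix the model was fitted on; vectors of the full width are
    sliced automatically.
    """

    lam: float
    kappa: float
    beta: np.ndarray
    covariate_indices: tuple | None = None

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("lambda and kappa must be positive")

    # -- basic quantities ---------------------------------------------------
    def linear_predictor(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if len(self.beta) == 0:
            return np.zeros(max(X.shape[0], 1))
        if self.covariate_indices is not None and X.shape[1] != len(self.beta):
            X = X[:, list(self.covariate_indices)]
        return X @ self.beta

    def cumulative_hazard(self, t, X) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be nonnegative")
        return np.where(
            t > 0, (self.lam * t) ** self.kappa * np.exp(self.linear_predictor(X)), 0.0
        )

    def survival(self, t, X) -> np.ndarray:
        """S(t | X) = exp{-(lambda t)^kappa e^{X'beta}}."""
        return np.exp(-self.cumulative_hazard(t, X))

    def hazard(self, t, X) -> np.ndarray:
        """h(t | X) = kappa lambda^kappa t^(kappa-1) e^{X'beta}."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or (self.kappa < 1 and np.any(t == 0)):
            raise ValueError("hazard requires t > 0 (t >= 0 when kappa >= 1)")
        return (
            self.kappa
            * self.lam**self.kappa
            * t ** (self.kappa - 1.0)
            * np.exp(self.linear_predictor(X))
        )

    def density(self, t, X) -> np.ndarray:
        return self.hazard(t, X) * self.survival(t, X)

    def inverse_survival(self, s, X) -> np.ndarray:
        """t such that S(t | X) = s; used for inverse-CDF sampling."""
        s = np.asarray(s, dtype=float)
        return (-np.log(s) / np.exp(self.linear_predictor(X))) ** (
            1.0 / self.kappa
        ) / self.lam

    def to_json(self) -> str:
        return json.dumps(
            {
                "lam": self.lam,
                "kappa": self.kappa,
                "beta": self.beta.tolist(),
                "covariate_indices": list(self.covariate_indices)
                if self.covariate_indices is not None
                else None,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "WeibullPHParams":
        d = json.loads(text)
        idx = d.get("covariate_indices")
        return cls(
            d["lam"],
            d["kappa"],
            np.asarray(d["beta"]),
            covariate_indices=tuple(idx) if idx is not None else None,
        )


def _as_params(model) -> WeibullPHParams:
    if isinstance(model, WeibullPHParams):
        return model
    if isinstance(model, WeibullPHResults):
        return model.params_struct
    raise TypeError(f"expected WeibullPHParams or WeibullPHResults, got {type(model)}")


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class WeibullPH:
    """Interval-censored Weibull PH model, built from (a-, a+] intervals.

    Parameters
    ----------
    left, right : array-like
        Censoring interval endpoints; ``right`` may be ``inf`` for
        right-censored subjects.  Exact event times can be encoded as
        arbitrarily tight intervals.
    X : array-like, shape (n, q)
        Covariates.
    """

    def __init__(self, left, right, X, covariate_indices=None):
        self.covariate_indices = (
            tuple(covariate_indices) if covariate_indices is not None else None
        )
        self.left = np.asarray(left, dtype=float)
        self.right = np.asarray(right, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(self.left)
        if len(self.right) != n or self.X.shape[0] != n:
            raise ValueError("left, right and X must have the same length")
        if np.any(self.left < 0) or np.any(self.right <= self.left):
            raise ValueError("intervals must satisfy 0 <= a- < a+")
        self.nobs = n
        self.q = self.X.shape[1]
        if n < self.q + 2:
            raise ValueError(f"need at least q+2={self.q + 2} subjects, got {n}")
        if not np.any(np.isfinite(self.right)):
            raise FitError("all subjects right-censored: no information on T")
        self.degenerate = bool(
            np.all(self.left == self.left[0]) and np.all(self.right == self.right[0])
        )

    @classmethod
    def from_sample(
        cls, sample: list[SubjectRecord], covariate_indices=None
    ) -> "WeibullPH":
        """Build from subject records, deriving (a-, a+] from visit histories."""
        lows, highs, xs = [], [], []
        for s in sample:
            a_minus, a_plus = censoring_interval(s)
            x = s.x if covariate_indices is None else s.x[list(covariate_indices)]
            lows.append(a_minus)
            highs.append(a_plus)
            xs.append(x)
        lo = np.array(lows)
        hi = np.array(highs)
        # subjects never reassessed after baseline carry no information
        # (their interval (0, inf) has likelihood 1) and are dropped;
        # a- = 0 with finite a+ is a valid left endpoint (event in (0, a+]).
        keep = ~((lo == 0) & ~np.isfinite(hi))
        if not np.all(keep):
            lo, hi = lo[keep], hi[keep]
            xs = [x for x, k in zip(xs, keep) if k]
        return cls(lo, hi, np.array(xs), covariate_indices=covariate_indices)

    # -- likelihood ---------------------------------------------------------
    def loglike(self, params: np.ndarray) -> float:
        """Log-likelihood at params = (log lambda, log kappa, beta)."""
        return -self._nll(params)

    def _nll(self, params: np.ndarray) -> float:
        loglam, logkap = params[0], params[1]
        beta = params[2:]
        kap = np.exp(logkap)
        eta = self.X @ beta

        def cumhaz(t, eta_sub):
            out = np.zeros_like(t)
            pos = t > 0
            out[pos] = np.exp(kap * (loglam + np.log(t[pos])) + eta_sub[pos])
            return out

        Hl = cumhaz(self.left, eta)
        finite = np.isfinite(self.right)
        ll = np.empty(self.nobs)
        # right-censored: log S(a-)
        ll[~finite] = -Hl[~finite]
        # interval: log(S(a-) - S(a+)) = -Hl + log(1 - exp(-(Hr - Hl)))
        Hr = cumhaz(self.right[finite], eta[finite])
        d = Hr - Hl[finite]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll[finite] = -Hl[finite] + np.log(-np.expm1(-np.maximum(d, 1e-300)))
        if not np.all(np.isfinite(ll)):
            return 1e100
        return -float(np.sum(ll))

    def _start_values(self) -> np.ndarray:
        finite = np.isfinite(self.right)
        if finite.any():
            mids = 0.5 * (self.left[finite] + self.right[finite])
            scale = max(float(np.median(mids)), 1e-3)
        else:  # pragma: no cover - guarded in __init__
            scale = 1.0
        return np.r_[-math.log(scale), 0.0, np.zeros(self.q)]

    def fit(self, start=None, maxiter=500, n_restarts=3) -> "WeibullPHResults":
        """Maximise the interval-censored likelihood.

        Multi-start BFGS on the unconstrained scale with a Nelder-Mead
        fallback; raises :class:`FitError` with the optimiser trace on
        failure.
        """
        if self.degenerate:
            raise FitError("degenerate data: all censoring intervals identical")
        x0 = np.asarray(start, dtype=float) if start is not None else self._start_values()
        rng = np.random.default_rng(0)
        best = None
        trace = []
        for attempt in range(n_restarts):
            xa = x0 if attempt == 0 else x0 + rng.normal(scale=0.3, size=x0.shape)
            res = optimize.minimize(
                self._nll, xa, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-6}
            )
            trace.append(f"start {attempt}: fun={res.fun:.6f} success={res.success}")
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if res.success:
                break
        if best is None or not np.isfinite(best.fun):
            raise FitError("optimization failed:\n" + "\n".join(trace))
        if not best.success:
            prev_fun = best.fun
            res = optimize.minimize(
                self._nll,
                best.x,
                method="Nelder-Mead",
                options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-9},
            )
            trace.append(f"nelder-mead polish: fun={res.fun:.6f} success={res.success}")
            if res.fun <= best.fun:
                best = res
            # the polish moving the objective by a negligible amount means the
            # earlier iterate was already at the optimum up to float noise
            improvement = prev_fun - best.fun
            if not res.success and improvement > 1e-6 * (1.0 + abs(best.fun)):
                raise FitError("non-convergence:\n" + "\n".join(trace))
        # observed information on the working scale
        try:
            hess = approx_hess1(best.x, self._nll)
            cov = np.linalg.inv(hess)
            bse = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            cov = np.full((len(best.x), len(best.x)), np.nan)
            bse = np.full(len(best.x), np.nan)
        return WeibullPHResults(
            model=self,
            params=best.x,
            cov_params=cov,
            bse=bse,
            llf=-best.fun,
            converged=True,
            trace=trace,
        )


@dataclass
class WeibullPHResults:
    """MLE results; parameters on the working scale (log lam, log kappa, beta)."""

    model: WeibullPH
    params: np.ndarray
    cov_params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    trace: list[str] = field(default_factory=list)

    @property
    def params_struct(self) -> WeibullPHParams:
        return WeibullPHParams(
            lam=float(np.exp(self.params[0])),
            kappa=float(np.exp(self.params[1])),
            beta=self.params[2:].copy(),
            covariate_indices=self.model.covariate_indices,
        )

    @property
    def lam(self) -> float:
        return float(np.exp(self.params[0]))

    @property
    def kappa(self) -> float:
        return float(np.exp(self.params[1]))

    @property
    def beta(self) -> np.ndarray:
        return self.params[2:]

    def survival(self, t, X):
        return self.params_struct.survival(t, X)

    def hazard(self, t, X):
        return self.params_struct.hazard(t, X)

    def param_names(self) -> list[str]:
        return ["log_lambda", "log_kappa"] + [
            f"beta_{j + 1}" for j in range(self.model.q)
        ]

    def summary(self) -> str:
        df = pd.DataFrame(
            {
                "estimate": self.params,
                "std_err": self.bse,
                "z": self.params / self.bse,
            },
            index=self.param_names(),
        )
        lines = [
            "Weibull PH model, interval-censored MLE",
            f"n = {self.model.nobs}, log-likelihood = {self.llf:.4f}",
            df.to_string(float_format=lambda v: f"{v: .4f}"),
            f"lambda = {self.lam:.4f}, kappa = {self.kappa:.4f}",
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "param_names": self.param_names(),
                "params": self.params.tolist(),
                "bse": self.bse.tolist(),
                "llf": self.llf,
                "converged": self.converged,
                "nobs": self.model.nobs,
            }
        )


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------


def survival(t, X, model) -> float | np.ndarray:
    """S(t | X) under ``model`` (WeibullPHParams or WeibullPHResults)."""
    out = _as_params(model).survival(t, X)
    return _scalar(out) if out.size == 1 else out


def hazard(t, X, model) -> float | np.ndarray:
    out = _as_params(model).hazard(t, X)
    return _scalar(out) if out.size == 1 else out


def fit_interval_censored(training, covariate_indices=None) -> WeibullPHResults:
    """Fit the Weibull PH model to interval-censored training data.

    ``training`` may be a list of :class:`SubjectRecord` (intervals derived
    from visit histories) or a tuple ``(left, right, X)``.
    """
    if isinstance(training, tuple):
        model = WeibullPH(*training)
    else:
        model = WeibullPH.from_sample(training, covariate_indices)
    return model.fit()


def predict_binary(X, model, t0: float, c: float = 0.5):
    """I(S(t0 | X) > c): the optimal binary predictor of Y at threshold c."""
    if not 0 < c < 1:
        raise ValueError("threshold c must lie in (0,1)")
    return (np.asarray(_as_params(model).survival(t0, X)) > c).astype(int)


def interval_conditional_survival(t0, a_minus, a_plus, X, model) -> float:
    """P(T > t0 | T in (a-, a+], X).

    Equals 0 when a+ <= t0 and 1 when a- >= t0; otherwise the ratio
    [S(max(t0, a-)) - S(a+)] / [S(a-) - S(a+)], clipped to [0, 1].
    """
    if not a_minus < a_plus:
        raise ValueError("need a- < a+")
    if a_plus <= t0:
        return 0.0
    if a_minus >= t0:
        return 1.0
    p = _as_params(model)
    s_lo = _scalar(p.survival(a_minus, X))
    s_hi = 0.0 if not math.isfinite(a_plus) else _scalar(p.survival(a_plus, X))
    denom = s_lo - s_hi
    if denom < _PROB_FLOOR:
        raise ValueError(
            f"interval ({a_minus}, {a_plus}] has probability {denom:g} under the model"
        )
    num = _scalar(p.survival(max(t0, a_minus), X)) - s_hi
    return float(np.clip(num / denom, 0.0, 1.0))


def conditional_density_given_failure(t, t0, X, model) -> float:
    """f(t | T <= t0, X) = f(t | X) / P(T <= t0 | X), for 0 < t <= t0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr > t0) or np.any(t_arr <= 0):
        raise ValueError("need 0 < t <= t0")
    p = _as_params(model)
    denom = 1.0 - _scalar(p.survival(t0, X))
    if denom < _PROB_FLOOR:
        raise ValueError("P(T <= t0 | X) is numerically zero")
    out = p.density(t_arr, X) / denom
    return _scalar(out) if out.size == 1 else out
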