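"""Classification probabilities pi = P(delta = 1 | Y, X) for IPW weighting.

A subject can be definitively classified at the landmark t0 only if the
visit process happened to reveal Y = I(T > t0).  Restricting estimation to
classified subjects therefore induces selection that depends on the event,
visit and drop-out processes jointly; the inverse-probability weights
1 / pi undo it.  Conditioning on (Y, X):

* ``Y = 0`` (failed by t0): classification requires a post-event visit in
  (T, t0] before loss to follow-up.  Averaging over the conditional failure
  density f(t | T <= t0, X),

      pi0 = int_0^t0  P(visit in (t, t0], no drop-out) f(t | T <= t0, X) dt.

* ``Y = 1`` (event-free at t0): classification requires the first visit
  after t0 to occur before the event, before drop-out and by the
  administrative end B:

      pi1 = int_t0^B lam_a(u) exp{-int_t0^u (lam_a + h) dv
                                   - int_0^u lam_c dv} du.

For a constant visit rate the inner quantities are closed-form; otherwise
adaptive quadrature is used.  For the Andersen-Gill step baseline the
integrals are evaluated exactly as piecewise sums between jump times: with
a pure-jump cumulative intensity Lambda, P(no visit in (s1, s2]) =
exp{-e^{X'gamma}(Lambda(s2) - Lambda(s1))} and a visit occurs at jump u_k
with probability 1 - exp{-e^{X'gamma} dLambda_k}.

A brute-force Monte-Carlo oracle (:func:`pi_monte_carlo`) simulates the
whole observation scheme and is used to validate the quadrature paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate

from .data import SubjectRecord, classify_at_landmark
from .event import _as_params, _scalar
from .observation import DropoutModel, PoissonVisitModel, StepBaselineVisitModel

__all__ = [
    "WeightResult",
    "pi_failed",
    "pi_survived",
    "compute_weights",
    "pi_monte_carlo",
    "weights_to_frame",
]

_QUAD_KW = dict(epsabs=1e-10, epsrel=1e-9, limit=200)


@dataclass(frozen=True)
class WeightResult:
    """Estimated classification probability for one delta = 1 subject."""

    id: str
    pi: float  # truncated value actually used in the estimators
    pi_raw: float
    y: int
    method: str
    truncated: bool


def _dropout_surv(dropout_model, u, X):
    if dropout_model is None or dropout_model.is_none:
        return np.ones_like(np.asarray(u, dtype=float))
    return dropout_model.survival(u, X)


def pi_failed(X, t0, event_model, visit_model, dropout_model=None) -> float:
    """P(delta = 1 | Y = 0, X): a post-event visit occurs in (T, t0]."""
    ev = _as_params(event_model)
    X = np.atleast_1d(np.asarray(X, dtype=float))
    F0 = 1.0 - _scalar(ev.survival(t0, X))
    if F0 <= 0:
        raise ValueError("P(T <= t0 | X) = 0: pi_failed undefined")

    if isinstance(visit_model, PoissonVisitModel):
        a = _scalar(visit_model.rate(X))
        if dropout_model is None or dropout_model.is_none:
            # inner integral in closed form: 1 - exp(-a (t0 - t))
            def integrand(t):
                return (-np.expm1(-a * (t0 - t))) * ev.density(t, X)

        else:
            def inner(t):
                val, _ = integrate.quad(
                    lambda u: a
                    * math.exp(-a * (u - t))
                    * _scalar(_dropout_surv(dropout_model, u, X)),
                    t,
                    t0,
                    epsabs=1e-10,
                    epsrel=1e-9,
                )
                return val

            def integrand(t):
                t = np.atleast_1d(t)
                return np.array([inner(ti) for ti in t]) * ev.density(t, X)

        val, err = integrate.quad(
            lambda t: float(np.asarray(integrand(t)).ravel()[0]), 0.0, t0, **_QUAD_KW
        )
        if not np.isfinite(val):
            raise RuntimeError(f"quadrature failed for pi_failed (err={err})")
        return min(val / F0, 1.0)

    if isinstance(visit_model, StepBaselineVisitModel):
        if dropout_model is not None and not dropout_model.is_none:
            raise NotImplementedError(
                "step-baseline weights with drop-out are not implemented"
            )
        g = _scalar(visit_model.multiplier(X))
        jumps, sizes = visit_model.jumps_in(0.0, t0)
        # segment endpoints 0 = v_0 < u_1 < ... < u_m <= t0
        knots = np.r_[0.0, jumps, t0]
        knots = np.unique(knots)
        Lam_t0 = _scalar(visit_model.cumulative_baseline(t0))
        Lam_at = visit_model.cumulative_baseline(knots[:-1])
        # on (v_j, v_{j+1}): P(visit in (t, t0]) = 1 - exp(-g (Lam(t0) - Lam(v_j+)))
        probs = -np.expm1(-g * (Lam_t0 - Lam_at))
        S = ev.survival(knots, X)
        seg_mass = S[:-1] - S[1:]  # P(T in (v_j, v_{j+1}] | X)
        return float(min(np.sum(probs * seg_mass) / F0, 1.0))

    raise TypeError(f"unsupported visit model {type(visit_model)}")


def pi_survived(X, t0, B, event_model, visit_model, dropout_model=None) -> float:
    """P(delta = 1 | Y = 1, X): first visit after t0 precedes T, drop-out, B."""
    ev = _as_params(event_model)
    X = np.atleast_1d(np.asarray(X, dtype=float))
    if B <= t0:
        return 0.0
    S_t0 = _scalar(ev.survival(t0, X))

    if isinstance(visit_model, PoissonVisitModel):
        a = _scalar(visit_model.rate(X))

        def integrand(u):
            return (
                a
                * math.exp(-a * (u - t0))
                * _scalar(ev.survival(u, X)) / S_t0
                * _scalar(_dropout_surv(dropout_model, u, X))
            )

        val, err = integrate.quad(integrand, t0, B, **_QUAD_KW)
        if not np.isfinite(val):
            raise RuntimeError(f"quadrature failed for pi_survived (err={err})")
        return min(val, 1.0)

    if isinstance(visit_model, StepBaselineVisitModel):
        if dropout_model is not None and not dropout_model.is_none:
            raise NotImplementedError(
                "step-baseline weights with drop-out are not implemented"
            )
        g = _scalar(visit_model.multiplier(X))
        jumps, sizes = visit_model.jumps_in(t0, B)
        if len(jumps) == 0:
            return 0.0
        Lam_t0 = _scalar(visit_model.cumulative_baseline(t0))
        Lam_before = visit_model.cumulative_baseline(jumps) - sizes  # Lambda(u_k^-)
        no_visit = np.exp(-g * (Lam_before - Lam_t0))
        p_visit = -np.expm1(-g * sizes)
        surv = ev.survival(jumps, X) / S_t0
        return float(min(np.sum(no_visit * p_visit * surv), 1.0))

    raise TypeError(f"unsupported visit model {type(visit_model)}")


def compute_weights(
    sample: list[SubjectRecord],
    t0: float,
    B: float,
    event_model,
    visit_model,
    dropout_model: DropoutModel | None = None,
    eps: float = 0.01,
    method: str | None = None,
) -> list[WeightResult]:
    """Estimate pi for every classified (delta = 1) subject in ``sample``.

    Probabilities below the floor ``eps`` are truncated (flagged in the
    result) to guard against unstable weights; delta = 0 subjects receive no
    entry.
    """
    if method is None:
        method = (
            "th" if isinstance(visit_model, PoissonVisitModel) else "ag"
        ) + ("" if dropout_model is None or dropout_model.is_none else "+dropout")
    out = []
    for s in sample:
        cls = classify_at_landmark(s, t0)
        if cls.delta == 0:
            continue
        if cls.y == 0:
            raw = pi_failed(s.x, t0, event_model, visit_model, dropout_model)
        else:
            raw = pi_survived(s.x, t0, B, event_model, visit_model, dropout_model)
        truncated = raw < eps
        out.append(
            WeightResult(
                id=s.id,
                pi=max(raw, eps),
                pi_raw=raw,
                y=cls.y,
                method=method,
                truncated=truncated,
            )
        )
    return out


def weights_to_frame(weights: list[WeightResult]) -> pd.DataFrame:
    """Audit table (id, y, pi, truncated)."""
    return pd.DataFrame(
        {
            "id": [w.id for w in weights],
            "y": [w.y for w in weights],
            "pi": [w.pi for w in weights],
            "truncated": [w.truncated for w in weights],
        }
    )


def pi_monte_carlo(
    X,
    y: int,
    t0: float,
    B: float,
    event_model,
    visit_model,
    dropout_model: DropoutModel | None = None,
    nrep: int = 100_000,
    seed=0,
) -> tuple[float, float]:
    """Brute-force simulation estimate of pi = P(delta = 1 | Y = y, X).

    Draws T from its conditional distribution given the Y-constraint, a full
    homogeneous Poisson visit sequence on (0, C] and (optionally) a drop-out
    time, then classifies exactly as :func:`~icval.data.classify_at_landmark`
    does.  Returns (estimate, Monte-Carlo standard error).
    """
    if nrep < 1_000:
        raise ValueError("nrep >= 1000 required for a meaningful oracle")
    if not isinstance(visit_model, PoissonVisitModel):
        raise NotImplementedError("Monte-Carlo oracle supports the Poisson visit model")
    rng = np.random.default_rng(seed)
    ev = _as_params(event_model)
    X = np.atleast_1d(np.asarray(X, dtype=float))
    S_t0 = _scalar(ev.survival(t0, X))
    # T | Y: S(T) uniform on (S_t0, 1) when T <= t0, on (0, S_t0) when T > t0
    if y == 0:
        u = rng.uniform(S_t0, 1.0, size=nrep)
    elif y == 1:
        if S_t0 <= 0:
            raise ValueError("P(T > t0 | X) = 0: conditioning impossible")
        u = rng.uniform(0.0, S_t0, size=nrep)
    else:
        raise ValueError("y must be 0 or 1")
    T = ev.inverse_survival(u, X).ravel()

    # end of follow-up
    C = np.full(nrep, B)
    if dropout_model is not None and not dropout_model.is_none:
        v = rng.uniform(size=nrep)
        # R: S_c(R) = v  ->  R = inverse cumulative hazard at -log v
        R = dropout_model.params.inverse_survival(v, dropout_model._x(X)).ravel()
        C = np.minimum(R, B)

    a = _scalar(visit_model.rate(X))
    # visit sequence: exponential gaps, enough columns to pass B w.h.p.
    ncol = max(20, int(a * B + 10 * math.sqrt(a * B) + 20))
    gaps = rng.exponential(1.0 / a, size=(nrep, ncol))
    times = np.cumsum(gaps, axis=1)
    incomplete = times[:, -1] <= B
    while np.any(incomplete):  # pragma: no cover - vanishing probability
        extra = rng.exponential(1.0 / a, size=(int(incomplete.sum()), ncol))
        times[incomplete] = times[incomplete, -1][:, None] + np.cumsum(extra, axis=1)
        incomplete = times[:, -1] <= B

    valid = times <= C[:, None]
    Tcol = T[:, None]
    post = valid & (times >= Tcol)
    pre = valid & (times < Tcol)
    a_plus = np.where(post, times, np.inf).min(axis=1)
    a_minus = np.where(pre, times, 0.0).max(axis=1)  # baseline visit at 0
    delta = (a_plus <= t0) | (a_minus >= t0)
    p = float(delta.mean())
    se = math.sqrt(max(p * (1.0 - p), 1e-12) / nrep)
    return p, se
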