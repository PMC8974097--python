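"""Estimators of prediction error and ROC/AUC at a landmark time.

The quantity validated is the binary event-free status Y = I(T > t0),
predicted by Yhat = I(S(t0 | X; theta_hat) > c) where S is the fitted
survivor function from the training sample (larger survival probability =
"positive" = predicted event-free) and c defaults to 0.5.

Because the validation sample is interval-censored, Y is only known for the
subset with delta = 1.  Four estimators are provided for both the mean
absolute prediction error PE = E|Y - Yhat| and the AUC:

``unweighted``
    complete-case: restrict to delta = 1, no weights (the biased
    comparator);
``imputation``
    replace unknown |Y - Yhat| by its conditional expectation given the
    censoring interval, E{|Y - Yhat| | T in (a-, a+], X}, under the fitted
    event model;
``ipw``
    weight classified subjects by 1 / pi, pi = P(delta = 1 | Y, X) from the
    joint event/visit/drop-out model;
``aipw``
    the augmented IPW estimator, adding the model-based term
    (1 - delta/pi) E{|Y - Yhat| | X} for stability and efficiency.

The ROC components and the AUC share a single representation: per-subject
"positive-mass" Psi_i (estimating Y_i) and "negative-mass" Phi_j
(estimating 1 - Y_j).  TPR(c) = sum I(s_i > c) Psi_i / sum Psi_i,
FPR(c) likewise with Phi, and the AUC is the tie-corrected rank statistic

    AUC = sum_ij [I(s_i > s_j) + 0.5 I(s_i = s_j)] Psi_i Phi_j
          / sum_ij Psi_i Phi_j ,

with ties defined on risk scores rounded to 12 digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SubjectRecord, classify_at_landmark
from .event import _as_params, interval_conditional_survival
from .weights import WeightResult, compute_weights

__all__ = [
    "ClassifiedSample",
    "AccuracyResult",
    "AccuracyEvaluator",
    "pe_unweighted",
    "pe_imputation",
    "pe_ipw",
    "pe_aipw",
    "psi_phi",
    "roc_points",
    "auc",
    "weighted_rank_auc",
    "DEFAULT_C_GRID",
]

METHODS = ("unweighted", "imputation", "ipw", "aipw")
DEFAULT_C_GRID = np.arange(1, 102) / 102.0  # 101 equispaced points in (0,1)


@dataclass
class ClassifiedSample:
    """Aligned per-subject arrays for a validation sample at landmark t0."""

    ids: list[str]
    delta: np.ndarray  # 0/1
    y: np.ndarray  # known Y where delta=1, else 0 (masked by delta)
    score: np.ndarray  # S(t0 | X; theta_hat)
    yhat: np.ndarray  # I(score > c)
    p_interval: np.ndarray  # P(T > t0 | T in (a-, a+], X; theta_hat)
    X: np.ndarray
    t0: float
    threshold: float

    @property
    def n(self) -> int:
        return len(self.delta)

    @classmethod
    def from_sample(
        cls, sample: list[SubjectRecord], event_model, t0: float, threshold: float = 0.5
    ) -> "ClassifiedSample":
        ev = _as_params(event_model)
        ids, delta, y, p_int = [], [], [], []
        X = np.array([s.x for s in sample], dtype=float)
        for s in sample:
            c = classify_at_landmark(s, t0)
            ids.append(s.id)
            delta.append(c.delta)
            y.append(c.y if c.delta else 0)
            p_int.append(
                float(c.y)
                if c.delta
                else interval_conditional_survival(t0, c.a_minus, c.a_plus, s.x, ev)
            )
        score = np.asarray(ev.survival(t0, X), dtype=float)
        return cls(
            ids=ids,
            delta=np.array(delta, dtype=int),
            y=np.array(y, dtype=int),
            score=score,
            yhat=(score > threshold).astype(int),
            p_interval=np.array(p_int, dtype=float),
            X=X,
            t0=t0,
            threshold=threshold,
        )


# ---------------------------------------------------------------------------
# Prediction error
# ---------------------------------------------------------------------------


def _loss(y, yhat) -> np.ndarray:
    return np.abs(np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float))


def _expected_loss(p, yhat) -> np.ndarray:
    """E|Y - Yhat| when P(Y = 1) = p: yhat (1 - p) + (1 - yhat) p."""
    yhat = np.asarray(yhat, dtype=float)
    return yhat * (1.0 - p) + (1.0 - yhat) * p


def pe_unweighted(delta, y, yhat) -> float:
    """Complete-case mean absolute error: sum_i delta |Y - Yhat| / sum_i delta."""
    delta = np.asarray(delta, dtype=float)
    if delta.sum() == 0:
        raise ValueError("no classified subjects")
    return float(np.sum(delta * _loss(y, yhat)) / delta.sum())


def pe_imputation(delta, y, yhat, p_interval) -> float:
    """Impute unknown losses by their interval-conditional expectation."""
    delta = np.asarray(delta, dtype=float)
    term = delta * _loss(y, yhat) + (1.0 - delta) * _expected_loss(
        np.asarray(p_interval, dtype=float), yhat
    )
    return float(term.mean())


def _pi_vector(delta, weights: list[WeightResult], ids) -> np.ndarray:
    """Align a weight list to the sample; error if a delta=1 subject lacks one."""
    by_id = {w.id: w.pi for w in weights}
    delta = np.asarray(delta)
    pi = np.ones(len(delta))
    for k, (sid, d) in enumerate(zip(ids, delta)):
        if d:
            if sid not in by_id:
                raise ValueError(f"no weight for classified subject {sid}")
            pi[k] = by_id[sid]
    return pi


def pe_ipw(delta, y, yhat, pi) -> float:
    """(1/n) sum_i (delta_i / pi_i) |Y_i - Yhat_i|, n the full sample size."""
    delta = np.asarray(delta, dtype=float)
    pi = np.asarray(pi, dtype=float)
    return float(np.mean(delta / pi * _loss(y, yhat)))


def pe_aipw(delta, y, yhat, pi, score) -> float:
    """IPW plus the augmentation (1 - delta/pi) E{|Y - Yhat| | X}.

    E{|Y - Yhat| | X} uses P(Y = 1 | X) = S(t0 | X; theta_hat) = ``score``.
    """
    delta = np.asarray(delta, dtype=float)
    pi = np.asarray(pi, dtype=float)
    w = delta / pi
    term = w * _loss(y, yhat) + (1.0 - w) * _expected_loss(
        np.asarray(score, dtype=float), yhat
    )
    return float(term.mean())


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def psi_phi(delta, y, pi, p_interval, score, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject estimates (Psi_i of Y_i, Phi_j of 1 - Y_j) for ``method``."""
    delta = np.asarray(delta, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "unweighted":
        return delta * y, delta * (1.0 - y)
    if method == "imputation":
        p = np.asarray(p_interval, dtype=float)
        return delta * y + (1.0 - delta) * p, delta * (1.0 - y) + (1.0 - delta) * (1.0 - p)
    w = delta / np.asarray(pi, dtype=float)
    if method == "ipw":
        return w * y, w * (1.0 - y)
    if method == "aipw":
        s = np.asarray(score, dtype=float)
        return w * y + (1.0 - w) * s, w * (1.0 - y) + (1.0 - w) * (1.0 - s)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def weighted_rank_auc(scores, psi, phi) -> float:
    """Tie-corrected rank AUC sum_ij [I(si>sj) + .5 I(si=sj)] Psi_i Phi_j / norm.

    O(n log n) via grouped prefix sums; ties taken on scores rounded to
    12 digits.  Works for signed Psi/Phi (AIPW masses can be negative).
    """
    s = np.round(np.asarray(scores, dtype=float), 12)
    psi = np.asarray(psi, dtype=float)
    phi = np.asarray(phi, dtype=float)
    denom = psi.sum() * phi.sum()
    if denom == 0:
        raise ValueError("AUC undefined: a class has zero total mass")
    uniq, inv = np.unique(s, return_inverse=True)
    psi_g = np.bincount(inv, weights=psi, minlength=len(uniq))
    phi_g = np.bincount(inv, weights=phi, minlength=len(uniq))
    phi_below = np.r_[0.0, np.cumsum(phi_g)][:-1]  # strictly lower scores
    num = float(np.sum(psi_g * (phi_below + 0.5 * phi_g)))
    return num / float(denom)


def roc_points(scores, psi, phi, c_grid=None) -> pd.DataFrame:
    """(c, FPR, TPR) over a threshold grid; predictor is I(score > c)."""
    if c_grid is None:
        c_grid = DEFAULT_C_GRID
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any((c_grid <= 0) | (c_grid >= 1)):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    spsi, sphi = psi.sum(), phi.sum()
    if spsi == 0 or sphi == 0:
        raise ValueError("ROC undefined: a class has zero total mass")
    ind = scores[None, :] > c_grid[:, None]
    tpr = ind @ psi / spsi
    fpr = ind @ phi / sphi
    return pd.DataFrame({"c": c_grid, "fpr": fpr, "tpr": tpr})


def auc(delta, y, scores, method: str, pi=None, p_interval=None) -> float:
    """AUC by the chosen estimator (functional interface)."""
    psi, phi = psi_phi(delta, y, pi, p_interval, scores, method)
    return weighted_rank_auc(scores, psi, phi)


# ---------------------------------------------------------------------------
# Evaluator (model-style orchestration)
# ---------------------------------------------------------------------------


@dataclass
class AccuracyResult:
    """Estimates of PE and AUC at t0 for one method, plus diagnostics."""

    method: str
    t0: float
    pe: float
    auc: float
    roc: pd.DataFrame
    n_used: int
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Predictive accuracy at t0 = {self.t0:g} ({self.method})",
            f"  prediction error (|Y - Yhat|, c = {self.diagnostics.get('threshold', 0.5)}): {self.pe:.4f}",
            f"  AUC: {self.auc:.4f}",
            f"  subjects used: {self.n_used}",
        ]
        if "sum_weights" in self.diagnostics:
            lines.append(
                "  sum delta/pi = {sum_weights:.1f}, truncated weights: {n_truncated}".format(
                    **self.diagnostics
                )
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"method": self.method, "t0": self.t0, "pe": self.pe, "auc": self.auc}]
        )

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc["fpr"], self.roc["tpr"], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls=":", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"{self.method}, t0 = {self.t0:g}, AUC = {self.auc:.3f}")
        return ax


class AccuracyEvaluator:
    """Assess a fitted event model on an interval-censored validation sample.

    Parameters
    ----------
    sample : list of SubjectRecord
        The validation sample.
    event_model : WeibullPHResults or WeibullPHParams
        The prediction model under assessment (fitted on training data).
    t0 : float
        Landmark time.
    B : float, optional
        Administrative end of follow-up; required for IPW/AIPW weights.
        Defaults to the largest C among non-drop-out subjects.
    threshold : float
        Classification threshold c for Yhat = I(S(t0|X) > c).
    """

    def __init__(self, sample, event_model, t0, B=None, threshold=0.5, eps=0.01):
        self.sample = sample
        self.event_model = event_model
        self.t0 = float(t0)
        if B is None:
            ends = [s.C for s in sample if s.delta_dropout == 0]
            B = max(ends) if ends else max(s.C for s in sample)
        self.B = float(B)
        self.threshold = threshold
        self.eps = eps
        self.classified = ClassifiedSample.from_sample(
            sample, event_model, self.t0, threshold
        )

    def fit(
        self,
        method: str = "aipw",
        visit_model=None,
        dropout_model=None,
        weights: list[WeightResult] | None = None,
        c_grid=None,
    ) -> AccuracyResult:
        """Compute PE, ROC and AUC by ``method``.

        For ``ipw``/``aipw`` supply either precomputed ``weights`` or a
        fitted ``visit_model`` (and optional ``dropout_model``) from which
        they are derived.
        """
        cs = self.classified
        diagnostics: dict = {"threshold": self.threshold}
        pi = None
        if method in ("ipw", "aipw"):
            if weights is None:
                if visit_model is None:
                    raise ValueError(f"{method} requires weights or a visit model")
                weights = compute_weights(
                    self.sample,
                    self.t0,
                    self.B,
                    self.event_model,
                    visit_model,
                    dropout_model,
                    eps=self.eps,
                )
            pi = _pi_vector(cs.delta, weights, cs.ids)
            diagnostics.update(
                sum_weights=float(np.sum(cs.delta / pi)),
                n_truncated=sum(w.truncated for w in weights),
            )

        if method == "unweighted":
            pe = pe_unweighted(cs.delta, cs.y, cs.yhat)
            n_used = int(cs.delta.sum())
        elif method == "imputation":
            pe = pe_imputation(cs.delta, cs.y, cs.yhat, cs.p_interval)
            n_used = cs.n
        elif method == "ipw":
            pe = pe_ipw(cs.delta, cs.y, cs.yhat, pi)
            n_used = cs.n
        elif method == "aipw":
            pe = pe_aipw(cs.delta, cs.y, cs.yhat, pi, cs.score)
            n_used = cs.n
        else:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")

        psi, phi = psi_phi(cs.delta, cs.y, pi, cs.p_interval, cs.score, method)
        roc = roc_points(cs.score, psi, phi, c_grid)
        auc_val = weighted_rank_auc(cs.score, psi, phi)
        return AccuracyResult(
            method=method,
            t0=self.t0,
            pe=pe,
            auc=auc_val,
            roc=roc,
            n_used=n_used,
            diagnostics=diagnostics,
        )
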