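"""Monte-Carlo study orchestration: empirical bias and SE of the estimators.

One replicate generates a training/validation pair, fits the Weibull PH
event model to the (interval-censored) training sample, fits visit-process
models to the validation sample, and computes the unweighted, imputation,
IPW and AIPW estimates of the prediction error and AUC at the landmark.
Each estimate is compared with a replicate-specific truth: the population
values of PE and AUC for *that replicate's* fitted predictor, evaluated on
a fresh Monte-Carlo covariate population with Y integrated out analytically
(P(Y = 1 | X) is known under the generating model).

EBIAS = mean over replicates of (estimate - truth); ESE = sample SD of the
estimates.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accuracy import AccuracyEvaluator
from .event import FitError, WeibullPH, _as_params
from .observation import fit_ag, fit_th_poisson
from .simulate import Design, SimulationConfig, draw_covariates, generate_dataset, resolve_design
from .weights import compute_weights

__all__ = [
    "DEFAULT_METHODS",
    "true_pe",
    "true_auc",
    "run_replicate",
    "SimulationStudy",
    "StudyResult",
    "run_study",
]

DEFAULT_METHODS = ("unweighted", "imputation", "ipw-th", "aipw-th", "ipw-ag", "aipw-ag")

EVENT_COVARIATES = (0, 1)  # event model uses (X1, X2)
VISIT_COVARIATES = (0, 2)  # visit model uses (X1, X3)


def _truth_population(design: Design, rng, npop: int):
    cfg = design.config
    X = draw_covariates(cfg.scenario, cfg.corr23, npop, rng)
    p_true = np.asarray(design.event_params.survival(design.t0, X[:, EVENT_COVARIATES]))
    return X, p_true


def _score(event_model, X, t0) -> np.ndarray:
    return np.asarray(_as_params(event_model).survival(t0, X[:, EVENT_COVARIATES]))


def true_pe(event_model, design: Design, rng, npop: int = 100_000, threshold=0.5):
    """Population E|Y - Yhat(X; theta_hat)| for this replicate's predictor.

    Evaluated on ``npop`` fresh covariate draws with
    P(Y = 1 | X) = S_true(t0 | X) used exactly.
    """
    X, p_true = _truth_population(design, rng, npop)
    yhat = _score(event_model, X, design.t0) > threshold
    return float(np.mean(np.where(yhat, 1.0 - p_true, p_true)))


def _pairwise_auc(scores, p, q) -> float:
    """sum_{i != j} [I(si > sj) + .5 I(si = sj)] p_i q_j / sum_{i != j} p_i q_j."""
    s = np.round(np.asarray(scores, dtype=float), 12)
    uniq, inv = np.unique(s, return_inverse=True)
    pg = np.bincount(inv, weights=p, minlength=len(uniq))
    qg = np.bincount(inv, weights=q, minlength=len(uniq))
    q_below = np.r_[0.0, np.cumsum(qg)][:-1]
    num = float(np.sum(pg * (q_below + 0.5 * qg))) - 0.5 * float(np.sum(p * q))
    denom = float(p.sum() * q.sum()) - float(np.sum(p * q))
    return num / denom


def true_auc(event_model, design: Design, rng, npop: int = 100_000):
    """Population concordance P(s_i > s_j | T_i > t0, T_j <= t0) (+ half ties).

    Scores are the replicate's fitted survival probabilities; event-free /
    failed membership is weighted by the true P(T > t0 | X).
    """
    X, p_true = _truth_population(design, rng, npop)
    s = _score(event_model, X, design.t0)
    return _pairwise_auc(s, p_true, 1.0 - p_true)


def run_replicate(
    design: Design,
    seed,
    methods=DEFAULT_METHODS,
    truth_size: int = 100_000,
    threshold: float = 0.5,
    eps: float = 0.01,
) -> dict:
    """One simulation replicate: generate, fit, estimate, compute truths.

    Returns a flat dict with ``pe_<method>`` and ``auc_<method>`` entries
    plus ``true_pe``, ``true_auc`` and diagnostics.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    data_ss, truth_ss = ss.spawn(2)
    data = generate_dataset(design, data_ss)

    event_res = WeibullPH.from_sample(data.train, EVENT_COVARIATES).fit()
    evaluator = AccuracyEvaluator(
        data.valid, event_res, design.t0, B=design.B, threshold=threshold, eps=eps
    )

    weights = {}
    if any(m.endswith("-th") for m in methods):
        th = fit_th_poisson(data.valid, VISIT_COVARIATES)
        weights["th"] = compute_weights(
            data.valid, design.t0, design.B, event_res, th, eps=eps
        )
    if any(m.endswith("-ag") for m in methods):
        ag = fit_ag(data.valid, VISIT_COVARIATES)
        weights["ag"] = compute_weights(
            data.valid, design.t0, design.B, event_res, ag, eps=eps
        )

    out: dict = {}
    for m in methods:
        base, _, tag = m.partition("-")
        res = evaluator.fit(method=base, weights=weights.get(tag))
        out[f"pe_{m}"] = res.pe
        out[f"auc_{m}"] = res.auc
    truth_rng = np.random.default_rng(truth_ss)
    out["true_pe"] = true_pe(event_res, design, truth_rng, truth_size, threshold)
    out["true_auc"] = true_auc(event_res, design, truth_rng, truth_size)
    out["n_classified"] = int(evaluator.classified.delta.sum())
    for tag, wl in weights.items():
        out[f"n_truncated_{tag}"] = sum(w.truncated for w in wl)
    return out


@dataclass
class StudyResult:
    """Per-replicate estimates plus the EBIAS/ESE summary."""

    design: Design
    methods: tuple
    seed: int
    replicates: pd.DataFrame
    n_failed: int
    failures: list[str] = field(default_factory=list)
    runtime: float = 0.0

    def summary(self) -> pd.DataFrame:
        """EBIAS and ESE of each estimator of PE and AUC."""
        rows = []
        df = self.replicates
        for m in self.methods:
            row = {"method": m}
            for metric in ("pe", "auc"):
                est = df[f"{metric}_{m}"]
                truth = df[f"true_{metric}"]
                row[f"{metric}_ebias"] = float((est - truth).mean())
                row[f"{metric}_ese"] = float(est.std(ddof=1))
            rows.append(row)
        return pd.DataFrame(rows).set_index("method")

    def mc_se(self, metric: str, method: str) -> float:
        """Monte-Carlo standard error of the EBIAS entry."""
        diff = self.replicates[f"{metric}_{method}"] - self.replicates[f"true_{metric}"]
        return float(diff.std(ddof=1) / np.sqrt(len(diff)))

    def render_table(self) -> str:
        cfg = self.design.config
        head = (
            f"Scenario: {cfg.scenario}, corr(X2,X3)={cfg.corr23}, eta={cfg.eta}, "
            f"n={cfg.n_valid}, nsim={len(self.replicates)}"
        )
        return head + "\n" + self.summary().to_string(float_format=lambda v: f"{v: .4f}")


class SimulationStudy:
    """Run ``nsim`` independent replicates of a design.

    Per-replicate seeds derive from the master seed through
    ``numpy.random.SeedSequence(seed).spawn(nsim)``, so a fixed master seed
    reproduces every replicate regardless of execution order.
    """

    def __init__(self, config: SimulationConfig, methods=DEFAULT_METHODS, truth_size=100_000):
        self.config = config
        self.methods = tuple(methods)
        self.truth_size = truth_size
        self.design = resolve_design(config)

    def run(self, seed=None, progress=False, max_failure_rate=0.1) -> StudyResult:
        seed = self.config.seed if seed is None else seed
        if seed is None:
            seed = 0
        nsim = self.config.nsim
        children = np.random.SeedSequence(seed).spawn(nsim)
        rows, failures = [], []
        tic = time.perf_counter()
        for r, child in enumerate(children):
            try:
                row = run_replicate(
                    self.design, child, self.methods, truth_size=self.truth_size
                )
                row["replicate"] = r
                rows.append(row)
            except (FitError, RuntimeError, np.linalg.LinAlgError) as exc:
                failures.append(f"replicate {r}: {exc}")
                if len(failures) > max_failure_rate * nsim:
                    raise RuntimeError(
                        f"{len(failures)} of {r + 1} replicates failed; aborting.\n"
                        + "\n".join(failures)
                    )
            if progress and (r + 1) % 10 == 0:
                print(f"  replicate {r + 1}/{nsim}", flush=True)
        return StudyResult(
            design=self.design,
            methods=self.methods,
            seed=int(seed),
            replicates=pd.DataFrame(rows).set_index("replicate"),
            n_failed=len(failures),
            failures=failures,
            runtime=time.perf_counter() - tic,
        )


def run_study(config: SimulationConfig, methods=DEFAULT_METHODS, seed=None, **kw) -> StudyResult:
    """Convenience wrapper: ``SimulationStudy(config, methods).run(seed)``."""
    truth_size = kw.pop("truth_size", 100_000)
    return SimulationStudy(config, methods, truth_size=truth_size).run(seed=seed, **kw)
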