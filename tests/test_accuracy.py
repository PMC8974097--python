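"""Estimator suite: arithmetic oracles, reduction identities, ROC/AUC."""

import math

import numpy as np
import pytest

from icval.accuracy import (
    DEFAULT_C_GRID,
    AccuracyEvaluator,
    pe_aipw,
    pe_imputation,
    pe_ipw,
    pe_unweighted,
    psi_phi,
    roc_points,
    weighted_rank_auc,
)
from icval.event import WeibullPHParams
from icval.observation import PoissonVisitModel

from conftest import make_subject


def brute_force_auc(scores, psi, phi):
    """O(n^2) double loop directly transcribing the rank-statistic definition."""
    num = den = 0.0
    s = np.round(scores, 12)
    for i in range(len(s)):
        for j in range(len(s)):
            ind = 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
            num += ind * psi[i] * phi[j]
            den += psi[i] * phi[j]
    return num / den


class TestPredictionError:
    def test_unweighted_arithmetic(self):
        assert pe_unweighted([1, 1], [1, 0], [1, 1]) == 0.5

    def test_unweighted_perfect_predictor(self):
        assert pe_unweighted([1, 1, 1], [1, 0, 1], [1, 0, 1]) == 0.0

    def test_unweighted_requires_classified_subjects(self):
        with pytest.raises(ValueError):
            pe_unweighted([0, 0], [0, 0], [1, 1])

    def test_imputation_contribution(self):
        # delta = 0, yhat = 1, P(Y=1 | interval) = 0.25 -> contributes 0.75
        got = pe_imputation([0], [0], [1], [0.25])
        assert got == 0.75

    def test_imputation_reduces_to_apparent_error(self):
        y, yhat = [1, 0, 1, 0], [1, 1, 0, 0]
        assert pe_imputation([1] * 4, y, yhat, [0.0] * 4) == pytest.approx(
            np.mean(np.abs(np.array(y) - np.array(yhat)))
        )

    def test_ipw_arithmetic(self):
        # n = 4, delta = (1,1,0,0), pi = .5, losses (0,1,-,-) -> (1/4)(0 + 2) = .5
        got = pe_ipw([1, 1, 0, 0], [1, 0, 0, 0], [1, 1, 1, 1], [0.5, 0.5, 1, 1])
        assert got == 0.5

    def test_aipw_reduces_to_apparent_error_with_unit_weights(self):
        y, yhat = np.array([1, 0, 1]), np.array([1, 1, 0])
        s = np.array([0.8, 0.7, 0.4])
        got = pe_aipw([1, 1, 1], y, yhat, [1, 1, 1], s)
        assert got == pytest.approx(np.mean(np.abs(y - yhat)))

    def test_aipw_unclassified_contribution_is_model_term(self):
        # delta = 0: contribution is yhat(1-s) + (1-yhat)s
        got = pe_aipw([0], [0], [1], [1.0], [0.3])
        assert got == pytest.approx(0.7)

    def test_ipw_missing_weight_detected(self):
        from icval.accuracy import _pi_vector
        from icval.weights import WeightResult

        w = [WeightResult("a", 0.5, 0.5, 1, "th", False)]
        with pytest.raises(ValueError, match="no weight"):
            _pi_vector([1, 1], w, ["a", "b"])


class TestReductionChain:
    def test_all_methods_agree_on_complete_data(self, rng):
        """With delta = 1 and pi = 1 everywhere, the four estimators coincide
        exactly for PE and AUC."""
        n = 10
        y = rng.integers(0, 2, size=n)
        score = rng.uniform(size=n)
        yhat = (score > 0.5).astype(int)
        delta = np.ones(n, dtype=int)
        pi = np.ones(n)
        p_int = y.astype(float)
        pes = [
            pe_unweighted(delta, y, yhat),
            pe_imputation(delta, y, yhat, p_int),
            pe_ipw(delta, y, yhat, pi),
            pe_aipw(delta, y, yhat, pi, score),
        ]
        assert all(p == pes[0] for p in pes)
        aucs = []
        for method in ("unweighted", "imputation", "ipw", "aipw"):
            psi, phi = psi_phi(delta, y, pi, p_int, score, method)
            aucs.append(weighted_rank_auc(score, psi, phi))
        assert all(a == pytest.approx(aucs[0], abs=1e-12) for a in aucs)


class TestAUC:
    def test_matches_brute_force_double_loop(self, rng):
        for trial in range(5):
            n = 10
            scores = np.round(rng.uniform(size=n), 1)  # force some ties
            psi = rng.uniform(size=n)
            phi = rng.uniform(size=n)
            assert weighted_rank_auc(scores, psi, phi) == pytest.approx(
                brute_force_auc(scores, psi, phi), abs=1e-12
            )

    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        psi, phi = y.astype(float), 1.0 - y
        assert weighted_rank_auc(scores, psi, phi) == 1.0

    def test_identical_scores_give_half(self):
        scores = np.full(6, 0.4)
        y = np.array([1, 1, 1, 0, 0, 0]).astype(float)
        assert weighted_rank_auc(scores, y, 1 - y) == 0.5

    def test_score_reversal_complement(self, rng):
        n = 12
        scores = rng.uniform(size=n)
        y = rng.integers(0, 2, size=n).astype(float)
        if y.sum() in (0, n):
            y[0], y[-1] = 1.0, 0.0
        a1 = weighted_rank_auc(scores, y, 1 - y)
        a2 = weighted_rank_auc(-scores, y, 1 - y)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            weighted_rank_auc([0.1, 0.2], [1.0, 1.0], [0.0, 0.0])


class TestROC:
    def test_separable_toy_at_half(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0]).astype(float)
        df = roc_points(scores, y, 1 - y, c_grid=[0.5])
        assert (df["fpr"].iloc[0], df["tpr"].iloc[0]) == (0.0, 1.0)

    def test_endpoint_below_min_score(self):
        scores = np.array([0.6, 0.7, 0.3])
        y = np.array([1, 0, 1]).astype(float)
        df = roc_points(scores, y, 1 - y, c_grid=[0.05])
        assert (df["fpr"].iloc[0], df["tpr"].iloc[0]) == (1.0, 1.0)

    def test_monotone_in_threshold(self, rng):
        scores = rng.uniform(size=50)
        y = (scores + rng.normal(0, 0.3, 50) > 0.5).astype(float)
        if y.sum() in (0, 50):
            y[0], y[-1] = 1.0, 0.0
        df = roc_points(scores, y, 1 - y)
        assert (np.diff(df["tpr"]) <= 1e-12).all()
        assert (np.diff(df["fpr"]) <= 1e-12).all()

    def test_ipw_with_unit_weights_equals_unweighted(self, rng):
        n = 20
        delta = np.ones(n, dtype=int)
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            y[0], y[-1] = 1, 0
        scores = rng.uniform(size=n)
        psi_u, phi_u = psi_phi(delta, y, None, None, scores, "unweighted")
        psi_w, phi_w = psi_phi(delta, y, np.ones(n), None, scores, "ipw")
        df_u = roc_points(scores, psi_u, phi_u)
        df_w = roc_points(scores, psi_w, phi_w)
        np.testing.assert_allclose(df_u[["fpr", "tpr"]], df_w[["fpr", "tpr"]])

    def test_grid_bounds_enforced(self):
        with pytest.raises(ValueError):
            roc_points([0.5], [1.0], [1.0], c_grid=[0.0, 0.5])

    def test_default_grid(self):
        assert len(DEFAULT_C_GRID) == 101
        assert 0 < DEFAULT_C_GRID[0] and DEFAULT_C_GRID[-1] < 1


class TestEvaluator:
    @pytest.fixture(scope="class")
    def toy_setup(self):
        ev = WeibullPHParams(1.0, 1.0, [1.0])
        sample = [
            make_subject(0, [(0, 0), (0.5, 1)], C=3.0, x=[0.4]),  # delta=1, y=0
            make_subject(1, [(0, 0), (2.0, 0)], C=3.0, x=[-0.8]),  # delta=1, y=1
            make_subject(2, [(0, 0), (0.4, 0), (1.8, 1)], C=3.0, x=[0.1]),  # delta=0
            make_subject(3, [(0, 0), (1.5, 0)], C=3.0, x=[-1.4]),  # delta=1, y=1
            make_subject(4, [(0, 0), (0.2, 0)], C=3.0, x=[0.9]),  # delta=0 (censored)
        ]
        return sample, ev

    def test_classification_and_scores(self, toy_setup):
        sample, ev = toy_setup
        evaluator = AccuracyEvaluator(sample, ev, t0=1.0, B=3.0)
        cs = evaluator.classified
        np.testing.assert_array_equal(cs.delta, [1, 1, 0, 1, 0])
        np.testing.assert_array_equal(cs.y, [0, 1, 0, 1, 0])
        # interval-conditional survival equals known y for classified subjects
        np.testing.assert_allclose(cs.p_interval[[0, 1, 3]], [0.0, 1.0, 1.0])

    def test_methods_run_and_agree_with_functional_api(self, toy_setup):
        sample, ev = toy_setup
        evaluator = AccuracyEvaluator(sample, ev, t0=1.0, B=3.0)
        vm = PoissonVisitModel(gamma0=math.log(3.0), gamma=[])
        res_u = evaluator.fit("unweighted")
        res_i = evaluator.fit("imputation")
        res_w = evaluator.fit("ipw", visit_model=vm)
        res_a = evaluator.fit("aipw", visit_model=vm)
        cs = evaluator.classified
        assert res_u.pe == pe_unweighted(cs.delta, cs.y, cs.yhat)
        assert res_i.pe == pe_imputation(cs.delta, cs.y, cs.yhat, cs.p_interval)
        assert res_w.n_used == len(sample)
        assert 0 <= res_a.auc <= 1
        assert "sum_weights" in res_w.diagnostics
        assert "prediction error" in res_u.summary()

    def test_missing_visit_model_rejected(self, toy_setup):
        sample, ev = toy_setup
        evaluator = AccuracyEvaluator(sample, ev, t0=1.0, B=3.0)
        with pytest.raises(ValueError, match="requires weights or a visit model"):
            evaluator.fit("ipw")
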