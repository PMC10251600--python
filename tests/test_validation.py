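"""Validation metrics, protocols and enrichment."""

import math

import numpy as np
import pytest

from liabprof.validation import (
    enrichment_factor,
    external_validate,
    internal_validate,
    ranking_auc,
    regression_metrics,
)
from liabprof.modeling import fit_model


def direct_metrics(x, y):
    """Independent direct-summation implementation of the three formulas."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / (n - 1))
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / (n - 1))
    rss = sum((a - b) ** 2 for a, b in zip(x, y))
    tss = sum((a - mx) ** 2 for a in x)
    rmse = math.sqrt(rss / n)
    return cov / (sx * sy), 1 - rss / tss, rmse


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r, m.r2, m.rmse) == (1.0, 1.0, 0.0)

    def test_constant_offset(self, rng):
        x = rng.normal(size=20)
        m = regression_metrics(x, x + 1.0)
        tss = float(np.sum((x - x.mean()) ** 2))
        assert m.rmse == pytest.approx(1.0)
        assert m.r == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1 - len(x) / tss)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(6.5, 0.7, size=6)
            y = x + rng.normal(0, 0.5, size=6)
            m = regression_metrics(x, y)
            r, r2, rmse = direct_metrics(list(x), list(y))
            assert m.r == pytest.approx(r, abs=1e-10)
            assert m.r2 == pytest.approx(r2, abs=1e-10)
            assert m.rmse == pytest.approx(rmse, abs=1e-10)

    def test_zero_variance_flagged(self):
        m = regression_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not m.r_defined and math.isnan(m.r)


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(100, 8))
    y = X @ rng.normal(size=8) + rng.normal(0, 0.3, size=100)
    return X, y


class TestProtocols:
    def test_cv_partitions_each_iteration(self, data):
        # protocol contract is on fold structure: every compound held out once
        from sklearn.model_selection import KFold

        X, _ = data
        folds = list(KFold(5, shuffle=True, random_state=0).split(X))
        held = np.concatenate([va for _, va in folds])
        assert sorted(held) == list(range(100))
        assert {len(va) for _, va in folds} == {20}

    def test_bootstrap_split_sizes(self, data):
        X, y = data
        X2, y2 = np.tile(X, (2, 1)), np.tile(y, 2)  # n = 200 -> 180/20
        rep = internal_validate(X2, y2, "mlr", None, "bootstrap", iterations=3, seed=1)
        assert rep.iterations == 3 and rep.rmse_mean > 0

    def test_cv_report_sane(self, data):
        X, y = data
        rep = internal_validate(X, y, "mlr", None, "cv", iterations=3, seed=1)
        assert rep.r_mean > 0.9  # strong linear signal
        assert rep.r_sd >= 0

    def test_y_scrambling_kills_signal(self, data):
        X, y = data
        rep = internal_validate(X, y, "mlr", None, "y_scrambling", iterations=10, seed=1)
        assert abs(rep.r_mean) <= 0.25

    def test_order_invariance_given_seed(self, data):
        X, y = data
        perm = np.random.default_rng(9).permutation(len(y))
        a = internal_validate(X, y, "mlr", None, "cv", iterations=2, seed=4)
        b = internal_validate(X[perm], y[perm], "mlr", None, "cv", iterations=2, seed=4)
        assert a.rmse_mean == pytest.approx(b.rmse_mean, rel=0.1)

    def test_iterations_validated(self, data):
        X, y = data
        with pytest.raises(ValueError):
            internal_validate(X, y, "mlr", None, "cv", iterations=0)

    def test_external_overlap_rejected(self, data):
        X, y = data
        model = fit_model(X[:80], y[:80], "mlr")
        with pytest.raises(ValueError, match="overlap"):
            external_validate(model, X[70:], y[70:],
                              train_index=np.arange(80), test_index=np.arange(70, 100))
        rep = external_validate(model, X[80:], y[80:],
                                train_index=np.arange(80), test_index=np.arange(80, 100))
        assert rep.protocol == "external" and rep.r_mean > 0.8


class TestEnrichment:
    def test_perfect_ranking_at_5pc(self):
        y = np.arange(100, 0, -1, dtype=float)  # distinct activities
        res = enrichment_factor(y, y, chi=0.05, active_fraction=0.02)
        assert (res.a, res.m, res.m_chi, res.a_chi) == (2, 100, 5, 2)
        assert res.ef == pytest.approx((2 / 5) / (2 / 100))  # 20
        assert res.auc == 1.0

    def test_both_actives_in_top1pc(self):
        y_true = np.arange(100, 0, -1, dtype=float)
        y_score = np.zeros(100)
        y_score[:2] = [2.0, 1.0]  # the two actives ranked first
        res = enrichment_factor(y_true, y_score, chi=0.01, active_fraction=0.02)
        assert res.m_chi == 1 and res.a_chi == 1
        assert res.ef == pytest.approx(50.0)

    def test_reversed_ranking_zero_enrichment(self):
        y = np.arange(100, 0, -1, dtype=float)
        res = enrichment_factor(y, -y, chi=0.10, active_fraction=0.02)
        assert res.ef == 0.0 and res.auc == 0.0

    def test_ef_bound_property(self, rng):
        for _ in range(20):
            y = rng.normal(size=50)
            s = rng.normal(size=50)
            res = enrichment_factor(y, s, chi=0.10, active_fraction=0.05)
            assert 0.0 <= res.ef <= min(1 / 0.10, res.m / res.a) + 1e-12
            assert 0.0 <= res.auc <= 1.0

    def test_random_ranking_ef_near_one(self, rng):
        efs = [
            enrichment_factor(rng.normal(size=200), rng.normal(size=200),
                              chi=0.10, active_fraction=0.05).ef
            for _ in range(100)
        ]
        assert np.mean(efs) == pytest.approx(1.0, abs=0.25)

    def test_auc_matches_pair_counting_oracle(self, rng):
        labels = rng.integers(0, 2, size=30).astype(bool)
        labels[0], labels[1] = True, False
        scores = rng.normal(size=30)
        wins = ties = 0
        for i in np.flatnonzero(labels):
            for j in np.flatnonzero(~labels):
                wins += scores[i] > scores[j]
                ties += scores[i] == scores[j]
        expected = (wins + 0.5 * ties) / (labels.sum() * (~labels).sum())
        assert ranking_auc(labels, scores) == pytest.approx(expected)
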