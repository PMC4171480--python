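"""Random survival forest: concordance oracle, calibration, selection."""

import numpy as np
import pandas as pd
import pytest

from tmahet import rsf
from tests.conftest import make_survival_data


def brute_force_error(pred, t, e):
    """Independent pairwise enumeration of the concordance error."""
    num = den = 0.0
    n = len(pred)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (t[i] < t[j] and e[i] == 1) or (
                t[i] == t[j] and e[i] == 1 and e[j] == 0
            )
            if not comparable:
                continue
            den += 1
            if pred[i] > pred[j]:
                num += 1
            elif pred[i] == pred[j]:
                num += 0.5
    return 1.0 - num / den


class TestConcordanceError:
    def test_perfectly_concordant_is_zero(self):
        t = np.arange(1.0, 21.0)
        e = np.ones(20, dtype=int)
        pred = -t  # reverse rank of survival time
        assert rsf.harrell_concordance_error(pred, t, e) == 0.0

    def test_perfectly_anticoncordant_is_one(self):
        t = np.arange(1.0, 21.0)
        assert rsf.harrell_concordance_error(t, t, np.ones(20, dtype=int)) == 1.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 13))
            t = rng.integers(1, 8, n).astype(float)  # force ties
            e = rng.integers(0, 2, n)
            pred = rng.integers(0, 5, n).astype(float)  # force prediction ties
            if not (((t[:, None] > t[None, :]) | (t[:, None] == t[None, :])) & 1).any():
                continue
            try:
                mine = rsf.harrell_concordance_error(pred, t, e)
            except ValueError:
                # no comparable pairs: brute force agrees
                with pytest.raises(ZeroDivisionError):
                    brute_force_error(pred, t, e)
                continue
            assert mine == pytest.approx(brute_force_error(pred, t, e), abs=1e-12)

    def test_matches_scikit_survival(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 30
            t = rng.integers(1, 15, n).astype(float)
            e = rng.integers(0, 2, n).astype(bool)
            pred = rng.normal(size=n)
            if e.sum() == 0:
                continue
            c = concordance_index_censored(e, t, pred)[0]
            assert rsf.harrell_concordance_error(pred, t, e.astype(int)) == (
                pytest.approx(1.0 - c, abs=1e-12)
            )

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            rsf.harrell_concordance_error([1.0, 2.0], [5.0, 5.0], [0, 0])


class TestFitRsf:
    def test_null_features_error_near_half(self):
        errs = []
        for seed in range(5):
            X, t, e = make_survival_data(seed, n=100, p=20)
            m = rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=200, seed=seed))
            errs.append(m.oob_error)
        assert np.mean(errs) == pytest.approx(0.5, abs=0.07)

    def test_planted_signal_lowers_error(self):
        X, t, e = make_survival_data(1, n=200, p=20, coef=1.5)
        m = rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=300, seed=1))
        assert m.oob_error <= 0.4

    def test_duplicated_features_leave_error_roughly_unchanged(self):
        X, t, e = make_survival_data(2, n=120, p=10, coef=1.0)
        base = [
            rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=200, seed=s)).oob_error
            for s in range(3)
        ]
        dup = [
            rsf.fit_rsf(
                np.hstack([X, X]), t, e, rsf.RSFParams(n_trees=200, seed=s)
            ).oob_error
            for s in range(3)
        ]
        assert abs(np.mean(dup) - np.mean(base)) <= 3 * np.std(base, ddof=1) + 0.02

    def test_identical_seed_identical_forest(self):
        X, t, e = make_survival_data(3, n=60, p=8, coef=0.5)
        a = rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=40, seed=5))
        b = rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=40, seed=5))
        assert a.oob_error == b.oob_error
        np.testing.assert_array_equal(a.oob_mortality, b.oob_mortality)
        pd.testing.assert_series_equal(a.minimal_depth, b.minimal_depth)

    def test_every_subject_oob_somewhere(self):
        X, t, e = make_survival_data(4, n=80, p=5)
        m = rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=200, seed=0))
        assert np.isfinite(m.oob_mortality).all()
        assert (m.oob_mortality >= 0).all()

    def test_minimal_depth_ranks_planted_feature_first(self):
        X, t, e = make_survival_data(5, n=150, p=30, coef=1.5)
        m = rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=200, seed=2))
        assert m.minimal_depth.idxmin() == "f0"

    def test_preconditions(self):
        X, t, e = make_survival_data(0, n=10, p=3)
        with pytest.raises(ValueError):
            rsf.fit_rsf(X, t, e)
        X, t, e = make_survival_data(0, n=30, p=3)
        with pytest.raises(ValueError):
            rsf.fit_rsf(X, t, np.zeros_like(e))

    def test_oob_error_sd_shrinks_with_more_trees(self):
        X, t, e = make_survival_data(6, n=80, p=10, coef=1.0)
        few = [
            rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=25, seed=s)).oob_error
            for s in range(5)
        ]
        many = [
            rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=400, seed=s)).oob_error
            for s in range(5)
        ]
        assert np.std(many) <= np.std(few) + 0.01


class TestPredict:
    def test_single_tree_forest_returns_terminal_curve(self):
        X, t, e = make_survival_data(7, n=40, p=4, coef=1.0)
        m = rsf.fit_rsf(
            X, t, e, rsf.RSFParams(n_trees=1, seed=3), min_subjects=2
        )
        mort, curves = rsf.predict(m, X[:1])
        chf = m.trees[0].predict_chf(X[:1])[0]
        np.testing.assert_allclose(curves.iloc[:, 0].to_numpy(), np.exp(-chf))
        assert mort[0] == pytest.approx(chf.sum())

    def test_curves_monotone_within_unit_interval(self):
        X, t, e = make_survival_data(8, n=60, p=6, coef=1.0)
        m = rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=50, seed=1))
        _, curves = rsf.predict(m, X)
        vals = curves.to_numpy()
        assert (vals >= 0).all() and (vals <= 1.0 + 1e-12).all()
        assert (np.diff(vals, axis=0) <= 1e-12).all()

    def test_mortality_halves_separate_in_km(self):
        from tmahet.survstats import logrank_test

        hits = 0
        for seed in range(3):
            X, t, e = make_survival_data(30 + seed, n=150, p=10, coef=1.5)
            tr, te = np.arange(100), np.arange(100, 150)
            m = rsf.fit_rsf(X[tr], t[tr], e[tr], rsf.RSFParams(n_trees=200, seed=seed))
            mort, _ = rsf.predict(m, X[te])
            high = mort > np.median(mort)
            _, p = logrank_test(t[te], e[te], high)
            hits += p < 0.05
        assert hits >= 2

    def test_unknown_feature_names_raise(self):
        X = pd.DataFrame(
            np.random.default_rng(0).normal(size=(40, 3)), columns=list("abc")
        )
        _, t, e = make_survival_data(9, n=40, p=1)
        m = rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=10, seed=0))
        with pytest.raises(ValueError):
            rsf.predict(m, X.rename(columns={"a": "zzz"}))


class TestVariableHunting:
    def test_planted_feature_gets_top_count(self):
        X, t, e = make_survival_data(10, n=120, p=25, coef=2.0)
        res = rsf.variable_hunting(
            X, t, e, rsf.RSFParams(n_trees=30, seed=4), n_iter=10
        )
        assert res.ranking[0] == "f0"
        assert res.counts["f0"] >= 8

    def test_single_iteration_structure(self):
        X, t, e = make_survival_data(11, n=60, p=8, coef=1.0)
        res = rsf.variable_hunting(
            X, t, e, rsf.RSFParams(n_trees=20, seed=0), n_iter=1
        )
        assert res.n_iter == 1
        assert len(res.iterations) == 1
        assert res.counts.sum() == len(res.iterations[0]["selected"])

    def test_null_features_no_dominant_selection(self):
        X, t, e = make_survival_data(12, n=80, p=30)
        res = rsf.variable_hunting(
            X, t, e, rsf.RSFParams(n_trees=20, seed=2), n_iter=10
        )
        assert res.counts.max() <= 7  # no feature selected in most iterations

    def test_counts_bounded_by_iterations(self):
        X, t, e = make_survival_data(13, n=60, p=6, coef=1.0)
        res = rsf.variable_hunting(
            X, t, e, rsf.RSFParams(n_trees=15, seed=1), n_iter=5
        )
        assert (res.counts >= 0).all() and (res.counts <= 5).all()


class TestCrossValidate:
    def test_exact_repetition_count_and_range(self):
        X, t, e = make_survival_data(14, n=60, p=5, coef=1.0)
        res = rsf.cross_validate(
            X, t, e, rsf.RSFParams(n_trees=25, seed=0), n_rep=10
        )
        assert res.errors.shape == (10,)
        assert ((res.errors >= 0) & (res.errors <= 1)).all()

    def test_null_cv_error_near_half(self):
        X, t, e = make_survival_data(15, n=90, p=15)
        res = rsf.cross_validate(
            X, t, e, rsf.RSFParams(n_trees=60, seed=1), n_rep=15
        )
        assert res.mean == pytest.approx(0.5, abs=0.07)

    def test_cv_consistent_with_oob_on_signal(self):
        X, t, e = make_survival_data(16, n=200, p=10, coef=1.5)
        m = rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=200, seed=0))
        res = rsf.cross_validate(
            X, t, e, rsf.RSFParams(n_trees=200, seed=0), n_rep=15
        )
        assert abs(res.mean - m.oob_error) <= 0.05


class TestMortalityVsFeature:
    def test_monotone_profile_for_planted_risk_feature(self):
        from scipy.stats import spearmanr

        X, t, e = make_survival_data(17, n=150, p=5, coef=2.0)
        m = rsf.fit_rsf(
            pd.DataFrame(X, columns=[f"f{i}" for i in range(5)]),
            t,
            e,
            rsf.RSFParams(n_trees=150, seed=0),
        )
        prof = rsf.mortality_vs_feature(m, pd.DataFrame(X, columns=m.feature_names), "f0")
        rho = spearmanr(prof["value"], prof["mean_mortality"]).statistic
        assert rho >= 0.8

    def test_flat_profile_for_noise_feature(self):
        X, t, e = make_survival_data(18, n=150, p=5, coef=2.0)
        m = rsf.fit_rsf(
            pd.DataFrame(X, columns=[f"f{i}" for i in range(5)]),
            t,
            e,
            rsf.RSFParams(n_trees=150, seed=0),
        )
        prof = rsf.mortality_vs_feature(m, pd.DataFrame(X, columns=m.feature_names), "f3")
        spread = prof["mean_mortality"].max() - prof["mean_mortality"].min()
        base = rsf.mortality_vs_feature(m, pd.DataFrame(X, columns=m.feature_names), "f0")
        signal_spread = base["mean_mortality"].max() - base["mean_mortality"].min()
        assert spread < 0.25 * signal_spread

    def test_constant_feature_flat_single_point(self):
        X, t, e = make_survival_data(19, n=40, p=3, coef=1.0)
        X[:, 2] = 1.0
        m = rsf.fit_rsf(X, t, e, rsf.RSFParams(n_trees=30, seed=0))
        prof = rsf.mortality_vs_feature(m, X, "f2")
        assert len(prof) == 1
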