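"""Cox/log-rank/KM primitives and the centile cut-point grid."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmahet import cutpoint, synth
from tmahet.survstats import cox_fit_single, logrank_statistics, logrank_test


class TestCoxFit:
    def test_matches_lifelines_on_toy_data(self):
        from lifelines import CoxPHFitter

        # 5 subjects with a tie and censoring
        df = pd.DataFrame(
            {
                "t": [5.0, 8.0, 8.0, 12.0, 20.0],
                "e": [1, 1, 1, 0, 1],
                "x": [2.0, 1.0, 0.5, -1.0, -2.0],
            }
        )
        fit = cox_fit_single(df["x"], df["t"], df["e"])
        cph = CoxPHFitter()
        cph.fit(df, "t", "e", fit_options={"precision": 1e-9})
        assert fit.coef == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_matches_lifelines_on_random_instances(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        for _ in range(5):
            n = 60
            x = rng.normal(size=n)
            t = np.round(rng.exponential(100 * np.exp(-0.5 * x)) + 1, 0)
            e = (rng.random(n) < 0.7).astype(int)
            fit = cox_fit_single(x, t, e)
            cph = CoxPHFitter()
            cph.fit(
                pd.DataFrame({"t": t, "e": e, "x": x}),
                "t",
                "e",
                fit_options={"precision": 1e-10},
            )
            assert fit.coef == pytest.approx(cph.params_["x"], abs=1e-5)

    def test_null_p_values_uniform(self):
        ps = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            t = rng.exponential(1000, 200) + 1
            e = (rng.random(200) < 0.8).astype(int)
            ps.append(cox_fit_single(x, t, e).p)
        d = stats.kstest(ps, "uniform").statistic
        assert d <= 0.15

    def test_recovers_planted_coefficient(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=200)
            tt = rng.exponential(1000 * np.exp(-0.5 * x)) + 1
            ce = rng.exponential(4000, 200)
            t, e = np.minimum(tt, ce), (tt <= ce).astype(int)
            fit = cox_fit_single(x, t, e)
            if abs(fit.coef - 0.5) <= 1.96 * fit.se:
                hits += 1
        assert hits >= 90

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            cox_fit_single([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(ValueError):
            cox_fit_single([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.r_[np.array([3.0, 5.0, 9.0]), np.array([3.0, 5.0, 9.0])]
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_matches_hand_risk_table_on_six_patients(self):
        # groups A={2+,4,6}, B={1,3,5+} (+ = censored)
        t = np.array([2.0, 4.0, 6.0, 1.0, 3.0, 5.0])
        e = np.array([0, 1, 1, 1, 1, 0])
        g = np.array([1, 1, 1, 0, 0, 0], dtype=bool)

        # hand computation over event times 1, 3, 4, 6
        # t=1: Y=6, Y1=3, d=1, d1=0 -> E=0.5, V=6*1*3*3*(6-1)... use formula
        o_minus_e, var = 0.0, 0.0
        for time_i in sorted(t[e == 1]):
            at_risk = t >= time_i
            Y, Y1 = at_risk.sum(), (at_risk & g).sum()
            d = ((t == time_i) & (e == 1)).sum()
            d1 = ((t == time_i) & (e == 1) & g).sum()
            o_minus_e += d1 - d * Y1 / Y
            if Y > 1:
                var += d * (Y1 / Y) * (1 - Y1 / Y) * (Y - d) / (Y - 1)
        expected = o_minus_e**2 / var
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(expected, abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(9)
        t = rng.exponential(100, 80) + 1
        e = (rng.random(80) < 0.7).astype(int)
        g = rng.random(80) < 0.5
        chi2, p = logrank_test(t, e, g)
        ref = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_vectorised_splits_match_individual_tests(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(50, 30) + 1
        e = (rng.random(30) < 0.8).astype(int)
        M = rng.random((30, 7)) < 0.5
        chi2, _ = logrank_statistics(t, e, M)
        for k in range(7):
            single, _ = logrank_test(t, e, M[:, k])
            assert chi2[k] == pytest.approx(single, rel=1e-9)


class TestLogrankAllSplits:
    @staticmethod
    def _survival(n, seed=0, coef=0.0):
        rng = np.random.default_rng(seed)
        idx = rng.normal(size=n)
        tt = rng.exponential(1000 * np.exp(-coef * idx)) + 1
        ce = rng.exponential(3000, n)
        surv = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "time_days": np.minimum(tt, ce),
                "event": (tt <= ce).astype(int),
                "cohort": "t",
            }
        )
        return pd.Series(idx, index=surv["patient_id"]), surv

    def test_every_admissible_split_reported(self):
        index, surv = self._survival(30)
        scan = cutpoint.logrank_all_splits(index, surv, min_group_size=5)
        assert len(scan) == 30 - 2 * 5 + 1
        assert scan["n_low"].min() == 5
        assert scan["n_high"].min() == 5

    def test_too_few_patients_raise(self):
        index, surv = self._survival(8)
        with pytest.raises(ValueError):
            cutpoint.logrank_all_splits(index, surv, min_group_size=5)

    def test_monotone_hazard_optimal_split_interior(self):
        interior = 0
        for seed in range(5):
            index, surv = self._survival(60, seed=seed, coef=1.5)
            scan = cutpoint.logrank_all_splits(index, surv, min_group_size=5)
            k = scan["p"].idxmin()
            if scan["n_low"].iloc[0] < scan.loc[k, "n_low"] < scan["n_low"].iloc[-1]:
                interior += 1
        assert interior >= 4


class TestKaplanMeier:
    def test_no_events_curve_constant_one(self):
        surv = pd.DataFrame(
            {
                "patient_id": list("abcd"),
                "time_days": [5.0, 6.0, 7.0, 8.0],
                "event": [0, 0, 0, 0],
                "cohort": "x",
            }
        )
        curves = cutpoint.kaplan_meier(np.array(["g"] * 4), surv)
        assert (curves["g"]["survival"] == 1.0).all()

    def test_product_limit_steps_by_hand(self):
        surv = pd.DataFrame(
            {
                "patient_id": list("abc"),
                "time_days": [1.0, 2.0, 3.0],
                "event": [1, 1, 1],
                "cohort": "x",
            }
        )
        curves = cutpoint.kaplan_meier(np.array(["g"] * 3), surv)
        g = curves["g"].set_index("time")["survival"]
        assert g.loc[1.0] == pytest.approx(2 / 3)
        assert g.loc[2.0] == pytest.approx(1 / 3)
        assert g.loc[3.0] == pytest.approx(0.0)

    def test_curves_non_increasing_within_unit_interval(self, ratio_cohort):
        _, surv, frac = ratio_cohort
        groups = pd.Series(
            np.where(frac > frac.median(), "high", "low"), index=frac.index
        )
        curves = cutpoint.kaplan_meier(groups, surv)
        for c in curves.values():
            s = c["survival"].to_numpy()
            assert (np.diff(s) <= 1e-12).all()
            assert s.min() >= 0.0 and s.max() <= 1.0


class TestThresholdGrid:
    @pytest.fixture(scope="class")
    def planted(self):
        return synth.sample_ratio_cohort(
            60, 120, log_hazard_coef=2.0, seed=17
        )

    def test_single_pair_grid_equals_direct_cox(self, planted):
        cells, surv, _ = planted
        grid = cutpoint.threshold_grid_cox(
            cells, surv, cd99_centiles=[60], ki67_centiles=[40]
        )
        row = grid.table.iloc[0]
        thr_cd99 = np.percentile(cells["cd99_log2_nc_mean"], 60)
        thr_ki67 = np.percentile(cells["ki67_log2_nc_mean"], 40)
        idx = (
            cells.assign(
                pos=cells["cd99_log2_nc_mean"] < thr_cd99,
                kpos=cells["ki67_log2_nc_mean"] > thr_ki67,
            )
            .groupby("patient_id")
            .apply(
                lambda d: (d["pos"] & d["kpos"]).sum() / d["pos"].sum(),
                include_groups=False,
            )
        )
        s = surv.set_index("patient_id").loc[idx.index]
        direct = cox_fit_single(idx, s["time_days"], s["event"])
        assert row["coef"] == pytest.approx(direct.coef, rel=1e-9)
        assert row["p"] == pytest.approx(direct.p, rel=1e-9)

    def test_min_p_attained_by_optimal_cell(self, planted):
        cells, surv, _ = planted
        grid = cutpoint.threshold_grid_cox(
            cells, surv, cd99_centiles=range(10, 100, 20),
            ki67_centiles=range(10, 100, 20),
        )
        assert grid.min_p == grid.table["p"].min()

    def test_grid_invariant_to_monotone_transform(self, planted):
        cells, surv, _ = planted
        warped = cells.assign(
            cd99_log2_nc_mean=np.exp(cells["cd99_log2_nc_mean"]),
            ki67_log2_nc_mean=cells["ki67_log2_nc_mean"] ** 3,
        )
        kw = dict(cd99_centiles=[30, 60], ki67_centiles=[20, 80])
        a = cutpoint.threshold_grid_cox(cells, surv, **kw)
        b = cutpoint.threshold_grid_cox(warped, surv, **kw)
        np.testing.assert_allclose(
            a.table["p"].to_numpy(), b.table["p"].to_numpy(), rtol=1e-9
        )

    def test_planted_threshold_recovered_near_truth(self):
        # the planted subpopulation boundary sits where the mixture
        # components separate; the optimal pair should find a strongly
        # significant cell rather than a random one
        recovered = 0
        for seed in range(5):
            cells, surv, _ = synth.sample_ratio_cohort(
                80, 150, log_hazard_coef=2.5, seed=300 + seed
            )
            grid = cutpoint.threshold_grid_cox(
                cells,
                surv,
                cd99_centiles=range(5, 100, 10),
                ki67_centiles=range(5, 100, 10),
            )
            opt = grid.optimal
            if opt["coef"] > 0 and opt["p"] < 0.01:
                recovered += 1
        assert recovered >= 4


class TestNullBias:
    def test_grid_minimum_p_anticonservative_under_null(self):
        # the multiplicity bias: minimum p over the grid is far from uniform
        mins, singles = [], []
        for seed in range(15):
            cells, surv, _ = synth.sample_ratio_cohort(
                60, 80, log_hazard_coef=0.0, seed=700 + seed
            )
            grid = cutpoint.threshold_grid_cox(
                cells,
                surv,
                cd99_centiles=range(5, 100, 10),
                ki67_centiles=range(5, 100, 10),
            )
            mins.append(grid.min_p)
            singles.append(
                cutpoint.threshold_grid_cox(
                    cells, surv, cd99_centiles=[50], ki67_centiles=[50]
                ).min_p
            )
        assert np.mean(np.array(mins) < 0.05) > 0.5
        # the single pre-specified pair must not share the bias
        assert np.mean(np.array(singles) < 0.05) < 0.3
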