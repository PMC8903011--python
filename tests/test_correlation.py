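import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from fetalsplice.correlation import (
    compare_zero_order_vs_partial,
    loess_smooth,
    pairwise_event_correlations,
    partial_spearman,
    psi_regulator_correlations,
    spearman,
)
from fetalsplice.psi import build_psi_matrix


def _residual_rank_oracle(x, y, z):
    """Independent route: regress the ranks of x and y on the ranks of Z
    (with intercept) and correlate the residuals."""
    rx, ry = rankdata(x), rankdata(y)
    design = np.column_stack([np.ones(len(x))] + [rankdata(col) for col in z])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    res_x = rx - design @ beta_x
    res_y = ry - design @ beta_y
    return np.corrcoef(res_x, res_y)[0, 1]


class TestSpearman:
    def test_hand_computed_rho(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 24/60
        rho, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_monotone_transform_gives_one(self):
        x = np.array([0.2, 1.5, 3.0, 7.0, 9.0])
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho2, _ = spearman(x, np.log(x))
        assert rho2 == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho, _ = spearman(x, y)
        rho_t, _ = spearman(np.exp(x), y**3 + 5 * y)
        assert rho_t == pytest.approx(rho, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_type_one_error_at_nominal_level(self):
        """Independent pairs, n=50: rejection at alpha=0.05 stays within
        Monte-Carlo error of the nominal level over 10000 replicates."""
        rng = np.random.default_rng(1)
        n, reps, alpha = 50, 10_000, 0.05
        x = np.apply_along_axis(rankdata, 1, rng.normal(size=(reps, n)))
        y = np.apply_along_axis(rankdata, 1, rng.normal(size=(reps, n)))
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        y = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, keepdims=True)
        rho = (x * y).mean(axis=1)
        from scipy.stats import t as t_dist

        tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * t_dist.sf(np.abs(tstat), n - 2)
        rate = (p < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se


class TestPartialSpearman:
    def test_empty_covariates_equal_zero_order(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert partial_spearman(x, y) == pytest.approx(spearman(x, y)[0], abs=1e-12)

    def test_first_order_recursion(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=40)
        x = z + rng.normal(size=40)
        y = -z + rng.normal(size=40)
        r_xy = spearman(x, y)[0]
        r_xz = spearman(x, z)[0]
        r_yz = spearman(y, z)[0]
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert partial_spearman(x, y, z[None, :]) == pytest.approx(expected, abs=1e-12)

    def test_matches_residual_rank_oracle(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(2, 60))
        x = z[0] - 0.5 * z[1] + rng.normal(size=60)
        y = 0.7 * z[0] + z[1] + rng.normal(size=60)
        assert partial_spearman(x, y, z) == pytest.approx(
            _residual_rank_oracle(x, y, z), abs=1e-10
        )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=["x", "y", "z"])
        ours = partial_spearman(
            df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy()[None, :]
        )
        theirs = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert ours == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-10)

    def test_shared_driver_collapses_to_zero(self):
        # both variables driven by z; just enough jitter to break exact rank
        # ties with the covariate (a noise-free copy is collinear by design)
        z = np.linspace(0, 1, 50)
        rng = np.random.default_rng(6)
        x = 2 * z + rng.normal(0, 0.06, 50)
        y = 3 * z + 1 + rng.normal(0, 0.06, 50)
        assert spearman(x, y)[0] > 0.9
        assert abs(partial_spearman(x, y, z[None, :])) < 0.3

    def test_covariate_equal_to_y_is_collinear(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=20), rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            partial_spearman(x, y, y[None, :])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            partial_spearman([1, 2, 3], [3, 1, 2], np.ones((2, 3)))


class TestRegulatorCorrelations:
    def test_signs_follow_truth(self, small_study):
        """Postnatal-up events correlate positively with MBNL1/2 expression and
        negatively with CELF1 in the developmental cohort (q < 0.05)."""
        dev = small_study["development"]
        pm = build_psi_matrix(dev.inclusion, dev.exclusion)
        up = dev.truth.index[(dev.truth.sign == 1)][:20]
        events = [e for e in up if e in pm.psi.index]
        res = psi_regulator_correlations(pm.psi.loc[events], dev.regulator_expr)
        res = res.set_index(["event_id", "regulator"])
        for ev in events:
            assert res.loc[(ev, "MBNL1"), "rho"] > 0
            assert res.loc[(ev, "MBNL2"), "rho"] > 0
            assert res.loc[(ev, "CELF1"), "rho"] < 0
        assert (res["q"] < 0.05).all()

    def test_unregulated_events_mostly_null(self, small_study):
        dev = small_study["development"]
        pm = build_psi_matrix(dev.inclusion, dev.exclusion)
        null = dev.truth.index[~dev.truth.regulated][:60]
        events = [e for e in null if e in pm.psi.index]
        res = psi_regulator_correlations(pm.psi.loc[events], dev.regulator_expr)
        assert (res["q"] >= 0.05).mean() > 0.8

    def test_insufficient_shared_samples_rejected(self, small_study):
        dev = small_study["development"]
        pm = build_psi_matrix(dev.inclusion, dev.exclusion)
        expr = dev.regulator_expr.iloc[:, :1]
        with pytest.raises(ValueError, match="shared samples"):
            psi_regulator_correlations(pm.psi, expr)


class TestPairwise:
    def test_pair_count_is_k_choose_2(self):
        rng = np.random.default_rng(8)
        psi = pd.DataFrame(rng.uniform(size=(7, 15)))
        assert len(pairwise_event_correlations(psi)) == 21

    def test_duplicated_event_has_rho_one(self):
        rng = np.random.default_rng(9)
        row = rng.uniform(size=12)
        psi = pd.DataFrame([row, row], index=["a", "b"])
        res = pairwise_event_correlations(psi)
        assert res["rho"].iloc[0] == pytest.approx(1.0)

    def test_single_event_rejected(self):
        with pytest.raises(ValueError):
            pairwise_event_correlations(pd.DataFrame([[0.1, 0.2, 0.3, 0.4]]))


class TestZeroOrderVsPartial:
    def test_random_covariate_changes_nothing(self, small_study):
        dev = small_study["development"]
        pm = build_psi_matrix(dev.inclusion, dev.exclusion)
        events = dev.truth.index[dev.truth.regulated][:15]
        sub = pm.psi.loc[[e for e in events if e in pm.psi.index]]
        rng = np.random.default_rng(10)
        cov = pd.DataFrame(
            {"noise": rng.normal(size=sub.shape[1])}, index=sub.columns
        )
        res = compare_zero_order_vs_partial(sub, {"random": cov})
        assert abs(res["median_shift"].iloc[0]) < 0.1

    def test_age_collapses_developmental_coordination(self, small_study):
        dev = small_study["development"]
        pm = build_psi_matrix(dev.inclusion, dev.exclusion)
        events = dev.truth.index[dev.truth.regulated][:15]
        sub = pm.psi.loc[[e for e in events if e in pm.psi.index]]
        meta = dev.metadata.set_index("sample_id")
        cov = pd.DataFrame(
            {"log10_age": np.log10(meta.loc[sub.columns, "age_days"])}
        )
        res = compare_zero_order_vs_partial(sub, {"age": cov})
        row = res.iloc[0]
        assert row["median_abs_partial"] < row["median_abs_zero"] - 0.2
        assert row["q"] < 0.05


class TestLoess:
    def test_constant_signal_gives_constant_fit(self):
        x = np.linspace(0, 1, 30)
        fit = loess_smooth(x, np.full(30, 0.7), span=0.5)
        assert np.allclose(fit, 0.7)

    def test_linear_signal_reproduced_exactly(self):
        x = np.linspace(0, 10, 25)
        y = -1.5 * x + 4
        assert np.abs(loess_smooth(x, y, span=1.0) - y).max() < 1e-10

    def test_noisy_logistic_rmse_below_noise(self):
        rng = np.random.default_rng(11)
        x = np.linspace(-4, 4, 200)
        truth = 1 / (1 + np.exp(-2 * x))
        noise_sd = 0.15
        y = truth + rng.normal(0, noise_sd, 200)
        fit = loess_smooth(x, y, span=0.5)
        rmse = np.sqrt(np.mean((fit - truth) ** 2))
        assert rmse < noise_sd

    def test_query_points_and_order(self):
        x = np.linspace(0, 10, 40)
        y = 2 * x
        q = np.array([7.0, 1.0, 5.0])
        fit = loess_smooth(x, y, query=q, span=1.0)
        assert np.allclose(fit, 2 * q, atol=1e-8)

    def test_tiny_span_rejected(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="span"):
            loess_smooth(x, x, span=0.05)
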