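import numpy as np
import pandas as pd
import pytest

from leaftemp import windows as win


def _series(n=120, leaf="L1", start="2016-10-01 10:00:00", cadence_s=10,
            transform=lambda x: x, rng=None, noise=0.0):
    t = pd.date_range(start, periods=n, freq=f"{cadence_s}s")
    obs = np.linspace(-1, 4, n)
    if rng is not None and noise:
        obs = obs + rng.normal(0, noise, n)
    est = transform(obs)
    return pd.DataFrame({"time": t, "leaf_id": leaf, "dt_obs": obs,
                         "dt_est": est})


class TestSelectWindows:
    def test_identity_selected_with_unit_slope(self):
        diags, mask = win.select_windows(_series())
        assert all(d.selected for d in diags)
        assert all(abs(d.slope - 1) < 1e-12 and abs(d.intercept) < 1e-12
                   for d in diags)
        assert mask.all()

    def test_offset_fails_intercept_gate(self):
        diags, mask = win.select_windows(_series(transform=lambda x: x + 5.0))
        assert not any(d.selected for d in diags)
        assert all("intercept" in d.reason for d in diags)

    def test_slope_gates_brute_force(self, rng):
        for factor, expect in ((1.4, False), (1.2, True)):
            df = _series(transform=lambda x, f=factor: f * x, rng=rng,
                         noise=0.1)
            diags, _ = win.select_windows(df)
            # brute-force OLS confirms the per-window slope
            bf = np.polyfit(df["dt_obs"], df["dt_est"], 1)[0]
            assert diags[0].slope == pytest.approx(bf, rel=1e-9)
            assert diags[0].selected is expect

    def test_sparse_window_rejected_with_reason(self):
        diags, _ = win.select_windows(_series(n=30))
        assert not diags[0].selected and "n_min" in diags[0].reason

    def test_selection_idempotent(self):
        df = pd.concat([_series(), _series(transform=lambda x: x + 5.0,
                                           start="2016-10-01 12:00:00")],
                       ignore_index=True)
        diags1, mask1 = win.select_windows(df)
        kept = df[mask1].reset_index(drop=True)
        diags2, mask2 = win.select_windows(kept)
        assert mask2.all()
        assert sum(d.selected for d in diags2) == sum(d.selected for d in diags1)


class TestMicroclimateBin:
    bin_ = win.MicroclimateBin("high", 1000, 1300, 18, 20, 0.5, 1.5)

    def test_upper_boundary_excluded(self):
        df = pd.DataFrame({"par": [1300.0, 1299.9], "ta": [19.0, 19.0],
                           "wind": [1.0, 1.0]})
        out = win.subset_by_microclimate(df, self.bin_)
        assert list(out["par"]) == [1299.9]

    def test_empty_intersection_is_empty_not_error(self):
        df = pd.DataFrame({"par": [10.0], "ta": [12.0], "wind": [0.1]})
        assert len(win.subset_by_microclimate(df, self.bin_)) == 0

    def test_counts_match_brute_force(self, small_leaf_series):
        df = small_leaf_series
        b = win.MicroclimateBin("mid", 50, 600, 13, 18, 0.05, 1.5)
        got = len(win.subset_by_microclimate(df, b))
        brute = sum(1 for p, t, u in zip(df["par"], df["ta"], df["wind"])
                    if 50 <= p < 600 and 13 <= t < 18 and 0.05 <= u < 1.5)
        assert got == brute

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            win.MicroclimateBin("bad", 100, 100, 0, 1, 0, 1)


class TestCompareSpecies:
    @staticmethod
    def _two_species(rng, offset=1.5, leaf_sd=0.3, resid_sd=0.5,
                     n_leaves=6, n_obs=20):
        rows = []
        for sp, mu in (("a", 0.0), ("b", offset)):
            for leaf in range(n_leaves):
                loff = rng.normal(0, leaf_sd)
                for _ in range(n_obs):
                    rows.append({"species": sp, "leaf_id": f"{sp}{leaf}",
                                 "dt_obs": mu + loff + rng.normal(0, resid_sd)})
        return pd.DataFrame(rows)

    def test_recovers_true_offset_within_2se(self, rng):
        diff, se, p, fit = win.compare_species(self._two_species(rng))
        assert abs(diff - 1.5) < 2 * se
        assert p < 0.05

    def test_single_species_rejected(self, rng):
        df = self._two_species(rng)
        with pytest.raises(ValueError):
            win.compare_species(df[df["species"] == "a"])

    def test_single_leaf_per_species_rejected(self, rng):
        df = self._two_species(rng, n_leaves=1)
        with pytest.raises(ValueError):
            win.compare_species(df)

    def test_single_observation_per_leaf_still_returns(self, rng):
        df = self._two_species(rng, n_obs=1, n_leaves=8)
        diff, se, p, fit = win.compare_species(df)
        assert np.isfinite(diff) and np.isfinite(se)


class TestPseudoRSquared:
    class _MockFit:
        """Fit with known variance components for the closed-form check."""

        def __init__(self, exog, fe, var_re, scale):
            import types
            self.model = types.SimpleNamespace(exog=exog)
            self.fe_params = np.asarray(fe)
            self.cov_re = np.array([[var_re]])
            self.k_re = 1
            self.scale = scale

    def test_closed_form(self):
        x = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        fit = self._MockFit(x, [0.0, 2.0], var_re=0.5, scale=0.75)
        var_f = np.var(x @ np.array([0.0, 2.0]))  # = 1.0
        m, c = win.pseudo_r_squared(fit)
        assert m == pytest.approx(var_f / (var_f + 0.5 + 0.75))
        assert c == pytest.approx((var_f + 0.5) / (var_f + 0.5 + 0.75))

    def test_zero_random_variance_collapses_marginal_conditional(self):
        x = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        fit = self._MockFit(x, [0.0, 2.0], var_re=0.0, scale=0.75)
        m, c = win.pseudo_r_squared(fit)
        assert m == pytest.approx(c)

    def test_zero_fixed_variance_gives_zero_marginal(self):
        x = np.ones((8, 1))
        fit = self._MockFit(x, [3.0], var_re=0.5, scale=0.75)
        m, c = win.pseudo_r_squared(fit)
        assert m == 0.0 and 0 < c < 1

    def test_ordering_on_real_fit(self, rng):
        df = TestCompareSpecies._two_species(rng)
        *_, fit = win.compare_species(df)
        m, c = win.pseudo_r_squared(fit)
        assert 0 <= m <= c <= 1


class TestDailySummaries:
    def test_symmetric_series_has_near_zero_skew(self, rng):
        n = 10_000
        df = pd.DataFrame({
            "time": pd.date_range("2016-10-01", periods=n, freq="10s"),
            "leaf_id": "L1", "par": 100.0, "dt_obs": rng.normal(0, 1, n)})
        out = win.daily_summaries(df)
        assert abs(out["dt_obs_skew"].iloc[0]) < 0.05

    def test_constant_series_reports_missing_skew(self):
        df = pd.DataFrame({"time": pd.date_range("2016-10-01", periods=10,
                                                 freq="10s"),
                           "leaf_id": "L1", "par": 100.0, "dt_obs": 1.5})
        out = win.daily_summaries(df)
        row = out.iloc[0]
        assert row["dt_obs_min"] == row["dt_obs_mean"] == row["dt_obs_max"]
        assert np.isnan(row["dt_obs_skew"])

    def test_exponential_tail_matches_brute_force_skewness(self, rng):
        v = rng.exponential(1.0, 5000)
        df = pd.DataFrame({"time": pd.date_range("2016-10-01", periods=5000,
                                                 freq="10s"),
                           "leaf_id": "L1", "par": 100.0, "dt_obs": v})
        out = win.daily_summaries(df)
        n = len(v)
        m = v.mean()
        g1 = (np.sum((v - m) ** 3) / n) / (np.sum((v - m) ** 2) / n) ** 1.5
        adj = g1 * np.sqrt(n * (n - 1)) / (n - 2)  # adjusted Fisher-Pearson
        assert out["dt_obs_skew"].iloc[0] == pytest.approx(adj, rel=1e-9)
        assert out["dt_obs_skew"].iloc[0] > 1.5

    def test_day_night_split_by_par(self, rng):
        n = 200
        df = pd.DataFrame({
            "time": pd.date_range("2016-10-01", periods=n, freq="10s"),
            "leaf_id": "L1",
            "par": np.r_[np.zeros(100), np.full(100, 800.0)],
            "dt_obs": np.r_[np.full(100, -0.2), np.full(100, 2.0)]})
        out = win.daily_summaries(df)
        day = out[out["period"] == "day"].iloc[0]
        night = out[out["period"] == "night"].iloc[0]
        assert day["dt_obs_mean"] == pytest.approx(2.0)
        assert night["dt_obs_mean"] == pytest.approx(-0.2)


class TestRegressionThroughOrigin:
    def test_exact_identity(self):
        x = np.linspace(1, 10, 50)
        slope, (lo, hi) = win.regression_through_origin(x, x)
        assert slope == pytest.approx(1.0)
        assert hi - lo < 1e-9

    def test_ci_excludes_unity_for_attenuated_slope(self, rng):
        x = rng.uniform(0, 10, 5000)
        y = 0.91 * x + rng.normal(0, 0.3, 5000)
        slope, (lo, hi) = win.regression_through_origin(x, y)
        assert lo < 0.91 < hi or abs(slope - 0.91) < 0.02
        assert hi < 1.0

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            win.regression_through_origin(np.zeros(10), np.ones(10))


def test_balanced_par_subsample_caps_dim_bins(rng):
    df = pd.DataFrame({"par": np.r_[rng.uniform(0, 250, 3000),
                                    rng.uniform(1200, 1500, 50)]})
    out = win.balanced_par_subsample(df, rng, n_per_bin=500)
    assert (out["par"] < 250).sum() == 500
    assert (out["par"] >= 1200).sum() == 50
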