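"""Fixed-effects estimator: demeaning, oracle equivalence, inference."""

import numpy as np
import pandas as pd
import pytest

from heatspeech.meteo import BinScheme, add_weather_features
from heatspeech.panel import (
    ConvergenceError,
    PanelDesign,
    assign_age_quartile,
    assign_period,
    build_design,
    cluster_robust_vcov,
    demean_multiway,
    fit_fe_ols,
    fit_interaction,
)
from heatspeech.synthetic import SimConfig, simulate_panel

from conftest import dense_dummy_ols, random_panel


class TestDemeaning:
    def test_single_dimension_exact(self):
        out, iters, conv = demean_multiway(
            np.array([1.0, 2.0, 3.0, 5.0]), [np.array([0, 0, 1, 1])]
        )
        np.testing.assert_allclose(out, [-0.5, 0.5, -1.0, 1.0])
        assert conv and iters == 1

    def test_nested_dimensions_equal_finer_alone(self):
        rng = np.random.default_rng(1)
        fine = rng.integers(0, 12, 300)
        coarse = fine // 4  # nested coarsening
        y = rng.normal(size=300)
        both, _, _ = demean_multiway(y, [coarse, fine])
        fine_only, _, _ = demean_multiway(y, [fine])
        np.testing.assert_allclose(both, fine_only, atol=1e-10)

    def test_group_means_below_tolerance(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(500, 3))
        groups = [rng.integers(0, k, 500) for k in (17, 9, 5)]
        out, _, conv = demean_multiway(M, groups, tol=1e-12)
        assert conv
        for g in groups:
            for j in range(3):
                means = np.bincount(g, weights=out[:, j]) / np.bincount(g)
                assert np.max(np.abs(means)) < 1e-10

    def test_nonconvergence_raises_with_residual(self):
        rng = np.random.default_rng(3)
        groups = [rng.integers(0, 40, 200), rng.integers(0, 40, 200)]
        with pytest.raises(ConvergenceError) as exc:
            demean_multiway(rng.normal(size=200), groups, tol=1e-14, max_iter=1)
        assert exc.value.residual > 0

    def test_frisch_waugh_consistency(self):
        """Demeaning only y and regressing on demeaned X equals demeaning both."""
        rng = np.random.default_rng(4)
        design, _ = random_panel(rng, n=400)
        groups = list(design.fe_codes.values())
        yd, _, _ = demean_multiway(design.y, groups, tol=1e-12)
        Xd, _, _ = demean_multiway(design.X, groups, tol=1e-12)
        b_both, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
        y_only, _, _ = demean_multiway(design.y, groups, tol=1e-12)
        b_mixed, *_ = np.linalg.lstsq(Xd, y_only, rcond=None)
        np.testing.assert_allclose(b_both, b_mixed, rtol=1e-9)


class TestOracleEquivalence:
    def test_coefficients_match_dense_dummy_ols(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            design, _ = random_panel(rng)
            est = fit_fe_ols(design)
            dense = dense_dummy_ols(design)
            np.testing.assert_allclose(est.beta.to_numpy(), dense, rtol=1e-8)

    def test_clustered_se_match_statsmodels_on_dense_dummies(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        design, _ = random_panel(rng, n=600)
        est = fit_fe_ols(design)
        blocks = [design.X]
        first = True
        for name, codes in design.fe_codes.items():
            d = np.equal.outer(codes, np.arange(design.fe_levels[name])).astype(float)
            blocks.append(d if first else d[:, 1:])
            first = False
        D = np.column_stack(blocks)
        m = sm.OLS(design.y, D).fit(
            cov_type="cluster", cov_kwds={"groups": design.cluster_codes}
        )
        np.testing.assert_allclose(
            est.se.to_numpy(), m.bse[: design.X.shape[1]], rtol=1e-6
        )


class TestClusterRobustVcov:
    def test_singleton_clusters_reduce_to_hc1(self):
        rng = np.random.default_rng(20)
        n, k = 300, 4
        X = rng.normal(size=(n, k))
        e = rng.normal(size=n)
        V = cluster_robust_vcov(X, e, np.arange(n), n, df_model=k)
        bread = np.linalg.inv(X.T @ X)
        hc1 = (n / (n - k)) * bread @ (X * e[:, None] ** 2).T @ X @ bread
        np.testing.assert_allclose(V, hc1, rtol=1e-10)

    def test_iid_errors_clustered_ses_approach_iid_ses(self):
        """With iid errors and many clusters the two SEs agree on average."""
        rng = np.random.default_rng(21)
        ratios = []
        for _ in range(30):
            n = 2000
            X = rng.normal(size=(n, 2))
            e = rng.normal(size=n)
            clusters = rng.integers(0, 100, n)
            Vc = cluster_robust_vcov(X, e, clusters, 100, df_model=2)
            Vh = cluster_robust_vcov(X, e, np.arange(n), n, df_model=2)
            ratios.append(np.sqrt(np.diag(Vc) / np.diag(Vh)))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_psd_and_symmetric(self):
        rng = np.random.default_rng(22)
        design, _ = random_panel(rng, n=500)
        est = fit_fe_ols(design)
        V = est.vcov.to_numpy()
        np.testing.assert_allclose(V, V.T)
        assert np.min(np.linalg.eigvalsh(V)) > -1e-12

    def test_single_cluster_rejected(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(50, 2))
        with pytest.raises(ValueError):
            cluster_robust_vcov(X, rng.normal(size=50), np.zeros(50, dtype=int), 1, 2)

    def test_ci_width_uses_normal_critical_value(self):
        rng = np.random.default_rng(24)
        design, _ = random_panel(rng, n=400)
        est = fit_fe_ols(design)
        width = (est.ci_high - est.ci_low).to_numpy()
        np.testing.assert_allclose(width, 2 * 1.96 * est.se.to_numpy(), rtol=1e-3)


class TestRecovery:
    def test_zero_noise_recovers_injected_effects_exactly(self, zero_noise_fit=None):
        cfg = SimConfig(
            n_politicians=20,
            cities=("Arlen", "Bergsee", "Corvale", "Dunmere"),
            start="2010-01-01",
            end="2010-12-31",
            speeches_per_sitting_day=3.0,
            noise_sd=0.0,
            intra_cluster_rho=0.0,
            seed=7,
        )
        speeches, weather, truth = simulate_panel(cfg)
        feats = add_weather_features(weather, cfg.scheme())
        design, _ = build_design(speeches, feats, cfg.scheme())
        est = fit_fe_ols(design)
        for lab, b in truth.bin_effects.items():
            if lab in est.beta.index:
                assert est.beta[lab] == pytest.approx(b, abs=1e-8)
        for name, g in truth.control_effects.items():
            assert est.beta[name] == pytest.approx(g, abs=1e-8)

    def test_estimate_within_sampling_error_on_noisy_panel(self, small_bundle, small_features):
        speeches, _, truth = small_bundle
        design, _ = build_design(speeches, small_features, BinScheme.full_10bin())
        est = fit_fe_ols(design)
        for lab, b in truth.bin_effects.items():
            if lab in est.beta.index:
                assert abs(est.beta[lab] - b) < 4 * est.se[lab]

    def test_permutation_null_kills_exposure_effects(self, small_bundle):
        """Shuffling bin labels across days within city breaks the exposure link."""
        speeches, weather, _ = small_bundle
        feats = add_weather_features(weather, BinScheme.full_10bin())
        rng = np.random.default_rng(99)
        rejections, total = 0, 0
        for _ in range(25):
            perm = feats.copy()
            perm["temp_bin"] = (
                perm.groupby("city")["temp_bin"]
                .transform(lambda s: s.sample(frac=1.0, random_state=rng.integers(2**31)).to_numpy())
            )
            design, _ = build_design(speeches, perm, BinScheme.full_10bin())
            est = fit_fe_ols(design)
            bins = [c for c in design.exposure_cols if c in est.beta.index]
            z = (est.beta[bins] / est.se[bins]).to_numpy()
            rejections += int(np.sum(np.abs(z) > 1.96))
            total += len(z)
        assert 0.0 <= rejections / total < 0.15


class TestInteraction:
    @staticmethod
    def _gender_design(noise_sd=0.0, seed=5):
        cfg = SimConfig(
            n_politicians=24,
            cities=("Arlen", "Bergsee", "Corvale", "Dunmere"),
            start="2010-01-01",
            end="2010-12-31",
            speeches_per_sitting_day=3.0,
            noise_sd=noise_sd,
            intra_cluster_rho=0.0,
            with_demographics=True,
            p_female=0.4,
            seed=seed,
        )
        speeches, weather, truth = simulate_panel(cfg)
        feats = add_weather_features(weather, cfg.scheme())
        # inject level-specific effects on top of the shared bin effects
        joined = speeches.merge(
            feats[["city", "date", "temp_bin"]].assign(
                date=feats["date"].dt.strftime("%Y-%m-%d")
            ),
            on=["city", "date"],
        )
        bump = {("18-21", "F"): -0.10, (">27", "F"): -0.20}
        extra = np.array(
            [
                bump.get((b, g), 0.0)
                for b, g in zip(joined["temp_bin"], joined["gender"])
            ]
        )
        joined["flesch_kincaid"] = joined["flesch_kincaid"] + extra
        joined = joined.drop(columns=["temp_bin"])
        design, _ = build_design(
            joined, feats, BinScheme.full_10bin(), cluster_scheme="politician"
        )
        demo = joined["gender"].to_numpy()
        return design, demo, truth, bump

    def test_zero_noise_level_specific_effects_recovered_exactly(self):
        design, demo, truth, bump = self._gender_design()
        est, me = fit_interaction(design, demo)
        for (b, g), extra in bump.items():
            expected = truth.bin_effects[b] + extra
            row = me[(me["bin"] == b) & (me["level"] == g)].iloc[0]
            assert row["estimate"] == pytest.approx(expected, abs=1e-8)
        # a male cell keeps the shared effect only
        row = me[(me["bin"] == ">27") & (me["level"] == "M")].iloc[0]
        assert row["estimate"] == pytest.approx(truth.bin_effects[">27"], abs=1e-8)

    def test_minority_level_has_wider_intervals(self):
        design, demo, _, _ = self._gender_design(noise_sd=1.0, seed=6)
        est, me = fit_interaction(design, demo)
        ok = me[~me["missing"]]
        assert (
            ok[ok["level"] == "F"]["se"].mean() > ok[ok["level"] == "M"]["se"].mean()
        )

    def test_single_level_reduces_to_plain_fit(self):
        design, demo, _, _ = self._gender_design()
        est_plain = fit_fe_ols(design)
        est_one, me = fit_interaction(design, np.full(design.n_obs, "M", dtype=object))
        pd.testing.assert_series_equal(est_plain.beta, est_one.beta)

    def test_empty_cell_reported_missing(self):
        rng = np.random.default_rng(30)
        n = 400
        hot = (np.arange(n) % 4 == 0).astype(float)
        demo = np.where(np.arange(n) % 2 == 0, "A", "B").astype(object)
        demo[hot == 1] = "A"  # level B never experiences the hot bin
        f1 = rng.integers(0, 10, n)
        f2 = rng.integers(0, 4, n)
        y = -0.5 * hot + rng.normal(size=n)
        design = PanelDesign(
            y=y, X=hot[:, None], colnames=["hot"], fe={"f1": f1, "f2": f2},
            clusters=rng.integers(0, 20, n), exposure_cols=["hot"],
        )
        est, me = fit_interaction(design, demo, speaker_fe="none")
        row = me[(me["bin"] == "hot") & (me["level"] == "B")].iloc[0]
        assert bool(row["missing"]) and np.isnan(row["estimate"])

    def test_varying_trait_rejected_when_declared_constant(self):
        design, demo, _, _ = self._gender_design()
        bad = demo.copy()
        bad[0] = "F" if bad[0] == "M" else "M"
        with pytest.raises(ValueError, match="speaker-constant"):
            fit_interaction(design, bad)


class TestDemographicGroupers:
    @pytest.mark.parametrize(
        "age,q",
        [(19, "Q1"), (44, "Q1"), (45, "Q2"), (50, "Q2"), (51, "Q3"), (56, "Q3"), (57, "Q4"), (80, "Q4")],
    )
    def test_age_quartiles(self, age, q):
        assert assign_age_quartile(age) == q

    def test_age_missing_and_invalid(self):
        assert assign_age_quartile(np.nan) is None
        with pytest.raises(ValueError):
            assign_age_quartile(17)

    @pytest.mark.parametrize(
        "year,label",
        [(1950, "1950-1967"), (1967, "1950-1967"), (1968, "1968-1985"),
         (1986, "1986-2003"), (2004, "2004-2019"), (2019, "2004-2019")],
    )
    def test_periods(self, year, label):
        assert assign_period(year) == label

    @pytest.mark.parametrize("year", [1949, 2020])
    def test_period_out_of_span(self, year):
        with pytest.raises(ValueError):
            assign_period(year)


class TestBuildDesign:
    @staticmethod
    def _toy(n=10, missing_weather_for=None):
        dates = pd.date_range("2010-06-01", periods=n)
        speeches = pd.DataFrame(
            {
                "speech_id": [f"s{i}" for i in range(n)],
                "speaker_id": [f"p{i % 3}" for i in range(n)],
                "city": "Arlen",
                "date": dates.strftime("%Y-%m-%d"),
                "flesch_kincaid": np.linspace(10, 12, n),
            }
        )
        wdates = dates if missing_weather_for is None else dates.delete(missing_weather_for)
        weather = pd.DataFrame(
            {
                "city": "Arlen",
                "date": wdates,
                "t_mean": np.linspace(10, 30, len(wdates)),
                "t_dew": np.linspace(5, 20, len(wdates)),
                "precip": 1.0,
                "u_wind": 1.0,
                "v_wind": 2.0,
            }
        )
        return speeches, add_weather_features(weather)

    def test_unjoined_speech_logged_and_dropped(self):
        speeches, feats = self._toy(missing_weather_for=3)
        # second FE dims need >=2 levels: extend with a second city block
        sp2, wx2 = self._toy()
        sp2["city"] = "Bergsee"
        sp2["speech_id"] = sp2["speech_id"] + "b"
        wx2["city"] = "Bergsee"
        design, log = build_design(
            pd.concat([speeches, sp2], ignore_index=True),
            pd.concat([feats, wx2], ignore_index=True),
            BinScheme.full_10bin(),
        )
        assert log["unjoined"] == 1
        assert log["estimated"] == 19
        assert log["read"] == 20

    def test_comfort_day_has_all_zero_dummies(self):
        scheme = BinScheme.full_10bin()
        speeches, feats = self._toy()
        feats["temp_bin"] = scheme.assign(np.full(len(feats), 15.0))
        sp2, wx2 = self._toy()
        sp2["city"], wx2["city"] = "Bergsee", "Bergsee"
        sp2["speech_id"] = sp2["speech_id"] + "b"
        wx2["temp_bin"] = scheme.assign(np.linspace(-5, 30, len(wx2)))
        design, _ = build_design(
            pd.concat([speeches, sp2], ignore_index=True),
            pd.concat([feats, wx2], ignore_index=True),
            scheme,
        )
        arlen = np.asarray(design.fe["month_city"]).astype(str)
        mask = np.char.startswith(arlen, "Arlen")
        exp_idx = [design.colnames.index(c) for c in design.exposure_cols]
        assert np.all(design.X[np.ix_(mask, exp_idx)] == 0.0)

    def test_hot_day_sets_only_top_bin(self):
        scheme = BinScheme.full_10bin()
        speeches, feats = self._toy(n=40)  # spans two months -> 2 FE levels
        feats28 = feats.copy()
        feats28.loc[0, "temp_bin"] = scheme.assign(28.0)
        design, _ = build_design(speeches, feats28, scheme)
        i = list(design.row_ids).index("s0")
        hot_col = design.colnames.index(">27")
        assert design.X[i, hot_col] == 1.0
        others = [design.colnames.index(c) for c in design.exposure_cols if c != ">27"]
        assert np.all(design.X[i, others] == 0.0)

    def test_collinear_column_dropped_and_reported(self):
        rng = np.random.default_rng(40)
        design, _ = random_panel(rng, n=300)
        X = np.column_stack([design.X, design.X[:, 0]])
        dup = PanelDesign(
            y=design.y, X=X, colnames=design.colnames + ["dup"],
            fe=design.fe, clusters=design.clusters,
        )
        est = fit_fe_ols(dup)
        assert est.dropped_columns == ["dup"] or "dup" in est.dropped_columns

    def test_fe_dimension_needs_two_levels(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            PanelDesign(
                y=np.zeros(4), X=np.ones((4, 1)), colnames=["x"],
                fe={"f": np.zeros(4, dtype=int)}, clusters=np.arange(4),
            )
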