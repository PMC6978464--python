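import numpy as np
import pandas as pd
import pytest

import braincomplexity as bc
from braincomplexity.cohort import METRICS


def latent_profiles(rng, n=30, noise=0.0):
    """Profiles where every metric is a (noisy) linear function of one latent."""
    latent = rng.standard_normal(n)
    rows = []
    for i in range(n):
        rows.append(
            {
                "subject_id": f"s{i}",
                "condition": "a" if i % 2 else "b",
                "lzc": -latent[i] + noise * rng.standard_normal(),
                "sampen": -2 * latent[i] + noise * rng.standard_normal(),
                "pca_n": -5 * latent[i] + noise * rng.standard_normal(),
                "hurst": latent[i] + noise * rng.standard_normal(),
                "higuchi": -0.5 * latent[i] + noise * rng.standard_normal(),
                "alg_conn": -100 * latent[i] + noise * rng.standard_normal(),
                "lz_graph": -1000 * latent[i] + noise * rng.standard_normal(),
            }
        )
    return pd.DataFrame(rows)


class TestComputeProfile:
    def test_all_fields_finite(self, small_profiles):
        assert np.isfinite(small_profiles[list(METRICS)].to_numpy()).all()

    def test_deterministic(self, small_cohort):
        _, scans, meta, _ = small_cohort
        row = meta.iloc[0]
        scan = scans[(row.subject_id, row.condition)]
        p1 = bc.compute_profile(scan, row.subject_id, row.condition)
        p2 = bc.compute_profile(scan, row.subject_id, row.condition)
        assert p1 == p2

    def test_deep_vs_awake_sign_pattern(self, small_profiles):
        means = small_profiles.groupby("condition")[list(METRICS)].mean()
        delta = means.loc["deep"] - means.loc["awake"]
        assert delta["hurst"] > 0
        for name in ("lzc", "sampen", "pca_n", "higuchi", "alg_conn", "lz_graph"):
            assert delta[name] < 0, name


class TestMetricCorrelationMatrix:
    def test_perfect_collinearity(self, rng):
        corr = bc.metric_correlation_matrix(latent_profiles(rng))
        off = corr.to_numpy()[~np.eye(7, dtype=bool)]
        assert np.allclose(np.abs(off), 1.0)

    def test_diagonal_masked(self, rng):
        corr = bc.metric_correlation_matrix(latent_profiles(rng, noise=0.5))
        assert np.isnan(np.diag(corr)).all()

    def test_independent_noise_metric_uncorrelated(self, rng):
        df = latent_profiles(rng, n=400, noise=0.1)
        df["lz_graph"] = rng.standard_normal(len(df))  # replace with pure noise
        corr = bc.metric_correlation_matrix(df)
        assert abs(corr.loc["lz_graph", "lzc"]) < 0.2

    def test_cohort_sign_pattern(self, small_profiles):
        corr = bc.metric_correlation_matrix(small_profiles)
        assert corr.loc["hurst", "lzc"] < 0
        assert corr.loc["hurst", "sampen"] < 0
        assert corr.loc["lzc", "sampen"] > 0

    def test_too_few_profiles_rejected(self, rng):
        with pytest.raises(ValueError):
            bc.metric_correlation_matrix(latent_profiles(rng, n=3))


class TestOverallComplexityPca:
    def test_rank_one_explains_everything(self, rng):
        out = bc.overall_complexity_pca(latent_profiles(rng))
        assert out["pc1_variance_explained"] == pytest.approx(1.0)

    def test_iid_metrics_explain_little(self, rng):
        fractions = []
        for s in range(20):
            r = np.random.default_rng(s)
            df = latent_profiles(r, n=30)
            for m in METRICS:
                df[m] = r.standard_normal(30)
            fractions.append(bc.overall_complexity_pca(df)["pc1_variance_explained"])
        assert max(fractions) < 0.45

    def test_orientation_convention(self, rng):
        out = bc.overall_complexity_pca(latent_profiles(rng, noise=0.3))
        assert out["pc1_loadings"]["lzc"] < 0

    def test_invariant_to_rescaling_any_metric(self, rng):
        df = latent_profiles(rng, noise=0.5)
        base = bc.overall_complexity_pca(df)["pc1_variance_explained"]
        for m in METRICS:
            scaled = df.copy()
            scaled[m] = scaled[m] * 1000.0
            out = bc.overall_complexity_pca(scaled)["pc1_variance_explained"]
            assert out == pytest.approx(base, abs=1e-12)

    def test_constant_metric_column_masked_with_warning(self, rng):
        df = latent_profiles(rng, noise=0.5)
        df["pca_n"] = 7.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = bc.overall_complexity_pca(df)
        assert out["pc1_loadings"]["pca_n"] == 0.0
        assert 0 < out["pc1_variance_explained"] <= 1

    def test_invariant_to_sign_flip_of_hurst(self, rng):
        df = latent_profiles(rng, noise=0.5)
        base = bc.overall_complexity_pca(df)["pc1_variance_explained"]
        flipped = df.copy()
        flipped["hurst"] = -flipped["hurst"]
        out = bc.overall_complexity_pca(flipped)["pc1_variance_explained"]
        assert out == pytest.approx(base, abs=1e-12)


class TestGroupComparison:
    def test_identical_values_no_signal(self):
        df = pd.DataFrame(
            {
                "value": [1.0] * 12,
                "label": ["a", "b", "c"] * 4,
                "subject": [f"s{i // 3}" for i in range(12)],
            }
        )
        out = bc.group_comparison(df["value"], df["label"], df["subject"])
        assert out["omnibus"]["H"] == 0.0 and out["omnibus"]["p"] == 1.0
        assert all(t["p"] == 1.0 for t in out["pairwise"].values())

    def test_exact_signed_rank_enumeration(self):
        # 8 paired subjects, all differences positive: W = 0, p = 2 / 2^8
        drug = [1, 2, 3, 4, 5, 6, 7, 8]
        ctrl = [d - delta for d, delta in zip(drug, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])]
        values = pd.Series(drug + ctrl, dtype=float)
        labels = pd.Series(["drug"] * 8 + ["ctrl"] * 8)
        subjects = pd.Series([f"s{i}" for i in range(8)] * 2)
        out = bc.group_comparison(values, labels, subjects)
        test = out["pairwise"][("drug", "ctrl")]
        assert test["W"] == 0.0
        assert test["p"] == pytest.approx(2 * 0.5**8)

    def test_wilcoxon_exact_matches_full_enumeration(self, rng):
        from itertools import product
        from scipy.stats import rankdata

        diffs = rng.standard_normal(10)
        out = bc.cohort.group_comparison(
            pd.Series(np.concatenate([diffs, np.zeros(10)])),
            pd.Series(["a"] * 10 + ["b"] * 10),
            pd.Series([f"s{i}" for i in range(10)] * 2),
        )
        w_obs, p_obs = (
            out["pairwise"][("a", "b")]["W"],
            out["pairwise"][("a", "b")]["p"],
        )
        ranks = rankdata(np.abs(diffs))
        stats = []
        for signs in product([0, 1], repeat=10):
            w_plus = sum(r for r, s in zip(ranks, signs) if s)
            w_minus = ranks.sum() - w_plus
            stats.append(min(w_plus, w_minus))
        p_exact = np.mean([s <= w_obs for s in stats])
        assert p_obs == pytest.approx(p_exact, abs=1e-12)

    def test_unpaired_subject_dropped_with_warning(self):
        values = pd.Series([1.0, 2, 3, 4, 5, 1, 2, 3, 4])
        labels = pd.Series(["a"] * 5 + ["b"] * 4)
        subjects = pd.Series([f"s{i}" for i in range(5)] + [f"s{i}" for i in range(4)])
        with pytest.warns(RuntimeWarning):
            out = bc.group_comparison(values, labels, subjects)
        assert out["pairwise"][("a", "b")]["n"] == 4


class TestDoseCorrelation:
    def test_exact_linear_function(self):
        dose = pd.Series([100.0, 200, 300, 400, 500])
        r, p = bc.dose_correlation(-0.01 * dose + 3, dose)
        assert r == pytest.approx(-1.0)

    def test_independent_values_null(self):
        rs = []
        for s in range(50):
            rng = np.random.default_rng(s)
            dose = pd.Series(rng.uniform(100, 900, 20))
            vals = pd.Series(rng.standard_normal(20))
            rs.append(bc.dose_correlation(vals, dose)[0])
        assert abs(np.mean(rs)) < 0.1

    def test_constant_dose_rejected(self):
        with pytest.raises(ValueError):
            bc.dose_correlation(pd.Series([1.0, 2, 3, 4]), pd.Series([5.0, 5, 5, 5]))

    def test_cohort_dose_signs(self, small_profiles):
        sedated = small_profiles[small_profiles["dose"] > 0]
        if len(sedated) >= 4 and sedated["dose"].nunique() > 1:
            r_lzc, _ = bc.dose_correlation(sedated["lzc"], sedated["dose"])
            r_hurst, _ = bc.dose_correlation(sedated["hurst"], sedated["dose"])
            assert r_lzc < 0 < r_hurst


class TestAnalyseCohort:
    def test_full_report_on_synthetic_cohort(self, small_profiles):
        result = bc.analyse_cohort(small_profiles)
        assert 0 < result.pc1_variance_explained <= 1
        assert set(result.omnibus_tests) == set(METRICS) | {"overall"}
        assert result.metric_correlations.shape == (7, 7)
        assert len(result.pc1_scores) == len(small_profiles)
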