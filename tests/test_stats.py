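"""Cohort statistics: oracles, worked values, and recovery simulations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from trabkit import (
    CohortSpec,
    coefficient_of_variation,
    correlation_matrix,
    dunn_posthoc,
    estimate_log_body_mass,
    kruskal_wallis,
    pca,
    run_cohort_analysis,
    scaling_regression,
    simulate_cohort,
    stereographic_projection,
)


class TestBodyMass:
    def test_log_linear_form(self):
        assert estimate_log_body_mass(10.0, (1.0, 0.0)) == pytest.approx(1.0)
        assert estimate_log_body_mass(123.0, (0.0, 0.75)) == pytest.approx(0.75)

    def test_two_element_mean(self):
        # one circumference giving 0.6 and one giving 0.8 average to 0.7
        a, b = 1.0, 0.0
        c1, c2 = 10 ** 0.6, 10 ** 0.8
        assert estimate_log_body_mass([c1, c2], (a, b)) == pytest.approx(0.7)

    def test_missing_coefficients_refused(self):
        with pytest.raises(ValueError, match="coefficients"):
            estimate_log_body_mass(10.0, None)


class TestCoefficientOfVariation:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([3.3, 3.3, 3.3]) == pytest.approx(0.0, abs=1e-9)

    def test_hand_worked_value(self):
        assert coefficient_of_variation([2, 4, 6]) == pytest.approx(50.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, c):
        base = np.array([2.0, 4.0, 6.0, 9.0])
        assert coefficient_of_variation(c * base) == pytest.approx(
            coefficient_of_variation(base), rel=1e-9)

    def test_cohort_cv_recovery(self):
        # 2-month humeral anisotropy dispersion (CV 22.1) recovered by simulation
        cvs = []
        for seed in range(300):
            t = simulate_cohort(CohortSpec(seed=seed))
            g = t[(t.element == "humerus") & (t.age_group == "2mo")]["da"]
            cvs.append(coefficient_of_variation(g))
        assert abs(np.mean(cvs) - 22.1) / 22.1 < 0.15


class TestCorrelation:
    def test_perfect_linear_dependence(self):
        x = np.arange(10.0)
        tab = pd.DataFrame({"x": x, "y": 2 * x})
        r, _ = correlation_matrix(tab)
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_hand_worked_r(self):
        tab = pd.DataFrame({"x": [1, 2, 3, 1, 2, 3], "y": [1, 3, 2, 1, 3, 2]})
        r, _ = correlation_matrix(tab)
        assert r.loc["x", "y"] == pytest.approx(0.5)

    def test_pearson_matches_covariance_definition(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        r, _ = correlation_matrix(tab)
        x = tab.to_numpy()
        for i, j in itertools.combinations(range(4), 2):
            cov = np.cov(x[:, i], x[:, j])
            expect = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
            assert r.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_partial_matches_residualization_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        z = x + y + 0.05 * rng.normal(size=60)
        tab = pd.DataFrame({"x": x, "y": y, "z": z})
        r, _ = correlation_matrix(tab, mode="partial")
        # brute force: correlate residuals of x|z and y|z
        def resid(v, w):
            beta = np.polyfit(w, v, 1)
            return v - np.polyval(beta, w)
        expect = np.corrcoef(resid(x, z), resid(y, z))[0, 1]
        assert r.loc["x", "y"] == pytest.approx(expect, abs=1e-8)
        assert r.loc["x", "y"] < -0.9


class TestPCA:
    def test_single_varying_column_concentrates_pc1(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame({"a": rng.normal(size=30), "b": np.full(30, 2.0),
                            "c": np.full(30, -1.0)})
        res = pca(tab)
        assert res["explained_ratio"]["PC1"] == pytest.approx(1.0)
        assert abs(res["loadings"].loc["a", "PC1"]) == pytest.approx(1.0)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
        res = pca(tab)
        recon = res["scores"].to_numpy() @ res["loadings"].to_numpy().T \
            + res["means"].to_numpy()
        np.testing.assert_allclose(recon, tab.to_numpy(), atol=1e-9)
        ev = res["explained_variance"].to_numpy()
        assert np.all(np.diff(ev) <= 1e-12)

    def test_raw_azimuth_refused(self):
        tab = pd.DataFrame({"azimuth": [1.0, 2, 3], "x": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="folded"):
            pca(tab)

    def test_constant_column_with_scaling_fails(self):
        tab = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        with pytest.raises(ValueError, match="constant"):
            pca(tab, scale=True)

    def test_cotrending_variables_dominate_pc1(self):
        # a shared latent trend across logbm, da, plunge mirrors the
        # ontogenetic signal: those columns take the top PC1 loadings
        rng = np.random.default_rng(4)
        latent = rng.normal(size=80)
        tab = pd.DataFrame({
            "logbm": latent + 0.1 * rng.normal(size=80),
            "da": latent + 0.1 * rng.normal(size=80),
            "plunge": latent + 0.1 * rng.normal(size=80),
            "tbn": 0.2 * rng.normal(size=80),
            "tbsp": 0.2 * rng.normal(size=80),
        })
        res = pca(tab)
        top3 = res["loadings"]["PC1"].abs().nlargest(3).index
        assert set(top3) == {"logbm", "da", "plunge"}


def brute_force_kruskal(groups):
    """Hand implementation: midranks, rank-sum H, tie correction."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    n_total = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - ((counts ** 3 - counts).sum()) / (n_total ** 3 - n_total)
    return h / correction


class TestKruskalWallis:
    def test_hand_worked_h(self):
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)

    def test_all_tied_returns_null(self):
        assert kruskal_wallis([[5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            kruskal_wallis([[1, 2], []])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            sizes = rng.integers(3, 8, size=rng.integers(2, 5))
            groups = [rng.integers(0, 6, size=s).astype(float) for s in sizes]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(brute_force_kruskal(groups), abs=1e-10)


def brute_force_dunn_z(groups):
    """Hand formula: z_ij with tie term T = sum(t^3-t)/(12(N-1))."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, start = [], 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie = ((counts ** 3 - counts).sum()) / (12.0 * (n_total - 1))
    out = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie)
                     * (1 / len(groups[i]) + 1 / len(groups[j])))
        out[(i, j)] = (mean_ranks[i] - mean_ranks[j]) / se
    return out


class TestDunn:
    def test_identical_groups_give_null_z(self):
        out = dunn_posthoc([[1, 2, 3], [1, 2, 3]], omnibus_p=None)
        assert out["z"].iloc[0] == pytest.approx(0.0)
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_no_tie_hand_formula(self):
        groups = [[1.0, 2, 3], [4.0, 5, 6], [7.0, 8, 9]]
        out = dunn_posthoc(groups, omnibus_p=0.01)
        expect = brute_force_dunn_z([np.asarray(g) for g in groups])
        for _, row in out.iterrows():
            assert row["z"] == pytest.approx(expect[(row["group_i"], row["group_j"])],
                                             abs=1e-10)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            sizes = rng.integers(3, 9, size=rng.integers(2, 6))
            groups = [rng.integers(0, 5, size=s).astype(float) for s in sizes]
            out = dunn_posthoc(groups, omnibus_p=None)
            expect = brute_force_dunn_z(groups)
            for _, row in out.iterrows():
                assert row["z"] == pytest.approx(
                    expect[(row["group_i"], row["group_j"])], abs=1e-10)

    def test_bonferroni_definition(self):
        groups = [[1.0, 2, 3], [2.0, 3, 4], [5.0, 6, 7], [1.0, 5, 9], [2.0, 2, 8]]
        out = dunn_posthoc(groups, adjustment="bonferroni", omnibus_p=None)
        m = len(out)
        assert m == 10
        np.testing.assert_allclose(out["p_adjusted"],
                                   np.minimum(1.0, out["p_raw"] * m))

    def test_refused_without_significant_omnibus(self):
        with pytest.raises(ValueError, match="refused"):
            dunn_posthoc([[1, 2, 3], [1, 2, 3]], omnibus_p=0.8)


class TestScalingRegression:
    def test_noise_free_quadratic_selects_degree_two(self):
        x = np.linspace(0, 2, 40)
        y = 1.0 + 0.5 * x - 0.8 * x ** 2
        fit = scaling_regression(x, y, k=5, seed=0)
        assert fit.chosen_degree == 2
        pred = np.polyval(fit.poly_coefficients, x)
        assert np.mean((pred - y) ** 2) < 1e-16

    def test_isometric_slope_recovered_within_ci(self):
        rng = np.random.default_rng(8)
        logm = rng.uniform(0.3, 1.2, size=50)
        logy = -1.0 + logm / 3.0 + rng.normal(0, 0.02, size=50)
        fit = scaling_regression(logm, logy, isometric_reference=1 / 3, seed=0)
        assert fit.slope_ci[0] <= 0.33 <= fit.slope_ci[1]
        assert fit.isometry_rejected is False

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            scaling_regression(np.arange(5.0), np.arange(5.0), k=10)


class TestStereographicProjection:
    def test_vertical_plots_at_center(self):
        px, py = stereographic_projection(123.0, 90.0)
        assert float(px) == pytest.approx(0.0, abs=1e-12)
        assert float(py) == pytest.approx(0.0, abs=1e-12)

    def test_horizontal_north_on_unit_circle(self):
        px, py = stereographic_projection(0.0, 0.0)
        assert float(px) == pytest.approx(0.0, abs=1e-12)
        assert float(py) == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_azimuths_oppose(self):
        p1 = np.array(stereographic_projection(30.0, 0.0))
        p2 = np.array(stereographic_projection(210.0, 0.0))
        np.testing.assert_allclose(p1, -p2, atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0, max_value=359.99), st.floats(min_value=0, max_value=90))
    def test_points_stay_in_unit_disk(self, az, pl):
        px, py = stereographic_projection(az, pl)
        assert np.hypot(px, py) <= 1.0 + 1e-12


class TestCohortAnalysis:
    def test_identical_groups_trigger_no_posthoc(self):
        spec = CohortSpec(seed=5)
        for element in spec.means:
            for metric in spec.means[element]:
                spec.means[element][metric] = [spec.means[element][metric][0]] * 5
                spec.cvs[element][metric] = [0.0] * 5
        spec.logbm_means = [0.8] * 5
        spec.logbm_cvs = [0.0] * 5
        table = simulate_cohort(spec)
        # orientation draws are continuous; pin them for a fully degenerate null
        table["azimuth"] = 45.0
        table["plunge"] = 45.0
        report = run_cohort_analysis(table, seed=1)
        assert (report["kruskal_wallis"]["p"] > 0.05).all()
        assert report["dunn"] == {}

    def test_default_cohort_report_is_complete(self):
        table = simulate_cohort(CohortSpec(seed=6))
        report = run_cohort_analysis(table, seed=2)
        assert set(report["regressions"]) == {"humerus", "femur"}
        for fits in report["regressions"].values():
            assert set(fits) == {"da", "bvtv", "tbth", "tbsp", "tbn"}
            for fit in fits.values():
                assert fit.chosen_degree in (1, 2, 3, 4)
        # group means in the report equal direct groupby means
        gm = report["group_means"]
        sub = table[table.element == "humerus"]
        direct = sub.groupby("age_group")["bvtv"].mean()
        got = gm[(gm.element == "humerus") & (gm.metric == "bvtv")] \
            .set_index("age_group")["mean"]
        for g in direct.index:
            assert got[g] == pytest.approx(direct[g], abs=1e-12)
        # ontogenetic signal is strong enough for the omnibus test to see
        kw = report["kruskal_wallis"]
        assert kw[(kw.element == "humerus") & (kw.metric == "tbsp")]["p"].iloc[0] < 0.05

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="missing columns"):
            run_cohort_analysis(pd.DataFrame({"specimen_id": [1]}))
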