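import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import array_shapes, arrays

from swemap import (
    classify_icc,
    icc_2_1,
    normalized_mehs,
    paired_t,
    regional_association,
    regional_contrast,
    regional_reliability,
    sem_measure,
    spearman_rho,
    two_way_mean_squares,
    whole_muscle_reliability,
)
from swemap.reliability import benjamini_hochberg
from swemap.simulate import CohortSpec, simulate_cohort


def anova_oracle(X):
    """Hand two-way ANOVA via explicit sums (independent of the library path)."""
    X = np.asarray(X, float)
    n, k = X.shape
    g = X.sum() / (n * k)
    ss_rows = sum(k * (X[i].mean() - g) ** 2 for i in range(n))
    ss_cols = sum(n * (X[:, j].mean() - g) ** 2 for j in range(k))
    ss_tot = sum((x - g) ** 2 for x in X.ravel())
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return ss_rows / (n - 1), ss_cols / (k - 1), mse


def icc_oracle(X):
    msr, msc, mse = anova_oracle(X)
    n, k = np.asarray(X).shape
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestTwoWayMeanSquares:
    def test_perfect_agreement_table(self):
        msr, msc, mse = two_way_mean_squares([[1, 1], [2, 2], [3, 3]])
        assert (msr, msc, mse) == (2.0, 0.0, 0.0)

    def test_constant_table_all_zero(self):
        assert two_way_mean_squares(np.full((4, 3), 2.5)) == (0.0, 0.0, 0.0)

    def test_column_shift_changes_only_msc(self, rng):
        X = rng.normal(size=(8, 3))
        Y = X.copy()
        Y[:, 1] += 5.0
        a, b = two_way_mean_squares(X), two_way_mean_squares(Y)
        assert b[0] == pytest.approx(a[0], abs=1e-9)
        assert b[2] == pytest.approx(a[2], abs=1e-9)
        assert b[1] > a[1]

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            two_way_mean_squares([[1.0, 2.0]])


class TestICC21:
    def test_perfect_agreement_gives_one(self):
        r = icc_2_1([[1, 1], [2, 2], [3, 3]])
        assert r.icc == 1.0 and r.sem == 0.0 and r.band == "very_good"

    def test_reversed_columns_match_anova_oracle(self):
        X = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        assert icc_2_1(X).icc == pytest.approx(icc_oracle(X), abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        arrays(
            float,
            array_shapes(min_dims=2, max_dims=2, min_side=3, max_side=12),
            elements=st.floats(-10, 10, allow_nan=False),
        )
    )
    def test_matches_oracle_on_random_tables(self, X):
        msr, msc, mse = two_way_mean_squares(X)
        denom = msr + (X.shape[1] - 1) * mse + (X.shape[1] / X.shape[0]) * (msc - mse)
        if np.ptp(X) == 0 or denom == 0:
            assert icc_2_1(X).status == "undefined"
        else:
            assert icc_2_1(X).icc == pytest.approx(icc_oracle(X), abs=1e-12)

    def test_matches_pingouin_absolute_agreement_single(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(5):
            n, k = int(rng.integers(5, 25)), int(rng.integers(2, 5))
            X = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            mine = icc_2_1(X)
            df = pd.DataFrame(
                {
                    "t": np.repeat(np.arange(n), k),
                    "r": np.tile(np.arange(k), n),
                    "y": X.ravel(),
                }
            )
            row = pg.intraclass_corr(df, targets="t", raters="r", ratings="y").iloc[1]
            assert mine.icc == pytest.approx(row.ICC, abs=1e-10)
            lo, hi = row.CI95
            assert mine.ci95[0] == pytest.approx(lo, abs=5e-3)  # pingouin rounds
            assert mine.ci95[1] == pytest.approx(hi, abs=5e-3)

    def test_cohort_recovery_of_true_icc(self):
        """Mean estimate over replicates approaches sigma_b^2/(sigma_b^2+sigma_e^2)."""
        spec = CohortSpec(
            n_subjects=200, sigma_subject=np.sqrt(3), sigma_region=0.0,
            sigma_error=1.0,
        )
        iccs = []
        for rep in range(120):
            c = simulate_cohort(spec, map_shape=(1, 1, 1), seed=9000 + rep)
            iccs.append(whole_muscle_reliability(c.session_maps(0), c.session_maps(1)).icc)
        assert abs(np.mean(iccs) - 0.75) < 0.03

    def test_constant_table_is_undefined_not_a_number(self):
        r = icc_2_1(np.full((5, 2), 1.5))
        assert r.status == "undefined" and np.isnan(r.icc)

    def test_missing_rows_dropped_listwise(self):
        X = np.array([[1.0, 1.1], [2.0, np.nan], [3.0, 3.1], [4.0, 4.2]])
        r = icc_2_1(X)
        assert r.n_dropped == 1 and r.anova[3] == 3

    def test_ci_brackets_estimate(self, rng):
        X = rng.normal(size=(15, 2)) + rng.normal(size=(15, 1))
        r = icc_2_1(X)
        assert r.ci95[0] <= r.icc <= r.ci95[1]


class TestSem:
    def test_perfect_icc_gives_zero(self, rng):
        X = rng.normal(size=(6, 2))
        assert sem_measure(X, 1.0) == 0.0

    def test_zero_icc_gives_full_sd(self, rng):
        X = rng.normal(size=(6, 2))
        assert sem_measure(X, 0.0) == pytest.approx(np.std(X, ddof=1))

    def test_anova_variant_is_root_mse(self, rng):
        X = rng.normal(size=(6, 3))
        assert sem_measure(X, 0.5, method="anova") == pytest.approx(
            np.sqrt(two_way_mean_squares(X)[2])
        )


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.0, "poor"),
            (0.2, "poor"),
            (0.200001, "fair"),
            (0.4, "fair"),
            (0.41, "moderate"),
            (0.578, "moderate"),  # regional inter-subject scale estimate
            (0.6, "moderate"),
            (0.61, "good"),
            (0.752, "good"),  # regional inter-regional scale estimate
            (0.8, "good"),
            (0.801, "very_good"),
            (0.941, "very_good"),  # whole-muscle scale estimate
            (-0.3, "poor"),
        ],
    )
    def test_band_boundaries_as_printed(self, value, band):
        assert classify_icc(value) == band

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(float("nan"))


class TestWholeMuscleReliability:
    def test_identical_sessions_perfect(self):
        c = simulate_cohort(CohortSpec(n_subjects=8, sigma_error=0.3, seed=2), (2, 2, 2))
        maps = c.session_maps(0)
        r = whole_muscle_reliability(maps, maps)
        assert r.icc == pytest.approx(1.0) and r.sem == pytest.approx(0.0, abs=1e-12)

    def test_single_subject_rejected(self):
        c = simulate_cohort(CohortSpec(n_subjects=2, seed=3), (2, 2, 2))
        with pytest.raises(ValueError, match="2 subjects"):
            whole_muscle_reliability([c.maps[0][0]], [c.maps[0][1]])


class TestRegionalReliability:
    def test_identical_sessions_all_ones(self):
        c = simulate_cohort(CohortSpec(n_subjects=6, seed=4), (3, 2, 2))
        maps = c.session_maps(0)
        for domain in ("inter_regional", "inter_subject"):
            rr = regional_reliability(maps, maps, domain)
            assert rr.icc_median == pytest.approx(1.0)
            assert rr.icc_iqr[1] - rr.icc_iqr[0] == pytest.approx(0.0)

    def test_regional_structure_favors_inter_regional_domain(self):
        """With region variance >> subject variance, re-identifying a region
        within a subject is more reliable than ranking subjects in a region."""
        spec = CohortSpec(
            n_subjects=12, sigma_region=1.0, sigma_subject=0.05,
            sigma_error=0.3, seed=5,
        )
        med_regional, med_subject = [], []
        for rep in range(20):
            c = simulate_cohort(spec, map_shape=(4, 3, 3), seed=700 + rep)
            m1, m2 = c.session_maps(0), c.session_maps(1)
            med_regional.append(regional_reliability(m1, m2, "inter_regional").icc_median)
            med_subject.append(regional_reliability(m1, m2, "inter_subject").icc_median)
        assert np.mean(med_regional) > np.mean(med_subject)

    def test_misspelled_domain_rejected(self):
        c = simulate_cohort(CohortSpec(n_subjects=4, seed=6), (2, 2, 2))
        with pytest.raises(ValueError, match="domain"):
            regional_reliability(c.session_maps(0), c.session_maps(1), "interregional")


class TestPairedT:
    def test_symmetric_swap_gives_zero_t(self):
        r = paired_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert r.t == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_constant_shift_is_degenerate(self):
        r = paired_t([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])
        assert r.status == "degenerate" and np.isnan(r.t)
        assert r.mean_diff == pytest.approx(1.0)

    def test_matches_closed_form_and_scipy(self, rng):
        from scipy import stats

        for _ in range(20):
            n = int(rng.integers(3, 30))
            pre, post = rng.normal(size=n), rng.normal(size=n)
            r = paired_t(pre, post)
            d = post - pre
            t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            assert r.t == pytest.approx(t_hand, abs=1e-12)
            sp = stats.ttest_rel(post, pre)
            assert r.t == pytest.approx(sp.statistic, abs=1e-10)
            assert r.p == pytest.approx(sp.pvalue, abs=1e-10)


class TestRegionalContrast:
    def test_uniform_shift_without_noise_is_degenerate(self):
        c = simulate_cohort(
            CohortSpec(n_subjects=16, sigma_error=0.0, sigma_subject=0.2, seed=7),
            (3, 2, 2),
        )
        pre = c.session_maps(0)
        post = [
            type(m)(config=m.config, means=m.means + 0.2, counts=m.counts.copy())
            for m in pre
        ]
        for contrastbin in regional_contrast(pre, post, "radial"):
            assert contrastbin.result.status == "degenerate"

    def test_shift_plus_noise_gives_positive_t_everywhere(self):
        spec = CohortSpec(n_subjects=16, sigma_error=0.02, sigma_subject=0.2, seed=8)
        c = simulate_cohort(spec, (3, 2, 2))
        pre, post = c.session_maps(0), c.session_maps(1)
        post = [
            type(m)(config=m.config, means=m.means + 0.2, counts=m.counts.copy())
            for m in post
        ]
        for ax in ("radial", "angular", "longitudinal"):
            for contrastbin in regional_contrast(pre, post, ax):
                assert contrastbin.result.t > 0

    def test_invalid_axis_rejected(self):
        c = simulate_cohort(CohortSpec(n_subjects=4, seed=9), (2, 2, 2))
        with pytest.raises(ValueError, match="unknown axis"):
            regional_contrast(c.session_maps(0), c.session_maps(1), "sideways")

    def test_benjamini_hochberg_matches_reference(self, rng):
        from scipy.stats import false_discovery_control

        p = rng.uniform(size=25)
        np.testing.assert_allclose(benjamini_hochberg(p), false_discovery_control(p), atol=1e-12)


class TestSpearman:
    def test_monotone_relationships(self):
        x = np.arange(10.0)
        assert spearman_rho(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_rho(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self, rng):
        from scipy import stats

        for _ in range(10):
            x = rng.integers(0, 5, size=20).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=20).astype(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            rho, p = spearman_rho(x, y)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            rho_hand = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(rho_hand, abs=1e-12)
            sp = stats.spearmanr(x, y)
            assert rho == pytest.approx(sp.statistic, abs=1e-12)

    def test_invariance_under_strictly_monotone_transforms(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == base
        assert spearman_rho(x, 3 * y + 7) == base
        assert spearman_rho(np.tanh(x), np.exp(y)) == base

    def test_exact_permutation_p_small_n(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=7)
        rho, p_exact = spearman_rho(x, y, method="exact")
        _, p_approx = spearman_rho(x, y)
        assert 0 <= p_exact <= 1
        assert abs(p_exact - p_approx) < 0.15  # approximation in the right place
        with pytest.raises(ValueError, match="n <= 10"):
            spearman_rho(np.arange(12.0), np.arange(12.0), method="exact")


class TestRegionalAssociation:
    def test_identity_covariate_gives_perfect_rho(self):
        c = simulate_cohort(CohortSpec(n_subjects=10, sigma_subject=0.3, seed=10), (2, 2, 3))
        maps = c.session_maps(0)
        from swemap.parameterization import subject_profiles

        prof = subject_profiles(maps, "radial")
        bins = regional_association(maps, prof[:, 1], "radial")
        assert bins[1].rho == pytest.approx(1.0) and bins[1].significant

    def test_too_few_subjects_flagged(self):
        c = simulate_cohort(CohortSpec(n_subjects=3, sigma_subject=0.3, seed=11), (2, 2, 2))
        bins = regional_association(c.session_maps(0), [1.0, 2.0, 3.0], "radial")
        assert all(b.status == "insufficient_n" and not b.significant for b in bins)


class TestNormalizedMehs:
    def test_median_of_six_over_mass(self):
        assert normalized_mehs([300, 310, 320, 330, 340, 350], 70.0) == pytest.approx(
            325.0 / 70.0
        )

    def test_equal_forces(self):
        assert normalized_mehs([400.0] * 6, 80.0) == pytest.approx(5.0)

    def test_wrong_repetition_count_rejected(self):
        with pytest.raises(ValueError, match="six repetitions"):
            normalized_mehs([300, 310, 320, 330, 340], 70.0)
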