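"""ICC, between-observer COV and agreement labels, checked against
independent oracles (brute-force least squares, pingouin, closed forms)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratpet import (
    RaterTable,
    agreement_label,
    between_observer_cov,
    icc_two_way_mixed,
    paired_ttest,
    shapiro_wilk,
)
from ratpet.stats import bonferroni_pairwise, two_way_anova


def brute_force_mean_squares(x):
    """Two-way mean squares via explicit least-squares model fits: residual
    sums of squares of nested linear models built from dummy design matrices."""
    n, k = x.shape
    y = x.reshape(-1)

    def rss(columns):
        design = np.column_stack(columns)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return float(np.sum((y - design @ beta) ** 2))

    ones = np.ones(n * k)
    subj = [(np.repeat(np.arange(n), k) == i).astype(float) for i in range(n)]
    obs = [(np.tile(np.arange(k), n) == j).astype(float) for j in range(k)]
    rss_full = rss([ones] + subj[1:] + obs[1:])
    rss_no_subj = rss([ones] + obs[1:])
    rss_no_obs = rss([ones] + subj[1:])
    ms_error = rss_full / ((n - 1) * (k - 1))
    ms_rows = (rss_no_subj - rss_full) / (n - 1)
    ms_cols = (rss_no_obs - rss_full) / (k - 1)
    return ms_rows, ms_cols, ms_error


class TestICC:
    def test_identical_observers_give_icc_one(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = icc_two_way_mixed(RaterTable(np.column_stack([col, col, col])))
        assert res.icc_a == pytest.approx(1.0)
        assert res.icc_c == pytest.approx(1.0)

    def test_matches_brute_force_variance_decomposition(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            x = rng.normal(0, 1, (5, 3)) + rng.normal(0, 1, (5, 1)) + rng.normal(0, 0.5, (1, 3))
            res = icc_two_way_mixed(RaterTable(x))
            ms_r, ms_c, ms_e = brute_force_mean_squares(x)
            assert res.ms_rows == pytest.approx(ms_r, abs=1e-10)
            assert res.ms_cols == pytest.approx(ms_c, abs=1e-10)
            assert res.ms_error == pytest.approx(ms_e, abs=1e-10)
            icc_c = (ms_r - ms_e) / (ms_r + 2 * ms_e)
            icc_a = (ms_r - ms_e) / (ms_r + 2 * ms_e + (3 / 5) * (ms_c - ms_e))
            assert res.icc_c == pytest.approx(icc_c, abs=1e-10)
            assert res.icc_a == pytest.approx(icc_a, abs=1e-10)

    def test_matches_pingouin_point_estimates_and_cis(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        x = rng.normal(10, 2, (8, 1)) + rng.normal(0, 1, (8, 3)) + np.array([[0.0, 0.7, -0.4]])
        res = icc_two_way_mixed(RaterTable(x))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "rater": np.tile(np.arange(3), 8),
                "score": x.reshape(-1),
            }
        )
        ping = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        icc_a = ping.loc["ICC(A,1)"]  # single-rater absolute agreement
        icc_c = ping.loc["ICC(C,1)"]  # single-rater consistency
        assert res.icc_a == pytest.approx(icc_a["ICC"], abs=1e-6)
        assert res.icc_c == pytest.approx(icc_c["ICC"], abs=1e-6)
        # pingouin rounds its CI bounds to two decimals
        np.testing.assert_allclose(res.ci_a, np.asarray(icc_a["CI95"], dtype=float), atol=0.011)
        np.testing.assert_allclose(res.ci_c, np.asarray(icc_c["CI95"], dtype=float), atol=0.011)

    def test_variance_component_recovery(self):
        # subject SD 1.0, observer biases (0, 0.5), residual SD 0.1: the
        # expected ICCs follow from the variance components; over many
        # simulated tables the mean estimates recover them within 0.05 and
        # consistency exceeds absolute agreement.
        rng = np.random.default_rng(31)
        n, k = 10, 2
        sigma_s, bias, sigma_e = 1.0, np.array([0.0, 0.5]), 0.1
        icc_a_vals, icc_c_vals = [], []
        for _ in range(500):
            x = rng.normal(0, sigma_s, (n, 1)) + bias[None, :] + rng.normal(0, sigma_e, (n, k))
            res = icc_two_way_mixed(RaterTable(x))
            icc_a_vals.append(res.icc_a)
            icc_c_vals.append(res.icc_c)
        exp_c = sigma_s**2 / (sigma_s**2 + sigma_e**2)
        assert np.mean(icc_c_vals) == pytest.approx(exp_c, abs=0.05)
        assert np.mean(icc_c_vals) > np.mean(icc_a_vals)
        # absolute agreement is additionally penalised by the between-observer
        # bias variance theta = sum (b_j - mean b)^2 / (k - 1)
        theta = float(np.var(bias, ddof=1))
        exp_a = sigma_s**2 / (sigma_s**2 + theta + sigma_e**2)
        assert np.mean(icc_a_vals) == pytest.approx(exp_a, abs=0.05)

    def test_independent_noise_columns_give_icc_near_zero(self):
        rng = np.random.default_rng(41)
        x = rng.normal(0, 1, (50, 3))
        res = icc_two_way_mixed(RaterTable(x))
        assert abs(res.icc_a) <= 0.15

    def test_zero_variance_table_marked_undefined(self):
        res = icc_two_way_mixed(RaterTable(np.full((4, 3), 2.0)))
        assert not res.defined

    def test_cis_contain_point_estimates(self):
        rng = np.random.default_rng(53)
        for _ in range(20):
            x = rng.normal(0, 1, (6, 3)) + rng.normal(0, 1.5, (6, 1))
            res = icc_two_way_mixed(RaterTable(x))
            assert res.ci_a[0] - 1e-9 <= res.icc_a <= res.ci_a[1] + 1e-9
            assert res.ci_c[0] - 1e-9 <= res.icc_c <= res.ci_c[1] + 1e-9
            if res.ms_cols >= res.ms_error:
                assert res.icc_c >= res.icc_a - 1e-12

    def test_too_small_tables_rejected(self):
        with pytest.raises(ValueError):
            RaterTable(np.ones((1, 3)))
        with pytest.raises(ValueError):
            RaterTable(np.ones((5, 1)))


class TestBetweenObserverCov:
    def test_identical_observers_give_zero(self):
        col = np.array([1.0, 2.0, 3.0])
        assert between_observer_cov(RaterTable(np.column_stack([col, col]))) == 0.0

    def test_constant_offset_between_observers_gives_zero(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        table = RaterTable(np.column_stack([col, col + 0.7]))
        assert between_observer_cov(table) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_noise_matches_closed_form(self):
        # two observers with iid noise sigma about subject means: differences
        # have SD sqrt(2) sigma, so COV -> sqrt(2) sigma / m x 100
        rng = np.random.default_rng(61)
        m, sigma, n = 10.0, 0.8, 1000
        x = m + rng.normal(0, sigma, (n, 2))
        cov = between_observer_cov(RaterTable(x))
        assert cov == pytest.approx(np.sqrt(2) * sigma / m * 100.0, rel=0.10)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(factor=st.floats(0.01, 100.0))
    def test_scale_invariance(self, factor):
        rng = np.random.default_rng(71)
        x = 5.0 + rng.normal(0, 0.5, (8, 3))
        base = between_observer_cov(RaterTable(x))
        scaled = between_observer_cov(RaterTable(x * factor))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_grand_mean_undefined(self):
        x = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert np.isnan(between_observer_cov(RaterTable(x)))


class TestAgreementLabel:
    @pytest.mark.parametrize(
        "icc,label",
        [
            (0.40, "poor to fair"),
            (0.41, "moderate"),
            (0.605, "substantial"),
            (0.856, "almost perfect"),
            (1.0, "almost perfect"),
            (-0.2, "poor to fair"),
        ],
    )
    def test_bins(self, icc, label):
        assert agreement_label(icc) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            agreement_label(1.2)


class TestWrappers:
    def test_shapiro_and_paired_t_pass_through(self):
        rng = np.random.default_rng(83)
        a = rng.normal(0, 1, 30)
        w, p = shapiro_wilk(a)
        assert 0 <= w <= 1 and 0 <= p <= 1
        t, p2 = paired_ttest(a, a + rng.normal(0.5, 0.1, 30))
        assert p2 < 0.01

    def test_two_way_anova_and_bonferroni(self):
        rng = np.random.default_rng(97)
        df = pd.DataFrame(
            {
                "value": rng.normal(0, 1, 30),
                "subject": np.repeat(np.arange(10), 3),
                "observer": np.tile(["a", "b", "c"], 10),
            }
        )
        table = two_way_anova(df, "value", "subject", "observer")
        assert "PR(>F)" in table.columns
        groups = {o: df[df.observer == o]["value"].to_numpy() for o in ("a", "b", "c")}
        pw = bonferroni_pairwise(groups)
        assert (pw["p_bonferroni"] >= pw["p_raw"] - 1e-12).all()
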