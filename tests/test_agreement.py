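import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgdi.agreement import (
    bland_altman,
    compare_series,
    icc_agreement,
    method_by_time_interaction,
    pearson,
    within_cv,
)

# ---------------------------------------------------------------------------
# independent oracles: literal sums-of-squares / definitional computations,
# written against the formulas, never against the implementation under test
# ---------------------------------------------------------------------------


def oracle_two_way_icc(matrix):
    """Absolute-agreement average-measures ICC from explicit double loops."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = sum(m[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(m[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(m[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n)


def oracle_interaction_f(a, b):
    """Method x time interaction F from explicit cell means."""
    y = np.stack([a, b])  # (method=2, subject, time)
    m, n, t = y.shape
    grand = y.mean()
    mt = y.mean(axis=1)  # method x time cell means
    mm = y.mean(axis=(1, 2))
    tt = y.mean(axis=(0, 1))
    ss_mt = n * sum(
        (mt[i, j] - mm[i] - tt[j] + grand) ** 2 for i in range(m) for j in range(t)
    )
    ms = y.mean(axis=2)
    st_ = y.mean(axis=0)
    ss = y.mean(axis=(0, 2))
    ss_err = sum(
        (
            y[i, s, j]
            - mt[i, j]
            - ms[i, s]
            - st_[s, j]
            + mm[i]
            + ss[s]
            + tt[j]
            - grand
        )
        ** 2
        for i in range(m)
        for s in range(n)
        for j in range(t)
    )
    df_mt = (m - 1) * (t - 1)
    df_err = (m - 1) * (t - 1) * (n - 1)
    return (ss_mt / df_mt) / (ss_err / df_err)


FIXTURE = np.array(
    [
        [9.0, 2.0, 5.0, 8.0],
        [6.0, 1.0, 3.0, 2.0],
        [8.0, 4.0, 6.0, 8.0],
        [7.0, 1.0, 2.0, 6.0],
        [10.0, 5.0, 6.0, 9.0],
        [6.0, 2.0, 4.0, 7.0],
    ]
)


class TestIcc:
    def test_identical_raters_icc_one(self):
        a = np.array([10.0, 20.0, 15.0, 30.0, 25.0])
        icc, _ = icc_agreement(np.column_stack([a, a]))
        assert icc == pytest.approx(1.0)

    def test_fixture_matches_sums_of_squares_oracle(self):
        icc, _ = icc_agreement(FIXTURE)
        assert icc == pytest.approx(oracle_two_way_icc(FIXTURE), abs=1e-10)

    def test_fixture_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = FIXTURE.shape
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "ratings": FIXTURE.ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="ratings"
        ).set_index("Type")
        icc, (lo, hi) = icc_agreement(FIXTURE)
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        assert icc == pytest.approx(table.loc["ICC(A,k)", "ICC"], abs=1e-9)
        ref_lo, ref_hi = table.loc["ICC(A,k)", ci_col]
        assert lo == pytest.approx(ref_lo, abs=0.011)  # pingouin rounds the CI
        assert hi == pytest.approx(ref_hi, abs=0.011)

    def test_offset_penalized_only_by_absolute_agreement(self):
        rng = np.random.default_rng(2)
        a = rng.normal(50, 10, size=12)
        m = np.column_stack([a, a + 15.0 + rng.normal(0, 0.5, size=12)])
        icc_abs, _ = icc_agreement(m)
        icc_con, _ = icc_agreement(m, form="consistency")
        assert icc_abs < icc_con

    def test_constant_matrix_is_error_not_nan(self):
        with pytest.raises(ValueError, match="ICC undefined"):
            icc_agreement(np.full((5, 2), 3.0))

    def test_global_shift_invariance(self):
        icc1, _ = icc_agreement(FIXTURE)
        icc2, _ = icc_agreement(FIXTURE + 100.0)
        assert icc1 == pytest.approx(icc2, abs=1e-12)

    def test_single_rater_offset_decreases_icc(self):
        base, _ = icc_agreement(FIXTURE)
        shifted = FIXTURE.copy()
        shifted[:, 1] += 10.0
        worse, _ = icc_agreement(shifted)
        assert worse < base

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            icc_agreement(FIXTURE[:2])

    def test_ci_brackets_point_estimate(self):
        icc, (lo, hi) = icc_agreement(FIXTURE)
        assert lo < icc < hi
        assert -1 <= lo and hi <= 1


class TestBlandAltman:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(a, a)
        assert ba.bias == ba.loa_low == ba.loa_high == 0.0

    def test_hand_computed_two_pairs(self):
        ba = bland_altman(np.array([1.0, 3.0]), np.array([2.0, 2.0]))
        assert ba.bias == pytest.approx(0.0)
        assert ba.loa_high == pytest.approx(1.96 * np.sqrt(2))
        assert ba.loa_low == pytest.approx(-1.96 * np.sqrt(2))

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(3)
        n, delta, sigma = 1000, 10.0, 2.0
        b = rng.normal(50, 10, size=n)
        a = b + delta + rng.normal(0, sigma, size=n)
        ba = bland_altman(a, b)
        assert abs(ba.bias - delta) < 3 * sigma / np.sqrt(n)
        assert ba.loa_high == pytest.approx(delta + 1.96 * sigma, rel=0.10)
        assert ba.loa_low == pytest.approx(delta - 1.96 * sigma, rel=0.10)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            bland_altman(np.array([1.0]), np.array([2.0]))

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30),
        st.lists(st.floats(-100, 100), min_size=3, max_size=30),
    )
    @settings(max_examples=30, deadline=None)
    def test_limits_symmetric_about_bias(self, xs, ys):
        n = min(len(xs), len(ys))
        ba = bland_altman(np.array(xs[:n]), np.array(ys[:n]))
        assert ba.loa_high - ba.bias == pytest.approx(ba.bias - ba.loa_low, abs=1e-9)


class TestWithinCv:
    def test_constant_values(self):
        assert within_cv(np.array([5.0, 5.0, 5.0])) == 0.0

    def test_hand_computed(self):
        assert within_cv(np.array([8.0, 10.0, 12.0])) == pytest.approx(20.0)

    def test_scale_invariance(self):
        v = np.array([8.0, 10.0, 12.0])
        assert within_cv(3.7 * v) == pytest.approx(within_cv(v))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            within_cv(np.array([-1.0, 1.0]))


class TestPearson:
    def test_perfect_linear(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(a, 2 * a + 1) == pytest.approx(1.0)

    def test_perfect_inverse(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_definitional_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=10)
        b = 0.5 * a + rng.normal(size=10)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        want = cov / (a.std() * b.std())
        assert pearson(a, b) == pytest.approx(want, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson(np.ones(5), np.arange(5.0))


class TestInteraction:
    def test_parallel_curves_no_interaction(self):
        rng = np.random.default_rng(5)
        a = rng.normal(30, 5, size=(6, 8))
        b = a + 7.5  # constant offset per subject/time
        f, p = method_by_time_interaction(a, b)
        assert f == pytest.approx(0.0, abs=1e-18)
        assert p == pytest.approx(1.0)

    def test_time_proportional_divergence_detected(self):
        rng = np.random.default_rng(6)
        n, t = 7, 6
        base = rng.normal(30, 5, size=(n, t))
        a = base + rng.normal(0, 2, size=(n, t))
        b = base + 10.0 * np.arange(t) / 60.0 * 60.0 / 6.0 + rng.normal(0, 2, size=(n, t))
        f, p = method_by_time_interaction(a, b)
        assert p < 0.05

    def test_fixture_matches_cell_means_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(5, 4))
        b = rng.normal(size=(5, 4))
        f, _ = method_by_time_interaction(a, b)
        assert f == pytest.approx(oracle_interaction_f(a, b), abs=1e-8)

    def test_unbalanced_grid_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="common minute grid"):
            method_by_time_interaction(np.zeros((4, 5)), np.zeros((4, 6)))


class TestCompareSeries:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(8)
        a = rng.normal(40, 12, size=30)
        b = a + rng.normal(1.0, 3.0, size=30)
        rep = compare_series(a, b)
        assert rep.n_pairs == 30
        assert rep.loa_low == pytest.approx(rep.bias - 1.96 * np.std(a - b, ddof=1))
        assert -1 <= rep.icc <= 1
        payload = rep.to_json()
        import json

        parsed = json.loads(payload)
        assert set(parsed) >= {"icc", "bias", "loa_low", "loa_high", "pearson_r"}
        assert len(parsed["diffs"]) == 30
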