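"""Agreement statistics versus independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gaitval import cmc, icc_1_3, interpret, mae, mae_ci, paired_t, pearson


# --- independent textbook transcriptions (double loops, no vectorization) ---

def oracle_mae(a, b):
    total = 0.0
    for x, y in zip(a, b):
        total += abs(x - y)
    return total / len(a)


def oracle_cmc(y):
    f, t = y.shape
    mean_t = [sum(y[i][j] for i in range(f)) / f for j in range(t)]
    grand = sum(y[i][j] for i in range(f) for j in range(t)) / (f * t)
    num = sum((y[i][j] - mean_t[j]) ** 2 for i in range(f) for j in range(t)) / (t * (f - 1))
    den = sum((y[i][j] - grand) ** 2 for i in range(f) for j in range(t)) / (f * t - 1)
    ratio = num / den
    if ratio > 1:
        return float("nan")
    return np.sqrt(1 - ratio)


def oracle_icc_1_k(y):
    n, k = y.shape
    grand = sum(y[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(y[i]) / k for i in range(n)]
    ssb = k * sum((m - grand) ** 2 for m in row_means)
    ssw = sum((y[i][j] - row_means[i]) ** 2 for i in range(n) for j in range(k))
    bms = ssb / (n - 1)
    wms = ssw / (n * (k - 1))
    return (bms - wms) / bms


def oracle_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / np.sqrt(sxx * syy)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, p


def oracle_paired_t(x, y):
    n = len(x)
    d = [a - b for a, b in zip(x, y)]
    md = sum(d) / n
    sd = np.sqrt(sum((v - md) ** 2 for v in d) / (n - 1))
    t = md / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return t, p


class TestMae:
    def test_identical_is_zero(self):
        assert mae(np.arange(101.0), np.arange(101.0)) == 0.0

    def test_hand_sum(self):
        assert mae([1, 2, 3], [2, 2, 5]) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-100, 100))
    def test_constant_offset(self, c):
        x = np.linspace(-3, 7, 101)
        assert mae(x, x + c) == pytest.approx(abs(c), abs=1e-10)

    def test_triangle_inequality(self, rng):
        for _ in range(50):
            a, b, c = rng.normal(size=(3, 101))
            assert mae(a, c) <= mae(a, b) + mae(b, c) + 1e-12

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            mae(np.zeros(100), np.zeros(101))


class TestMaeCi:
    def test_equal_values_zero_width(self):
        m, lo, hi = mae_ci([3.0, 3.0, 3.0, 3.0])
        assert (m, lo, hi) == (3.0, 3.0, 3.0)

    def test_two_values_t_table(self):
        # t_{0.975, 1} = 12.7062; SE of {2, 4} is 1
        m, lo, hi = mae_ci([2.0, 4.0])
        assert m == pytest.approx(3.0)
        assert lo == pytest.approx(3 - 12.7062, abs=1e-3)
        assert hi == pytest.approx(3 + 12.7062, abs=1e-3)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            mae_ci([1.0])


class TestCmc:
    def test_identical_waveforms_is_one(self):
        y = np.vstack([np.sin(np.linspace(0, 6, 101))] * 2)
        assert cmc(y) == pytest.approx(1.0)

    def test_hand_case_undefined(self):
        # within-time variance exceeds total variance: ratio 3 > 1
        assert np.isnan(cmc(np.array([[0.0, 2.0], [2.0, 0.0]])))

    def test_all_constant_undefined(self):
        assert np.isnan(cmc(np.full((2, 10), 4.2)))

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            f = rng.integers(2, 5)
            t = rng.integers(2, 30)
            y = rng.normal(size=(f, t))
            ours, theirs = cmc(y), oracle_cmc(y)
            if np.isnan(theirs):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(theirs, abs=1e-12)

    def test_degrades_with_phase_shift(self):
        # similarity of a smooth cyclic waveform with shifted copies
        # decreases monotonically over shifts up to a quarter cycle
        t = np.linspace(0, 1, 101)
        base = np.sin(2 * np.pi * t) + 0.4 * np.cos(4 * np.pi * t)
        values = []
        for shift in [0.02, 0.07, 0.12, 0.18, 0.24]:
            shifted = np.sin(2 * np.pi * (t - shift)) + 0.4 * np.cos(4 * np.pi * (t - shift))
            values.append(cmc(np.vstack([base, shifted])))
        finite = [v for v in values if not np.isnan(v)]
        assert all(a >= b - 1e-12 for a, b in zip(finite, finite[1:]))

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            cmc(np.zeros(10))


class TestIcc13:
    def test_zero_within_subject_variance_is_one(self):
        icc, lo, hi = icc_1_3(np.array([[1.0, 1, 1], [2, 2, 2], [3, 3, 3]]))
        assert icc == 1.0

    def test_matches_anova_oracle(self, rng):
        for _ in range(100):
            y = rng.normal(size=(10, 3)) + 3 * rng.normal(size=(10, 1))
            icc, _, _ = icc_1_3(y)
            assert icc == pytest.approx(oracle_icc_1_k(y), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        for i in range(3):
            y = rng.normal(size=(12, 3)) + 2 * rng.normal(size=(12, 1))
            icc, lo, hi = icc_1_3(y)
            df = pd.DataFrame(
                {"targets": np.repeat(np.arange(12), 3), "raters": np.tile(np.arange(3), 12),
                 "ratings": y.ravel()}
            )
            row = pg.intraclass_corr(df, targets="targets", raters="raters",
                                     ratings="ratings").set_index("Type").loc["ICC(1,k)"]
            ci = row["CI95" if "CI95" in row.index else "CI95%"]
            assert icc == pytest.approx(row["ICC"], abs=1e-6)
            assert lo == pytest.approx(ci[0], abs=5e-3)
            assert hi == pytest.approx(ci[1], abs=5e-3)

    def test_increases_with_between_subject_variance(self, rng):
        noise = rng.normal(size=(30, 3))
        subject = rng.normal(size=(30, 1))
        iccs = [icc_1_3(noise + s * subject)[0] for s in (0.5, 2.0, 8.0)]
        assert iccs[0] < iccs[1] < iccs[2]

    def test_incomplete_matrix_rejected(self):
        y = np.ones((5, 3))
        y[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_1_3(y)

    def test_zero_between_subject_variance_not_floored(self):
        y = np.array([[0.0, 1.0, -1.0], [1.0, -1.0, 0.0], [-1.0, 0.0, 1.0]])
        icc, _, _ = icc_1_3(y)  # all rows share mean 0: BMS = 0
        assert icc == -np.inf


class TestPearsonPairedT:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_identical_paired_t_convention(self):
        x = np.arange(5.0)
        assert paired_t(x, x) == (0.0, 1.0)

    def test_zero_variance_pearson_undefined(self):
        r, p = pearson(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)

    def test_matches_textbook_oracles(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            r, p = pearson(x, y)
            r0, p0 = oracle_pearson(x, y)
            assert r == pytest.approx(r0, abs=1e-12)
            assert p == pytest.approx(p0, abs=1e-12)
            t, pt = paired_t(x, y)
            t0, pt0 = oracle_paired_t(x, y)
            assert t == pytest.approx(t0, abs=1e-10)
            assert pt == pytest.approx(pt0, abs=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(2), np.ones(2))
        with pytest.raises(ValueError):
            paired_t(np.ones(2), np.ones(2))


class TestInterpret:
    @pytest.mark.parametrize(
        "metric,value,label",
        [
            ("AE", 1.2, "good accuracy"),
            ("AE", 2.0, "good accuracy"),
            ("AE", 3.1, "acceptable accuracy"),
            ("AE", 5.0, "acceptable accuracy"),
            ("AE", 7.0, "tolerable accuracy"),
            ("AE", 10.0, "tolerable accuracy"),
            ("AE", 10.5, "unacceptable accuracy"),
            ("ICC", 0.75, "excellent"),
            ("ICC", 0.9, "excellent"),
            ("ICC", 0.4, "fair to good"),
            ("ICC", 0.39, "poor"),
            ("CMC", 0.936, "very good"),
            ("CMC", 0.95, "excellent"),
            ("CMC", 1.0, "excellent"),
            ("CMC", 0.85, "very good"),
            ("CMC", 0.75, "good"),
            ("CMC", 0.65, "moderate"),
            ("CMC", 0.5, "poor"),
        ],
    )
    def test_band_mapping(self, metric, value, label):
        assert interpret(metric, value) == label

    def test_undefined_value(self):
        assert interpret("CMC", float("nan")) == "undefined"

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            interpret("RMSE", 1.0)


def test_mae_matches_oracle(rng):
    for _ in range(100):
        a, b = rng.normal(size=(2, 17))
        assert mae(a, b) == pytest.approx(oracle_mae(a, b), abs=1e-12)
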