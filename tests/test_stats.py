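import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from choroid_sps import (
    DegenerateDataError,
    ParameterError,
    cohort_compare,
    cov_percent,
    icc_2_1,
    inter_observer,
    intra_observer,
    ks_normality,
    load_measurement_table,
    pearson_r,
    students_t,
)

from oracles import icc_2_1_bf


class TestStudentsT:
    def test_identical_samples(self):
        gc = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert gc.t_statistic == 0.0
        assert gc.p_value == 1.0

    def test_hand_computed_three_plus_three(self):
        # a={1,2,3}, b={11,12,13}: equal unit variances, pooled SE = sqrt(2/3)
        gc = students_t([1, 2, 3], [11, 12, 13])
        assert gc.t_statistic == pytest.approx(-10 / np.sqrt(2 / 3))
        assert gc.dof == 4

    def test_matches_scipy_pooled_and_welch(self, rng):
        from scipy import stats as ss

        a = rng.normal(0, 1, 25)
        b = rng.normal(0.4, 2.0, 31)
        gc = students_t(a, b, pooled=True)
        t, p = ss.ttest_ind(a, b)
        assert gc.t_statistic == pytest.approx(t)
        assert gc.p_value == pytest.approx(p)
        gw = students_t(a, b, pooled=False)
        tw, pw = ss.ttest_ind(a, b, equal_var=False)
        assert gw.t_statistic == pytest.approx(tw)
        assert gw.p_value == pytest.approx(pw)

    def test_pooled_equals_welch_for_balanced_equal_spread(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [11.0, 12.0, 13.0, 14.0]
        gp = students_t(a, b, pooled=True)
        gw = students_t(a, b, pooled=False)
        assert gp.t_statistic == pytest.approx(gw.t_statistic)
        assert gp.dof == pytest.approx(gw.dof)

    @given(
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-100.0, 100.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        a = rng.normal(5, 2, 20)
        b = rng.normal(6, 2, 22)
        g0 = students_t(a, b)
        g1 = students_t(scale * a + shift, scale * b + shift)
        assert g1.t_statistic == pytest.approx(g0.t_statistic, rel=1e-9)
        assert g1.p_value == pytest.approx(g0.p_value, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            students_t([1.0], [1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            students_t([2.0, 2.0], [2.0, 2.0])

    def test_table_style_simulation_separates_groups(self):
        rng = np.random.default_rng(0)
        dia = rng.normal(88016.71, 20978.93, 110)
        hea = rng.normal(154435.85, 19714.12, 92)
        assert students_t(dia, hea).p_value < 0.001


class TestKsNormality:
    def test_affine_invariance_of_statistic(self, rng):
        x = rng.normal(3, 2, 200)
        d1, _ = ks_normality(x, n_reps=200, seed=0)
        d2, _ = ks_normality(5 * x + 3, n_reps=200, seed=0)
        assert d1 == pytest.approx(d2)

    def test_rejects_exponential(self, rng):
        x = rng.exponential(1.0, 2000)
        _, p = ks_normality(x, n_reps=500, seed=1)
        assert p < 0.05

    def test_accepts_normal_mostly(self):
        # calibration: a valid 5%-level test keeps ~95% of normal samples
        keep = 0
        for i in range(40):
            x = np.random.default_rng(1000 + i).standard_normal(400)
            _, p = ks_normality(x, n_reps=400, seed=5)
            keep += p > 0.05
        assert keep >= 34

    def test_small_sample_and_degenerate(self):
        with pytest.raises(ParameterError):
            ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            ks_normality([2.0] * 10)


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_r([1, 2, 3, 4], [3, 5, 7, 9])  # y = 2x + 1
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0)
        r2, _ = pearson_r([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r2 == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, _ = pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_matches_scipy(self, rng):
        from scipy import stats as ss

        x = rng.normal(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 1, 40)
        r, p = pearson_r(x, y)
        ref = ss.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_errors(self):
        with pytest.raises(ParameterError):
            pearson_r([1, 2, 3], [1, 2])
        with pytest.raises(DegenerateDataError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestCov:
    def test_identical_replicates_zero(self):
        assert cov_percent({"a": [5.0, 5.0, 5.0], "b": [9.0, 9.0]}) == 0.0

    def test_two_point_subject(self):
        assert cov_percent({"s": [90.0, 110.0]}) == pytest.approx(
            100 * np.sqrt(200) / 100
        )  # SD=14.142, mean=100

    def test_scale_invariance(self, rng):
        reps = {i: rng.uniform(50, 150, 4) for i in range(6)}
        base = cov_percent(reps)
        assert cov_percent({k: 3 * v for k, v in reps.items()}) == pytest.approx(base)

    def test_duplicated_replicate_sets_unchanged(self, rng):
        reps = [list(rng.uniform(50, 150, 3)) for _ in range(4)]
        assert cov_percent(reps + reps) == pytest.approx(cov_percent(reps))

    def test_zero_mean_error(self):
        with pytest.raises(DegenerateDataError):
            cov_percent({"s": [-1.0, 1.0]})


class TestIcc:
    def test_perfect_agreement(self):
        m = np.array([[1, 1, 1], [2, 2, 2], [5, 5, 5], [9, 9, 9]], float)
        icc, comp = icc_2_1(m)
        assert icc == pytest.approx(1.0)
        assert comp.mse == pytest.approx(0.0)

    def test_matches_brute_force_anova(self, rng):
        m = rng.normal(50, 10, size=(7, 3)) + rng.normal(0, 3, size=(7, 1))
        icc, _ = icc_2_1(m)
        assert icc == pytest.approx(icc_2_1_bf(m))

    def test_matches_pingouin_absolute_agreement(self):
        import pingouin as pg

        m = np.array(
            [[9, 2, 5], [6, 1, 7], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]], float
        )
        icc, _ = icc_2_1(m)
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(6), 3),
                "rater": list("abc") * 6,
                "y": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "subj", "rater", "y")
        want = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc == pytest.approx(want)

    def test_null_no_subject_effect_near_zero(self):
        rng = np.random.default_rng(3)
        m = rng.normal(0, 1, size=(200, 3))
        icc, _ = icc_2_1(m)
        assert abs(icc) < 0.1

    def test_shift_invariance(self, rng):
        m = rng.normal(20, 5, size=(6, 3))
        assert icc_2_1(m + 100)[0] == pytest.approx(icc_2_1(m)[0])

    def test_bounds_on_nondegenerate_data(self, rng):
        for _ in range(10):
            m = rng.normal(0, 1, size=(5, 3))
            icc, _ = icc_2_1(m)
            assert -1 < icc <= 1

    def test_errors(self):
        with pytest.raises(DegenerateDataError):
            icc_2_1(np.full((4, 3), 7.0))
        with pytest.raises(ParameterError):
            icc_2_1(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ParameterError):
            icc_2_1(np.array([[1.0, 2.0]]))


def build_table(rng, n=12):
    """Per-image latent CA/COID plus small examiner noise (replicated design)."""
    rows = []
    for group, mu in (("diabetic", 88016.71), ("healthy", 154435.85)):
        for i in range(n):
            base_ca = rng.normal(mu, 20000)
            base_coid = rng.normal(65, 8)
            for ex in ("E1", "E2", "E3"):
                rows.append(
                    {
                        "image_id": f"{group}_{i}",
                        "group": group,
                        "examiner_id": ex,
                        "session_id": "S1",
                        "ca_px2": base_ca + rng.normal(0, 2000),
                        "coid": base_coid + rng.normal(0, 1.0),
                    }
                )
    return pd.DataFrame(rows)


class TestCohortCompare:
    def test_simulated_cohorts_significant(self, rng):
        table = build_table(rng)
        sub = table[table.examiner_id == "E1"]
        gc = cohort_compare(sub, "ca_px2")
        assert gc.p_value < 0.001
        assert gc.n_a == 12 and gc.n_b == 12

    def test_null_p_uniform(self):
        # both groups from one distribution: p should be uniform on (0,1)
        from scipy import stats as ss

        ps = []
        rng = np.random.default_rng(11)
        for _ in range(400):
            a = rng.normal(100, 10, 20)
            b = rng.normal(100, 10, 20)
            ps.append(students_t(a, b).p_value)
        assert ss.kstest(ps, "uniform").pvalue > 0.01

    def test_single_row_group_is_error(self):
        df = pd.DataFrame(
            {
                "image_id": ["a", "b", "c"],
                "group": ["diabetic", "healthy", "healthy"],
                "examiner_id": ["E1"] * 3,
                "session_id": ["S1"] * 3,
                "ca_px2": [1.0, 2.0, 3.0],
                "coid": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(DegenerateDataError):
            cohort_compare(df, "ca_px2")

    def test_missing_group_is_error(self, rng):
        table = build_table(rng)
        with pytest.raises(ParameterError):
            cohort_compare(table[table.group == "healthy"], "ca_px2")


class TestMeasurementTable:
    def test_load_validates(self, tmp_path, rng):
        table = build_table(rng, n=3)
        path = tmp_path / "t.csv"
        table.to_csv(path, index=False)
        df = load_measurement_table(path)
        assert len(df) == len(table)

    def test_duplicate_key_rejected(self, tmp_path, rng):
        table = build_table(rng, n=2)
        dup = pd.concat([table, table.iloc[[0]]])
        path = tmp_path / "t.csv"
        dup.to_csv(path, index=False)
        with pytest.raises(ParameterError):
            load_measurement_table(path)

    def test_observer_reliability_on_replicated_measurements(self, rng):
        table = build_table(rng, n=10)
        res = inter_observer(table, "ca_px2")
        # examiners draw independent noise around a strong subject effect
        assert res["n_raters"] == 3
        assert res["icc"] > 0.8
        assert res["cov_percent"] > 0
        # intra-observer needs >= 2 sessions
        with pytest.raises(ParameterError):
            intra_observer(table, "ca_px2")
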