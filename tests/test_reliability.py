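"""Reliability battery: CV%, ICC(3,1), SEM, Bland-Altman, paired t-test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from strikevel import (
    ReliabilityTable,
    between_day_cv,
    bland_altman,
    cv_percent,
    full_report,
    icc_3_1,
    paired_t,
    sem_from_anova,
    simulate_cohort,
)
from strikevel.io import write_results_csv
from strikevel.reliability import TestRetestModel as RetestModel
from strikevel.reliability import ReliabilityReport, loa_lower_from, two_way_anova


def table_from(values, metric="m"):
    values = np.asarray(values, dtype=float)
    return ReliabilityTable([f"s{i}" for i in range(len(values))], values, metric)


def anova_oracle(x):
    """Brute-force two-way sums of squares via explicit Python loops."""
    n = len(x)
    k = len(x[0])
    total = 0.0
    for row in x:
        for v in row:
            total += v
    grand = total / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_b = k * sum((m - grand) ** 2 for m in row_means)
    ss_s = n * sum((m - grand) ** 2 for m in col_means)
    ss_t = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_e = ss_t - ss_b - ss_s
    ms_b = ss_b / (n - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    icc = (ms_b - ms_e) / (ms_b + (k - 1) * ms_e)
    return ms_b, ms_e, icc


class TestCvPercent:
    def test_constant_values_zero(self):
        assert cv_percent([6.0, 6.0, 6.0]) == 0.0

    def test_hand_computed_sample_sd(self):
        # SD([4,6]) = sqrt(2), mean 5 -> 100*sqrt(2)/5
        assert cv_percent([4.0, 6.0]) == pytest.approx(100 * math.sqrt(2) / 5)

    @given(
        st.lists(st.floats(1.0, 50.0), min_size=2, max_size=10),
        st.floats(0.1, 100.0),
    )
    def test_scale_invariance(self, values, c):
        scaled = [c * v for v in values]
        assert cv_percent(scaled) == pytest.approx(cv_percent(values), abs=1e-8)

    def test_errors(self):
        with pytest.raises(ValueError):
            cv_percent([6.0])
        with pytest.raises(ValueError):
            cv_percent([-1.0, 1.0])


class TestBetweenDayCv:
    def test_identical_sessions_zero(self):
        cvs, _ = between_day_cv(table_from([[6.0, 6.0], [5.0, 5.0], [4.0, 4.0]]))
        assert cvs == pytest.approx([0.0, 0.0, 0.0])

    def test_hand_computed(self):
        cvs, _ = between_day_cv(table_from([[5.0, 6.0], [5.0, 5.0], [4.0, 4.0]]))
        assert cvs[0] == pytest.approx(100 * math.sqrt(0.5) / 5.5)

    def test_summary_min_mean_max(self):
        # subjects with CVs 0, 10, 20 % exactly
        def pair(cv, mean=10.0):
            sd = cv * mean / 100.0
            d = sd / math.sqrt(2)
            return [mean - d, mean + d]

        table = table_from([pair(0.0), pair(10.0), pair(20.0)])
        _, summary = between_day_cv(table)
        assert summary["min"] == pytest.approx(0.0)
        assert summary["mean"] == pytest.approx(10.0)
        assert summary["max"] == pytest.approx(20.0)


class TestIcc31:
    def test_identical_sessions_give_one(self):
        table = table_from([[i, i] for i in range(1, 11)])
        assert icc_3_1(table).icc == pytest.approx(1.0)

    def test_constant_session_offset_gives_one(self):
        # consistency ICC removes the session main effect
        table = table_from([[i, i + 0.5] for i in range(1, 11)])
        res = icc_3_1(table)
        assert res.icc == pytest.approx(1.0)
        assert res.ci_lower == pytest.approx(1.0)

    def test_matches_bruteforce_anova_oracle(self, rng):
        x = rng.normal(6, 1, size=(10, 2))
        _, _, icc_ref = anova_oracle(x.tolist())
        assert icc_3_1(table_from(x)).icc == pytest.approx(icc_ref, abs=1e-10)

    def test_200_random_matrices_match_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 51))
            k = int(rng.integers(2, 4))
            x = rng.normal(8, 2, size=(n, k))
            ms_b, ms_e, icc_ref = anova_oracle(x.tolist())
            table = table_from(x)
            assert icc_3_1(table).icc == pytest.approx(icc_ref, abs=1e-10)
            assert sem_from_anova(table)[0] == pytest.approx(
                math.sqrt(ms_e), abs=1e-10
            )

    def test_matches_pingouin_consistency_icc(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(6, 1, size=(12, 2))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "session": np.tile([0, 1], 12),
                "y": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "subject", "session", "y")
        ref = ref[ref["Type"].isin(["ICC3", "ICC(C,1)"])].iloc[0]
        res = icc_3_1(table_from(x))
        assert res.icc == pytest.approx(ref["ICC"], abs=1e-9)
        lo, hi = ref["CI95"]
        assert res.ci_lower == pytest.approx(lo, abs=6e-3)  # pingouin rounds its CI
        assert res.ci_upper == pytest.approx(hi, abs=6e-3)

    def test_all_identical_undefined(self):
        with pytest.raises(ValueError):
            icc_3_1(table_from([[5.0, 5.0]] * 4))

    @given(st.floats(-5, 5), st.floats(0.1, 10))
    def test_invariance_under_shift_and_scale(self, shift, scale):
        rng = np.random.default_rng(99)
        x = rng.normal(6, 1, size=(8, 2))
        base = icc_3_1(table_from(x)).icc
        assert icc_3_1(table_from(scale * (x + shift))).icc == pytest.approx(
            base, abs=1e-9
        )


class TestSem:
    def test_identical_sessions_zero(self):
        table = table_from([[i, i] for i in range(1, 6)])
        sem, _ = sem_from_anova(table)
        assert sem == pytest.approx(0.0)

    def test_translation_changes_only_percent(self, rng):
        x = rng.normal(6, 1, size=(10, 2))
        sem1, semp1 = sem_from_anova(table_from(x))
        sem2, semp2 = sem_from_anova(table_from(x + 3.0))
        assert sem2 == pytest.approx(sem1, abs=1e-12)
        assert semp2 != pytest.approx(semp1)


class TestBlandAltman:
    def test_identical_sessions(self):
        ba = bland_altman(table_from([[i, i] for i in range(1, 6)]))
        assert ba == (0.0, 0.0, 0.0)

    def test_constant_shift_has_zero_width(self):
        ba = bland_altman(table_from([[i, i + 1.0] for i in range(1, 6)]))
        assert ba.mean_difference == pytest.approx(1.0)
        assert ba.loa_upper == pytest.approx(1.0)
        assert ba.loa_lower == pytest.approx(1.0)

    def test_loa_identity(self, rng):
        for _ in range(20):
            x = rng.normal(8, 2, size=(int(rng.integers(3, 40)), 2))
            ba = bland_altman(table_from(x))
            assert ba.loa_upper + ba.loa_lower == pytest.approx(
                2 * ba.mean_difference, abs=1e-10
            )

    def test_matches_direct_formula(self, rng):
        x = rng.normal(8, 2, size=(15, 2))
        d = x[:, 1] - x[:, 0]
        ba = bland_altman(table_from(x))
        assert ba.mean_difference == pytest.approx(d.mean())
        assert ba.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))


class TestPairedT:
    def test_identical_sessions(self):
        res = paired_t(table_from([[i, i] for i in range(1, 6)]))
        assert res.t == 0.0 and res.p == 1.0

    def test_df_convention_n38(self, rng):
        x = rng.normal(6, 1, size=(38, 2))
        assert paired_t(table_from(x)).df == 37

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(6, 1, size=(12, 2))
        d = x[:, 1] - x[:, 0]
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_ref = 2 * stats.t.sf(abs(t_ref), len(d) - 1)
        res = paired_t(table_from(x))
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_constant_shift(self, caplog):
        with caplog.at_level("WARNING"):
            res = paired_t(table_from([[i, i + 1.0] for i in range(1, 6)]))
        assert math.isinf(res.t) and res.t > 0
        assert res.p == 0.0


class TestFullReport:
    def test_zero_within_subject_noise(self):
        table, _ = simulate_cohort(n_subjects=10, sigma_between=1.0,
                                   sigma_within=0.0, seed=4)
        s1 = dict(zip(table.subject_ids, table.values[:, 0]))
        s2 = dict(zip(table.subject_ids, table.values[:, 1]))
        report = full_report(s1, s2, metric_name="noiseless")
        assert report.icc == pytest.approx(1.0)
        assert report.sem == pytest.approx(0.0, abs=1e-6)
        assert report.between_day_cv_max == pytest.approx(0.0, abs=1e-6)
        assert (report.mean_difference, report.loa_upper, report.loa_lower) == \
            pytest.approx((0.0, 0.0, 0.0), abs=1e-6)

    def test_icc_estimates_center_on_analytic_value(self):
        # sigma_b=1.0, sigma_w=0.5 -> ICC_true = 1/(1+0.25) = 0.8
        iccs = []
        for rep in range(100):
            table, icc_true = simulate_cohort(
                n_subjects=38, sigma_between=1.0, sigma_within=0.5, seed=600 + rep
            )
            iccs.append(icc_3_1(table).icc)
        assert icc_true == pytest.approx(0.8)
        assert np.mean(iccs) == pytest.approx(0.8, abs=0.03)

    def test_complete_case_drop_and_minimum(self, caplog):
        s1 = {"a": 6.0, "b": 7.0, "c": 5.0, "d": 8.0}
        s2 = {"a": 6.1, "b": 7.2, "c": 5.1}
        model = RetestModel.from_sessions(s1, s2)
        assert model.table.n_subjects == 3
        assert model.n_dropped == 1
        with pytest.raises(ValueError, match="at least 3"):
            RetestModel.from_sessions({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})

    def test_report_roundtrip_preserves_values(self, tmp_path, rng):
        x = rng.normal(6, 1, size=(10, 2))
        table = table_from(x, metric="jab_avg")
        model = RetestModel(
            table,
            per_strike={"session1": {"s0": [6.0, 6.2, 6.4], "s1": [5.0, 5.5]}},
        )
        report = model.fit().report
        path = tmp_path / "report.csv"
        write_results_csv(report, path)
        back = ReliabilityReport.from_csv(path)
        for name in ReliabilityReport._SCALARS:
            assert getattr(back, name) == pytest.approx(getattr(report, name),
                                                        abs=1e-9)
        assert back.metric_name == "jab_avg"
        assert back.within_day_cv["session1"]["mean"] == pytest.approx(
            report.within_day_cv["session1"]["mean"], abs=1e-9
        )

    def test_summary_reports_all_statistics(self, rng):
        x = rng.normal(6, 1, size=(10, 2))
        text = RetestModel(table_from(x, "jab_avg")).fit().summary()
        for token in ("ICC(3,1)", "SEM", "Bland-Altman", "paired t(9)", "CV%"):
            assert token in text


class TestLoaLowerFrom:
    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_inverse_of_bland_altman_identity(self, md, upper):
        assert loa_lower_from(md, upper) == pytest.approx(2 * md - upper)


class TestTwoWayAnova:
    def test_mean_squares_against_loops(self, rng):
        x = rng.normal(10, 3, size=(7, 3))
        ms = two_way_anova(table_from(x))
        ms_b, ms_e, _ = anova_oracle(x.tolist())
        assert ms.ms_subjects == pytest.approx(ms_b, abs=1e-10)
        assert ms.ms_error == pytest.approx(ms_e, abs=1e-10)
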