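"""Paired statistics: change classes, normality omnibus test, paired t."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from flvae import stats as fst


class TestClassifyChange:
    @pytest.mark.parametrize(
        "post,follow,expected",
        [
            (0.4, 0.4, "unchanged"),
            (0.2, 0.4, "increased"),
            (0.4, 0.2, "decreased"),
            (0.4, 0.4004, "unchanged"),  # below default tolerance
            (0.4, 0.402, "increased"),
        ],
    )
    def test_examples(self, post, follow, expected):
        delta, cls = fst.classify_change(post, follow)
        assert cls == expected
        assert delta == pytest.approx(follow - post)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fst.classify_change(np.nan, 0.2)

    @given(post=st.floats(-5, 5), follow=st.floats(-5, 5))
    def test_partition_of_finite_deltas(self, post, follow):
        _, cls = fst.classify_change(post, follow)
        assert cls in fst.CHANGE_ORDER


class TestSummarizeChanges:
    def test_per_class_statistics(self):
        rec = pd.DataFrame(
            {"change_class": ["increased", "increased"], "delta": [0.1, 0.3]}
        )
        out = fst.summarize_changes(rec).set_index("change")
        assert out.loc["increased", "n_patients"] == 2
        assert out.loc["increased", "mean_difference"] == pytest.approx(0.2)
        assert out.loc["increased", "min_difference"] == pytest.approx(0.1)
        assert out.loc["increased", "max_difference"] == pytest.approx(0.3)
        assert out.loc["decreased", "n_patients"] == 0
        assert np.isnan(out.loc["decreased", "mean_difference"])

    def test_counts_sum_to_cohort_size(self):
        rng = np.random.default_rng(0)
        deltas = rng.normal(0, 0.1, 25)
        rec = pd.DataFrame(
            {
                "delta": deltas,
                "change_class": [fst.classify_change(0, d)[1] for d in deltas],
            }
        )
        out = fst.summarize_changes(rec)
        assert out["n_patients"].sum() == 25

    def test_stable_only_cohort_reports_zero_differences(self):
        rec = pd.DataFrame({"change_class": ["unchanged"] * 3, "delta": [0.0] * 3})
        out = fst.summarize_changes(rec).set_index("change")
        assert out.loc["unchanged", "mean_difference"] == 0.0


class TestDagostinoPearson:
    def test_agrees_with_reference_implementation(self):
        """Oracle equivalence with scipy.stats.normaltest on varied data."""
        rng = np.random.default_rng(123)
        for i in range(50):
            n = int(rng.integers(20, 200))
            kind = i % 3
            if kind == 0:
                x = rng.normal(size=n)
            elif kind == 1:
                x = rng.exponential(size=n)
            else:
                x = rng.uniform(size=n)
            k2, p = fst.dagostino_pearson(x)
            ref = sps.normaltest(x)
            assert k2 == pytest.approx(ref.statistic, rel=1e-6, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)

    def test_null_rarely_rejected(self):
        rng = np.random.default_rng(7)
        cover = np.mean(
            [fst.dagostino_pearson(rng.normal(size=30))[1] > 0.05 for _ in range(200)]
        )
        assert cover >= 0.9

    def test_skewed_alternative_detected(self):
        rng = np.random.default_rng(8)
        power = np.mean(
            [
                fst.dagostino_pearson(rng.exponential(size=100))[1] < 0.05
                for _ in range(200)
            ]
        )
        assert power >= 0.9

    def test_small_sample_rejected_and_warned(self):
        with pytest.raises(ValueError, match="n >= 8"):
            fst.dagostino_pearson(np.arange(5))
        with pytest.warns(UserWarning, match="n = 12"):
            fst.dagostino_pearson(np.random.default_rng(0).normal(size=12))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fst.dagostino_pearson(np.full(30, 1.7))


class TestPairedT:
    def test_hand_computed_example(self):
        # d = [1, 2, 3]: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 3.4641
        t, df, p = fst.paired_t([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2

    def test_symmetric_differences_give_zero_t(self):
        t, df, p = fst.paired_t([0, 0, 0, 0], [1, -1, 1, -1])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_identical_arrays_are_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            fst.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fst.paired_t([1.0, 2.0], [1.0])

    def test_antisymmetric_under_timepoint_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=15)
            b = a + rng.normal(0.2, 0.5, size=15)
            t1, df1, p1 = fst.paired_t(a, b)
            t2, df2, p2 = fst.paired_t(b, a)
            assert t1 == pytest.approx(-t2)
            assert p1 == pytest.approx(p2)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=30), rng.normal(0.1, 1, size=30)
        t, df, p = fst.paired_t(a, b)
        ref = sps.ttest_rel(b, a)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


def _patient_table(scores):
    rows = []
    for pid, (post, follow) in scores.items():
        rows.append({"patient_id": pid, "timepoint": "postop", "normalized_score": post})
        rows.append({"patient_id": pid, "timepoint": "followup", "normalized_score": follow})
    return pd.DataFrame(rows)


class TestRunComparison:
    def test_small_cohort_counts_and_tests(self):
        rng = np.random.default_rng(0)
        scores = {}
        for i in range(10):
            post = rng.uniform(0.2, 0.6)
            scores[f"P{i:02d}"] = (post, post + 0.1)
        for i in range(10, 15):
            post = rng.uniform(0.4, 0.8)
            scores[f"P{i:02d}"] = (post, post - 0.15)
        scores["P15"] = (0.5, 0.5)
        result = fst.run_comparison(_patient_table(scores))
        assert result.class_counts == {"increased": 10, "decreased": 5, "unchanged": 1}
        assert result.t_df == 15
        t_ref = sps.ttest_rel(
            result.records["score_followup"], result.records["score_postop"]
        )
        assert result.t_stat == pytest.approx(t_ref.statistic, rel=1e-10)

    def test_missing_followup_names_patient(self):
        tbl = _patient_table({"P00": (0.1, 0.2)})
        tbl = pd.concat(
            [tbl, pd.DataFrame([{"patient_id": "P01", "timepoint": "postop",
                                 "normalized_score": 0.3}])]
        )
        with pytest.raises(ValueError, match="P01"):
            fst.run_comparison(tbl)

    def test_identical_pairs_cohort_degenerates_gracefully(self):
        scores = {f"P{i}": (0.4, 0.4) for i in range(10)}
        result = fst.run_comparison(_patient_table(scores))
        assert result.class_counts["unchanged"] == 10
        assert result.t_stat is None  # zero-variance condition reported, not raised
        assert np.isnan(result.normality_stat)

    def test_csv_input_roundtrip(self, tmp_path):
        tbl = _patient_table({f"P{i}": (0.2 + 0.01 * i, 0.3 + 0.012 * i) for i in range(9)})
        path = tmp_path / "scores.csv"
        tbl.to_csv(path, index=False)
        result = fst.run_comparison(str(path))
        assert result.class_counts["increased"] == 9
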