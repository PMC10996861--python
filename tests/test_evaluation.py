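"""LOSO protocol, rank-sum test and report summaries."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from cppscreen import (
    CaseStudyConfig,
    EvaluationReport,
    ModelSpec,
    ValidationError,
    comparison_table,
    loso_folds,
    rank_sum_test,
    run_case_study,
    summarize,
    write_accuracy_csv,
    write_comparison_csv,
)
from cppscreen.evaluation import format_percent


def permutation_oracle(x, y):
    """Brute-force two-sided p: enumerate every assignment of the pooled
    ranks to sample 1 and count deviations at least as extreme."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    total = extreme = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            extreme += 1
    return extreme / total


class TestRankSum:
    def test_textbook_example(self):
        result = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert result.u_statistic == 0
        assert result.p_value == pytest.approx(0.1)
        assert result.sum_ranks_1 == 6

    def test_two_vs_two(self):
        result = rank_sum_test([1, 2], [3, 4])
        assert result.u_statistic == 0
        assert result.p_value == pytest.approx(1 / 3)

    def test_identical_constants_give_na(self):
        result = rank_sum_test([1.0] * 10, [1.0] * 10)
        assert result.p_value is None
        assert result.significant is None
        assert result.u_statistic == pytest.approx(50.0)  # midranks: n1*n2/2

    def test_identical_nonconstant_vectors_get_a_p_value(self):
        result = rank_sum_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert result.p_value is not None
        assert result.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_exact_matches_permutation_oracle(self, n, rng):
        for _ in range(10):
            pooled = rng.permutation(np.arange(1.0, 2 * n + 1))
            x, y = pooled[:n], pooled[n:]
            assert rank_sum_test(x, y).p_value == pytest.approx(
                permutation_oracle(x, y)
            )

    def test_asymptotic_matches_scipy_with_ties(self, rng):
        for _ in range(10):
            x = rng.integers(0, 5, 12).astype(float)
            y = rng.integers(0, 5, 12).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            ours = rank_sum_test(x, y).p_value
            ref = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])

    def test_u_within_bounds(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal(8), rng.standard_normal(5)
            result = rank_sum_test(x, y)
            assert 0 <= result.u_statistic <= result.n1 * result.n2


class TestLosoFolds:
    def test_one_fold_per_speaker_disjoint(self, small_windowed):
        folds = loso_folds(small_windowed)
        assert len(folds) == 24
        all_names = set(small_windowed.data["Name"])
        for train, val, speaker in folds:
            assert set(val["Name"]) | set(train["Name"]) == all_names
            assert not set(val["Name"]) & set(train["Name"])
            val_speakers = set(val["Name"].str.rsplit(".", n=1).str[0])
            train_speakers = set(train["Name"].str.rsplit(".", n=1).str[0])
            assert val_speakers == {speaker}
            assert speaker not in train_speakers

    def test_single_class_training_partition_rejected(self):
        from conftest import make_fold

        table_df = make_fold(n_sms=10, n_n=10)
        # keep only one speaker per class -> every fold's training set is single-class
        keep = table_df["Name"].str.rsplit(".", n=1).str[0].isin(["SMS1", "N1"])
        from cppscreen import WindowedTable

        table = WindowedTable(data=table_df[keep].reset_index(drop=True), nprime=7)
        with pytest.raises(ValidationError, match="single-class"):
            loso_folds(table)


@pytest.fixture(scope="module")
def ce1_report(small_windowed):
    cfg = CaseStudyConfig(
        model_specs=(ModelSpec("lda"), ModelSpec("knn"), ModelSpec("svm"), ModelSpec("rf", seed=1)),
        use_smote=False,
        n_iterations=3,
    )
    return run_case_study(small_windowed, cfg)


class TestRunCaseStudy:
    def test_report_dimensions(self, ce1_report):
        assert set(ce1_report.methods) == {"rf", "svm", "knn", "lda"}
        for matrix in ce1_report.accuracy.values():
            assert matrix.shape == (24, 3)
            assert np.all((matrix >= 0) & (matrix <= 1))

    def test_ce1_deterministic_models_have_zero_iteration_variance(self, ce1_report):
        for method in ("lda", "knn", "svm", "rf"):
            assert np.all(ce1_report.accuracy[method].std(axis=1) == 0)

    def test_ce1_bit_identical_on_rerun(self, small_windowed, ce1_report):
        cfg = CaseStudyConfig(
            model_specs=(ModelSpec("lda"), ModelSpec("knn"), ModelSpec("svm"), ModelSpec("rf", seed=1)),
            use_smote=False,
            n_iterations=3,
        )
        again = run_case_study(small_windowed, cfg)
        for method in ce1_report.methods:
            np.testing.assert_array_equal(
                again.accuracy[method], ce1_report.accuracy[method]
            )

    def test_ce2_reproducible_and_varying(self, small_windowed):
        cfg = CaseStudyConfig(
            model_specs=(ModelSpec("lda"),), use_smote=True, n_iterations=3
        )
        a = run_case_study(small_windowed, cfg)
        b = run_case_study(small_windowed, cfg)
        np.testing.assert_array_equal(a.accuracy["lda"], b.accuracy["lda"])

    def test_duplicate_methods_rejected(self, small_windowed):
        cfg = CaseStudyConfig(model_specs=(ModelSpec("lda"), ModelSpec("lda", seed=1)))
        with pytest.raises(ValidationError):
            run_case_study(small_windowed, cfg)

    def test_seeds_must_be_distinct(self):
        with pytest.raises(ValidationError):
            CaseStudyConfig(model_specs=(ModelSpec("lda"),), n_iterations=2, seeds=(1, 1))


class TestComparisonAndSummary:
    def test_six_pairwise_columns_in_conventional_order(self, ce1_report):
        table = comparison_table(ce1_report)
        assert list(table.columns) == [
            "RF_vs_SVM",
            "RF_vs_KNN",
            "RF_vs_LDA",
            "SVM_vs_KNN",
            "SVM_vs_LDA",
            "KNN_vs_LDA",
        ]
        assert len(table) == 24

    def test_uniform_perfect_speaker_is_all_na(self):
        acc = {m: np.ones((2, 10)) for m in ("rf", "svm", "knn", "lda")}
        report = EvaluationReport(["A", "B"], ["rf", "svm", "knn", "lda"], acc, tuple(range(10)))
        table = comparison_table(report)
        assert table.loc["A"].isna().all() or all(v is None for v in table.loc["A"])

    def test_summarize_constant_matrix(self):
        acc = {"lda": np.ones((3, 10))}
        report = EvaluationReport(["A", "B", "C"], ["lda"], acc, tuple(range(10)))
        summary = summarize(report)
        assert summary["overall_mean"]["lda"] == pytest.approx(1.0)
        stats = summary["per_speaker"]
        assert np.all(stats[("lda", "sd")] == 0)

    def test_mean_sd_match_brute_force(self, ce1_report):
        stats = ce1_report.per_speaker_stats()
        for method in ce1_report.methods:
            matrix = ce1_report.accuracy[method]
            for i, speaker in enumerate(ce1_report.speaker_ids):
                row = matrix[i]
                assert stats.loc[speaker, (method, "mean")] == pytest.approx(
                    sum(row) / len(row), abs=1e-12
                )
                mean = sum(row) / len(row)
                sd = (sum((v - mean) ** 2 for v in row) / (len(row) - 1)) ** 0.5
                assert stats.loc[speaker, (method, "sd")] == pytest.approx(sd, abs=1e-12)
        overall = ce1_report.overall_mean()
        for method in ce1_report.methods:
            per_speaker = ce1_report.accuracy[method].mean(axis=1)
            assert overall[method] == pytest.approx(per_speaker.mean(), abs=1e-12)

    def test_percent_formatting(self):
        assert format_percent(0.5923, 2) == "59.23%"
        assert format_percent(0.711, 1) == "71.1%"
        assert format_percent(1.0, 2) == "100.00%"

    def test_csv_writers(self, ce1_report, tmp_path):
        acc_path = tmp_path / "accuracy.csv"
        cmp_path = tmp_path / "comparison.csv"
        write_accuracy_csv(ce1_report, acc_path)
        write_comparison_csv(ce1_report, cmp_path)
        acc = pd.read_csv(acc_path)
        assert list(acc.columns) == ["Speaker", "RF", "SVM", "KNN", "LDA"]
        assert acc["Speaker"].iloc[-1] == "Overall"
        assert acc["LDA"].str.endswith("%").all()
        cmp_text = cmp_path.read_text()
        assert cmp_text.splitlines()[0].startswith("Speaker,RF_vs_SVM")
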