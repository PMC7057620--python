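"""Evaluation-statistics tests: accuracy records, adjusted Rand index
(against an exhaustive pair-counting oracle and scikit-learn), ANOVA/Tukey,
Fisher r-to-z intervals and the Bayes-factor comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from herdcnv import (
    adjusted_rand_index,
    anova_tukey,
    compare_bayes_factors,
    imputation_accuracy,
    pearson_fisher_ci,
    render_reports,
)
from herdcnv.stats import (
    accuracy_quartile_table,
    agreement_by_breed,
    high_accuracy_table,
    scatter_data,
)


def results_frame(called, imputed, breed="B", locus="l1", k=10):
    n = len(called)
    return pd.DataFrame(
        {
            "breed": breed,
            "locus_id": locus,
            "k": k,
            "mode": "triallelic",
            "method": "hmm",
            "animal_id": [f"a{i}" for i in range(n)],
            "called_cn": called,
            "imputed_cn": imputed,
            "population_frequency": 30,
            "length_kb": 50.0,
            "mean_bayes_factor": 5.0,
        }
    )


class TestImputationAccuracy:
    def test_simple_ratio(self):
        rec = imputation_accuracy(results_frame([1, 1, 1], [1, 2, 1]))
        state1 = rec[rec["called_state"] == 1].iloc[0]
        assert state1["accuracy"] == pytest.approx(2 / 3)
        assert state1["n_called"] == 3 and state1["n_correct"] == 2

    def test_identity_gives_one_per_state(self):
        rec = imputation_accuracy(results_frame([0, 1, 2, 2], [0, 1, 2, 2]))
        assert (rec["accuracy"] == 1.0).all()
        assert set(rec["called_state"]) == {0, 1, 2}

    def test_absent_state_has_no_record(self):
        rec = imputation_accuracy(results_frame([2, 2], [2, 2]))
        assert set(rec["called_state"]) == {2}

    def test_all_validation_denominator(self):
        rec = imputation_accuracy(
            results_frame([1, 1, 2, 2], [1, 1, 2, 2]), denominator="all_validation"
        )
        state1 = rec[rec["called_state"] == 1].iloc[0]
        assert state1["accuracy"] == pytest.approx(0.5)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(3)
        called = rng.integers(0, 3, size=200)
        imputed = rng.integers(0, 3, size=200)
        rec = imputation_accuracy(results_frame(called, imputed))
        for state in np.unique(called):
            mask = called == state
            expected = (imputed[mask] == state).sum() / mask.sum()
            got = rec.loc[rec["called_state"] == state, "accuracy"].iloc[0]
            assert got == pytest.approx(expected)

    def test_invariant_to_animal_order(self):
        rng = np.random.default_rng(4)
        called = rng.integers(0, 3, size=50)
        imputed = rng.integers(0, 3, size=50)
        perm = rng.permutation(50)
        a = imputation_accuracy(results_frame(called, imputed))
        b = imputation_accuracy(results_frame(called[perm], imputed[perm]))
        cols = ["called_state", "n_called", "n_correct", "accuracy"]
        pd.testing.assert_frame_equal(a[cols], b[cols])


def ari_pair_counting_oracle(a, b):
    """Classify all C(n,2) pairs; Hubert-Arabie from raw pair counts."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = 0.5 * ((ss + sd) + (ss + ds))
    if max_index == expected:
        return 0.0
    return (ss - expected) / (max_index - expected)


class TestAdjustedRandIndex:
    def test_identical_labelings(self):
        assert adjusted_rand_index([0, 0, 1, 2], [5, 5, 9, 7]) == pytest.approx(1.0)

    def test_independent_random_labelings_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 4, size=1000)
        b = rng.integers(0, 4, size=1000)
        assert abs(adjusted_rand_index(a, b)) < 0.05

    def test_single_cluster_degenerate_returns_zero(self):
        assert adjusted_rand_index([1, 1, 1], [2, 2, 2]) == 0.0

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 3, size=40)
        b = rng.integers(0, 3, size=40)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
        remap = np.array([7, 3, 11])
        assert adjusted_rand_index(remap[a], b) == pytest.approx(
            adjusted_rand_index(a, b)
        )

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(
        st.integers(2, 12).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(0, 3), min_size=n, max_size=n),
                st.lists(st.integers(0, 3), min_size=n, max_size=n),
            )
        )
    )
    def test_matches_pair_counting_oracle(self, ab):
        a, b = ab
        assert adjusted_rand_index(a, b) == pytest.approx(
            ari_pair_counting_oracle(a, b), abs=1e-12
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(10)
        for _ in range(25):
            a = rng.integers(0, 5, size=60)
            b = rng.integers(0, 5, size=60)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestAnovaTukey:
    def test_identical_groups_not_significant(self):
        res = anova_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert res.f_stat == 0.0
        assert not res.tukey["reject"].any()

    def test_three_equal_groups_all_p_one(self):
        res = anova_tukey({"a": [0.5, 0.5], "b": [0.5, 0.5], "c": [0.5, 0.5]})
        assert np.allclose(res.tukey["p_adj"].astype(float), 1.0)

    def test_power_for_three_sd_shift(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 60
        for _ in range(reps):
            res = anova_tukey(
                {"a": rng.normal(0, 1, 30), "b": rng.normal(3, 1, 30)}
            )
            if res.tukey["reject"].iloc[0]:
                hits += 1
        assert hits / reps >= 0.95

    def test_small_group_excluded(self):
        res = anova_tukey({"a": [1.0, 2.0, 1.5], "b": [0.9], "c": [2.0, 2.2, 2.6]})
        assert set(res.group_means) == {"a", "c"}

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1, 2, 3]})


class TestPearsonFisherCi:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_fisher_ci(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.ci95[1] == pytest.approx(1.0)
        assert res.significant

    def test_null_ci_closed_form_at_n_103(self):
        # construct data with sample r exactly 0 at n = 103
        rng = np.random.default_rng(14)
        x = rng.normal(size=103)
        y = rng.normal(size=103)
        xc = x - x.mean()
        y = y - y.mean()
        y = y - (y @ xc) / (xc @ xc) * xc  # orthogonalize
        res = pearson_fisher_ci(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        bound = math.tanh(1.959963984540054 / 10.0)
        assert res.ci95[0] == pytest.approx(-bound, abs=1e-6)
        assert res.ci95[1] == pytest.approx(bound, abs=1e-6)
        assert not res.significant

    def test_ci_width_decreasing_in_n(self):
        rng = np.random.default_rng(15)
        widths = []
        for n in (10, 40, 160):
            x = np.linspace(0, 1, n)
            y = x + rng.normal(0, 0.5, n)
            # keep r comparable by construction; width shrinks with n
            res = pearson_fisher_ci(x, y)
            widths.append(res.ci95[1] - res.ci95[0])
        assert widths[0] > widths[1] > widths[2]

    def test_coverage_of_null(self):
        """95% CI covers zero in 95% +/- 2% of independent-noise replicates."""
        rng = np.random.default_rng(16)
        n, reps = 200, 1000
        covered = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = pearson_fisher_ci(x, y)
            covered += not res.significant
        assert abs(covered / reps - 0.95) <= 0.02

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_fisher_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestCompareBayesFactors:
    def test_identical_distributions_not_significant(self):
        df = results_frame([1] * 20, [1] * 10 + [2] * 10)
        res = compare_bayes_factors(df)
        pooled = res[res["stratum"] == "pooled"].iloc[0]
        assert pooled["p_value"] == pytest.approx(1.0)
        assert pooled["direction"] == "none"

    def test_shift_detected_with_direction(self):
        rng = np.random.default_rng(17)
        frames = []
        for i in range(100):
            correct = i < 50
            f = results_frame([1], [1 if correct else 2], locus=f"l{i}")
            f["mean_bayes_factor"] = rng.normal(7.0 if correct else 5.0, 1.0)
            frames.append(f)
        res = compare_bayes_factors(pd.concat(frames, ignore_index=True))
        pooled = res[res["stratum"] == "pooled"].iloc[0]
        assert pooled["p_value"] < 0.05
        assert pooled["direction"] == "positive"

    def test_pooled_equals_concatenation_of_breeds(self):
        rng = np.random.default_rng(18)
        frames = []
        for breed in ("A", "B"):
            for i in range(30):
                f = results_frame([1], [1 if i % 2 else 2], breed=breed, locus=f"{breed}{i}")
                f["mean_bayes_factor"] = rng.normal(5, 1)
                frames.append(f)
        df = pd.concat(frames, ignore_index=True)
        res = compare_bayes_factors(df)
        from scipy.stats import f_oneway

        correct = df.loc[df.called_cn == df.imputed_cn, "mean_bayes_factor"]
        wrong = df.loc[df.called_cn != df.imputed_cn, "mean_bayes_factor"]
        f, p = f_oneway(correct, wrong)
        pooled = res[res["stratum"] == "pooled"].iloc[0]
        assert pooled["p_value"] == pytest.approx(p)

    def test_normal_state_excluded(self):
        df = results_frame([2, 2, 2], [2, 2, 1])
        assert compare_bayes_factors(df).empty


class TestReports:
    def test_quartile_convention(self):
        rec = pd.DataFrame(
            {
                "called_state": 1,
                "breed": "B",
                "accuracy": [0.0, 0.0, 0.083, 0.167],
                "locus_id": list("abcd"),
            }
        )
        t = accuracy_quartile_table(rec)
        assert t.iloc[0]["q1"] == pytest.approx(0.0)
        assert t.iloc[0]["median"] == pytest.approx(0.0415)
        assert t.iloc[0]["q3"] == pytest.approx(0.104)

    def test_empty_high_accuracy_table_is_valid(self):
        rec = imputation_accuracy(results_frame([1, 1], [2, 2]))
        assert high_accuracy_table(rec).empty

    def test_scatter_row_counts_match_records(self):
        rec = imputation_accuracy(results_frame([1, 1, 2, 2], [1, 2, 2, 2]))
        sc = scatter_data(rec)
        assert len(sc["frequency"]) == len(rec)
        assert len(sc["length"]) == len(rec)

    def test_render_reports_writes_tables(self, tmp_path):
        df = results_frame([1, 1, 2, 2], [1, 2, 2, 2])
        rec = imputation_accuracy(df)
        report = render_reports(rec, agreement_by_breed(df), out_dir=tmp_path)
        assert (tmp_path / "accuracy_quartiles.tsv").exists()
        assert (tmp_path / "agreement_ari.tsv").exists()
        assert not report["quartiles"].empty
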