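"""Signal-score comparison: rank test vs permutation oracle, Holm, CLD."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

from gelascan import synth
from gelascan.errors import FormatError, ValidationError
from gelascan.sigscores import (
    compact_letter_display,
    family_comparison,
    holm_adjust,
    parse_signalp_summary,
    rank_sum_test,
    records_to_long_tsv,
)

SUMMARY = """\
# SignalP-4.1 euk predictions
# name Cmax pos Ymax pos Smean D
MMP2_zebrafish  0.355  30  0.410  30  0.795  0.401
Vtn_0001  0.820  20  0.870  20  0.950  0.881
"""


class TestParser:
    def test_reads_smean_and_family_prefix(self):
        records = parse_signalp_summary(SUMMARY)
        assert records[0].s_mean == 0.795 and records[0].family == "MMP2"
        assert records[1].family == "Vtn"

    def test_explicit_family_label_overrides_prefix(self):
        records = parse_signalp_summary(SUMMARY, family="MMP9")
        assert {r.family for r in records} == {"MMP9"}

    def test_comment_only_file_is_empty(self):
        assert parse_signalp_summary("# nothing\n#among other comments\n") == []

    def test_score_above_one_rejected_with_line_number(self):
        with pytest.raises(FormatError, match="line 1"):
            parse_signalp_summary("x_1 0.2 10 0.3 10 1.2 0.4")

    def test_truncated_line_rejected(self):
        with pytest.raises(FormatError):
            parse_signalp_summary("x_1 0.2 10")


def rank_sum_oracle(a, b):
    """Exhaustive permutation oracle via midrank sums (independent route)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, big_n = a.size, a.size + b.size
    ranks = rankdata(np.concatenate([a, b]))
    w_obs = ranks[:n].sum()
    mu = n * (big_n + 1) / 2
    hits = total = 0
    for idx in itertools.combinations(range(big_n), n):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_fully_separated_small_samples(self):
        # U = 0; of the C(6,3)=20 assignments only U in {0, 9} are as extreme
        assert rank_sum_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    @given(st.integers(0, 2**31 - 1))
    def test_exact_branch_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        a = rng.integers(0, 6, size=n).astype(float)  # small range forces ties
        b = rng.integers(0, 6, size=m).astype(float)
        assert rank_sum_test(a, b) == pytest.approx(rank_sum_oracle(a, b))

    def test_normal_approximation_matches_hand_computed_z(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        u = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        mu, var = 30 * 25 / 2, 30 * 25 * (30 + 25 + 1) / 12  # no ties
        z = (abs(u - mu) - 0.5) / math.sqrt(var)
        expected = 2 * (1 - 0.5 * (1 + math.erf(z / math.sqrt(2))))
        assert rank_sum_test(a, b) == pytest.approx(expected, rel=1e-12)

    def test_large_sample_agrees_with_scipy_asymptotic(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 40, size=35).astype(float)
        b = rng.integers(5, 45, size=28).astype(float)
        reference = mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert rank_sum_test(a, b) == pytest.approx(reference.pvalue, rel=1e-9)

    def test_all_tied_large_samples_give_p_one(self):
        assert rank_sum_test([5.0] * 20, [5.0] * 20) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]).tolist() == [0.03]

    def test_step_down_hand_example(self):
        assert holm_adjust([0.01, 0.04]).tolist() == [0.02, 0.04]

    def test_all_ones_stay_one(self):
        assert holm_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_matches_statsmodels_and_is_permutation_stable(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = holm_adjust(pvals)
        theirs = multipletests(pvals, method="holm")[1]
        assert np.allclose(ours, theirs)
        perm = np.random.default_rng(0).permutation(len(pvals))
        assert np.allclose(np.sort(holm_adjust(np.asarray(pvals)[perm])),
                           np.sort(ours))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.5, 1.5])


def assert_cld_axioms(diff, letters):
    k = len(letters)
    assert all(letters[i] for i in range(k)), "every group needs a letter"
    for i, j in itertools.combinations(range(k), 2):
        shared = letters[i] & letters[j]
        if diff[i][j]:
            assert not shared, f"different pair ({i},{j}) shares {shared}"
        else:
            assert shared, f"indistinguishable pair ({i},{j}) shares nothing"


class TestCompactLetterDisplay:
    def test_no_differences_single_shared_letter(self):
        letters = compact_letter_display(np.zeros((4, 4), dtype=bool))
        assert letters == [{"a"}] * 4

    def test_all_different_singleton_letters(self):
        diff = ~np.eye(3, dtype=bool)
        letters = compact_letter_display(diff)
        assert letters == [{"a"}, {"b"}, {"c"}]

    def test_chain_of_three_with_one_significant_pair(self):
        diff = np.zeros((3, 3), dtype=bool)
        diff[0, 2] = diff[2, 0] = True
        assert compact_letter_display(diff) == [{"a"}, {"a", "b"}, {"b"}]

    def test_asymmetric_matrix_rejected(self):
        diff = np.zeros((2, 2), dtype=bool)
        diff[0, 1] = True
        with pytest.raises(ValidationError):
            compact_letter_display(diff)

    def test_true_diagonal_rejected(self):
        with pytest.raises(ValidationError):
            compact_letter_display(np.eye(2, dtype=bool))

    @given(st.integers(0, 2**31 - 1))
    def test_axioms_hold_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 9))
        diff = rng.random((k, k)) < 0.4
        diff = np.triu(diff, 1)
        diff = diff | diff.T
        assert_cld_axioms(diff, compact_letter_display(diff))


class TestFamilyComparison:
    @staticmethod
    def _records(specs, seed):
        records, _ = synth.simulate_signal_scores(specs, seed=seed)
        return records

    def test_same_distribution_families_usually_share_a_letter(self):
        shared = 0
        for seed in range(40):
            records = self._records(
                [("A", 60, 0.8, 0.05), ("B", 60, 0.8, 0.05)], seed
            )
            fc = family_comparison(records)
            shared += bool(fc.letters["A"] & fc.letters["B"])
        assert shared >= 36  # alpha=0.05: expect ~38/40

    def test_well_separated_families_get_distinct_letters(self):
        for seed in range(10):
            records = self._records(
                [("A", 100, 0.80, 0.02), ("B", 100, 0.95, 0.02)], seed
            )
            fc = family_comparison(records)
            assert not (fc.letters["A"] & fc.letters["B"])

    def test_reference_family_flagging(self):
        records = self._records(
            [("MMP2", 80, 0.70, 0.03), ("MMP9", 80, 0.93, 0.03),
             ("Vtn", 80, 0.95, 0.03)], seed=5
        )
        fc = family_comparison(records, reference_family="Vtn")
        assert fc.like_reference["Vtn"] is True
        assert fc.like_reference["MMP2"] is False

    def test_pvalue_matrices_symmetric_with_unit_diagonal(self):
        records = self._records(
            [("A", 30, 0.6, 0.05), ("B", 30, 0.7, 0.05), ("C", 30, 0.8, 0.05)],
            seed=2,
        )
        fc = family_comparison(records)
        for mat in (fc.p_raw, fc.p_adjusted):
            assert np.allclose(mat, mat.T)
            assert np.allclose(np.diag(mat), 1.0)
        assert_cld_axioms(fc.significant, [fc.letters[f] for f in fc.families])

    def test_small_families_excluded_with_warning(self, caplog):
        records = self._records(
            [("A", 30, 0.6, 0.05), ("B", 30, 0.7, 0.05), ("C", 1, 0.8, 0.05)],
            seed=2,
        )
        fc = family_comparison(records)
        assert fc.excluded == ["C"] and "excluded" in caplog.text

    def test_single_family_is_an_error(self):
        records = self._records([("A", 10, 0.6, 0.05)], seed=0)
        with pytest.raises(ValidationError):
            family_comparison(records)

    def test_pairwise_type_one_error_controlled_under_holm(self):
        """Familywise error over 3 equal-mean families stays near alpha."""
        rejections = 0
        reps = 150
        for seed in range(reps):
            records = self._records(
                [("A", 25, 0.8, 0.05), ("B", 25, 0.8, 0.05),
                 ("C", 25, 0.8, 0.05)], seed
            )
            fc = family_comparison(records, alpha=0.05)
            rejections += bool(fc.significant.any())
        # binomial 3-sigma envelope around alpha = 0.05
        assert rejections / reps <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)

    def test_long_format_export_one_row_per_record(self):
        records = self._records([("A", 3, 0.6, 0.05)], seed=0)
        tsv = records_to_long_tsv(records)
        assert len(tsv.strip().splitlines()) == 4  # header + 3

    def test_tsv_export_has_letters_column(self):
        records = self._records(
            [("A", 20, 0.6, 0.02), ("B", 20, 0.9, 0.02)], seed=1
        )
        fc = family_comparison(records)
        header, *rows = fc.to_tsv().strip().splitlines()
        assert header.split("\t")[-1] == "letters" and len(rows) == 2
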