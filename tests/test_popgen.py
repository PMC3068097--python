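"""Diversity/differentiation statistics against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleospruce.haplotypes import collapse_haplotypes
from paleospruce.loci import DEFAULT_LOCI
from paleospruce.popgen import (
    fst_hudson,
    haplotype_diversity,
    ks_kst,
    locus_summary_report,
    mean_pairwise_differences,
    nucleotide_diversity,
    pairwise_differences,
    permutation_test,
    significance_stars,
)
from paleospruce.seqio import SequenceRecord

seq_strategy = st.text(alphabet="ACGT-", min_size=1, max_size=40)


def brute_force_diff(a, b, gap_mode):
    n = 0
    for x, y in zip(a, b):
        if gap_mode == "pairwise_deletion" and "-" in (x, y):
            continue
        if x != y:
            n += 1
    return n


class TestPairwiseDifferences:
    def test_simple_examples(self):
        assert pairwise_differences("ACGT", "ACGT") == 0
        assert pairwise_differences("ACGT", "AC-T", "fifth_state") == 1
        assert pairwise_differences("ACGT", "AC-T", "pairwise_deletion") == 0

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            pairwise_differences("ACG", "ACGT")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, derandomize=True)
    def test_matches_site_by_site_oracle_on_random_200mers(self, seed):
        r = np.random.default_rng(seed)
        a = "".join(r.choice(list("ACGT-"), 200))
        b = "".join(r.choice(list("ACGT-"), 200))
        for mode in ("fifth_state", "pairwise_deletion"):
            assert pairwise_differences(a, b, mode) == brute_force_diff(a, b, mode)


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([2, 1, 1], 0.8333),
            ([4, 2], 0.5333),
            ([11, 2, 1], 0.3846),
            ([2, 1], 0.6667),
            ([5], 0.0),
        ],
    )
    def test_published_values(self, counts, expected):
        assert haplotype_diversity(counts) == pytest.approx(expected, abs=5e-5)

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            haplotype_diversity([1])

    def test_invariant_under_relabeling(self, rng):
        counts = list(rng.integers(1, 20, size=6))
        perm = list(rng.permutation(counts))
        assert haplotype_diversity(counts) == pytest.approx(haplotype_diversity(perm))

    def test_duplicate_addition_follows_update_formula(self, rng):
        counts = [5, 3, 2]
        n = sum(counts)
        for i in range(len(counts)):
            new = counts.copy()
            new[i] += 1
            expected = (
                (n + 1)
                * (1 - sum((c / (n + 1)) ** 2 for c in new))
                / n
            )
            assert haplotype_diversity(new) == pytest.approx(expected)


class TestMeanPairwiseDifferences:
    def test_identical_sequences(self):
        assert mean_pairwise_differences(["ACGT", "ACGT"]) == 0

    def test_ancient_tl_value(self, table1):
        k = mean_pairwise_differences(table1.ancient_by_locus["TL"])
        assert k == pytest.approx(72 / 91, abs=1e-12)
        assert round(k, 4) == 0.7912

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_matches_double_loop_oracle(self, seed):
        r = np.random.default_rng(seed)
        seqs = ["".join(r.choice(list("ACGT-"), 30)) for _ in range(r.integers(2, 12))]
        total, pairs = 0, 0
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                total += brute_force_diff(seqs[i], seqs[j], "fifth_state")
                pairs += 1
        assert mean_pairwise_differences(seqs) == pytest.approx(total / pairs)

    def test_invariant_under_reordering(self, table1, rng):
        recs = table1.ancient_by_locus["TL"]
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert mean_pairwise_differences(recs) == pytest.approx(
            mean_pairwise_differences(shuffled)
        )


class TestNucleotideDiversity:
    def test_pi_equals_k_over_L_on_fixture(self, table1):
        for locus in ("B", "D", "TL", "Li"):
            recs = table1.ancient_by_locus[locus]
            L = len(recs[0].bases)
            assert nucleotide_diversity(recs) == pytest.approx(
                mean_pairwise_differences(recs) / L
            )

    def test_forced_value(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        assert nucleotide_diversity([a, b]) == pytest.approx(0.01)

    def test_monomorphic_sample(self):
        assert nucleotide_diversity(["ACGT"] * 4) == 0


class TestDifferentiation:
    def test_identical_populations_show_no_differentiation(self, table1):
        # identical monomorphic populations: exactly zero
        mono = ["ACGT"] * 3
        assert ks_kst(mono, mono)[2] == 0.0
        assert fst_hudson(mono, mono) == 0.0
        # a polymorphic sample duplicated into both populations: pooled
        # pairs include cross-copy self-matches, so the point estimates
        # are <= 0 (never spurious positive differentiation) and the
        # permutation test sees nothing
        pop = table1.ancient_by_locus["TL"][:4]
        ks, kt, kst = ks_kst(pop, pop)
        assert kst <= 0.0
        assert fst_hudson(pop, pop) <= 0.0
        assert permutation_test("Kst", pop, pop, n_perm=99, seed=0) > 0.5

    def test_kst_is_zero_in_expectation_under_label_permutation(self, table1):
        # Monte-Carlo check of the exchangeability property
        rng = np.random.default_rng(3)
        pooled = table1.ancient_by_locus["TL"]
        values = []
        for _ in range(300):
            idx = rng.permutation(len(pooled))
            pop1 = [pooled[i] for i in idx[:7]]
            pop2 = [pooled[i] for i in idx[7:]]
            values.append(ks_kst(pop1, pop2)[2])
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(np.mean(values)) < 3 * se + 1e-3

    def test_fixed_difference_is_complete_differentiation(self):
        pop1 = ["AAAA"] * 3
        pop2 = ["AATT"] * 3
        ks, kt, kst = ks_kst(pop1, pop2)
        assert ks == 0 and kst == pytest.approx(1.0)
        assert fst_hudson(pop1, pop2) == pytest.approx(1.0)

    def test_monomorphic_pool_defines_kst_zero(self):
        assert ks_kst(["AA"] * 2, ["AA"] * 2)[2] == 0.0
        assert fst_hudson(["AA"] * 2, ["AA"] * 2) == 0.0

    def test_weighted_average_on_toy_sample(self):
        # 4+4 sample, hand-computed from the pairwise-difference matrix
        pop1 = ["AAAA", "AAAA", "AAAT", "AAAT"]
        pop2 = ["TTAA", "TTAA", "TTAT", "TCAA"]
        k1 = mean_pairwise_differences(pop1)  # pairs: 4 of 6 differ by 1 -> 4/6
        assert k1 == pytest.approx(4 / 6)
        k2 = mean_pairwise_differences(pop2)
        # pop2 pairs: (1,2)=0 (1,3)=1 (1,4)=1 (2,3)=1 (2,4)=1 (3,4)=2 -> 6/6
        assert k2 == pytest.approx(1.0)
        ks, kt, kst = ks_kst(pop1, pop2)
        assert ks == pytest.approx(0.5 * k1 + 0.5 * k2)
        pooled = pop1 + pop2
        total = sum(
            brute_force_diff(a, b, "fifth_state")
            for a, b in itertools.combinations(pooled, 2)
        )
        assert kt == pytest.approx(total / 28)
        assert kst == pytest.approx(1 - ks / kt)

    def test_fst_brute_force_on_3plus3(self, rng):
        pop1 = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(3)]
        pop2 = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(3)]
        hw = 0.5 * (
            mean_pairwise_differences(pop1) + mean_pairwise_differences(pop2)
        )
        hb = np.mean(
            [brute_force_diff(a, b, "fifth_state") for a in pop1 for b in pop2]
        )
        assert fst_hudson(pop1, pop2) == pytest.approx(1 - hw / hb)


class TestPermutationTest:
    def test_perfect_differentiation_gives_minimal_p(self):
        # none of the 99 sampled label permutations reproduces the exact
        # split (checked for this seed), so the add-one p is minimal
        pop1 = ["AAAAAAAA"] * 8
        pop2 = ["TTTTTTTT"] * 8
        p = permutation_test("Kst", pop1, pop2, n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_seed_reproducibility(self, table1):
        args = (table1.ancient_by_locus["D"], table1.extant_by_locus["D"][:10])
        p1 = permutation_test("Kst", *args, n_perm=200, seed=7)
        p2 = permutation_test("Kst", *args, n_perm=200, seed=7)
        assert p1 == p2

    def test_ks_direction_is_toward_differentiation(self):
        # strongly differentiated pops have small Ks relative to permutations
        pop1 = ["AAAAAAAA"] * 8
        pop2 = ["TTTTTTTT"] * 8
        p = permutation_test("Ks", pop1, pop2, n_perm=99, seed=3)
        assert p == pytest.approx(1 / 100)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            permutation_test("Kst", ["AA"], ["AA"], n_perm=10)
        with pytest.raises(ValueError):
            permutation_test("Kst", ["AA"] * 3, ["AA"] * 3, n_perm=0)

    def test_null_rejection_rate_small_screen(self, rng):
        # quick null screen (the full 1000-trial calibration runs in the
        # acceptance suite)
        rejections = 0
        trials = 120
        for t in range(trials):
            pool = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(12)]
            p = permutation_test(
                "Kst", pool[:6], pool[6:], n_perm=99, seed=int(rng.integers(2**31))
            )
            rejections += p <= 0.05
        assert 0.01 <= rejections / trials <= 0.12


class TestSummaryReport:
    def test_fixture_report_hd_column(self, table1):
        report = locus_summary_report(
            table1.extant_by_locus, table1.ancient_by_locus,
            ["B", "D", "TL", "Li", "LF", "K2i"], n_perm=0,
        )
        ancient = report[report.population == "Ancient"].set_index("locus")
        want = {"B": 0.8333, "D": 0.5333, "TL": 0.3846, "Li": 0.6667,
                "LF": 0.0, "K2i": 0.0}
        for locus, hd in want.items():
            assert ancient.loc[locus, "Hd"] == pytest.approx(hd, abs=5e-5)

    def test_empty_ancient_locus_is_flagged(self, table1):
        report = locus_summary_report(
            table1.extant_by_locus, {"D": []}, ["D"], n_perm=0
        )
        row = report[report.population == "Ancient"].iloc[0]
        assert "sequences" in row["note"]

    def test_significance_stars(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.004) == "**"
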