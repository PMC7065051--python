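"""Descriptive statistics, AMOVA (with brute-force oracle), pairwise FST."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import stepstone as st
from stepstone.popgen import (
    _encode_locus,
    _locus_ss,
    allelic_richness,
    amova,
    bonferroni_threshold,
    f_statistics_from_components,
    null_allele_frequency,
    pairwise_fst_matrix,
)
from stepstone.synthetic import PopSimSpec

from conftest import make_genotypes


class TestAlleleFrequencies:
    def test_basic_counts(self, two_sample_genotypes):
        f = st.allele_frequencies(two_sample_genotypes, "A")["L1"]
        assert f.loc[100, "freq"] == pytest.approx(0.75)
        assert f.loc[120, "freq"] == pytest.approx(0.25)
        assert f["count"].sum() == 4

    def test_missing_excluded_from_denominator(self):
        gm = make_genotypes(
            [("A", "a1", [(100, 120)]), ("A", "a2", [(0, 0)])], ["L1"]
        )
        f = st.allele_frequencies(gm, "A")["L1"]
        assert f["count"].sum() == 2

    def test_frequencies_sum_to_one(self, two_sample_genotypes):
        for df in st.allele_frequencies(two_sample_genotypes, "B").values():
            assert df["freq"].sum() == pytest.approx(1.0)


class TestSummaryStats:
    def test_two_equifrequent_alleles(self):
        gm = make_genotypes(
            [("A", "a1", [(100, 120)]), ("A", "a2", [(100, 120)])], ["L1"]
        )
        row = st.sample_summary_stats(gm).loc["A"]
        assert row["Ne"] == pytest.approx(2.0)
        assert row["He"] == pytest.approx(0.5)
        assert row["Ho"] == pytest.approx(1.0)

    def test_monomorphic_sample(self):
        gm = make_genotypes(
            [("A", "a1", [(100, 100)]), ("A", "a2", [(100, 100)])], ["L1"]
        )
        row = st.sample_summary_stats(gm).loc["A"]
        assert row["Na"] == 1 and row["Ho"] == 0.0 and row["He"] == 0.0
        assert row["Ar"] == pytest.approx(1.0)

    def test_private_allele_counted_once(self, two_sample_genotypes):
        gm = make_genotypes(
            [
                ("A", "a1", [(100, 100)]),
                ("A", "a2", [(100, 140)]),  # 140 only in A
                ("B", "b1", [(100, 120)]),  # 120 only in B
                ("B", "b2", [(100, 100)]),
            ],
            ["L1"],
        )
        out = st.sample_summary_stats(gm)
        assert out.loc["A", "Np"] == 1
        assert out.loc["B", "Np"] == 1

    def test_invariant_bounds(self):
        spec = PopSimSpec(n_demes=3, deme_sizes=20, n_loci=4, n_generations=30)
        gm = st.simulate_metapopulation(spec, seed=2).genotypes
        out = st.sample_summary_stats(gm)
        assert ((out["Ho"] >= 0) & (out["Ho"] <= 1)).all()
        assert ((out["He"] >= 0) & (out["He"] <= 1)).all()
        assert (out["Ne"] <= out["Na"] + 1e-12).all()
        assert (out["Ar"] <= out["Na"] + 1e-12).all()
        assert (out["Np"] >= 0).all()


class TestAllelicRichness:
    def test_enumeration_oracle_two_plus_two(self):
        # counts (2,2), g=2: all C(4,2)=6 draws -> mean distinct = 5/3
        assert allelic_richness([2, 2], 2) == pytest.approx(5 / 3)

    def test_exhaustive_oracle_random_counts(self):
        # average distinct alleles over every g-subset, by direct enumeration
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 5, size=3)
        copies = np.repeat(np.arange(3), counts)
        g = 3
        subsets = list(itertools.combinations(range(len(copies)), g))
        mean_distinct = np.mean([len(set(copies[list(s)])) for s in subsets])
        assert allelic_richness(counts, g) == pytest.approx(mean_distinct)

    def test_g_equals_total_gives_observed_count(self):
        assert allelic_richness([3, 1, 2], 6) == pytest.approx(3.0)

    def test_monomorphic_is_one_for_any_g(self):
        for g in (1, 3, 6):
            assert allelic_richness([6], g) == pytest.approx(1.0)

    def test_g_too_large_rejected(self):
        with pytest.raises(ValueError):
            allelic_richness([2, 2], 5)


class TestNullAlleleEstimators:
    def test_equal_heterozygosities_give_zero(self):
        gm = make_genotypes(
            [("A", "a1", [(100, 120)]), ("A", "a2", [(100, 120)])], ["L1"]
        )
        # He = 0.5 < Ho = 1 -> clamped to 0
        assert null_allele_frequency(gm, "L1", "brookfield1") == 0.0

    def test_brookfield_arithmetic(self):
        # direct formula check: He=0.9, Ho=0.6 -> 0.3/1.9
        r = (0.9 - 0.6) / (1 + 0.9)
        assert r == pytest.approx(0.15789, abs=1e-4)

    def test_recovery_from_simulated_nulls(self):
        spec = PopSimSpec(n_demes=1, deme_sizes=500, n_loci=4, n_generations=0)
        gm = st.simulate_metapopulation(spec, seed=11).genotypes
        nulled = st.apply_null_alleles(gm, 0.2, seed=12)
        est_c = [null_allele_frequency(nulled, l, "chakraborty") for l in gm.loci]
        est_b = [null_allele_frequency(nulled, l, "brookfield1") for l in gm.loci]
        assert np.mean(est_c) == pytest.approx(0.2, abs=0.05)
        assert np.mean(est_b) == pytest.approx(0.2, abs=0.05)


def bruteforce_ss(records):
    """Independent AMOVA oracle: explicit pairwise allele-identity deviations.

    records: [(sample, (a1, a2)), ...] at one locus, fully called.
    Returns (SS among samples, SS among individuals within samples,
    SS within individuals) from group SS = (1/n) sum_{i<j} delta_ij.
    """
    def group_ss(copies):
        n = len(copies)
        return sum(
            copies[i] != copies[j] for i in range(n) for j in range(i + 1, n)
        ) / n

    all_copies = [a for _, g in records for a in g]
    ss_total = group_ss(all_copies)
    samples = sorted({s for s, _ in records})
    ss_within_samples = sum(
        group_ss([a for s, g in records if s == p for a in g]) for p in samples
    )
    ss_wi = sum(group_ss(list(g)) for _, g in records)
    return ss_total - ss_within_samples, ss_within_samples - ss_wi, ss_wi


class TestAmova:
    def test_brute_force_oracle_small_cases(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            records = []
            for s, n_ind in (("A", 3), ("B", 2)):
                for i in range(n_ind):
                    records.append((s, tuple(rng.integers(100, 104, size=2))))
            gm = make_genotypes(
                [(s, f"i{k}", [g]) for k, (s, g) in enumerate(records)], ["L1"]
            )
            codes = _encode_locus(gm, 0)
            sample_idx = (gm.samples == "B").astype(int)
            got = _locus_ss(codes, sample_idx, 2)
            expected = bruteforce_ss(records)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_fixed_difference_fixation(self, fixed_difference_genotypes):
        res = amova(fixed_difference_genotypes)
        assert res.fst == pytest.approx(1.0)
        assert res.fit == pytest.approx(1.0)

    def test_f_statistic_identity(self):
        spec = PopSimSpec(n_demes=4, deme_sizes=15, n_loci=5, n_generations=40)
        gm = st.simulate_metapopulation(spec, seed=7).genotypes
        res = amova(gm)
        assert (1 - res.fis) * (1 - res.fst) == pytest.approx(1 - res.fit, abs=1e-12)

    def test_df_bookkeeping_study_design(self):
        # 579 diploids in 25 samples -> df 24 / 554 / 579, total 1157
        sizes = [23] * 21 + [24] * 4  # 25 unequal samples totalling 579
        assert sum(sizes) == 579
        rng = np.random.default_rng(0)
        recs = []
        for p, n in enumerate(sizes):
            for i in range(n):
                recs.append((f"s{p}", f"i{p}_{i}",
                             [tuple(rng.integers(100, 110, size=2))]))
        gm = make_genotypes(recs, ["L1"])
        res = amova(gm)
        assert res.table["df"].tolist() == [24, 554, 579, 1157]

    def test_percentages_sum_to_hundred(self):
        spec = PopSimSpec(n_demes=3, deme_sizes=12, n_loci=3, n_generations=30)
        res = amova(st.simulate_metapopulation(spec, seed=9).genotypes)
        assert res.table.loc["total", "percent"] == pytest.approx(100.0)

    def test_small_sample_excluded_with_warning(self):
        recs = [("A", "a1", [(100, 101)]), ("A", "a2", [(100, 102)]),
                ("B", "b1", [(101, 102)]), ("B", "b2", [(100, 100)]),
                ("C", "c1", [(100, 101)])]
        gm = make_genotypes(recs, ["L1"])
        with pytest.warns(UserWarning, match="C"):
            res = amova(gm)
        assert res.table["df"].iloc[0] == 1  # two samples remain

    def test_permutation_p_uniform_under_null(self):
        # exchangeable data: one pool randomly split into two labelled samples
        rng = np.random.default_rng(21)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            recs = []
            for i in range(16):
                recs.append((("A", "B")[i % 2], f"i{i}",
                             [tuple(rng.integers(100, 104, size=2)) for _ in range(2)]))
            gm = make_genotypes(recs, ["L1", "L2"])
            res = amova(gm, n_permutations=59, seed=int(rng.integers(2**31)))
            rejections += res.p_fst <= 0.05
        lo, hi = sps.binom.interval(0.95, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_components_from_published_table(self):
        # printed variance components reproduce the printed F-statistics
        # components are printed to 3 decimals; ratios carry that rounding
        out = f_statistics_from_components(0.307, 1.193, 1.719)
        assert out["fst"] == pytest.approx(0.096, abs=1.5e-3)
        assert out["fis"] == pytest.approx(0.410, abs=1.5e-3)
        assert out["fit"] == pytest.approx(0.466, abs=1.5e-3)
        assert out["pct_within_individuals"] == pytest.approx(53.4, abs=0.1)


class TestPairwiseFst:
    def test_duplicated_sample_near_zero(self):
        rng = np.random.default_rng(13)
        recs = []
        for i in range(30):
            g = [tuple(rng.integers(100, 106, size=2)) for _ in range(3)]
            recs.append((("X", "Y")[i % 2], f"i{i}", g))
        gm = make_genotypes(recs, ["L1", "L2", "L3"])
        pw = pairwise_fst_matrix(gm, n_permutations=199, seed=1)
        assert pw.fst.loc["X", "Y"] < 0.05
        assert pw.p_values.loc["X", "Y"] > 0.05

    def test_fixed_difference_pair_is_one(self, fixed_difference_genotypes):
        pw = pairwise_fst_matrix(fixed_difference_genotypes)
        assert pw.fst.loc["A", "B"] == pytest.approx(1.0)

    def test_symmetry_zero_diagonal_and_clamping(self):
        spec = PopSimSpec(n_demes=3, deme_sizes=10, n_loci=3, n_generations=10)
        gm = st.simulate_metapopulation(spec, seed=3).genotypes
        pw = pairwise_fst_matrix(gm)
        f = pw.fst.to_numpy()
        np.testing.assert_allclose(f, f.T)
        assert (np.diag(f) == 0).all()
        assert (f >= 0).all()
        # raw values may be negative; clamped report never is
        assert pw.fst_raw.to_numpy().min() <= f.min() + 1e-15


class TestBonferroni:
    def test_study_scale(self):
        n_pairs, thr = bonferroni_threshold(0.05, 27)
        assert n_pairs == 351
        assert thr == pytest.approx(1.4245e-4, rel=1e-3)

    def test_two_samples(self):
        assert bonferroni_threshold(0.05, 2) == (1, 0.05)

    @pytest.mark.parametrize("n", [2, 5, 27, 100])
    def test_threshold_times_pairs_is_alpha(self, n):
        n_pairs, thr = bonferroni_threshold(0.05, n)
        assert n_pairs * thr == pytest.approx(0.05)
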