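"""Diversity statistics, the neutrality test battery, and UPGMA."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_alignment
from clonalpop.align_io import Alignment, write_newick
from clonalpop.errors import InputError, UndefinedStatisticError
from clonalpop.neutrality_stats import (
    ewens_haplotype_pmf,
    fu_fs,
    fu_li_d_star,
    fu_li_f_star,
    neutrality_significance,
    neutrality_summary,
    nucleotide_diversity,
    pairwise_distance_matrix,
    r2_from_counts,
    r2_statistic,
    segregating_sites,
    simulate_null_statistic,
    site_counts,
    tajima_d,
    tajima_d_by_class,
    upgma,
    watterson_theta,
)


def _aln(*seqs):
    return Alignment(
        ids=tuple(f"s{i}" for i in range(len(seqs))), seqs=tuple(seqs)
    )


class TestSegregatingSitesAndPi:
    def test_identical_sequences(self):
        aln = _aln("ACGTACGTAC", "ACGTACGTAC")
        assert segregating_sites(aln) == 0
        assert nucleotide_diversity(aln) == 0.0

    def test_two_sequences_three_diffs(self):
        aln = _aln("AAAAAAAAAA", "AAACCCAAAA")
        assert segregating_sites(aln) == 3
        assert nucleotide_diversity(aln) == pytest.approx(0.3)

    def test_four_sequence_hand_enumeration(self):
        aln = _aln("AAAA", "AAAT", "AATT", "CAAA")
        # 6 pairs: diffs 1,2,1 | 1,2 | 3 -> mean 10/6 over 4 sites
        assert nucleotide_diversity(aln) == pytest.approx(10 / 6 / 4)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_against_naive_column_and_pair_oracles(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=5, L=50)
        # naive column scan
        S = sum(
            len({s[c] for s in aln.seqs}) > 1 for c in range(aln.L)
        )
        assert segregating_sites(aln) == S
        # naive pair enumeration
        diffs = [
            sum(a != b for a, b in zip(x, y))
            for x, y in itertools.combinations(aln.seqs, 2)
        ]
        assert site_counts(aln).k_bar == pytest.approx(np.mean(diffs))

    def test_complete_deletion_drops_missing_columns(self):
        aln = _aln("ACGTN-", "ACCTAA")
        sc = site_counts(aln)
        assert sc.L == 4  # two columns removed
        assert sc.S == 1


class TestWattersonTheta:
    def test_published_chromosome_row(self):
        assert f"{watterson_theta(123, 14, 146721):.6f}" == "0.000264"

    def test_no_variation(self):
        assert watterson_theta(0, 10, 100) == 0.0

    def test_pair_of_sequences(self):
        # a1 = 1 for n = 2
        assert watterson_theta(5, 2, 100) == pytest.approx(0.05)


class TestTajimaD:
    @pytest.mark.parametrize(
        "L,S,pi,expected",
        [
            (146721, 123, 0.000135, -2.18),
            (66945, 58, 0.000136, -2.20),
        ],
    )
    def test_published_rows(self, L, S, pi, expected):
        assert tajima_d(pi * L, S, 14) == pytest.approx(expected, abs=0.02)

    def test_zero_numerator(self):
        a1 = sum(1 / i for i in range(1, 14))
        assert tajima_d(123 / a1, 123, 14) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_without_variation(self):
        with pytest.raises(UndefinedStatisticError):
            tajima_d(0.0, 0, 14)


def _fu_li_oracle(n):
    """Independent transcription of the corrected D*/F* variance constants."""
    an = np.sum(1.0 / np.arange(1, n))
    bn = np.sum(1.0 / np.arange(1, n) ** 2)
    an1 = an + 1.0 / n
    nn = float(n)
    cn = 2 * (nn * an - 2 * (nn - 1)) / ((nn - 1) * (nn - 2))
    dn = cn + (nn - 2) / (nn - 1) ** 2 + 2 / (nn - 1) * (
        1.5 - (2 * an1 - 3) / (nn - 2) - 1 / nn
    )
    frac = nn / (nn - 1)
    vd = (frac**2 * bn + an**2 * dn - 2 * nn * an * (an + 1) / (nn - 1) ** 2) / (
        an**2 + bn
    )
    ud = frac * (an - frac) - vd
    vf = (
        dn + 2 * (nn**2 + nn + 3) / (9 * nn * (nn - 1))
        - 2 / (nn - 1) * (4 * bn - 6 + 8 / nn)
    ) / (an**2 + bn)
    uf = (
        frac
        + (nn + 1) / (3 * (nn - 1))
        - 4 / (nn * (nn - 1))
        + 2 * (nn + 1) / (nn - 1) ** 2 * (an1 - 2 * nn / (nn + 1))
    ) / an - vf
    return an, ud, vd, uf, vf


class TestFuLi:
    def test_undefined_without_mutations(self):
        with pytest.raises(UndefinedStatisticError):
            fu_li_d_star(0, 0, 10)

    @pytest.mark.parametrize("n", range(5, 11))
    def test_against_independent_transcription(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            eta = int(rng.integers(1, 60))
            eta_s = int(rng.integers(0, eta + 1))
            kbar = float(rng.uniform(0, eta))
            an, ud, vd, uf, vf = _fu_li_oracle(n)
            d_exp = (n / (n - 1) * eta - an * eta_s) / math.sqrt(
                ud * eta + vd * eta**2
            )
            f_exp = (kbar - (n - 1) / n * eta_s) / math.sqrt(
                uf * eta + vf * eta**2
            )
            assert fu_li_d_star(eta, eta_s, n) == pytest.approx(d_exp, rel=1e-12)
            assert fu_li_f_star(kbar, eta, eta_s, n) == pytest.approx(
                f_exp, rel=1e-12
            )


def ewens_pmf_by_permutations(n, theta):
    """Exhaustive oracle: weight every permutation by theta^(#cycles)."""
    counts = np.zeros(n + 1)
    for p in itertools.permutations(range(n)):
        seen, cycles = set(), 0
        for i in range(n):
            if i not in seen:
                cycles += 1
                j = i
                while j not in seen:
                    seen.add(j)
                    j = p[j]
        counts[cycles] += theta**cycles
    rising = math.prod(theta + i for i in range(n))
    return counts / rising


class TestFuFs:
    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    @pytest.mark.parametrize("theta", [0.3, 1.0, 4.7])
    def test_pmf_matches_exhaustive_enumeration(self, n, theta):
        pmf = ewens_haplotype_pmf(n, theta)
        oracle = ewens_pmf_by_permutations(n, theta)
        assert pmf.sum() == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(pmf, oracle, rtol=1e-12)

    def test_fs_from_summed_tail(self):
        n, theta, k_obs = 5, 1.7, 3
        sp = ewens_pmf_by_permutations(n, theta)[k_obs:].sum()
        expected = math.log(sp / (1 - sp))
        assert fu_fs(theta, k_obs, n) == pytest.approx(expected, rel=1e-10)

    def test_single_haplotype_flagged(self):
        with pytest.raises(UndefinedStatisticError):
            fu_fs(2.0, 1, 10)

    def test_zero_diversity_flagged(self):
        with pytest.raises(UndefinedStatisticError):
            fu_fs(0.0, 3, 10)


class TestR2:
    def test_two_sequences_always_half(self):
        for S in (1, 4, 9):
            seqs = ["A" * 10, "C" * S + "A" * (10 - S)]
            assert r2_statistic(_aln(*seqs)) == pytest.approx(0.5)

    def test_hand_computation_n4(self):
        # S=2; each variant is a singleton carried by a different sequence
        aln = _aln("AAAA", "CAAA", "ATAA", "AAAA")
        sc = site_counts(aln)
        kbar = sc.k_bar
        U = [0, 1, 1, 0]
        expected = math.sqrt(np.mean((np.array(U) - kbar / 2) ** 2)) / 2
        assert r2_statistic(aln) == pytest.approx(expected)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_sequence_reordering(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=6, L=30)
        if site_counts(aln).S == 0:
            return
        perm = rng.permutation(6)
        shuffled = Alignment(
            ids=tuple(aln.ids[i] for i in perm),
            seqs=tuple(aln.seqs[i] for i in perm),
        )
        assert r2_statistic(shuffled) == pytest.approx(r2_statistic(aln))


class TestByClassD(object):
    def test_matches_split_then_compute_oracle(self, planted):
        reference, annotation, records = planted
        rng = np.random.default_rng(77)
        n = 6
        mat = [list(reference) for _ in range(n)]
        class_cols = {"synonymous": [], "non-synonymous": []}
        for rec in records:
            carriers = rng.choice(n, size=int(rng.integers(1, n)), replace=False)
            for i in carriers:
                mat[i][rec.position - 1] = rec.alt_allele
            if rec.snp_class == "sSNP":
                class_cols["synonymous"].append(rec.position - 1)
            elif rec.snp_class == "nsSNP":
                class_cols["non-synonymous"].append(rec.position - 1)
        aln = Alignment(
            ids=tuple(f"s{i}" for i in range(n)),
            seqs=tuple("".join(row) for row in mat),
        )
        for cls, cols in class_cols.items():
            sub = aln.subset_columns(cols)
            sc = site_counts(sub)
            expected = tajima_d(sc.k_bar, sc.S, n)
            assert tajima_d_by_class(aln, annotation, cls) == pytest.approx(expected)

    def test_all_identical_undefined(self, toy_genome):
        reference, annotation = toy_genome
        aln = Alignment(ids=("a", "b", "c", "d"), seqs=(reference,) * 4)
        for cls in ("synonymous", "non-synonymous"):
            with pytest.raises(UndefinedStatisticError):
                tajima_d_by_class(aln, annotation, cls)


class TestSignificance:
    def test_median_of_null_is_ns(self):
        null = simulate_null_statistic("tajima_d", 10, 10, reps=501, seed=4)
        bucket = neutrality_significance(
            "tajima_d", float(np.median(null)), 10, 10, reps=501, seed=4
        )
        assert bucket == "ns"

    def test_strongly_negative_d_significant(self):
        bucket = neutrality_significance("tajima_d", -2.18, 14, 123, reps=2000, seed=3)
        assert bucket == "<0.01"

    def test_deterministic_for_fixed_seed(self):
        kw = dict(n=14, S=40, reps=400, seed=9)
        b1 = neutrality_significance("tajima_d", -1.4, **kw)
        b2 = neutrality_significance("tajima_d", -1.4, **kw)
        assert b1 == b2

    def test_unknown_statistic_rejected(self):
        with pytest.raises(InputError):
            neutrality_significance("unknown", 0.0, 10, 5, reps=10, seed=0)


class TestSummaryBundle:
    def test_monomorphic_alignment_flags_instead_of_nan(self):
        summ = neutrality_summary(_aln("ACGT" * 5, "ACGT" * 5))
        assert summ.S == 0 and summ.tajima_d is None
        assert "tajima_d" in summ.undefined
        assert summ.pi == 0.0 and summ.theta_w == 0.0

    def test_polymorphic_alignment_reports_all(self):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, n=8, L=60)
        summ = neutrality_summary(aln)
        assert summ.S > 0
        for v in (summ.tajima_d, summ.fu_li_d_star, summ.fu_li_f_star, summ.r2):
            assert v is not None


class TestUpgma:
    def test_identical_sequences_zero_height_join(self):
        aln = _aln("ACGT", "ACGT", "TTTT")
        tree = upgma(pairwise_distance_matrix(aln), list(aln.ids))
        text = write_newick(tree)
        assert "(s0:0,s1:0)" in text

    def test_three_taxon_hand_agglomeration(self):
        m = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        tree = upgma(m, ["A", "B", "C"])
        assert write_newick(tree) == "((A:1,B:1):2,C:3);"

    def test_ultrametric_output(self):
        rng = np.random.default_rng(8)
        aln = random_alignment(rng, n=6, L=40)
        tree = upgma(pairwise_distance_matrix(aln), list(aln.ids))

        def depths(node, acc=0.0):
            if node.is_leaf:
                return [acc]
            out = []
            for c in node.children:
                out.extend(depths(c, acc + c.length))
            return out

        d = depths(tree)
        assert max(d) - min(d) < 1e-12

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_to_taxon_input_order(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=5, L=30)
        m = pairwise_distance_matrix(aln)
        labels = list(aln.ids)
        perm = rng.permutation(5)
        t1 = write_newick(upgma(m, labels))
        t2 = write_newick(upgma(m[np.ix_(perm, perm)], [labels[i] for i in perm]))
        import dendropy

        taxa = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1, schema="newick", taxon_namespace=taxa)
        d2 = dendropy.Tree.get(data=t2, schema="newick", taxon_namespace=taxa)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(d1, d2) == 0

    def test_negative_distance_rejected(self):
        with pytest.raises(InputError):
            upgma(np.array([[0, -1], [-1, 0]], float), ["A", "B"])
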