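"""Degeneracy, s/ns classification, the expected ns/s null, and filters."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonalpop.align_io import AnnotationTable, Feature
from clonalpop.errors import (
    ConsistencyError,
    CoordinateError,
    DegeneracyError,
    InputError,
    StopCodonError,
)
from clonalpop.snp_classification import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    FilterThresholds,
    VariantSiteSummary,
    apply_snp_filters,
    classify_snp,
    codon_degeneracy,
    count_degenerate_sites,
    expected_ns_s_ratio,
    snp_class_summary,
)


class TestDegeneracy:
    @pytest.mark.parametrize(
        "codon,site,fold",
        [
            ("GGG", 3, 4),  # glycine third position
            ("ATG", 1, 0),  # Met: any change is non-synonymous
            ("AAT", 3, 2),  # Asn AAT/AAC
            ("ATT", 3, 3),  # Ile ATT/ATC/ATA
            ("CGA", 1, 2),  # Arg CGA/AGA
        ],
    )
    def test_fold_classes(self, codon, site, fold):
        assert codon_degeneracy(codon, site) == fold

    def test_stop_codon_excluded(self):
        with pytest.raises(StopCodonError):
            codon_degeneracy("TAA", 3)

    def test_ambiguous_base_rejected(self):
        with pytest.raises(DegeneracyError):
            codon_degeneracy("ANG", 1)

    def test_counts_partition_sense_codon_sites(self):
        """0+2+3+4-fold counts cover every site of every sense codon."""
        counts = count_degenerate_sites(SENSE_CODONS)
        assert counts.total == 3 * len(SENSE_CODONS)

    def test_internal_stop_rejected(self):
        with pytest.raises(InputError):
            count_degenerate_sites(["ATGTAAGGG"])


def brute_force_ns_s(cds_seqs):
    """Independent oracle: enumerate all single-base changes one by one."""
    syn = ns = 0
    for seq in cds_seqs:
        for ci in range(len(seq) // 3):
            codon = seq[3 * ci : 3 * ci + 3]
            aa = CODON_TO_AA.get(codon, "*")
            if aa == "*":
                continue
            for i in range(3):
                for b in "ACGT":
                    if b == codon[i]:
                        continue
                    mutated = codon[:i] + b + codon[i + 1 :]
                    if CODON_TO_AA.get(mutated, "*") == aa:
                        syn += 1
                    else:
                        ns += 1
    return ns, syn


class TestExpectedRatio:
    def test_atg_ggg(self):
        # ATG: 9/9 non-synonymous; GGG: 3 synonymous at the third position
        assert expected_ns_s_ratio(["ATGGGG"]) == pytest.approx(15 / 3)

    def test_fourfold_only_hypothetical_code(self):
        # degenerate limit: a code where every 3rd position is synonymous
        code = {a + b + c: a + b for a in BASES for b in BASES for c in BASES}
        assert expected_ns_s_ratio(["ACGTGC"], code=code) == pytest.approx(6 / 3)

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            expected_ns_s_ratio([])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        seqs = [
            "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), 12))
            for _ in range(3)
        ]
        ns, syn = brute_force_ns_s(seqs)
        assert expected_ns_s_ratio(seqs) == pytest.approx(ns / syn, abs=0)


TOY_REF = "ATGGGGTTTTTT"
TOY_ANN = AnnotationTable(
    features=(Feature("g1", "chr", 1, 6, "+", "CDS"),),
    references={"chr": TOY_REF},
)


class TestClassify:
    def test_synonymous_fourfold(self):
        rec = classify_snp(6, "G", "A", TOY_ANN)
        assert rec.snp_class == "sSNP" and rec.feature_id == "g1"

    def test_nonsynonymous(self):
        assert classify_snp(4, "G", "A", TOY_ANN).snp_class == "nsSNP"

    def test_intergenic(self):
        rec = classify_snp(10, "T", "C", TOY_ANN)
        assert rec.snp_class == "iSNP" and rec.feature_id is None

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            classify_snp(6, "T", "A", TOY_ANN)

    def test_out_of_range_rejected(self):
        with pytest.raises(CoordinateError):
            classify_snp(99, "G", "A", TOY_ANN)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_strand_symmetry(self, seed):
        """Classification on a − strand CDS equals the + strand construction."""
        rng = np.random.default_rng(seed)
        coding = "ATG" + "".join(
            SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), 4)
        ) + "TAA"
        L = len(coding)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        minus_ref = "".join(comp[b] for b in reversed(coding))
        plus = AnnotationTable(
            features=(Feature("g", "chr", 1, L, "+", "CDS"),),
            references={"chr": coding},
        )
        minus = AnnotationTable(
            features=(Feature("g", "chr", 1, L, "-", "CDS"),),
            references={"chr": minus_ref},
        )
        pos = int(rng.integers(1, L + 1))
        ref_plus = coding[pos - 1]
        alt_plus = rng.choice([b for b in "ACGT" if b != ref_plus])
        plus_class = classify_snp(pos, ref_plus, alt_plus, plus).snp_class
        # the same biological change on the reverse-complemented genome
        pos_minus = L - pos + 1
        minus_class = classify_snp(
            pos_minus, comp[ref_plus], comp[alt_plus], minus
        ).snp_class
        assert plus_class == minus_class


class TestSummary:
    def test_published_style_accounting(self):
        labels = ["sSNP"] * 109 + ["nsSNP"] * 178 + ["iSNP"] * 83
        s = snp_class_summary(labels)
        assert s.total == 370
        assert s.ns_s_ratio == 1.63
        assert s.fractions_pct == {"sSNP": 29.5, "nsSNP": 48.1, "iSNP": 22.4}

    def test_even_split(self):
        s = snp_class_summary(["sSNP", "nsSNP"])
        assert s.ns_s_ratio == 1.0
        assert s.fractions_pct == {"sSNP": 50.0, "nsSNP": 50.0, "iSNP": 0.0}

    def test_no_ssnp_ratio_undefined(self):
        assert snp_class_summary(["nsSNP"] * 5).ns_s_ratio is None

    @given(
        st.tuples(
            st.integers(0, 400), st.integers(0, 400), st.integers(0, 400)
        ).filter(lambda t: sum(t) > 0)
    )
    def test_fractions_sum_to_100(self, counts):
        s_, n_, i_ = counts
        s = snp_class_summary(["sSNP"] * s_ + ["nsSNP"] * n_ + ["iSNP"] * i_)
        assert sum(s.fractions_pct.values()) == pytest.approx(100.0, abs=0.31)


class TestFilters:
    def _site(self, **kw):
        base = dict(
            coverage=60,
            alt_reads=60,
            variant_p=1e-8,
            strand_bias_p=1.0,
            alt_fraction_unique=1.0,
            strand_bias_fraction=0.5,
        )
        base.update(kw)
        return VariantSiteSummary(**base)

    def test_low_coverage_rejected(self):
        res = apply_snp_filters(self._site(coverage=5, alt_reads=5))
        assert not res.accepted and res.failed == ("coverage",)

    def test_boundary_coverage_accepted(self):
        assert apply_snp_filters(self._site(coverage=6, alt_reads=6)).accepted

    def test_allele_fraction_rejected(self):
        res = apply_snp_filters(self._site(alt_fraction_unique=0.94))
        assert res.failed == ("allele-fraction",)

    def test_boundary_allele_fraction_accepted(self):
        assert apply_snp_filters(self._site(alt_fraction_unique=0.95)).accepted

    def test_variant_p_boundary(self):
        assert apply_snp_filters(self._site(variant_p=6e-6)).accepted
        assert not apply_snp_filters(self._site(variant_p=6.1e-6)).accepted

    def test_strand_bias_two_part_rule(self):
        # biased beyond 65 % with a bad P-value: rejected
        res = apply_snp_filters(
            self._site(strand_bias_fraction=0.8, strand_bias_p=1e-6)
        )
        assert res.failed == ("strand-bias",)
        # same P-value but bias below the cutoff: the sub-filter passes
        assert apply_snp_filters(
            self._site(strand_bias_fraction=0.6, strand_bias_p=1e-6)
        ).accepted
        # biased but P-value at the threshold: accepted
        assert apply_snp_filters(
            self._site(strand_bias_fraction=0.8, strand_bias_p=5e-5)
        ).accepted

    def test_clean_site_accepted(self):
        assert apply_snp_filters(self._site()).accepted

    def test_malformed_summary_rejected(self):
        with pytest.raises(InputError):
            VariantSiteSummary(coverage=5, alt_reads=6, variant_p=0.1)

    def test_reject_lists_every_failed_condition(self):
        res = apply_snp_filters(
            self._site(coverage=5, alt_reads=5, variant_p=0.5, alt_fraction_unique=0.5)
        )
        assert set(res.failed) == {"coverage", "variant-p", "allele-fraction"}
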