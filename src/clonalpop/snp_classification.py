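"""Classify SNPs as synonymous / non-synonymous / intergenic.

Also: codon degeneracy (0/2/3/4-fold) accounting, the degeneracy-based
expected nsSNP/sSNP null ratio (every one of the three possible changes at
every coding site enumerated and classified under the standard genetic
code), and the per-site read filters used when accepting variant calls.

Conventions
-----------
* Stop codons are excluded from degeneracy counting and from the null
  enumeration; a mutation *creating* a stop counts as non-synonymous.
* 3-fold degenerate sites (Ile third positions) are tracked as their own
  class; the 0/2/4 summary reports them separately.
* A variant inside no CDS is an iSNP regardless of nearby features.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .align_io import AnnotationTable, Feature
from .errors import (
    AnnotationError,
    ConsistencyError,
    CoordinateError,
    DegeneracyError,
    InputError,
    StopCodonError,
)

BASES = ("A", "C", "G", "T")

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, with '*' for stops (standard code)
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_standard.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*"))


@dataclass(frozen=True)
class SnpRecord:
    """One classified variant (1-based position on its replicon)."""

    replicon: str
    position: int
    ref_allele: str
    alt_allele: str
    snp_class: str  # 'sSNP' | 'nsSNP' | 'iSNP'
    feature_id: str | None = None

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise InputError("ref_allele equals alt_allele")
        if (self.snp_class == "iSNP") != (self.feature_id is None):
            raise InputError("iSNP iff no host feature")


@dataclass(frozen=True)
class DegeneracyCounts:
    """Counts of coding sites by degeneracy fold (sense codons only)."""

    zero_fold: int = 0
    two_fold: int = 0
    three_fold: int = 0
    four_fold: int = 0

    @property
    def total(self) -> int:
        return self.zero_fold + self.two_fold + self.three_fold + self.four_fold


def codon_degeneracy(codon: str, site_index: int, code: Mapping[str, str] | None = None) -> int:
    """Degeneracy fold class (0, 2, 3 or 4) of one codon position.

    ``site_index`` is 1, 2 or 3.  The fold class is the number of bases at
    that position preserving the amino acid (1 base -> 0-fold, 2 -> 2-fold,
    3 -> 3-fold, 4 -> 4-fold).  ``code`` may override the genetic code for
    testing; changes to stop codons never count as preserving.
    """
    table = CODON_TO_AA if code is None else code
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise DegeneracyError(f"bad codon {codon!r}")
    if site_index not in (1, 2, 3):
        raise DegeneracyError(f"site_index must be 1..3, got {site_index}")
    aa = table.get(codon)
    if aa is None or aa == "*":
        raise StopCodonError(f"stop codon {codon} excluded from degeneracy")
    i = site_index - 1
    same = 0
    for b in BASES:
        alt = codon[:i] + b + codon[i + 1 :]
        if table.get(alt) == aa:
            same += 1
    return {1: 0, 2: 2, 3: 3, 4: 4}[same]


def count_degenerate_sites(
    cds_seqs: Iterable[str], code: Mapping[str, str] | None = None
) -> DegeneracyCounts:
    """Tally 0/2/3/4-fold degenerate sites over coding sequences.

    Terminal (and any) stop codons are skipped; internal stops raise.
    """
    table = CODON_TO_AA if code is None else code
    counts = Counter()
    for seq in cds_seqs:
        seq = seq.upper()
        if len(seq) % 3:
            raise InputError(f"CDS length {len(seq)} not divisible by 3")
        n_codons = len(seq) // 3
        for ci in range(n_codons):
            codon = seq[3 * ci : 3 * ci + 3]
            if table.get(codon, "*") == "*":
                if ci != n_codons - 1:
                    raise InputError(f"internal stop codon {codon} at codon {ci + 1}")
                continue
            for pos in (1, 2, 3):
                counts[codon_degeneracy(codon, pos, code=table)] += 1
    return DegeneracyCounts(
        zero_fold=counts[0],
        two_fold=counts[2],
        three_fold=counts[3],
        four_fold=counts[4],
    )


def expected_ns_s_ratio(
    cds_seqs: Sequence[str], code: Mapping[str, str] | None = None
) -> float:
    """Expected nsSNP/sSNP ratio under equiprobable point mutation.

    Every coding site contributes its 3 possible single-base changes; each
    change is synonymous or non-synonymous under the (standard) code, with
    changes to stop codons counted as non-synonymous.  Stop codons
    themselves are excluded from the enumeration.
    """
    if not cds_seqs:
        raise InputError("empty CDS set")
    table = CODON_TO_AA if code is None else code
    syn = 0
    nonsyn = 0
    for seq in cds_seqs:
        seq = seq.upper()
        if len(seq) % 3:
            raise InputError(f"CDS length {len(seq)} not divisible by 3")
        for ci in range(len(seq) // 3):
            codon = seq[3 * ci : 3 * ci + 3]
            aa = table.get(codon, "*")
            if aa == "*":
                continue
            for i in range(3):
                for b in BASES:
                    if b == codon[i]:
                        continue
                    alt = codon[:i] + b + codon[i + 1 :]
                    if table.get(alt) == aa:
                        syn += 1
                    else:
                        nonsyn += 1
    if syn == 0:
        raise InputError("no synonymous mutation opportunities in CDS set")
    return nonsyn / syn


def classify_snp(
    position: int,
    ref: str,
    alt: str,
    annotation: AnnotationTable,
    replicon: str | None = None,
) -> SnpRecord:
    """Classify one variant as sSNP / nsSNP / iSNP.

    The variant is intergenic when no CDS covers ``position``; otherwise
    the affected codon is translated (strand-aware) with the reference and
    the alternate base, and identical amino acids mean synonymous.
    """
    ref, alt = ref.upper(), alt.upper()
    if replicon is None:
        if len(annotation.references) != 1:
            raise InputError("replicon must be given for multi-replicon annotation")
        replicon = next(iter(annotation.references))
    refseq = annotation.references.get(replicon)
    if refseq is None:
        raise CoordinateError(f"unknown replicon {replicon!r}")
    if not (1 <= position <= len(refseq)):
        raise CoordinateError(f"position {position} outside {replicon}")
    if refseq[position - 1] != ref:
        raise ConsistencyError(
            f"{replicon}:{position}: reference has {refseq[position - 1]}, "
            f"variant says {ref}"
        )
    feature = annotation.feature_at(replicon, position, kind="CDS")
    if feature is None:
        return SnpRecord(replicon, position, ref, alt, "iSNP", None)

    ref_codon, alt_codon = _affected_codons(feature, refseq, position, alt)
    aa_ref = CODON_TO_AA.get(ref_codon)
    aa_alt = CODON_TO_AA.get(alt_codon)
    if aa_ref is None or aa_alt is None:
        raise AnnotationError(f"untranslatable codon in {feature.feature_id}")
    cls = "sSNP" if aa_ref == aa_alt else "nsSNP"
    return SnpRecord(replicon, position, ref, alt, cls, feature.feature_id)


def _affected_codons(
    feature: Feature, refseq: str, position: int, alt: str
) -> tuple[str, str]:
    """Reference and mutated codon (coding orientation) at a CDS position."""
    if feature.strand == "+":
        offset = position - feature.start
        base_alt = alt
    else:
        offset = feature.end - position
        base_alt = str(Seq(alt).complement())
    cds = refseq[feature.start - 1 : feature.end]
    if feature.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    ci, within = divmod(offset, 3)
    ref_codon = cds[3 * ci : 3 * ci + 3]
    alt_codon = ref_codon[:within] + base_alt + ref_codon[within + 1 :]
    return ref_codon, alt_codon


@dataclass(frozen=True)
class SnpClassSummary:
    """Per-class counts and fractions plus the observed ns/s ratio."""

    counts: Mapping[str, int]
    fractions_pct: Mapping[str, float]  # percent, rounded to 1 decimal
    total: int
    ns_s_ratio: float | None  # rounded to 2 decimals; None when no sSNPs


def snp_class_summary(records: Sequence[SnpRecord | str]) -> SnpClassSummary:
    """Tabulate classified SNPs the way a segregating-sites table reports them.

    Accepts SnpRecords or bare class labels.  The ratio is undefined (None)
    when there are no sSNPs — never reported as infinity.
    """
    if not records:
        raise InputError("no SNP records")
    labels = [r.snp_class if isinstance(r, SnpRecord) else r for r in records]
    bad = set(labels) - {"sSNP", "nsSNP", "iSNP"}
    if bad:
        raise InputError(f"unknown SNP classes {sorted(bad)}")
    counts = {c: labels.count(c) for c in ("sSNP", "nsSNP", "iSNP")}
    total = len(labels)
    fractions = {c: round(100.0 * k / total, 1) for c, k in counts.items()}
    ratio = (
        round(counts["nsSNP"] / counts["sSNP"], 2) if counts["sSNP"] else None
    )
    return SnpClassSummary(
        counts=counts, fractions_pct=fractions, total=total, ns_s_ratio=ratio
    )


@dataclass(frozen=True)
class VariantSiteSummary:
    """Per-site read evidence for a candidate variant call."""

    coverage: int
    alt_reads: int
    variant_p: float
    strand_bias_p: float = 1.0
    alt_fraction_unique: float = 1.0
    #: fraction of variant reads on the majority strand (0.5 = unbiased)
    strand_bias_fraction: float = 0.5

    def __post_init__(self):
        if not (0 <= self.alt_reads <= self.coverage):
            raise InputError("alt_reads must be within [0, coverage]")
        for p in (self.variant_p, self.strand_bias_p):
            if not (0.0 <= p <= 1.0):
                raise InputError("P-values must be in [0, 1]")
        if not (0.0 <= self.alt_fraction_unique <= 1.0):
            raise InputError("alt_fraction_unique must be in [0, 1]")


@dataclass(frozen=True)
class FilterThresholds:
    """Acceptance thresholds for candidate variant sites.

    Defaults are the stringent short-read calling settings this package
    targets: coverage >= 6 reads, variant P <= 6e-6, a strand-bias P >=
    5e-5 applied only when more than 65 % of variant reads sit on one
    strand, and the variant present in >= 95 % of unique reads.
    """

    min_coverage: int = 6
    max_variant_p: float = 6e-6
    min_strand_bias_p: float = 5e-5
    strand_bias_cutoff: float = 0.65
    min_alt_fraction_unique: float = 0.95


@dataclass(frozen=True)
class FilterResult:
    accepted: bool
    failed: tuple[str, ...] = ()


def apply_snp_filters(
    site: VariantSiteSummary, thresholds: FilterThresholds | None = None
) -> FilterResult:
    """Accept or reject a candidate variant site, with reason codes.

    The strand-bias check is two-part: the P-value threshold applies only
    when the majority-strand fraction exceeds the bias cutoff; otherwise
    that sub-filter passes.
    """
    t = thresholds or FilterThresholds()
    failed: list[str] = []
    if site.coverage < t.min_coverage:
        failed.append("coverage")
    if site.variant_p > t.max_variant_p:
        failed.append("variant-p")
    if (
        site.strand_bias_fraction > t.strand_bias_cutoff
        and site.strand_bias_p < t.min_strand_bias_p
    ):
        failed.append("strand-bias")
    if site.alt_fraction_unique < t.min_alt_fraction_unique:
        failed.append("allele-fraction")
    return FilterResult(accepted=not failed, failed=tuple(failed))
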