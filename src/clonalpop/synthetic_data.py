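"""Synthetic inputs with known truth: coalescent alignments and toy genomes.

Two generators back the whole test surface:

* an infinite-sites coalescent simulator for haploid samples under
  constant size, sudden expansion or exponential growth — every
  neutrality statistic and the mismatch model can be checked against the
  demography that actually generated the data;
* a codon-structured toy reference genome (alternating CDS / intergenic
  segments) with planted SNPs whose synonymous / non-synonymous /
  intergenic class is known by construction.

Time units: the constant and exponential models run in coalescent units
with mutations at rate θ/2 per branch per unit; the sudden-expansion
model runs in mutational units (τ = 2υt) with pair-coalescence rate
1/θ(s) — θ(s) = θ1 more recently than τ, θ0 earlier — and mutations at
rate 1/2 per branch per unit.  This makes simulated expansions directly
comparable with the sudden-expansion mismatch formula (same θ0, θ1, τ).

Mutations are placed at uniformly drawn *distinct* sites (sampling
without replacement), so the infinite-sites property holds exactly; a
capacity check refuses loci where a with-replacement placement would have
collided with probability ≥ 1 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Mapping

import numpy as np

from .align_io import Alignment, AnnotationTable, Feature, TreeNode
from .errors import CapacityError, InputError, SiteCapacityError
from .snp_classification import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    SnpRecord,
    codon_degeneracy,
)

__all__ = [
    "DemographicModel",
    "SimulatedSample",
    "simulate_coalescent",
    "simulate_population_panel",
    "generate_toy_genome",
    "plant_snps",
]


@dataclass(frozen=True)
class DemographicModel:
    """Generative regime for the coalescent simulator."""

    kind: str  # 'constant' | 'sudden_expansion' | 'exponential_growth'
    theta: float | None = None
    theta0: float | None = None
    theta1: float | None = None
    tau: float | None = None
    growth_rate: float | None = None

    def __post_init__(self):
        if self.kind == "constant":
            ok = self.theta is not None and self.theta >= 0
            extra = (self.theta0, self.theta1, self.tau, self.growth_rate)
        elif self.kind == "sudden_expansion":
            ok = all(
                v is not None and v >= 0 for v in (self.theta0, self.theta1, self.tau)
            ) and self.theta1 > 0
            extra = (self.theta, self.growth_rate)
        elif self.kind == "exponential_growth":
            ok = (
                self.theta is not None
                and self.theta >= 0
                and self.growth_rate is not None
                and self.growth_rate > 0
            )
            extra = (self.theta0, self.theta1, self.tau)
        else:
            raise InputError(f"unknown demographic model {self.kind!r}")
        if not ok:
            raise InputError(f"missing/invalid parameters for {self.kind}")
        if any(v is not None for v in extra):
            raise InputError(f"extraneous parameters for {self.kind}")

    @classmethod
    def constant(cls, theta: float) -> "DemographicModel":
        return cls(kind="constant", theta=theta)

    @classmethod
    def sudden_expansion(
        cls, theta0: float, theta1: float, tau: float
    ) -> "DemographicModel":
        return cls(kind="sudden_expansion", theta0=theta0, theta1=theta1, tau=tau)

    @classmethod
    def exponential_growth(cls, theta: float, growth_rate: float) -> "DemographicModel":
        return cls(kind="exponential_growth", theta=theta, growth_rate=growth_rate)

    @property
    def mutation_rate_per_branch(self) -> float:
        """Poisson mutation intensity per branch per unit of the model's time."""
        if self.kind == "sudden_expansion":
            return 0.5
        return self.theta / 2.0


@dataclass(frozen=True)
class SimulatedSample:
    """One simulated alignment plus its generating truth."""

    alignment: Alignment
    genealogy: TreeNode
    mutation_positions: tuple[int, ...]  # 0-based site indices
    true_model: DemographicModel
    seed: int


def _pair_rate(model: DemographicModel, t: float) -> float:
    """Coalescence rate per lineage pair at time ``t`` before present."""
    if model.kind == "constant":
        return 1.0
    if model.kind == "exponential_growth":
        return float(np.exp(model.growth_rate * t))
    return 1.0 / (model.theta1 if t < model.tau else model.theta0)


@lru_cache(maxsize=128)
def expected_mutation_count(n: int, model: DemographicModel) -> float:
    """E[number of mutations] = μ · E[total branch length] under the model.

    For the constant model this is θ·a1 in closed form; otherwise the
    expected total length is integrated exactly from the lineage-count
    death process dp_k/dt = λ(t)[C(k+1,2)p_{k+1} − C(k,2)p_k].
    """
    mu = model.mutation_rate_per_branch
    if model.kind == "constant":
        return model.theta * sum(1.0 / i for i in range(1, n))
    from scipy.integrate import solve_ivp

    def rhs(t, y):
        p = y[: n + 1]  # p[k] = P(k lineages), k = 0..n
        lam = _pair_rate(model, t)
        dp = np.zeros(n + 1)
        for k in range(2, n + 1):
            rate_k = lam * k * (k - 1) / 2.0
            dp[k] -= rate_k * p[k]
            dp[k - 1] += rate_k * p[k]
        total_rate = sum(k * p[k] for k in range(2, n + 1))
        return np.append(dp, total_rate)

    def absorbed(t, y):
        return float(np.sum(y[2 : n + 1])) - 1e-10

    absorbed.terminal = True
    y0 = np.zeros(n + 2)
    y0[n] = 1.0
    if model.kind == "sudden_expansion":
        t_max = model.tau + 100.0 * max(model.theta0, 1e-3)
    else:
        t_max = 100.0
    sol = solve_ivp(
        rhs, (0.0, t_max), y0, events=absorbed, rtol=1e-9, atol=1e-12,
        max_step=t_max / 50.0,
    )
    return mu * float(sol.y[-1, -1])


def _draw_intervals(n: int, model: DemographicModel, rng: np.random.Generator):
    """Coalescence times t_n < t_{n-1} < ... < t_2 under the model.

    Returns the absolute merge times (model time units, 0 = present) for
    the n-1 coalescence events.
    """
    times = []
    t = 0.0
    for k in range(n, 1, -1):
        pairs = k * (k - 1) / 2.0
        if model.kind == "constant":
            t += rng.exponential(1.0 / pairs)
        elif model.kind == "exponential_growth":
            # intensity pairs * e^{g t}; invert the cumulative hazard
            g = model.growth_rate
            e = rng.exponential(1.0)
            t = np.log(np.exp(g * t) + g * e / pairs) / g
        else:  # sudden_expansion, mutational-time units
            while True:
                theta_now = model.theta1 if t < model.tau else model.theta0
                rate = pairs / theta_now
                w = rng.exponential(1.0 / rate)
                if t >= model.tau or t + w <= model.tau:
                    t = t + w
                    break
                t = model.tau  # epoch boundary: redraw in the older epoch
        times.append(t)
    return times


def _build_genealogy(
    n: int, times: list[float], ids: list[str], rng: np.random.Generator
) -> tuple[TreeNode, list[tuple[float, int]]]:
    """Random-topology genealogy; returns (root, branches as (length, leafset))."""
    active: list[tuple[TreeNode, float, int]] = [
        (TreeNode(name=ids[i]), 0.0, 1 << i) for i in range(n)
    ]
    branches: list[tuple[float, int]] = []
    for t in times:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        node_j, birth_j, set_j = active.pop(j)
        node_i, birth_i, set_i = active.pop(i)
        node_i.length = t - birth_i
        node_j.length = t - birth_j
        branches.append((node_i.length, set_i))
        branches.append((node_j.length, set_j))
        active.append((TreeNode(children=(node_i, node_j)), t, set_i | set_j))
    root = active[0][0]
    return root, branches


def simulate_coalescent(
    n: int,
    model: DemographicModel,
    L: int,
    seed: int,
    ids: list[str] | None = None,
) -> SimulatedSample:
    """Simulate one haploid sample of ``n`` sequences of length ``L``.

    The genealogy is drawn under ``model``; mutations fall as a Poisson
    process on branches and land at distinct uniformly drawn sites (the
    ancestral base is A everywhere; a mutation flips its site to a random
    other base in all carriers).  Bit-identical for a fixed seed.
    """
    if n < 2:
        raise InputError("need n >= 2")
    if L < 1:
        raise InputError("need L >= 1")
    if ids is None:
        ids = [f"iso{i + 1:02d}" for i in range(n)]
    rng = np.random.default_rng(seed)
    times = _draw_intervals(n, model, rng)
    root, branches = _build_genealogy(n, times, ids, rng)

    mu = model.mutation_rate_per_branch
    total_len = sum(b for b, _ in branches)
    # model-level capacity: with-replacement collision mass for E[mutations]
    e_mut = expected_mutation_count(n, model)
    if e_mut > 1 and 1.0 - np.exp(-e_mut * (e_mut - 1) / (2.0 * L)) >= 0.01:
        raise SiteCapacityError(
            f"L={L} too short for ~{e_mut:.0f} expected infinite-sites mutations"
        )
    n_mut = rng.poisson(mu * total_len) if mu > 0 else 0
    if n_mut > L:
        raise SiteCapacityError(f"{n_mut} mutations exceed {L} sites")
    positions = np.sort(rng.choice(L, size=n_mut, replace=False))
    if n_mut:
        lengths = np.array([b for b, _ in branches])
        branch_idx = rng.choice(
            len(branches), size=n_mut, p=lengths / lengths.sum()
        )
    else:
        branch_idx = np.array([], dtype=int)

    mat = np.full((n, L), ord("A"), dtype=np.uint8)
    alt_bases = [ord(b) for b in BASES if b != "A"]
    for pos, bi in zip(positions, branch_idx):
        leafset = branches[bi][1]
        alt = alt_bases[rng.integers(3)]
        for i in range(n):
            if leafset >> i & 1:
                mat[i, pos] = alt
    aln = Alignment(
        ids=tuple(ids),
        seqs=tuple(bytes(row).decode("ascii") for row in mat),
    )
    return SimulatedSample(
        alignment=aln,
        genealogy=root,
        mutation_positions=tuple(int(p) for p in positions),
        true_model=model,
        seed=seed,
    )


def simulate_population_panel(
    model: DemographicModel, n: int, L: int, reps: int, seed: int
) -> Iterator[SimulatedSample]:
    """Independent replicates with a documented counter-based seed scheme.

    Per-replicate seeds come from ``numpy.random.SeedSequence(seed)``
    state expansion, truncated below 2^31, so any replicate can be
    regenerated in isolation from (seed, index).
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    child_seeds = (
        np.random.SeedSequence(seed).generate_state(reps, dtype=np.uint32)
        & 0x7FFFFFFF
    )
    for s in child_seeds:
        yield simulate_coalescent(n, model, L, int(s))


# ---------------------------------------------------------------------------
# toy genomes with planted variants
# ---------------------------------------------------------------------------


def generate_toy_genome(
    n_cds: int,
    cds_len: int,
    igr_len: int,
    seed: int,
    replicon: str = "chr",
) -> tuple[str, AnnotationTable]:
    """Random reference of alternating CDS and intergenic segments.

    Each CDS is ATG + random sense codons + a stop codon on a random
    strand; intergenic segments are uniform random bases.  The returned
    annotation validates by construction.
    """
    if cds_len % 3:
        raise InputError("cds_len must be divisible by 3")
    if cds_len < 6:
        raise InputError("cds_len must be >= 6 (start + stop)")
    rng = np.random.default_rng(seed)
    internal = tuple(c for c in SENSE_CODONS if c != "ATG") or SENSE_CODONS
    stops = sorted(STOP_CODONS)
    parts: list[str] = []
    feats: list[Feature] = []
    pos = 1
    for gi in range(n_cds):
        coding = (
            "ATG"
            + "".join(
                internal[rng.integers(len(internal))]
                for _ in range((cds_len - 6) // 3)
            )
            + stops[rng.integers(len(stops))]
        )
        strand = "+" if rng.integers(2) == 0 else "-"
        segment = coding if strand == "+" else _revcomp(coding)
        parts.append(segment)
        feats.append(
            Feature(f"g{gi + 1}", replicon, pos, pos + cds_len - 1, strand, "CDS")
        )
        pos += cds_len
        if igr_len > 0:
            igr = "".join(BASES[rng.integers(4)] for _ in range(igr_len))
            parts.append(igr)
            feats.append(
                Feature(f"igr{gi + 1}", replicon, pos, pos + igr_len - 1, "+", "IGR")
            )
            pos += igr_len
    reference = "".join(parts)
    table = AnnotationTable(features=tuple(feats), references={replicon: reference})
    return reference, table


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _coding_context(feature: Feature, reference: str, position: int):
    """(codon, within-codon index 0..2, coding-strand ref base) at a CDS site."""
    cds = reference[feature.start - 1 : feature.end]
    if feature.strand == "-":
        cds = _revcomp(cds)
        offset = feature.end - position
    else:
        offset = position - feature.start
    ci, within = divmod(offset, 3)
    return cds[3 * ci : 3 * ci + 3], within, cds[offset]


def plant_snps(
    reference: str,
    annotation: AnnotationTable,
    class_counts: Mapping[str, int],
    seed: int,
    replicon: str | None = None,
) -> list[SnpRecord]:
    """Plant SNPs whose class is known by construction.

    ``class_counts`` maps 'sSNP' / 'nsSNP' / 'iSNP' to requested counts.
    Synonymous variants are drawn at degenerate (2/3/4-fold) codon
    positions with a synonymous alternate base; non-synonymous variants
    use an amino-acid-changing alternate; intergenic variants land in IGR
    features.  At most one variant per reference position.  Raises
    CapacityError when the genome cannot host the request.
    """
    unknown = set(class_counts) - {"sSNP", "nsSNP", "iSNP"}
    if unknown:
        raise InputError(f"unknown classes {sorted(unknown)}")
    if replicon is None:
        if len(annotation.references) != 1:
            raise InputError("replicon required with multi-replicon annotation")
        replicon = next(iter(annotation.references))
    rng = np.random.default_rng(seed)

    syn_candidates: list[tuple[int, str, str]] = []  # (pos, ref, alt)
    ns_candidates: list[tuple[int, str, str]] = []
    for f in annotation.cds_features(replicon):
        for position in range(f.start, f.end + 1):
            codon, within, _ = _coding_context(f, reference, position)
            aa = CODON_TO_AA.get(codon)
            if aa is None or aa == "*":
                continue  # stop codon: skip entirely
            ref_base = reference[position - 1]
            syn_alts = []
            ns_alts = []
            for b in BASES:
                if b == codon[within]:
                    continue
                alt_codon = codon[:within] + b + codon[within + 1 :]
                genomic_alt = b if f.strand == "+" else _revcomp(b)
                if CODON_TO_AA.get(alt_codon) == aa:
                    syn_alts.append(genomic_alt)
                else:
                    ns_alts.append(genomic_alt)
            if syn_alts:
                syn_candidates.append(
                    (position, ref_base, syn_alts[rng.integers(len(syn_alts))])
                )
            if ns_alts:
                ns_candidates.append(
                    (position, ref_base, ns_alts[rng.integers(len(ns_alts))])
                )
    igr_candidates: list[tuple[int, str, str]] = []
    for f in annotation.features:
        if f.kind != "IGR" or f.replicon != replicon:
            continue
        for position in range(f.start, f.end + 1):
            ref_base = reference[position - 1]
            alts = [b for b in BASES if b != ref_base]
            igr_candidates.append(
                (position, ref_base, alts[rng.integers(3)])
            )

    pools = {"sSNP": syn_candidates, "nsSNP": ns_candidates, "iSNP": igr_candidates}
    records: list[SnpRecord] = []
    used: set[int] = set()
    for cls in ("sSNP", "nsSNP", "iSNP"):
        want = class_counts.get(cls, 0)
        pool = [c for c in pools[cls] if c[0] not in used]
        if want > len(pool):
            raise CapacityError(
                f"requested {want} {cls}s but only {len(pool)} candidate sites"
            )
        chosen = rng.choice(len(pool), size=want, replace=False) if want else []
        for idx in sorted(int(i) for i in np.atleast_1d(chosen)):
            position, ref_base, alt = pool[idx]
            used.add(position)
            feature = annotation.feature_at(replicon, position, kind="CDS")
            records.append(
                SnpRecord(
                    replicon=replicon,
                    position=position,
                    ref_allele=ref_base,
                    alt_allele=alt,
                    snp_class=cls,
                    feature_id=feature.feature_id if cls != "iSNP" else None,
                )
            )
    return records
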