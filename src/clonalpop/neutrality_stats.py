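"""Diversity and neutrality statistics for haploid alignments.

Implements the classical site-frequency / haplotype test battery used to
detect departures from the standard neutral model in clonal samples:
Watterson's θ, nucleotide diversity π, Tajima's D (overall and restricted
to synonymous / non-synonymous sites), Fu & Li's outgroup-free D* and F*
(corrected variance constants), Fu's Fs via the Ewens sampling
distribution, and the Ramos-Onsins & Rozas R2 statistic.  Significance is
assessed by conditional coalescent simulation with the observed number of
segregating sites (fixed-S), mapped to the reporting buckets
{ns, <0.05, <0.02, <0.01}.

Missing data policy: complete deletion — any column containing ``N`` or
``-`` is removed before anything is counted, and L is the number of sites
that survive.  Singletons are unpolarized (an allele carried by exactly
one sequence).  Under infinite-sites simulated data η = S; on real
alignments a column with a alleles contributes a−1 to η and 1 to S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align_io import Alignment, AnnotationTable, TreeNode
from .errors import InputError, UndefinedStatisticError
from .snp_classification import CODON_TO_AA, _affected_codons

__all__ = [
    "SiteCounts",
    "NeutralitySummary",
    "site_counts",
    "segregating_sites",
    "nucleotide_diversity",
    "mean_pairwise_differences",
    "watterson_theta",
    "tajima_constants",
    "tajima_d",
    "tajima_d_by_class",
    "fu_li_d_star",
    "fu_li_f_star",
    "fu_fs",
    "r2_statistic",
    "neutrality_significance",
    "neutrality_summary",
    "pairwise_distance_matrix",
    "upgma",
]

_MISSING = (ord("N"), ord("-"))


def _matrix(aln: Alignment) -> np.ndarray:
    return np.vstack(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in aln.seqs]
    )


def _analysed(aln: Alignment, policy: str = "complete") -> np.ndarray:
    """Alignment as a uint8 matrix after the missing-data policy."""
    if policy != "complete":
        raise InputError(f"unknown missing-data policy {policy!r}")
    mat = _matrix(aln)
    keep = ~np.isin(mat, _MISSING).any(axis=0)
    return mat[:, keep]


@dataclass(frozen=True)
class SiteCounts:
    """Sufficient statistics of an alignment for the neutrality tests."""

    n: int
    L: int  # sites analysed (after complete deletion)
    S: int  # segregating sites
    eta: int  # total mutations (alleles - 1 summed over columns)
    eta_singletons: int  # mutations carried by exactly one sequence
    k_bar: float  # mean pairwise differences per sequence pair
    singletons_per_seq: tuple[int, ...]  # U_i, for R2
    n_haplotypes: int


def site_counts(aln: Alignment, policy: str = "complete") -> SiteCounts:
    """One pass over the alignment collecting everything the tests need."""
    if aln.n < 2:
        raise InputError("need at least 2 sequences")
    mat = _analysed(aln, policy)
    n, L = mat.shape
    var_cols = np.nonzero(np.any(mat != mat[0], axis=0))[0]
    npairs = n * (n - 1) // 2
    S = len(var_cols)
    eta = 0
    eta_s = 0
    kbar = 0.0
    U = np.zeros(n, dtype=int)
    for c in var_cols:
        col = mat[:, c]
        alleles, counts = np.unique(col, return_counts=True)
        a = len(alleles)
        eta += a - 1
        same_pairs = int((counts * (counts - 1) // 2).sum())
        kbar += (npairs - same_pairs) / npairs
        single = alleles[counts == 1]
        # at most (alleles - 1) of the count-1 alleles are mutations
        eta_s += min(len(single), a - 1)
        if len(single):
            U[np.isin(col, single)] += 1
    if S:
        hap = len(np.unique(mat[:, var_cols], axis=0))
    else:
        hap = 1
    return SiteCounts(
        n=n,
        L=L,
        S=S,
        eta=eta,
        eta_singletons=eta_s,
        k_bar=kbar,
        singletons_per_seq=tuple(int(u) for u in U),
        n_haplotypes=hap,
    )


def segregating_sites(aln: Alignment, policy: str = "complete") -> int:
    """Number of columns with at least two distinct non-missing bases."""
    return site_counts(aln, policy).S


def mean_pairwise_differences(aln: Alignment, policy: str = "complete") -> float:
    """k̄: mean number of nucleotide differences per sequence pair."""
    return site_counts(aln, policy).k_bar


def nucleotide_diversity(aln: Alignment, policy: str = "complete") -> float:
    """π: mean pairwise difference per analysed site (no multiple-hit correction)."""
    sc = site_counts(aln, policy)
    return sc.k_bar / sc.L


def _harmonic(m: int) -> float:
    return sum(1.0 / i for i in range(1, m + 1))


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's estimator per site: S / (a1 · L), a1 = Σ_{i<n} 1/i."""
    if n < 2:
        raise InputError("need n >= 2")
    if L < 1:
        raise InputError("need L >= 1")
    return S / (_harmonic(n - 1) * L)


def tajima_constants(n: int) -> dict[str, float]:
    """Variance constants of Tajima's D as functions of the sample size."""
    a1 = _harmonic(n - 1)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(k_bar: float, S: int, n: int) -> float:
    """Tajima's D from mean pairwise differences (per pair) and S."""
    if S < 1:
        raise UndefinedStatisticError("tajima_d", "no segregating sites")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (k_bar - S / c["a1"]) / math.sqrt(var)


def tajima_d_from_alignment(aln: Alignment, policy: str = "complete") -> float:
    sc = site_counts(aln, policy)
    return tajima_d(sc.k_bar, sc.S, sc.n)


def _column_class(
    aln_col: np.ndarray, position: int, annotation: AnnotationTable, replicon: str
) -> str | None:
    """'synonymous' / 'non-synonymous' for a CDS column, None outside CDS.

    The reference base is taken from the annotation's reference sequence;
    the variant base is the most frequent non-reference allele.
    """
    feature = annotation.feature_at(replicon, position, kind="CDS")
    if feature is None:
        return None
    refseq = annotation.references[replicon]
    ref = refseq[position - 1]
    alleles, counts = np.unique(aln_col, return_counts=True)
    non_ref = [
        (int(k), chr(a)) for a, k in zip(alleles, counts) if chr(a) != ref
    ]
    if not non_ref:
        return None
    alt = max(non_ref)[1]
    ref_codon, alt_codon = _affected_codons(feature, refseq, position, alt)
    same = CODON_TO_AA.get(ref_codon) == CODON_TO_AA.get(alt_codon)
    return "synonymous" if same else "non-synonymous"


def tajima_d_by_class(
    aln: Alignment,
    annotation: AnnotationTable,
    snp_class: str,
    replicon: str | None = None,
) -> float:
    """Tajima's D restricted to synonymous or non-synonymous sites.

    The alignment must be in reference coordinates (column i ↔ reference
    position i+1 of a single replicon).  Columns whose variant lies
    outside any CDS are ignored for both classes.
    """
    if snp_class not in ("synonymous", "non-synonymous"):
        raise InputError(f"unknown class {snp_class!r}")
    if replicon is None:
        if len(annotation.references) != 1:
            raise InputError("replicon required with multi-replicon annotation")
        replicon = next(iter(annotation.references))
    if len(annotation.references[replicon]) != aln.L:
        raise InputError("alignment length does not match reference length")
    mat = _matrix(aln)
    keep = ~np.isin(mat, _MISSING).any(axis=0)
    n = aln.n
    npairs = n * (n - 1) // 2
    S = 0
    kbar = 0.0
    for c in np.nonzero(np.any(mat != mat[0], axis=0) & keep)[0]:
        col = mat[:, c]
        cls = _column_class(col, int(c) + 1, annotation, replicon)
        if cls != snp_class:
            continue
        S += 1
        _, counts = np.unique(col, return_counts=True)
        same_pairs = int((counts * (counts - 1) // 2).sum())
        kbar += (npairs - same_pairs) / npairs
    if S == 0:
        raise UndefinedStatisticError("tajima_d", f"no {snp_class} segregating sites")
    return tajima_d(kbar, S, n)


def _fu_li_constants(n: int) -> dict[str, float]:
    """Corrected variance constants for Fu & Li's outgroup-free D* and F*."""
    if n < 4:
        raise InputError("Fu & Li statistics need n >= 4")
    an = _harmonic(n - 1)
    bn = sum(1.0 / i**2 for i in range(1, n))
    an1 = an + 1.0 / n
    cn = 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / ((n - 1) ** 2)
        + (2.0 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    v_d = (
        (n / (n - 1.0)) ** 2 * bn
        + an**2 * dn
        - 2 * (n * an * (an + 1)) / ((n - 1.0) ** 2)
    ) / (an**2 + bn)
    u_d = (n / (n - 1.0)) * (an - n / (n - 1.0)) - v_d
    v_f = (
        dn
        + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        - (2.0 / (n - 1)) * (4 * bn - 6 + 8.0 / n)
    ) / (an**2 + bn)
    u_f = (
        n / (n - 1.0)
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 / (n * (n - 1))
        + 2.0 * (n + 1) / ((n - 1.0) ** 2) * (an1 - 2.0 * n / (n + 1))
    ) / an - v_f
    return {"an": an, "bn": bn, "u_d": u_d, "v_d": v_d, "u_f": u_f, "v_f": v_f}


def fu_li_d_star(eta: int, eta_singletons: int, n: int) -> float:
    """Fu & Li's D*: total vs singleton mutations, no outgroup required."""
    if eta < 1:
        raise UndefinedStatisticError("fu_li_d_star", "no mutations")
    c = _fu_li_constants(n)
    num = (n / (n - 1.0)) * eta - c["an"] * eta_singletons
    var = c["u_d"] * eta + c["v_d"] * eta**2
    return num / math.sqrt(var)


def fu_li_f_star(k_bar: float, eta: int, eta_singletons: int, n: int) -> float:
    """Fu & Li's F*: mean pairwise differences vs singleton mutations."""
    if eta < 1:
        raise UndefinedStatisticError("fu_li_f_star", "no mutations")
    c = _fu_li_constants(n)
    num = k_bar - ((n - 1.0) / n) * eta_singletons
    var = c["u_f"] * eta + c["v_f"] * eta**2
    return num / math.sqrt(var)


def log_stirling_first_kind(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind, row ``n``.

    Entry k is log|S(n, k)| (−inf where zero); computed with the
    triangular recurrence in log space to stay finite for large n.
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        for k in range(1, m + 1):
            terms = [row[k - 1]]
            if m > 1:
                terms.append(math.log(m - 1) + row[k])
            new[k] = np.logaddexp.reduce(terms)
        row = new
    return row


def ewens_haplotype_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 0..n under the Ewens sampling distribution."""
    if theta <= 0:
        raise InputError("theta must be positive")
    logS = log_stirling_first_kind(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    logp = logS + np.arange(n + 1) * math.log(theta) - log_rising
    p = np.exp(logp)
    p[np.isneginf(logp)] = 0.0
    return p


def fu_fs(k_bar: float, k_obs: int, n: int) -> float:
    """Fu's Fs: log-odds of seeing ≥ k_obs haplotypes given θ = k̄.

    Strongly negative when the sample carries more haplotypes than the
    Ewens distribution at the observed diversity predicts — the signature
    of a recent expansion.
    """
    if k_bar <= 0:
        raise UndefinedStatisticError("fu_fs", "k_bar must be positive")
    if not (1 <= k_obs <= n):
        raise InputError("k_obs must be in 1..n")
    pmf = ewens_haplotype_pmf(n, k_bar)
    s_prime = float(pmf[k_obs:].sum())
    if k_obs == 1 or s_prime >= 1.0:
        raise UndefinedStatisticError("fu_fs", "tail probability is 1 (k_obs = 1)")
    if s_prime <= 0.0:
        raise UndefinedStatisticError("fu_fs", "tail probability underflowed to 0")
    return math.log(s_prime) - math.log1p(-s_prime)


def r2_statistic(aln: Alignment, policy: str = "complete") -> float:
    """Ramos-Onsins & Rozas R2 from singleton counts and k̄."""
    sc = site_counts(aln, policy)
    return r2_from_counts(sc.singletons_per_seq, sc.k_bar, sc.S)


def r2_from_counts(U: Sequence[int], k_bar: float, S: int) -> float:
    if S < 1:
        raise UndefinedStatisticError("r2", "no segregating sites")
    U = np.asarray(U, dtype=float)
    return float(np.sqrt(np.mean((U - k_bar / 2.0) ** 2)) / S)


# ---------------------------------------------------------------------------
# fixed-S significance via conditional coalescent simulation
# ---------------------------------------------------------------------------


def _coalescent_branches(n: int, rng: np.random.Generator):
    """Constant-size coalescent genealogy as (branch length, leaf set) pairs.

    Times are in coalescent units; leaf sets are bitmasks over the n tips.
    """
    active = [(1 << i, 0.0) for i in range(n)]  # (leafset, birth time)
    branches: list[tuple[float, int]] = []
    t = 0.0
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (set_j, birth_j) = active.pop(j)
        (set_i, birth_i) = active.pop(i)
        branches.append((t - birth_i, set_i))
        branches.append((t - birth_j, set_j))
        active.append((set_i | set_j, t))
        k -= 1
    return branches


def _stats_from_placement(
    branches, counts: np.ndarray, n: int
) -> dict[str, float]:
    """Summary statistics implied by a fixed-S placement of mutations."""
    npairs = n * (n - 1) / 2.0
    kbar = 0.0
    eta_s = 0
    U = np.zeros(n, dtype=int)
    S = int(counts.sum())
    for (length, leafset), m in zip(branches, counts):
        if m == 0:
            continue
        c = bin(leafset).count("1")
        kbar += m * c * (n - c) / npairs
        if c == 1 or c == n - 1:
            eta_s += m
            small = leafset if c == 1 else ((1 << n) - 1) ^ leafset
            for i in range(n):
                if small >> i & 1:
                    U[i] += m
    # distinct haplotype = which mutated branches cover the leaf
    mutated = [ls for (_, ls), m in zip(branches, counts) if m]
    keys = {
        tuple(j for j, ls in enumerate(mutated) if ls >> i & 1) for i in range(n)
    }
    return {
        "S": S,
        "eta": S,
        "eta_singletons": eta_s,
        "k_bar": kbar,
        "U": U,
        "K": len(keys),
    }


_STAT_NAMES = ("tajima_d", "fu_li_d_star", "fu_li_f_star", "fu_fs", "r2")


def simulate_null_statistic(
    statistic: str, n: int, S: int, reps: int, seed: int
) -> np.ndarray:
    """Null distribution of a statistic under the fixed-S coalescent.

    Genealogies are drawn from the constant-size coalescent and exactly S
    mutations are placed multinomially on branches in proportion to their
    lengths (conditioning on the observed number of segregating sites).
    Replicates where the statistic is undefined are redrawn.
    """
    if statistic not in _STAT_NAMES:
        raise InputError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    filled = 0
    while filled < reps:
        branches = _coalescent_branches(n, rng)
        lengths = np.array([b[0] for b in branches])
        counts = rng.multinomial(S, lengths / lengths.sum())
        st = _stats_from_placement(branches, counts, n)
        try:
            if statistic == "tajima_d":
                val = tajima_d(st["k_bar"], st["S"], n)
            elif statistic == "fu_li_d_star":
                val = fu_li_d_star(st["eta"], st["eta_singletons"], n)
            elif statistic == "fu_li_f_star":
                val = fu_li_f_star(st["k_bar"], st["eta"], st["eta_singletons"], n)
            elif statistic == "fu_fs":
                val = fu_fs(st["k_bar"], st["K"], n)
            else:
                val = r2_from_counts(st["U"], st["k_bar"], st["S"])
        except UndefinedStatisticError:
            continue
        out[filled] = val
        filled += 1
    return out


def neutrality_significance(
    statistic: str,
    observed: float,
    n: int,
    S: int,
    reps: int = 5000,
    seed: int = 0,
) -> str:
    """Two-sided p-value bucket for an observed statistic.

    Returns one of ``ns``, ``<0.05``, ``<0.02``, ``<0.01`` from the
    fixed-S conditional coalescent null.  Deterministic for a given seed.
    """
    null = simulate_null_statistic(statistic, n, S, reps, seed)
    lo = (np.sum(null <= observed) + 1) / (reps + 1)
    hi = (np.sum(null >= observed) + 1) / (reps + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    if p < 0.01:
        return "<0.01"
    if p < 0.02:
        return "<0.02"
    if p < 0.05:
        return "<0.05"
    return "ns"


@dataclass(frozen=True)
class NeutralitySummary:
    """Per-dataset bundle of diversity and neutrality statistics.

    Statistics that are undefined for the input (e.g. S = 0) are None,
    with the reason recorded in ``undefined``.
    """

    name: str
    n: int
    L: int
    S: int
    eta: int
    eta_singletons: int
    k_bar: float
    pi: float
    theta_w: float
    tajima_d: float | None = None
    fu_li_d_star: float | None = None
    fu_li_f_star: float | None = None
    fu_fs: float | None = None
    r2: float | None = None
    significance: Mapping[str, str] = field(default_factory=dict)
    undefined: Mapping[str, str] = field(default_factory=dict)


def neutrality_summary(
    aln: Alignment,
    name: str = "alignment",
    policy: str = "complete",
    significance_reps: int = 0,
    seed: int = 0,
) -> NeutralitySummary:
    """Compute the full test battery for one alignment.

    With ``significance_reps > 0`` each defined statistic also gets a
    fixed-S significance bucket (seeded, reproducible).
    """
    sc = site_counts(aln, policy)
    values: dict[str, float | None] = {}
    undefined: dict[str, str] = {}

    def attempt(key, fn, *args):
        try:
            values[key] = fn(*args)
        except UndefinedStatisticError as exc:
            values[key] = None
            undefined[key] = exc.reason

    attempt("tajima_d", tajima_d, sc.k_bar, sc.S, sc.n)
    attempt("fu_li_d_star", fu_li_d_star, sc.eta, sc.eta_singletons, sc.n)
    attempt(
        "fu_li_f_star", fu_li_f_star, sc.k_bar, sc.eta, sc.eta_singletons, sc.n
    )
    attempt("fu_fs", fu_fs, sc.k_bar, sc.n_haplotypes, sc.n)
    attempt("r2", r2_from_counts, sc.singletons_per_seq, sc.k_bar, sc.S)

    significance: dict[str, str] = {}
    if significance_reps > 0:
        for stat in _STAT_NAMES:
            if values.get(stat) is not None:
                significance[stat] = neutrality_significance(
                    stat, values[stat], sc.n, sc.S, significance_reps, seed
                )
    return NeutralitySummary(
        name=name,
        n=sc.n,
        L=sc.L,
        S=sc.S,
        eta=sc.eta,
        eta_singletons=sc.eta_singletons,
        k_bar=sc.k_bar,
        pi=sc.k_bar / sc.L,
        theta_w=watterson_theta(sc.S, sc.n, sc.L),
        tajima_d=values["tajima_d"],
        fu_li_d_star=values["fu_li_d_star"],
        fu_li_f_star=values["fu_li_f_star"],
        fu_fs=values["fu_fs"],
        r2=values["r2"],
        significance=significance,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# distances and clustering
# ---------------------------------------------------------------------------


def pairwise_distance_matrix(aln: Alignment, policy: str = "complete") -> np.ndarray:
    """Symmetric matrix of per-site differences (p-distances)."""
    mat = _analysed(aln, policy)
    n, L = mat.shape
    d = np.zeros((n, n))
    for i in range(n):
        diff = (mat[i] != mat[i + 1 :]).sum(axis=1) / L
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return d


def upgma(matrix: np.ndarray, labels: Sequence[str] | None = None) -> TreeNode:
    """UPGMA agglomeration of a distance matrix into a rooted ultrametric tree.

    Ties between candidate merges are broken by the lexicographically
    smallest pair of cluster labels (a cluster is labelled by its smallest
    leaf name), so the result is independent of input order.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise InputError("distance matrix must be square")
    if (matrix < 0).any():
        raise InputError("negative distance")
    if not np.allclose(matrix, matrix.T) or not np.allclose(np.diag(matrix), 0):
        raise InputError("matrix must be symmetric with zero diagonal")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n)]
    if len(set(labels)) != n:
        raise InputError("labels must be unique")

    if n == 1:
        return TreeNode(name=labels[0])

    # cluster state: label -> (node, height, size)
    clusters: dict[str, tuple[TreeNode, float, int]] = {
        lab: (TreeNode(name=lab), 0.0, 1) for lab in labels
    }
    dist: dict[frozenset[str], float] = {
        frozenset((labels[i], labels[j])): float(matrix[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }

    while len(clusters) > 1:
        best = None
        for pair, d in dist.items():
            a, b = sorted(pair)
            key = (d, a, b)
            if best is None or key < best:
                best = key
        d, a, b = best
        node_a, h_a, size_a = clusters.pop(a)
        node_b, h_b, size_b = clusters.pop(b)
        height = d / 2.0
        node_a.length = height - h_a
        node_b.length = height - h_b
        merged = TreeNode(children=(node_a, node_b))
        new_label = min(a, b)
        new_dist: dict[frozenset[str], float] = {}
        for pair, dv in dist.items():
            if a in pair or b in pair:
                continue
            new_dist[pair] = dv
        for other in clusters:
            d_ao = dist[frozenset((a, other))]
            d_bo = dist[frozenset((b, other))]
            new_dist[frozenset((new_label, other))] = (
                size_a * d_ao + size_b * d_bo
            ) / (size_a + size_b)
        clusters[new_label] = (merged, height, size_a + size_b)
        dist = new_dist
    (root, _, _) = next(iter(clusters.values()))
    return root
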