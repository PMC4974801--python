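"""Mismatch-distribution demography: observed spectra, the sudden-expansion
model, raggedness, and conversion of mutational time to calendar time.

Model
-----
For a pair of haploid sequences the number of nucleotide differences is
Poisson given the pair's coalescence time.  Measuring time *t* in
mutational units (τ = 2υt, υ the per-locus per-generation mutation rate)
the pair accumulates differences at total rate 1 per unit, and in a
population of scaled size θ the pair coalesces at rate 1/θ per unit.  At
equilibrium this yields the geometric distribution

    F̂_i(θ) = θ^i / (θ + 1)^{i+1}.

Under a sudden expansion — size θ0 jumping to θ1 at τ units before the
present — the pair either coalesces in the post-expansion epoch (an
incomplete-gamma weighted geometric in θ1) or survives it, picking up
Poisson(τ) differences plus a θ0-equilibrium geometric by memorylessness:

    F_i(τ; θ0, θ1) = F̂_i(θ1) · P[Γ_{i+1} ≤ τ (1 + 1/θ1)]
                     + e^{-τ/θ1} Σ_{j≤i} Pois(j; τ) F̂_{i-j}(θ0),

with Γ_{i+1} a gamma(i+1) variable at unit rate.  This is the classic
sudden-expansion ("pure demographic growth") mismatch solution; it reduces
to F̂(θ0) at τ = 0 and to F̂(θ1) as τ → ∞, and the synthetic-data module's
coalescent simulator doubles as its independent numerical check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .align_io import Alignment
from .errors import InputError
from .neutrality_stats import _analysed

__all__ = [
    "MismatchDistribution",
    "MismatchFit",
    "ClockParameters",
    "observed_mismatch",
    "equilibrium_mismatch",
    "expansion_mismatch",
    "expansion_mismatch_curve",
    "fit_sudden_expansion",
    "moment_estimates",
    "raggedness",
    "time_since_expansion",
    "convert_mutation_rate",
]


@dataclass(frozen=True)
class MismatchDistribution:
    """Relative frequencies of pairwise difference counts 0..d_max."""

    freqs: tuple[float, ...]
    pair_count: int

    def __post_init__(self):
        if any(f < 0 for f in self.freqs):
            raise InputError("negative frequency")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise InputError("frequencies must sum to 1")

    @property
    def d_max(self) -> int:
        return len(self.freqs) - 1

    @property
    def mean(self) -> float:
        return float(sum(i * f for i, f in enumerate(self.freqs)))

    @property
    def var(self) -> float:
        m = self.mean
        return float(sum((i - m) ** 2 * f for i, f in enumerate(self.freqs)))


@dataclass(frozen=True)
class MismatchFit:
    """Sudden-expansion least-squares fit and its diagnostics."""

    theta0: float
    theta1: float
    tau: float
    sse: float
    raggedness_r: float
    tau_moment: float | None = None
    fitted: tuple[float, ...] = ()
    degenerate: bool = False


@dataclass(frozen=True)
class ClockParameters:
    """Strict molecular clock used to convert τ into calendar time.

    Defaults are a soil-bacterium clock: a universal mutation rate of
    0.0033 per genome per generation, ~44 generations per year (200 h per
    generation) and a 7,139,558 bp genome, i.e. υ ≈ 2.03e-8 per site per
    year.
    """

    rate_per_site_per_year: float = 2.03e-8
    rate_per_genome_per_generation: float = 0.0033
    generations_per_year: float = 44.0
    genome_length: int = 7_139_558
    locus_length: int | None = None

    def __post_init__(self):
        for v in (
            self.rate_per_site_per_year,
            self.rate_per_genome_per_generation,
            self.generations_per_year,
            self.genome_length,
        ):
            if v <= 0:
                raise InputError("clock parameters must be strictly positive")


def observed_mismatch(aln: Alignment, policy: str = "complete") -> MismatchDistribution:
    """Histogram of pairwise difference counts over all sequence pairs."""
    mat = _analysed(aln, policy)
    n = mat.shape[0]
    if n < 2:
        raise InputError("need at least 2 sequences")
    diffs = [
        int((mat[i] != mat[j]).sum()) for i in range(n) for j in range(i + 1, n)
    ]
    d_max = max(diffs)
    counts = np.bincount(diffs, minlength=d_max + 1)
    return MismatchDistribution(
        freqs=tuple(counts / counts.sum()), pair_count=len(diffs)
    )


def equilibrium_mismatch(theta: float, i: int | np.ndarray) -> float | np.ndarray:
    """Stationary mismatch probability F̂_i(θ) = θ^i / (θ+1)^(i+1)."""
    if theta < 0:
        raise InputError("theta must be >= 0")
    i = np.asarray(i)
    if theta == 0:
        out = np.where(i == 0, 1.0, 0.0)
    else:
        out = np.exp(i * math.log(theta) - (i + 1) * math.log1p(theta))
    return out if out.ndim else float(out)


def expansion_mismatch_curve(
    theta0: float, theta1: float, tau: float, i_max: int
) -> np.ndarray:
    """F_i(τ; θ0, θ1) for i = 0..i_max under the sudden-expansion model."""
    if theta0 < 0 or theta1 <= 0 or tau < 0:
        raise InputError("need theta0 >= 0, theta1 > 0, tau >= 0")
    i = np.arange(i_max + 1)
    eq1 = np.asarray(equilibrium_mismatch(theta1, i))
    # pair coalesced after the expansion: gamma(i+1) tail at rate (1 + 1/theta1)
    coalesced = eq1 * special.gammainc(i + 1, tau * (1.0 + 1.0 / theta1))
    # pair survived the recent epoch: Poisson(tau) differences + theta0 geometric
    pois = stats.poisson.pmf(i, tau)
    eq0 = np.asarray(equilibrium_mismatch(theta0, i))
    survived = math.exp(-tau / theta1) * np.convolve(pois, eq0)[: i_max + 1]
    return coalesced + survived


def expansion_mismatch(theta0: float, theta1: float, tau: float, i: int) -> float:
    """Expected frequency of difference class ``i`` after a sudden expansion."""
    return float(expansion_mismatch_curve(theta0, theta1, tau, i)[i])


def raggedness(obs: MismatchDistribution | np.ndarray) -> float:
    """Harpending's raggedness r = Σ (x_i − x_{i−1})² over adjacent classes.

    Computed across the supplied frequency vector (classes 0..d_max), with
    no wrap-around term; a single-class distribution has r = 0.
    """
    x = np.asarray(obs.freqs if isinstance(obs, MismatchDistribution) else obs, float)
    if x.size < 2:
        return 0.0
    return float(np.sum(np.diff(x) ** 2))


def moment_estimates(obs: MismatchDistribution) -> tuple[float, float]:
    """Method-of-moments (θ̂0, τ̂) assuming a large post-expansion size.

    With θ1 → ∞ the mismatch is Poisson(τ) ⊕ geometric(θ0), so
    mean = τ + θ0 and var − mean = θ0²; hence θ̂0 = sqrt(max(v − m, 0))
    and τ̂ = m − θ̂0 (clamped at 0).
    """
    m, v = obs.mean, obs.var
    theta0 = math.sqrt(max(v - m, 0.0))
    tau = max(m - theta0, 0.0)
    return theta0, tau


def fit_sudden_expansion(
    obs: MismatchDistribution,
    n_starts: int = 16,
    compute_moment: bool = True,
) -> MismatchFit:
    """Least-squares fit of (θ0, θ1, τ) to an observed mismatch distribution.

    Minimizes Σ_i (obs_i − F_i(τ; θ0, θ1))² over the classes
    0..max(3·d_max, 50) with bounded multi-start Levenberg–Marquardt
    (trust-region reflective); θ1 is parameterized as θ0 + Δ so the
    expansion constraint θ1 ≥ θ0 holds by construction.
    """
    d_max = obs.d_max
    r = raggedness(obs)
    tau_mom = moment_estimates(obs)[1] if compute_moment else None
    if d_max == 0:
        # no pair differs: nothing to date
        return MismatchFit(
            theta0=0.0,
            theta1=0.0,
            tau=0.0,
            sse=0.0,
            raggedness_r=r,
            tau_moment=tau_mom,
            fitted=(1.0,),
            degenerate=True,
        )
    i_max = max(3 * d_max, 50)
    target = np.zeros(i_max + 1)
    target[: d_max + 1] = obs.freqs
    mean = max(obs.mean, 1e-3)

    def residuals(params):
        theta0, delta, tau = params
        return expansion_mismatch_curve(theta0, theta0 + delta + 1e-9, tau, i_max) - target

    theta_pi = mean  # diversity-scaled upper bound for theta0
    bounds = ([0.0, 0.0, 0.0], [theta_pi + 1e-9, 1e4, 2.0 * d_max])
    starts = []
    for t0 in (1e-3, 0.05 * mean, 0.25 * mean, 0.8 * mean):
        for tau0 in (0.25 * mean, 0.5 * mean, min(mean, 2.0 * d_max * 0.9), min(1.5 * mean, 2.0 * d_max * 0.99)):
            starts.append([min(t0, theta_pi), 10.0 * mean, tau0])
    best = None
    for x0 in starts[:n_starts]:
        sol = optimize.least_squares(
            residuals, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    sse, (theta0, delta, tau) = best
    theta1 = theta0 + delta + 1e-9
    fitted = expansion_mismatch_curve(theta0, theta1, tau, i_max)
    return MismatchFit(
        theta0=float(theta0),
        theta1=float(theta1),
        tau=float(tau),
        sse=sse,
        raggedness_r=r,
        tau_moment=tau_mom,
        fitted=tuple(float(f) for f in fitted),
    )


def time_since_expansion(
    tau: float, clock: ClockParameters, locus_length: int | None = None
) -> tuple[float, float]:
    """Calendar time of the expansion: t = τ / (2 υ L).

    υ is the per-site per-year rate and L the locus (concatenated
    alignment) length in bp.  Returns (years before sampling, generations
    before sampling).
    """
    if tau < 0:
        raise InputError("tau must be >= 0")
    L = locus_length if locus_length is not None else clock.locus_length
    if not L or L <= 0:
        raise InputError("locus_length must be set and positive")
    years = tau / (2.0 * clock.rate_per_site_per_year * L)
    return years, years * clock.generations_per_year


def convert_mutation_rate(
    rate_per_genome_per_generation: float,
    genome_length: int,
    generations_per_year: float,
) -> float:
    """Per-site per-year mutation rate from a per-genome per-generation rate."""
    if min(rate_per_genome_per_generation, genome_length, generations_per_year) <= 0:
        raise InputError("rates and lengths must be positive")
    return rate_per_genome_per_generation / genome_length * generations_per_year
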