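"""Observed methylation-level distributions and their depth-matched
binomial nulls.

The per-site methylation level beta = M/T is kept as an exact reduced
fraction, and equal values merge across depths (1/2 from depth 2 and 2/4
from depth 4 share one support point). The null distribution is the
analytic binomial mixture over the observed depth profile, computed in
exact rational arithmetic so that it sums to 1 exactly; Monte-Carlo
sampling of the same null is provided only as a validation cross-check.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import MethylationSite

Probability = Fraction | float

_ZERO = Fraction(0)
_ONE = Fraction(1)


@dataclass(frozen=True)
class BetaDistribution:
    """Probability mass over exact rational beta values in [0, 1].

    ``mass`` maps reduced fractions to probability mass (exact Fractions
    when built analytically, floats when sampled); ``n_sites`` is the N of
    the underlying site collection.
    """

    mass: Mapping[Fraction, Probability]
    n_sites: int

    def __post_init__(self) -> None:
        for beta, m in self.mass.items():
            if not _ZERO <= beta <= _ONE:
                raise ValueError(f"support point {beta} outside [0, 1]")
            if m < 0:
                raise ValueError(f"negative mass {m} at {beta}")
        total = self.total()
        if abs(float(total) - 1.0) > 1e-9:
            raise ValueError(f"total mass {float(total)} != 1")

    def __getitem__(self, beta: Fraction | int) -> Probability:
        return self.mass.get(Fraction(beta), _ZERO)

    def support(self) -> list[Fraction]:
        return sorted(self.mass)

    def total(self) -> Probability:
        return sum(self.mass.values())

    def mean(self) -> Probability:
        return sum(beta * m for beta, m in self.mass.items())


@dataclass(frozen=True)
class DepthProfile:
    """Multiset of per-site sequencing depths {T_i}."""

    counts: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for depth, count in self.counts.items():
            if depth < 1:
                raise ValueError(f"depth must be >= 1, got {depth}")
            if count < 1:
                raise ValueError(f"count must be >= 1, got {count} at depth {depth}")
        if self.n_sites < 1:
            raise ValueError("profile must contain at least one site")

    @classmethod
    def from_sites(cls, sites: Iterable[MethylationSite]) -> "DepthProfile":
        return cls(dict(Counter(site.depth for site in sites)))

    @classmethod
    def from_depths(cls, depths: Iterable[int]) -> "DepthProfile":
        return cls(dict(Counter(depths)))

    @property
    def n_sites(self) -> int:
        return sum(self.counts.values())

    def depths(self) -> list[int]:
        return sorted(self.counts)


def beta_value(meth_count: int, depth: int) -> Fraction:
    """Per-site methylation level M/T as an exact reduced fraction."""
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if not 0 <= meth_count <= depth:
        raise ValueError(
            f"meth_count must satisfy 0 <= M <= depth, got {meth_count}/{depth}"
        )
    return Fraction(meth_count, depth)


def observed_distribution(sites: Iterable[MethylationSite]) -> BetaDistribution:
    """Empirical distribution of beta over a site collection.

    Mass at each distinct reduced fraction is (sites with that beta)/N;
    equal values from different depths merge into one support point.
    """
    counts: Counter[Fraction] = Counter()
    n = 0
    for site in sites:
        counts[site.beta] += 1
        n += 1
    if n == 0:
        raise ValueError("cannot build a distribution from zero sites")
    return BetaDistribution({beta: Fraction(c, n) for beta, c in counts.items()}, n)


def mean_methylation(
    sites: Iterable[MethylationSite], mode: str = "per_site"
) -> Fraction:
    """Average methylation level p of a site collection.

    ``per_site`` (the default) is the arithmetic mean of the per-site
    ratios M_i/T_i. ``pooled`` is the read-weighted alternative
    sum(M_i)/sum(T_i), provided as a diagnostic only.
    """
    if mode not in ("per_site", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    total = _ZERO
    n = 0
    meth_sum = depth_sum = 0
    for site in sites:
        n += 1
        if mode == "per_site":
            total += site.beta
        else:
            meth_sum += site.meth_count
            depth_sum += site.depth
    if n == 0:
        raise ValueError("cannot average zero sites")
    if mode == "per_site":
        return total / n
    return Fraction(meth_sum, depth_sum)


def binomial_pmf(depth: int, n: int, p: Probability) -> Fraction:
    """Exact binomial probability C(T, n) p^n (1-p)^(T-n).

    ``p`` may be a float (converted exactly to a Fraction) or a Fraction.
    The convention 0^0 = 1 makes the degenerate cases p = 0 and p = 1
    well defined.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if not 0 <= n <= depth:
        raise ValueError(f"n must satisfy 0 <= n <= depth, got n={n}, T={depth}")
    p = Fraction(p)
    if not _ZERO <= p <= _ONE:
        raise ValueError(f"p must lie in [0, 1], got {float(p)}")
    return math.comb(depth, n) * p**n * (_ONE - p) ** (depth - n)


def random_distribution(profile: DepthProfile, p: Probability) -> BetaDistribution:
    """Analytic depth-matched binomial null.

    For each depth T with c_T sites, mass c_T * P(T, n) / N is placed at
    the reduced fraction n/T for n = 0..T; equal fractions merge. Computed
    in exact rational arithmetic, so the total mass is exactly 1.
    """
    p = Fraction(p)
    n_sites = profile.n_sites
    mass: defaultdict[Fraction, Fraction] = defaultdict(lambda: _ZERO)
    for depth, count in sorted(profile.counts.items()):
        weight = Fraction(count, n_sites)
        for n in range(depth + 1):
            mass[Fraction(n, depth)] += weight * binomial_pmf(depth, n, p)
    # degenerate p leaves zero-mass points; keep the support tight
    return BetaDistribution({b: m for b, m in mass.items() if m > 0}, n_sites)


def restrict_to_depth(
    sites: Iterable[MethylationSite], depth: int
) -> list[MethylationSite]:
    """Exactly the sites with T equal to ``depth``; may be empty."""
    return [site for site in sites if site.depth == depth]


def sample_random_methylome(
    profile: DepthProfile, p: float, draws: int, seed: int
) -> BetaDistribution:
    """Monte-Carlo estimate of the binomial null (validation oracle only).

    Each draw generates one artificial methylome over the whole profile;
    the returned masses are empirical frequencies over draws * N site
    values. Deterministic given ``seed``; depths are consumed in ascending
    order.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    n_sites = profile.n_sites
    total = n_sites * draws
    mass: defaultdict[Fraction, float] = defaultdict(float)
    for depth, count in sorted(profile.counts.items()):
        samples = rng.binomial(depth, p, size=count * draws)
        hits = np.bincount(samples, minlength=depth + 1)
        for n in range(depth + 1):
            if hits[n]:
                mass[Fraction(n, depth)] += hits[n] / total
    return BetaDistribution(dict(mass), n_sites)


def write_distribution_tsv(
    dist: BetaDistribution, path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Export a distribution as TSV: exact fraction, decimal, mass."""
    with open(path, "wt", encoding="utf-8") as handle:
        for comment in comments:
            handle.write(f"# {comment}\n")
        handle.write("beta\tbeta_decimal\tmass\n")
        for beta in dist.support():
            m = dist.mass[beta]
            handle.write(
                f"{beta.numerator}/{beta.denominator}\t"
                f"{float(beta):.9g}\t{float(m):.9g}\n"
            )
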