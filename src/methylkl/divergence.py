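"""Relative-entropy statistics comparing observed and null distributions.

The full divergence KL = sum_beta r_obs(beta) log2(r_obs(beta)/r_ran(beta))
is non-negative (Gibbs); the endpoint terms KL(0) and KL(1) are the single
summands at beta = 0 and beta = 1 and are reported as signed values. The
direct differences d(0) and d(1) are the simpler deviation measures
r_obs(e) - r_ran(e). All logarithms are base 2 (bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

from .distributions import (
    BetaDistribution,
    DepthProfile,
    mean_methylation,
    observed_distribution,
    random_distribution,
)
from .io import MethylationSite

_ZERO = Fraction(0)
_ONE = Fraction(1)


class DivergenceUndefinedError(ValueError):
    """Observed mass where the null has none (possible only at p in {0,1})."""


@dataclass(frozen=True)
class DivergenceResult:
    """Per-context divergence record.

    ``kl0``/``kl1`` are the endpoint relative-entropy terms in bits (signed
    single-term contributions, not full divergences); ``d0``/``d1`` the
    direct endpoint mass differences; ``kl_full`` the full divergence.
    """

    context: str
    n_sites: int
    p: float
    robs0: float
    rran0: float
    robs1: float
    rran1: float
    kl0: float
    kl1: float
    d0: float
    d1: float
    kl_full: float


def _check_compatible(obs: BetaDistribution, ran: BetaDistribution) -> None:
    if obs.n_sites != ran.n_sites:
        raise ValueError(
            f"distributions built from different site sets "
            f"(N={obs.n_sites} vs N={ran.n_sites})"
        )


def kl_divergence(obs: BetaDistribution, ran: BetaDistribution) -> float:
    """Full relative entropy of obs from ran, in bits.

    The sum runs over the support of obs; terms with obs(beta) = 0
    contribute nothing (0 log 0 = 0 convention).
    """
    _check_compatible(obs, ran)
    total = 0.0
    for beta, o in obs.mass.items():
        if o == 0:
            continue
        r = ran[beta]
        if r == 0:
            raise DivergenceUndefinedError(
                f"observed mass {float(o)} at beta={beta} where the null "
                f"has none"
            )
        total += float(o) * math.log2(float(o) / float(r))
    return total


def endpoint_kl(
    obs: BetaDistribution, ran: BetaDistribution, endpoint: int
) -> float:
    """Single-term relative entropy at beta = 0 or beta = 1, in bits.

    Returns 0 when the observed endpoint mass is 0; raises when the null
    endpoint mass is 0 (degenerate p).
    """
    e = _endpoint(endpoint)
    _check_compatible(obs, ran)
    o = obs[e]
    r = ran[e]
    if r == 0:
        raise DivergenceUndefinedError(
            f"null mass at beta={endpoint} is zero (degenerate p)"
        )
    if o == 0:
        return 0.0
    return float(o) * math.log2(float(o) / float(r))


def direct_difference(
    obs: BetaDistribution, ran: BetaDistribution, endpoint: int
) -> float:
    """Direct endpoint deviation r_obs(e) - r_ran(e); sign is meaningful."""
    e = _endpoint(endpoint)
    _check_compatible(obs, ran)
    return float(obs[e] - ran[e])


def _endpoint(endpoint: int) -> Fraction:
    if endpoint == 0:
        return _ZERO
    if endpoint == 1:
        return _ONE
    raise ValueError(f"endpoint must be 0 or 1, got {endpoint}")


def summarize(
    context_label: str,
    sites: Iterable[MethylationSite],
    p_mode: str = "per_site",
) -> DivergenceResult:
    """Build the full divergence record for one site collection.

    p is computed over exactly these sites; the observed distribution and
    its depth-matched binomial null are then compared at the endpoints and
    over the full observed support.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("cannot summarize zero sites")
    p = mean_methylation(sites, mode=p_mode)
    obs = observed_distribution(sites)
    ran = random_distribution(DepthProfile.from_sites(sites), p)
    return DivergenceResult(
        context=context_label,
        n_sites=len(sites),
        p=float(p),
        robs0=float(obs[_ZERO]),
        rran0=float(ran[_ZERO]),
        robs1=float(obs[_ONE]),
        rran1=float(ran[_ONE]),
        kl0=endpoint_kl(obs, ran, 0),
        kl1=endpoint_kl(obs, ran, 1),
        d0=direct_difference(obs, ran, 0),
        d1=direct_difference(obs, ran, 1),
        kl_full=kl_divergence(obs, ran),
    )
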