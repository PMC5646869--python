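"""Synthetic reference and methylome generation.

The generator plants CpG dinucleotides into a random background at a
requested rate, then draws for every strand-cytosine a true methylation
level from a per-context beta mixture, a depth from a shifted-Poisson (or
empirical) depth model and a methylated read count binomially. Default
mixture parameters encode an endpoint-concentrated ("conserved") truth for
G/C 5'-flank contexts and a flatter ("variable") truth for A/T 5'-flank
contexts, both with true mean 0.5, so variability is isolated from level.

All draws come from one seeded generator with a documented order: chroms
sorted, sites in coordinate order with plus strand before minus; per site
the mixture component, then beta*, then T, then M. Sites without an
available context are skipped before any draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .context import TETRA_CONTEXTS, enumerate_cpg_sites, extract_context
from .distributions import DepthProfile
from .io import MethylationSite

DEPTH_KINDS = ("shifted_poisson", "empirical")


@dataclass(frozen=True)
class BetaMixture:
    """Two-component beta mixture for per-site true methylation levels.

    ``w`` is the weight of the low component. A shape parameter of 0 is
    the degenerate convention: the component collapses to a point mass
    (a = 0 -> beta* = 0; b = 0 -> beta* = 1).
    """

    w: float
    a_low: float
    b_low: float
    a_high: float
    b_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.w <= 1:
            raise ValueError(f"mixture weight must lie in [0, 1], got {self.w}")
        for name in ("a_low", "b_low", "a_high", "b_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def mean(self) -> float:
        return self.w * _beta_mean(self.a_low, self.b_low) + (1 - self.w) * (
            _beta_mean(self.a_high, self.b_high)
        )

    def draw(self, rng: np.random.Generator) -> float:
        low = rng.random() < self.w
        a, b = (self.a_low, self.b_low) if low else (self.a_high, self.b_high)
        if a == 0:
            return 0.0
        if b == 0:
            return 1.0
        return float(rng.beta(a, b))


def _beta_mean(a: float, b: float) -> float:
    if a == 0:
        return 0.0
    if b == 0:
        return 1.0
    return a / (a + b)


#: Endpoint-concentrated truth for conserved contexts (true mean 0.5).
CONSERVED_MIXTURE = BetaMixture(w=0.5, a_low=0.3, b_low=6.0, a_high=6.0, b_high=0.3)
#: Flatter truth for variable contexts (true mean 0.5).
VARIABLE_MIXTURE = BetaMixture(w=0.5, a_low=1.0, b_low=3.0, a_high=3.0, b_high=1.0)


def default_context_mixtures() -> dict[str, BetaMixture]:
    """Conserved truth for GCG*/CCG*, variable truth for ACG*/TCG*."""
    return {
        context: CONSERVED_MIXTURE if context[0] in "GC" else VARIABLE_MIXTURE
        for context in TETRA_CONTEXTS
    }


@dataclass(frozen=True)
class SimulationModel:
    """Full generative model: per-context truth, depth model, genome, seed."""

    context_mixtures: Mapping[str, BetaMixture] = field(
        default_factory=default_context_mixtures
    )
    depth_kind: str = "shifted_poisson"
    depth_lambda: float = 3.0
    depth_values: Sequence[int] | None = None
    genome_length: int = 100_000
    cpg_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_kind not in DEPTH_KINDS:
            raise ValueError(f"depth_kind must be one of {DEPTH_KINDS}")
        if self.depth_kind == "shifted_poisson" and self.depth_lambda < 0:
            raise ValueError("depth_lambda must be >= 0")
        if self.depth_kind == "empirical":
            if not self.depth_values:
                raise ValueError("empirical depth model needs depth_values")
            if any(d < 1 for d in self.depth_values):
                raise ValueError("empirical depths must be >= 1")
        if self.genome_length < 10:
            raise ValueError("genome_length must be >= 10")
        if not 0 < self.cpg_rate < 0.5:
            raise ValueError("cpg_rate must lie in (0, 0.5)")

    def draw_depth(self, rng: np.random.Generator) -> int:
        if self.depth_kind == "shifted_poisson":
            return 1 + int(rng.poisson(self.depth_lambda))
        values = self.depth_values
        return int(values[int(rng.integers(len(values)))])


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated site."""

    chrom: str
    position: int
    strand: str
    context: str
    true_beta: float
    depth: int
    meth_count: int


@dataclass
class SimulatedMethylome:
    """Sites plus their ground-truth table and exclusion bookkeeping."""

    sites: list[MethylationSite]
    truth: list[TruthRecord]
    n_excluded: int


def simulate_reference(length: int, cpg_rate: float, seed: int) -> str:
    """Random sequence with CpG dinucleotides planted at ``cpg_rate``.

    Filler bases are uniform over {A, C, G, T} except that a G is never
    placed directly after a filler C, so every CG occurrence is a planted
    one and the CpG count is binomially controlled. Deterministic given
    ``seed``.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    if not 0 < cpg_rate < 0.5:
        raise ValueError("cpg_rate must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    plant = rng.random(length)
    filler = rng.integers(0, 4, size=length)
    alt = rng.integers(0, 3, size=length)  # non-G fallback after a C
    bases: list[str] = []
    i = 0
    while i < length:
        if plant[i] < cpg_rate and i + 1 < length:
            bases.append("C")
            bases.append("G")
            i += 2
            continue
        b = "ACGT"[filler[i]]
        # a trailing C is always a filler C (planted pairs end in G), so
        # blocking G here keeps every CG occurrence a planted one
        if b == "G" and bases and bases[-1] == "C":
            b = "ACT"[alt[i]]
        bases.append(b)
        i += 1
    return "".join(bases[:length])


def _iter_methylome(
    reference: Mapping[str, str], model: SimulationModel
) -> Iterator[tuple[MethylationSite, TruthRecord] | None]:
    rng = np.random.default_rng(model.seed)
    for chrom in sorted(reference):
        sub = {chrom: reference[chrom]}
        for _, position, strand in enumerate_cpg_sites(sub):
            context = extract_context(reference, chrom, position, strand)
            if context is None:
                yield None
                continue
            mixture = model.context_mixtures[context]
            true_beta = mixture.draw(rng)
            depth = model.draw_depth(rng)
            meth = int(rng.binomial(depth, true_beta))
            site = MethylationSite(chrom, position, strand, meth, depth)
            yield site, TruthRecord(
                chrom, position, strand, context, true_beta, depth, meth
            )


def simulate_methylome(
    reference: Mapping[str, str], model: SimulationModel
) -> SimulatedMethylome:
    """Simulate strand-resolved methylation calls over every CpG.

    For every strand-cytosine with an available tetranucleotide context:
    true beta* from the context's mixture, depth T from the depth model,
    M ~ Binomial(T, beta*). Sites at boundaries or with ambiguous flanks
    are excluded (no draws consumed) and counted.
    """
    sites: list[MethylationSite] = []
    truth: list[TruthRecord] = []
    n_excluded = 0
    n_cpg = 0
    for item in _iter_methylome(reference, model):
        n_cpg += 1
        if item is None:
            n_excluded += 1
            continue
        site, rec = item
        sites.append(site)
        truth.append(rec)
    if n_cpg == 0:
        raise ValueError("reference contains no CpG dinucleotide")
    return SimulatedMethylome(sites, truth, n_excluded)


def simulate_null_methylome(
    profile: DepthProfile, p: float, seed: int
) -> list[MethylationSite]:
    """Generative twin of the analytic null: M ~ Binomial(T, p) per site.

    Depths are expanded in ascending order; sites are placed on a synthetic
    chromosome at consecutive positions, plus strand. Deterministic given
    ``seed``.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    sites: list[MethylationSite] = []
    position = 1
    for depth, count in sorted(profile.counts.items()):
        meth = rng.binomial(depth, p, size=count)
        for m in meth:
            sites.append(MethylationSite("null", position, "+", int(m), depth))
            position += 2
    return sites


def write_truth_tsv(truth: Sequence[TruthRecord], path: str) -> None:
    """Write a truth table: chrom, position, strand, context, true beta, T, M."""
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("chrom\tposition\tstrand\tcontext\ttrue_beta\tdepth\tmeth_count\n")
        for rec in truth:
            handle.write(
                f"{rec.chrom}\t{rec.position}\t{rec.strand}\t{rec.context}\t"
                f"{rec.true_beta:.9g}\t{rec.depth}\t{rec.meth_count}\n"
            )
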