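"""Strand-aware flanking-sequence context annotation for CpG cytosines.

Every CpG dinucleotide carries one cytosine per strand and the two chains
are treated as separate sites throughout: the plus-strand cytosine gets the
plus-strand tetranucleotide read 5'->3', the minus-strand cytosine gets the
reverse complement of the corresponding plus-strand window. This yields 16
tetranucleotide classes (one flanking base per side) and 4 trinucleotide
classes after merging over the 3' base.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Iterator, Mapping

from .io import MethylationSite

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The 16 tetranucleotide context classes (N5 + CG + N3), lexicographic.
TETRA_CONTEXTS: tuple[str, ...] = tuple(
    f"{n5}CG{n3}" for n5, n3 in itertools.product("ACGT", "ACGT")
)

#: The 4 trinucleotide context classes (N5 + CG).
TRI_CONTEXTS: tuple[str, ...] = tuple(f"{n5}CG" for n5 in "ACGT")


class StrandMismatchError(ValueError):
    """The reference lacks a CG dinucleotide at the expected offsets."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def extract_context(
    reference: Mapping[str, str], chrom: str, position: int, strand: str
) -> str | None:
    """Tetranucleotide context of the cytosine at a CpG, or None.

    For a plus-strand site the reference must carry C at ``position`` and G
    at ``position + 1``; the context is the plus-strand window
    [position - 1, position + 2]. For a minus-strand site the reference
    must carry G at ``position`` and C at ``position - 1``; the context is
    the reverse complement of [position - 2, position + 1], so it reads
    N5-C-G-N3 5'->3' on the minus strand.

    Returns None (context unavailable) when the window extends past a
    sequence boundary or contains a non-ACGT base. Raises
    StrandMismatchError when the expected CG is absent.
    """
    try:
        seq = reference[chrom]
    except KeyError:
        raise KeyError(f"chrom {chrom!r} absent from reference") from None
    i = position - 1  # 0-based index of the site's own base
    if strand == "+":
        if i + 1 >= len(seq) or seq[i] != "C" or seq[i + 1] != "G":
            raise StrandMismatchError(
                f"{chrom}:{position}(+): reference does not carry CG at "
                f"positions {position}..{position + 1}"
            )
        if i - 1 < 0 or i + 3 > len(seq):
            return None
        window = seq[i - 1 : i + 3]
    elif strand == "-":
        if i - 1 < 0 or seq[i] != "G" or seq[i - 1] != "C":
            raise StrandMismatchError(
                f"{chrom}:{position}(-): reference does not carry CG at "
                f"positions {position - 1}..{position}"
            )
        if i - 2 < 0 or i + 2 > len(seq):
            return None
        window = reverse_complement(seq[i - 2 : i + 2])
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if any(base not in "ACGT" for base in window):
        return None
    return window


def trinucleotide_of(context: str) -> str:
    """Collapse a tetranucleotide context to its N5-C-G trinucleotide."""
    if len(context) != 4 or context[1:3] != "CG":
        raise ValueError(f"not a tetranucleotide CpG context: {context!r}")
    return context[:3]


def annotate_sites(
    sites: Iterable[MethylationSite], reference: Mapping[str, str]
) -> Iterator[tuple[MethylationSite, str]]:
    """Pair each site with its tetranucleotide context, preserving order.

    Sites whose context is unavailable (boundary or ambiguous flank) are
    dropped; the drop count is logged.
    """
    n_dropped = 0
    for site in sites:
        context = extract_context(reference, site.chrom, site.position, site.strand)
        if context is None:
            n_dropped += 1
            continue
        yield site, context
    if n_dropped:
        logger.info("annotate_sites: dropped %d sites without context", n_dropped)


def enumerate_cpg_sites(
    reference: Mapping[str, str],
) -> Iterator[tuple[str, int, str]]:
    """Yield (chrom, 1-based position, strand) for every strand-cytosine.

    Every plus-strand CG occurrence at 0-based index i yields the
    plus-strand cytosine at position i + 1 and the minus-strand cytosine at
    position i + 2, in coordinate order with plus before minus.
    """
    for chrom, seq in reference.items():
        start = 0
        while True:
            i = seq.find("CG", start)
            if i < 0:
                break
            yield chrom, i + 1, "+"
            yield chrom, i + 2, "-"
            start = i + 1
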