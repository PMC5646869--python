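"""Readers and writers for the file formats the pipeline touches.

Supported formats: Bismark-style cytosine/CX reports (1-based, 7 columns),
bedGraph coverage rows (0-based half-open), FASTA references, BED3+ region
sets and the TSV result tables produced by the divergence analysis.

Internal coordinates are 1-based for cytosine positions (the CX convention);
BED stays 0-based half-open at the parsing boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, TYPE_CHECKING

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .divergence import DivergenceResult

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: IUPAC nucleotide one-letter codes accepted in reference sequences.
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")


class ParseError(ValueError):
    """A malformed row in an input file; the message names the line number."""


@dataclass(frozen=True, slots=True)
class MethylationSite:
    """One strand-specific cytosine call.

    ``position`` is the 1-based reference coordinate of the cytosine; for
    minus-strand sites it is the coordinate of the G-paired base carrying
    the minus-strand C. ``meth_count`` is the number of methylated reads,
    ``depth`` the total read count covering the site.
    """

    chrom: str
    position: int
    strand: str
    meth_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if not 0 <= self.meth_count <= self.depth:
            raise ValueError(
                f"meth_count must satisfy 0 <= M <= depth, got "
                f"M={self.meth_count}, depth={self.depth}"
            )

    @property
    def beta(self) -> Fraction:
        """Methylation level as an exact reduced fraction M/T."""
        return Fraction(self.meth_count, self.depth)


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a reference sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )


def _open(path: str | Path) -> IO[str]:
    return open(path, "rt", encoding="utf-8")


def read_cx_report(
    path: str | Path,
    min_depth: int = 1,
    max_depth: int | None = None,
    cpg_only: bool = False,
) -> Iterator[MethylationSite]:
    """Stream sites from a cytosine/CX report.

    Rows are tab-separated: chrom, position (1-based), strand,
    count_methylated, count_unmethylated, context-class, trinucleotide;
    the trailing two columns are optional. Rows with zero depth, depth
    outside [min_depth, max_depth], or (when ``cpg_only``) a context class
    other than ``CG`` are skipped; skip counts are logged.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if max_depth is not None and max_depth < min_depth:
        raise ValueError("max_depth must be >= min_depth")
    n_zero = n_filtered = n_noncpg = n_yielded = 0
    with _open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}: line {lineno}: expected >= 5 columns")
            chrom, pos_s, strand, m_s, u_s = fields[:5]
            try:
                position = int(pos_s)
                meth = int(m_s)
                unmeth = int(u_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer field ({exc})"
                ) from None
            if strand not in STRANDS:
                raise ParseError(
                    f"{path}: line {lineno}: bad strand symbol {strand!r}"
                )
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}: line {lineno}: negative count")
            if cpg_only and len(fields) >= 6 and fields[5] != "CG":
                n_noncpg += 1
                continue
            depth = meth + unmeth
            if depth == 0:
                n_zero += 1
                continue
            if depth < min_depth or (max_depth is not None and depth > max_depth):
                n_filtered += 1
                continue
            n_yielded += 1
            yield MethylationSite(chrom, position, strand, meth, depth)
    logger.info(
        "read_cx_report(%s): %d sites, skipped %d zero-depth, "
        "%d depth-filtered, %d non-CpG",
        path, n_yielded, n_zero, n_filtered, n_noncpg,
    )


def read_bedgraph_cov(
    path: str | Path, min_depth: int = 1, max_depth: int | None = None
) -> Iterator[MethylationSite]:
    """Stream sites from bedGraph-style coverage rows.

    Columns: chrom, start (0-based), end, methylation percentage,
    count_methylated, count_unmethylated; an optional strand column may
    follow (default ``+``). Positions are converted to 1-based
    (position = start + 1). The percentage column is ignored in favour of
    recomputation from the counts; a discrepancy > 0.5 only logs a warning.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    n_zero = n_filtered = n_yielded = 0
    with _open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >= 6 columns")
            chrom = fields[0]
            try:
                start = int(fields[1])
                pct = float(fields[3])
                meth = int(fields[4])
                unmeth = int(fields[5])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: malformed field ({exc})"
                ) from None
            strand = fields[6] if len(fields) >= 7 else "+"
            if strand not in STRANDS:
                raise ParseError(
                    f"{path}: line {lineno}: bad strand symbol {strand!r}"
                )
            depth = meth + unmeth
            if depth == 0:
                n_zero += 1
                continue
            recomputed = 100.0 * meth / depth
            if abs(recomputed - pct) > 0.5:
                logger.warning(
                    "%s: line %d: percentage %.3f inconsistent with counts "
                    "(recomputed %.3f); counts win",
                    path, lineno, pct, recomputed,
                )
            if depth < min_depth or (max_depth is not None and depth > max_depth):
                n_filtered += 1
                continue
            n_yielded += 1
            yield MethylationSite(chrom, start + 1, strand, meth, depth)
    logger.info(
        "read_bedgraph_cov(%s): %d sites, skipped %d zero-depth, %d depth-filtered",
        path, n_yielded, n_zero, n_filtered,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA reference into a map of id -> uppercase sequence.

    Sequence ids are the first whitespace-delimited token of each header.
    Soft-masked (lowercase) bases are uppercased. Duplicate ids and
    non-IUPAC characters are errors.
    """
    reference: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in reference:
            raise ValueError(f"{path}: duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        for i, base in enumerate(seq):
            if base not in IUPAC_NUCLEOTIDES:
                raise ValueError(
                    f"{path}: sequence {record.id!r}: non-IUPAC character "
                    f"{base!r} at position {i + 1}"
                )
        reference[record.id] = seq
    return reference


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ rows into intervals, in file order; extra columns ignored."""
    intervals: list[GenomicInterval] = []
    with _open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            try:
                intervals.append(GenomicInterval(fields[0], start, end))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return intervals


RESULT_COLUMNS = (
    "context", "n_sites", "p", "robs0", "rran0", "robs1", "rran1",
    "kl0", "kl1", "d0", "d1", "kl_full",
)


def write_results_tsv(
    results: Sequence["DivergenceResult"],
    path: str | Path,
    comments: Sequence[str] = (),
) -> None:
    """Write divergence results as a TSV table.

    Floating values are printed with 6 significant digits. Optional
    ``comments`` lines are emitted first, prefixed with ``#``.
    """
    with open(path, "wt", encoding="utf-8") as handle:
        for comment in comments:
            handle.write(f"# {comment}\n")
        handle.write("\t".join(RESULT_COLUMNS) + "\n")
        for res in results:
            row = [
                str(res.context),
                str(res.n_sites),
                format(float(res.p), ".6g"),
                format(res.robs0, ".6g"),
                format(res.rran0, ".6g"),
                format(res.robs1, ".6g"),
                format(res.rran1, ".6g"),
                format(res.kl0, ".6g"),
                format(res.kl1, ".6g"),
                format(res.d0, ".6g"),
                format(res.d1, ".6g"),
                format(res.kl_full, ".6g"),
            ]
            handle.write("\t".join(row) + "\n")


def write_cx_report(
    sites: Iterable[MethylationSite],
    path: str | Path,
    trinucleotides: Iterable[str] | None = None,
) -> None:
    """Write sites as a 7-column CX report (context class fixed to CG).

    ``trinucleotides`` optionally supplies the 7th column per site; when
    absent the column is written as ``CGN``.
    """
    tri_iter = iter(trinucleotides) if trinucleotides is not None else None
    with open(path, "wt", encoding="utf-8") as handle:
        for site in sites:
            tri = next(tri_iter) if tri_iter is not None else "CGN"
            handle.write(
                f"{site.chrom}\t{site.position}\t{site.strand}\t"
                f"{site.meth_count}\t{site.depth - site.meth_count}\tCG\t{tri}\n"
            )


def write_fasta(reference: dict[str, str], path: str | Path, width: int = 70) -> None:
    """Write a reference map as FASTA with fixed line width."""
    with open(path, "wt", encoding="utf-8") as handle:
        for name, seq in reference.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
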