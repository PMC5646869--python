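"""Stratified divergence analyses: per-context tables, per-depth strata
and region-restricted subsets.

p is always estimated within each context class for the context tables
(each row's p is the average methylation level of that class); whole-set
runs use a single p over all sites passed in.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .context import TETRA_CONTEXTS, TRI_CONTEXTS, trinucleotide_of
from .distributions import mean_methylation, restrict_to_depth
from .divergence import DivergenceResult, summarize
from .io import GenomicInterval, MethylationSite

logger = logging.getLogger(__name__)

AnnotatedSite = tuple[MethylationSite, str]

MODES = ("tetra", "tri")


@dataclass
class ReportRow:
    """One stratified result: a stratum label plus its divergence record."""

    stratum: str
    result: DivergenceResult


@dataclass
class StratificationReport:
    """Collection of per-context divergence rows with run metadata."""

    rows: list[ReportRow]
    metadata: dict = field(default_factory=dict)

    def results(self, stratum: str | None = None) -> list[DivergenceResult]:
        return [
            row.result
            for row in self.rows
            if stratum is None or row.stratum == stratum
        ]

    def kl0(self, context: str, stratum: str | None = None) -> float:
        for res in self.results(stratum):
            if res.context == context:
                return res.kl0
        raise KeyError(context)

    def kl1(self, context: str, stratum: str | None = None) -> float:
        for res in self.results(stratum):
            if res.context == context:
                return res.kl1
        raise KeyError(context)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {"stratum": row.stratum}
            rec.update(vars(row.result))
            records.append(rec)
        return pd.DataFrame(records)


def _expected_contexts(mode: str) -> tuple[str, ...]:
    if mode == "tetra":
        return TETRA_CONTEXTS
    if mode == "tri":
        return TRI_CONTEXTS
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _group_by_context(
    annotated_sites: Iterable[AnnotatedSite], mode: str
) -> dict[str, list[MethylationSite]]:
    groups: dict[str, list[MethylationSite]] = {}
    for site, context in annotated_sites:
        key = trinucleotide_of(context) if mode == "tri" else context
        groups.setdefault(key, []).append(site)
    return groups


def analyze_all_contexts(
    annotated_sites: Iterable[AnnotatedSite],
    mode: str = "tetra",
    p_mode: str = "per_site",
    stratum: str = "all",
) -> StratificationReport:
    """Per-context divergence table (16 tetra classes or 4 tri classes).

    Sites are grouped by context; each group gets its own p. Expected
    contexts with zero sites are omitted with a warning.
    """
    expected = _expected_contexts(mode)
    groups = _group_by_context(annotated_sites, mode)
    if not groups:
        raise ValueError("no annotated sites to analyze")
    rows = []
    for context in expected:
        if context not in groups:
            logger.warning("context %s has no sites; omitted", context)
            continue
        rows.append(
            ReportRow(stratum, summarize(context, groups[context], p_mode=p_mode))
        )
    n_total = sum(len(g) for g in groups.values())
    return StratificationReport(
        rows,
        metadata={
            "mode": mode,
            "p_mode": p_mode,
            "n_sites": n_total,
            "p_scope": "per_context",
        },
    )


def analyze_by_depth(
    annotated_sites: Iterable[AnnotatedSite],
    depths: Sequence[int],
    mode: str = "tetra",
    p_mode: str = "per_site",
) -> StratificationReport:
    """Per-depth, per-context divergence strata.

    For each requested depth the input is restricted to sites with exactly
    that depth before the context analysis. Depths with no sites produce an
    empty stratum and a warning.
    """
    if not depths:
        raise ValueError("depths must be non-empty")
    annotated = list(annotated_sites)
    rows: list[ReportRow] = []
    empty_strata: list[int] = []
    for depth in depths:
        stratum = f"depth={depth}"
        subset = [
            (site, ctx)
            for site, ctx in annotated
            if site.depth == depth
        ]
        if not subset:
            logger.warning("depth stratum %d has no sites", depth)
            empty_strata.append(depth)
            continue
        sub_report = analyze_all_contexts(
            subset, mode=mode, p_mode=p_mode, stratum=stratum
        )
        rows.extend(sub_report.rows)
    return StratificationReport(
        rows,
        metadata={
            "mode": mode,
            "p_mode": p_mode,
            "depths": list(depths),
            "empty_strata": empty_strata,
        },
    )


def _merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out: list[tuple[int, int]] = []
        for start, end in spans:
            if out and start <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], end))
            else:
                out.append((start, end))
        merged[chrom] = out
    return merged


def subset_by_regions(
    sites: Iterable[MethylationSite],
    intervals: Iterable[GenomicInterval],
    keep: str = "inside",
) -> list[MethylationSite]:
    """Sites inside (or outside) a set of 0-based half-open intervals.

    Membership is decided by the cytosine's own 1-based coordinate p:
    inside iff start < p <= end for some interval. Overlapping intervals
    are merged first, so no site is ever double-counted.
    """
    if keep not in ("inside", "outside"):
        raise ValueError(f"keep must be 'inside' or 'outside', got {keep!r}")
    merged = _merge_intervals(intervals)
    selected: list[MethylationSite] = []
    for site in sites:
        spans = merged.get(site.chrom, ())
        pos0 = site.position - 1  # 0-based coordinate of the cytosine
        inside = False
        if spans:
            starts = [s for s, _ in spans]
            idx = bisect_right(starts, pos0) - 1
            inside = idx >= 0 and pos0 < spans[idx][1]
        if inside == (keep == "inside"):
            selected.append(site)
    return selected


def average_methylation_by_context(
    annotated_sites: Iterable[AnnotatedSite], mode: str = "tetra"
) -> pd.DataFrame:
    """Per-context mean methylation level and site count.

    Returns a DataFrame with columns context, mean_beta, n_sites, ordered
    by context.
    """
    groups = _group_by_context(annotated_sites, mode)
    if not groups:
        raise ValueError("no annotated sites to average")
    records = []
    for context in _expected_contexts(mode):
        if context not in groups:
            continue
        group = groups[context]
        records.append(
            {
                "context": context,
                "mean_beta": float(mean_methylation(group)),
                "n_sites": len(group),
            }
        )
    return pd.DataFrame.from_records(records)
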