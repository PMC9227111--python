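"""Align the matched literature with the exceptional-species list.

This module turns per-article match results and the exceptional-species
records into the gap-analysis summaries: per-taxon article counts and
top-N rankings, literature/exceptional overlap sets, within-family genus
overlap percentages, the exceptionality-factor (EF) breakdown of families
with no literature at all, the share of a family's articles concentrated on
a single species, and per-genus tree fractions.

All percentages are integer percents rounded half-up (half away from zero);
tree fractions may exceed 100% because the tree database and the backbone
circumscribe genera differently.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

from .corpus_io import (
    EF_CATEGORIES,
    ExceptionalSpeciesRecord,
    TreeCountRow,
)
from .errors import ValidationError
from .taxonomy_matching import MatchResult


def round_half_up(value: float | Decimal) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(Decimal(value).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PercentValue:
    """A ratio reported as an integer percent (round-half-up)."""

    numerator: float
    denominator: float
    percent: int

    @classmethod
    def of(cls, numerator: float, denominator: float) -> "PercentValue":
        if denominator <= 0:
            raise ValidationError("percent denominator must be positive")
        return cls(
            numerator,
            denominator,
            round_half_up(Decimal(100) * Decimal(numerator) / Decimal(denominator)),
        )


@dataclass(frozen=True)
class TaxonCount:
    taxon: str
    level: str  # genus | family
    n_articles: int


@dataclass(frozen=True)
class RankedCounts:
    """Top-N ranking; ties straddling the cutoff are included, not dropped."""

    entries: tuple[TaxonCount, ...]
    n_requested: int
    cutoff_expanded: bool


@dataclass(frozen=True)
class OverlapSummary:
    """Set comparison of literature taxa vs exceptional-list taxa."""

    common: frozenset[str]
    literature_only: frozenset[str]
    exceptional_only: frozenset[str]

    @property
    def n_common(self) -> int:
        return len(self.common)

    @property
    def n_exceptional_missing(self) -> int:
        return len(self.exceptional_only)


@dataclass(frozen=True)
class EFBreakdownRow:
    """Per-family species total plus per-EF flag counts.

    EF flags are non-exclusive, so ef1+ef2+ef3+ef4 may exceed ``total``
    (``total`` counts species; the EF columns count flags).
    """

    family: str
    total: int
    ef1: int
    ef2: int
    ef3: int
    ef4: int

    def ef_counts(self) -> tuple[int, int, int, int]:
        return (self.ef1, self.ef2, self.ef3, self.ef4)


# ---------------------------------------------------------------------------
# counting and ranking
# ---------------------------------------------------------------------------


def count_by_taxon(
    match_results: Sequence[MatchResult], level: str
) -> list[TaxonCount]:
    """Article counts per taxon at ``level``; an article with k matched taxa
    contributes one article to each of the k.  Sorted by count descending,
    then name ascending."""
    if level not in {"genus", "family"}:
        raise ValidationError(f"level must be genus or family, got {level!r}")
    counts: dict[str, int] = {}
    for result in match_results:
        taxa = (
            result.matched_genera if level == "genus" else result.matched_families
        )
        for taxon in taxa:
            counts[taxon] = counts.get(taxon, 0) + 1
    return [
        TaxonCount(name, level, n)
        for name, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def top_n(counts: Sequence[TaxonCount], n: int) -> RankedCounts:
    """First *n* taxa by count desc / name asc; if taxa tied at the cutoff
    count would be split, all of them are included and the expansion noted."""
    ordered = sorted(counts, key=lambda c: (-c.n_articles, c.taxon))
    if n <= 0 or not ordered:
        return RankedCounts((), n, False)
    if len(ordered) <= n:
        return RankedCounts(tuple(ordered), n, False)
    cutoff = ordered[n - 1].n_articles
    end = n
    while end < len(ordered) and ordered[end].n_articles == cutoff:
        end += 1
    return RankedCounts(tuple(ordered[:end]), n, end > n)


def overlap(lit_taxa: Iterable[str], exc_taxa: Iterable[str]) -> OverlapSummary:
    """Exact set algebra between literature taxa and exceptional taxa."""
    lit, exc = frozenset(lit_taxa), frozenset(exc_taxa)
    return OverlapSummary(
        common=lit & exc, literature_only=lit - exc, exceptional_only=exc - lit
    )


# ---------------------------------------------------------------------------
# percent tables
# ---------------------------------------------------------------------------


def genera_overlap_by_family(
    family: str, exc_genera_count: int, common_count: int
) -> PercentValue:
    """Percent of a family's exceptional genera that appear in the literature."""
    if exc_genera_count <= 0:
        raise ValidationError(f"{family}: exceptional genera count must be positive")
    return PercentValue.of(common_count, exc_genera_count)


def species_share(
    species_article_count: int, family_article_count: int
) -> PercentValue:
    """Share of a family's articles that concern one species."""
    if family_article_count <= 0:
        raise ValidationError("family article count must be positive")
    return PercentValue.of(species_article_count, family_article_count)


def percent_trees(row: TreeCountRow) -> Optional[PercentValue]:
    """Tree fraction of a genus: tree count over backbone accepted+unchecked
    species (missing counts are zero).  Returns None for a flagged row whose
    denominator is zero; values above 100% are legitimate (differing genus
    circumscriptions between the two sources)."""
    denominator = (row.wfo_accepted or 0) + (row.wfo_unchecked or 0)
    if denominator <= 0:
        return None
    return PercentValue.of(row.gts_trees, denominator)


# ---------------------------------------------------------------------------
# EF breakdown of zero-literature families
# ---------------------------------------------------------------------------


def ef_rows_from_records(
    families: Iterable[str], records: Sequence[ExceptionalSpeciesRecord]
) -> list[EFBreakdownRow]:
    """Tabulate species totals and EF flag counts for the given families,
    sorted by species total descending then family name."""
    wanted = set(families)
    per_family: dict[str, list[ExceptionalSpeciesRecord]] = {}
    for rec in records:
        if rec.family in wanted:
            per_family.setdefault(rec.family, []).append(rec)
    rows = []
    for family, recs in per_family.items():
        flags = {ef: 0 for ef in EF_CATEGORIES}
        for rec in recs:
            for ef in rec.efs:
                flags[ef] += 1
        rows.append(
            EFBreakdownRow(family, len(recs), flags["EF1"], flags["EF2"],
                           flags["EF3"], flags["EF4"])
        )
    return sorted(rows, key=lambda r: (-r.total, r.family))


def summarize_ef_rows(
    rows: Sequence[EFBreakdownRow],
) -> tuple[EFBreakdownRow, tuple[int, int, int, int]]:
    """Column-wise totals plus per-EF percents of the species total."""
    total = sum(r.total for r in rows)
    efs = [sum(r.ef_counts()[i] for r in rows) for i in range(4)]
    totals = EFBreakdownRow("TOTAL", total, *efs)
    if total <= 0:
        raise ValidationError("EF breakdown has no species")
    percents = tuple(PercentValue.of(e, total).percent for e in efs)
    return totals, percents


def zero_literature_families(
    family_counts: Mapping[str, int] | Sequence[TaxonCount],
    records: Sequence[ExceptionalSpeciesRecord],
    min_species: int = 2,
) -> list[str]:
    """Exceptional families with no matched articles and at least
    ``min_species`` exceptional species."""
    if not isinstance(family_counts, Mapping):
        family_counts = {c.taxon: c.n_articles for c in family_counts}
    n_species: dict[str, int] = {}
    for rec in records:
        n_species[rec.family] = n_species.get(rec.family, 0) + 1
    return sorted(
        fam
        for fam, n in n_species.items()
        if n >= min_species and family_counts.get(fam, 0) == 0
    )


def ef_breakdown(
    zero_lit_families: Iterable[str],
    records: Sequence[ExceptionalSpeciesRecord],
) -> tuple[list[EFBreakdownRow], EFBreakdownRow, tuple[int, int, int, int]]:
    """EF tabulation for the zero-literature families: per-family rows,
    the totals row, and the per-EF percent row."""
    rows = ef_rows_from_records(zero_lit_families, records)
    totals, percents = summarize_ef_rows(rows)
    return rows, totals, percents
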