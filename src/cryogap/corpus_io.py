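"""Readers, writers and validation for every pipeline input.

Handles four kinds of input:

* **article exports** — tabular files (CSV/TSV/XLSX) with a unique article
  id, title and abstract, mapped through a user-supplied column map (the
  defaults mirror common bibliographic export field tags: UT/TI/AB);
* **a taxonomic backbone** — a Darwin-Core-like CSV giving accepted genus
  and family names and the genus-to-family assignment, plus an editable
  sidecar list of homograph names (genera spelled like ordinary words,
  e.g. "Medium") that must never be matched;
* **the exceptional-species list** — species / family / exceptionality
  factor rows (EF1 few or no seeds, EF2 desiccation-sensitive seeds,
  EF3 short-lived seeds, EF4 deeply dormant seeds);
* **keyword lexicons** — a sectioned plain-text format holding the
  positive/negative/non-seed/tissue keyword sets, common-name aliases and
  the homograph exclusions;
* **per-genus tree-count tables** — tree species counts alongside backbone
  accepted/unchecked/synonym/doubtful species counts ("NA" = missing).

All free text is NFC-normalized with whitespace collapsed on the way in.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from ._text import normalize
from .errors import ConfigurationError, ValidationError
from .keyword_classification import (
    KeywordLexicon,
    NONSEED_CATEGORIES,
    TISSUE_CATEGORIES,
)

#: Default article-export column map (bibliographic export field tags).
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "article_id": "UT",
    "title": "TI",
    "abstract": "AB",
}

EF_CATEGORIES = ("EF1", "EF2", "EF3", "EF4")

#: Homograph genus names shipped as the default exclusion seed: genera whose
#: names are ordinary words (or place names) and therefore only ever match
#: non-taxonomic uses in titles/abstracts.
DEFAULT_EXCLUDED_NAMES = ("Aa", "Cotyledon", "Cuba", "India", "Ion", "Medium")


def packaged_data(name: str):
    """Path-like handle to a data file shipped inside the package."""
    return resources.files("cryogap.data").joinpath(name)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArticleRecord:
    """One literature record: id, title, abstract plus passthrough fields."""

    article_id: str
    title: str
    abstract: str = ""
    source_fields: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.article_id:
            raise ValidationError("article_id must be non-empty")
        if not normalize(self.title):
            raise ValidationError(f"article {self.article_id}: empty title")


@dataclass(frozen=True)
class TaxonBackbone:
    """Accepted genus/family names plus the genus-to-family assignment.

    ``excluded_names`` are never matched; ``common_names`` maps a lowercase
    alias to its (genus, family) pair.
    """

    genera: frozenset[str]
    families: frozenset[str]
    genus_to_family: Mapping[str, str]
    excluded_names: frozenset[str] = frozenset()
    common_names: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = self.genera - set(self.genus_to_family)
        if missing:
            raise ValidationError(
                f"genus_to_family is not total; missing {sorted(missing)[:5]}..."
            )
        stray = set(self.genus_to_family.values()) - self.families
        if stray:
            raise ValidationError(
                f"genus_to_family maps into unknown families {sorted(stray)[:5]}"
            )
        lowered = [a.lower() for a in self.common_names]
        if len(lowered) != len(set(lowered)):
            raise ValidationError("common-name aliases collide case-insensitively")

    @property
    def searchable_names(self) -> frozenset[str]:
        """Genus and family names eligible for matching (exclusions removed)."""
        return (self.genera | self.families) - self.excluded_names


@dataclass(frozen=True)
class ExceptionalSpeciesRecord:
    """One exceptional species with its exceptionality factor(s).

    EF flags are non-exclusive: a species may be, e.g., both short-lived
    (EF3) and deeply dormant (EF4); ``efs`` is the sorted tuple of flags.
    """

    species: str
    family: str
    efs: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.efs) - set(EF_CATEGORIES)
        if bad or not self.efs:
            raise ValidationError(
                f"species {self.species!r}: bad EF categories {sorted(bad)}"
            )

    @property
    def genus(self) -> str:
        return self.species.split()[0]


@dataclass(frozen=True)
class TreeCountRow:
    """Per-genus tree count with backbone species tallies; None = missing."""

    genus: str
    gts_trees: int
    wfo_synonym: Optional[int] = None
    wfo_accepted: Optional[int] = None
    wfo_unchecked: Optional[int] = None
    wfo_doubtful: Optional[int] = None


class ReadReport(NamedTuple):
    """Records read from an export plus the rows skipped (row, reason)."""

    records: list[ArticleRecord]
    skipped: list[tuple[int, str]]


# ---------------------------------------------------------------------------
# article exports
# ---------------------------------------------------------------------------


def _read_table(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    try:
        if suffix in {".xlsx", ".xls"}:
            return pd.read_excel(path, dtype=str)
        sep = "\t" if suffix in {".tsv", ".txt"} else ","
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc


def read_article_export(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> ReadReport:
    """Read an article export; skip (and report) rows with empty id or title.

    ``column_map`` maps the logical fields ``article_id``/``title``/
    ``abstract`` to the file's column names; remaining columns are kept as
    passthrough ``source_fields``.  Row order is preserved.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    frame = _read_table(path).fillna("")
    for logical, col in cmap.items():
        if col not in frame.columns:
            raise ConfigurationError(
                f"{path}: mapped column {col!r} (for {logical}) not found; "
                f"columns are {list(frame.columns)}"
            )
    extra_cols = [c for c in frame.columns if c not in cmap.values()]
    records: list[ArticleRecord] = []
    skipped: list[tuple[int, str]] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        data = dict(zip(frame.columns, row))
        article_id = normalize(data[cmap["article_id"]])
        title = normalize(data[cmap["title"]])
        if not article_id:
            skipped.append((i, "empty article id"))
            continue
        if not title:
            skipped.append((i, "empty title"))
            continue
        records.append(
            ArticleRecord(
                article_id,
                title,
                normalize(data[cmap["abstract"]]),
                {c: data[c] for c in extra_cols},
            )
        )
    return ReadReport(records, skipped)


def write_article_export(
    records: Sequence[ArticleRecord], path: str | Path
) -> None:
    """Write records as CSV in the default UT/TI/AB dialect.

    Passthrough ``source_fields`` become extra columns so that a
    read -> write -> read cycle reproduces the records exactly.
    """
    extra: list[str] = []
    for rec in records:
        for key in rec.source_fields:
            if key not in extra:
                extra.append(key)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["UT", "TI", "AB", *extra])
        for rec in records:
            writer.writerow(
                [rec.article_id, rec.title, rec.abstract]
                + [rec.source_fields.get(k, "") for k in extra]
            )


def deduplicate_articles(
    records: Sequence[ArticleRecord],
) -> tuple[list[ArticleRecord], int]:
    """Drop repeat ids, keeping the first occurrence in input order."""
    seen: set[str] = set()
    unique: list[ArticleRecord] = []
    for rec in records:
        if rec.article_id not in seen:
            seen.add(rec.article_id)
            unique.append(rec)
    return unique, len(records) - len(unique)


# ---------------------------------------------------------------------------
# taxonomic backbone
# ---------------------------------------------------------------------------


def read_excluded_names(path: str | Path | None = None) -> frozenset[str]:
    """Read the homograph exclusion sidecar (one name per line, # comments)."""
    if path is None:
        text = packaged_data("excluded_names.txt").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    names = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.add(line)
    return frozenset(names)


def read_backbone(
    path: str | Path,
    excluded_path: str | Path | None = None,
    common_names: Mapping[str, str] | None = None,
) -> TaxonBackbone:
    """Load a backbone CSV (taxonID, scientificName, taxonRank, family,
    taxonomicStatus); only genus- and family-rank rows are consumed.

    ``common_names`` maps alias -> genus; aliases whose genus is absent from
    the backbone are dropped (they cannot be resolved to a family).
    A genus listed with two different families is a validation error.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"scientificName", "taxonRank", "family"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"{path}: backbone lacks columns {sorted(missing)}")
    genus_to_family: dict[str, str] = {}
    families: set[str] = set()
    conflicts: set[str] = set()
    for row in frame.itertuples(index=False):
        rank = normalize(getattr(row, "taxonRank")).lower()
        name = normalize(getattr(row, "scientificName"))
        fam = normalize(getattr(row, "family"))
        if rank == "family" and name:
            families.add(name)
        elif rank == "genus" and name:
            if name in genus_to_family and fam and genus_to_family[name] != fam:
                conflicts.add(name)
            elif fam:
                genus_to_family.setdefault(name, fam)
    if conflicts:
        raise ValidationError(
            f"genera with conflicting family assignments: {sorted(conflicts)}"
        )
    families |= set(genus_to_family.values())
    excluded = read_excluded_names(excluded_path)
    aliases: dict[str, tuple[str, str]] = {}
    for alias, genus in (common_names or {}).items():
        if genus in genus_to_family:
            aliases[alias.lower()] = (genus, genus_to_family[genus])
    return TaxonBackbone(
        genera=frozenset(genus_to_family),
        families=frozenset(families),
        genus_to_family=genus_to_family,
        excluded_names=excluded,
        common_names=aliases,
    )


def write_backbone(backbone: TaxonBackbone, path: str | Path) -> None:
    """Write a backbone back to the CSV dialect ``read_backbone`` consumes."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["taxonID", "scientificName", "taxonRank", "family", "taxonomicStatus"]
        )
        for i, fam in enumerate(sorted(backbone.families)):
            writer.writerow([f"fam-{i}", fam, "family", fam, "Accepted"])
        for i, genus in enumerate(sorted(backbone.genera)):
            writer.writerow(
                [f"gen-{i}", genus, "genus", backbone.genus_to_family[genus], "Accepted"]
            )


# ---------------------------------------------------------------------------
# exceptional-species list
# ---------------------------------------------------------------------------


def read_exceptional_list(path: str | Path) -> list[ExceptionalSpeciesRecord]:
    """Read the exceptional-species CSV (species, family, exceptionality_factor).

    The EF cell holds one or more of EF1..EF4 separated by ``;`` (flags are
    non-exclusive).  An unknown EF token raises with the offending row number.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"species", "family", "exceptionality_factor"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    records: list[ExceptionalSpeciesRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        species = normalize(getattr(row, "species"))
        family = normalize(getattr(row, "family"))
        raw = normalize(getattr(row, "exceptionality_factor"))
        if not species:
            continue
        efs = tuple(sorted({t.strip() for t in raw.replace("+", ";").split(";") if t.strip()}))
        bad = set(efs) - set(EF_CATEGORIES)
        if bad or not efs:
            raise ValidationError(
                f"{path} row {i}: unknown exceptionality factor {raw!r}"
            )
        records.append(ExceptionalSpeciesRecord(species, family, efs))
    return records


def write_exceptional_list(
    records: Sequence[ExceptionalSpeciesRecord], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "family", "exceptionality_factor"])
        for rec in records:
            writer.writerow([rec.species, rec.family, ";".join(rec.efs)])


def packaged_exceptional_list() -> list[ExceptionalSpeciesRecord]:
    """The packaged 775-species synthetic working list (see its header)."""
    with resources.as_file(packaged_data("exceptional_list_synthetic.csv")) as p:
        return read_exceptional_list(p)


# ---------------------------------------------------------------------------
# keyword lexicon
# ---------------------------------------------------------------------------

_SIMPLE_SECTIONS = {"positive", "negative", "review", "exclusions", "common_names"}


def read_lexicon(path: str | Path | None = None) -> KeywordLexicon:
    """Parse a sectioned lexicon file; ``None`` loads the packaged default.

    Sections: ``[positive]``, ``[negative]``, ``[review]``,
    ``[nonseed:<category>]``, ``[tissue:<category>]``, ``[common_names]``
    (lines ``alias = Genus``) and ``[exclusions]``.  Keywords are lowercased;
    duplicates within a section collapse silently; a keyword appearing in
    both positive and negative sections is a validation error.
    """
    if path is None:
        text = packaged_data("default_lexicon.txt").read_text(encoding="utf-8")
        src = "<packaged default>"
    else:
        text = Path(path).read_text(encoding="utf-8")
        src = str(path)
    sections: dict[str, list[str]] = {}
    current: Optional[str] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip().lower()
            base = current.split(":", 1)[0]
            if base not in _SIMPLE_SECTIONS | {"nonseed", "tissue"}:
                raise ValidationError(f"{src} line {lineno}: unknown section {line}")
            sections.setdefault(current, [])
        elif current is None:
            raise ValidationError(f"{src} line {lineno}: entry before any section")
        else:
            sections[current].append(line)

    def words(key: str) -> frozenset[str]:
        return frozenset(w.lower() for w in sections.get(key, []))

    nonseed = {}
    tissue = {}
    for key, entries in sections.items():
        if key.startswith("nonseed:"):
            nonseed[key.split(":", 1)[1]] = frozenset(w.lower() for w in entries)
        elif key.startswith("tissue:"):
            # tissue category names are case-sensitive labels (e.g. InVitro)
            label = key.split(":", 1)[1]
            canonical = {c.lower(): c for c in TISSUE_CATEGORIES}.get(label)
            if canonical is None:
                raise ValidationError(f"{src}: unknown tissue category {label!r}")
            tissue[canonical] = frozenset(w.lower() for w in entries)
    aliases: dict[str, str] = {}
    for entry in sections.get("common_names", []):
        if "=" not in entry:
            raise ValidationError(f"{src}: bad common-name line {entry!r}")
        alias, genus = (part.strip() for part in entry.split("=", 1))
        aliases[alias.lower()] = genus
    exclusions = frozenset(sections.get("exclusions", []))
    return KeywordLexicon(
        positive=words("positive"),
        negative=words("negative"),
        nonseed=nonseed,
        tissue=tissue,
        review_triggers=words("review") or frozenset({"human"}),
        common_names=aliases,
        excluded_names=exclusions,
    )


def write_lexicon(lexicon: KeywordLexicon, path: str | Path) -> None:
    """Write a lexicon in the sectioned format ``read_lexicon`` consumes."""
    lines: list[str] = []
    for name, wordset in (
        ("positive", lexicon.positive),
        ("negative", lexicon.negative),
        ("review", lexicon.review_triggers),
    ):
        lines.append(f"[{name}]")
        lines.extend(sorted(wordset))
    for cat in NONSEED_CATEGORIES:
        if cat in lexicon.nonseed:
            lines.append(f"[nonseed:{cat}]")
            lines.extend(sorted(lexicon.nonseed[cat]))
    for cat in TISSUE_CATEGORIES:
        if cat in lexicon.tissue:
            lines.append(f"[tissue:{cat}]")
            lines.extend(sorted(lexicon.tissue[cat]))
    lines.append("[common_names]")
    lines.extend(f"{a} = {g}" for a, g in sorted(lexicon.common_names.items()))
    lines.append("[exclusions]")
    lines.extend(sorted(lexicon.excluded_names))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# tree counts
# ---------------------------------------------------------------------------

_TREE_COLUMNS = (
    "genus",
    "gts_trees",
    "wfo_synonym",
    "wfo_accepted",
    "wfo_unchecked",
    "wfo_doubtful",
)


def read_tree_counts(path: str | Path) -> list[TreeCountRow]:
    """Read the per-genus tree-count table; "NA" or blank means missing."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_TREE_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")

    def cell(value: str) -> Optional[int]:
        value = value.strip()
        if value in {"", "NA", "na", "NaN"}:
            return None
        return int(value)

    rows = []
    for row in frame.itertuples(index=False):
        rows.append(
            TreeCountRow(
                genus=normalize(getattr(row, "genus")),
                gts_trees=cell(getattr(row, "gts_trees")) or 0,
                wfo_synonym=cell(getattr(row, "wfo_synonym")),
                wfo_accepted=cell(getattr(row, "wfo_accepted")),
                wfo_unchecked=cell(getattr(row, "wfo_unchecked")),
                wfo_doubtful=cell(getattr(row, "wfo_doubtful")),
            )
        )
    return rows


def write_tree_counts(rows: Sequence[TreeCountRow], path: str | Path) -> None:
    def cell(value: Optional[int]) -> str:
        return "NA" if value is None else str(value)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TREE_COLUMNS)
        for r in rows:
            writer.writerow(
                [r.genus, r.gts_trees, cell(r.wfo_synonym), cell(r.wfo_accepted),
                 cell(r.wfo_unchecked), cell(r.wfo_doubtful)]
            )
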