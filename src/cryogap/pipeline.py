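"""End-to-end orchestration: read, dedup, match, screen, classify, report.

A single config drives the whole run; outputs are a bundle of report CSVs
(one per summary table shape), per-article provenance logs, plot-ready
category counts, and a JSON run manifest recording input digests, the config
snapshot and every stage count.  Given identical inputs and config the
bundle is byte-identical across reruns.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import __version__
from .corpus_io import (
    ArticleRecord,
    deduplicate_articles,
    packaged_data,
    read_article_export,
    read_backbone,
    read_exceptional_list,
    read_lexicon,
    read_tree_counts,
)
from .errors import ConfigurationError, ValidationError
from ._text import compile_phrase, normalize
from .gap_analysis import (
    count_by_taxon,
    ef_breakdown,
    genera_overlap_by_family,
    overlap,
    percent_trees,
    species_share,
    top_n,
    zero_literature_families,
)
from .keyword_classification import (
    TISSUE_CATEGORIES,
    classify_tissue,
    screen_articles,
)
from .taxonomy_matching import batch_match, write_match_results

REPORT_FILES = (
    "taxon_counts.csv",
    "overlap.csv",
    "table3_family_overlap.csv",
    "table4_percent_trees.csv",
    "table5_species_share.csv",
    "table6_ef_breakdown.csv",
    "category_counts.csv",
)


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``from_yaml`` for the file layout)."""

    article_exports: Sequence[str]
    backbone: str
    exceptional_list: Optional[str] = None  # None -> packaged synthetic list
    lexicon: Optional[str] = None  # None -> packaged default lexicon
    excluded_names: Optional[str] = None  # None -> packaged homograph seed
    tree_counts: Optional[str] = None
    column_map: Mapping[str, str] = field(default_factory=dict)
    top_n: int = 25
    family_overlap_top: int = 10
    min_species_zero_lit: int = 2
    species_share_min_articles: int = 5
    nonseed_excluded_from_tissue: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        inputs = raw.get("inputs", {})
        options = raw.get("options", {})
        if "article_exports" not in inputs or "backbone" not in inputs:
            raise ConfigurationError(
                "config must provide inputs.article_exports and inputs.backbone"
            )
        base = Path(path).resolve().parent

        def resolve(p: Optional[str]) -> Optional[str]:
            return None if p is None else str((base / p) if not Path(p).is_absolute() else Path(p))

        return cls(
            article_exports=[resolve(p) for p in inputs["article_exports"]],
            backbone=resolve(inputs["backbone"]),
            exceptional_list=resolve(inputs.get("exceptional_list")),
            lexicon=resolve(inputs.get("lexicon")),
            excluded_names=resolve(inputs.get("excluded_names")),
            tree_counts=resolve(inputs.get("tree_counts")),
            column_map=inputs.get("column_map", {}),
            seed=int(raw.get("seed", 0)),
            **{k: options[k] for k in (
                "top_n", "family_overlap_top", "min_species_zero_lit",
                "species_share_min_articles", "nonseed_excluded_from_tissue",
            ) if k in options},
        )


@dataclass
class RunManifest:
    """What ran: input digests, config, per-stage article counts."""

    input_digests: dict[str, str]
    config: dict
    stage_counts: dict[str, int]
    seed: int
    version: str = __version__

    def check_monotone(self) -> None:
        chain = ("articles_read", "articles_deduplicated", "articles_kept")
        values = [self.stage_counts[k] for k in chain]
        if values != sorted(values, reverse=True):
            raise ValidationError(f"stage counts not monotone: {values}")

    def write(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "inputs": self.input_digests,
            "config": self.config,
            "stage_counts": self.stage_counts,
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_csv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def count_species_articles(
    records: Sequence[ArticleRecord], species: Sequence[str]
) -> dict[str, int]:
    """Articles mentioning each species binomial (case-sensitive genus,
    whole-phrase, title or abstract)."""
    counts = {s: 0 for s in species}
    patterns = {s: compile_phrase(s, casefold=False) for s in species}
    for rec in records:
        text = normalize(rec.title) + " \n " + normalize(rec.abstract)
        for s, pat in patterns.items():
            if pat.search(text):
                counts[s] += 1
    return counts


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute every stage and write the report bundle into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lexicon = read_lexicon(config.lexicon)
    backbone = read_backbone(
        config.backbone, config.excluded_names, common_names=lexicon.common_names
    )
    if config.exceptional_list is None:
        exceptional = read_exceptional_list(
            packaged_data("exceptional_list_synthetic.csv")
        )
    else:
        exceptional = read_exceptional_list(config.exceptional_list)

    # --- read + merge + dedup
    records: list[ArticleRecord] = []
    n_skipped = 0
    for export in config.article_exports:
        report = read_article_export(export, config.column_map)
        records.extend(report.records)
        n_skipped += len(report.skipped)
    deduped, n_dup = deduplicate_articles(records)

    # --- match
    match_results, match_summary = batch_match(deduped, backbone)
    write_match_results(match_results, out / "match_results.csv")

    # --- screen + classify
    screening = screen_articles(deduped, lexicon)
    kept_ids = set(screening.kept)
    kept_records = [r for r in deduped if r.article_id in kept_ids]
    kept_matches = [m for m in match_results if m.article_id in kept_ids]
    _write_csv(
        out / "screening.csv",
        ["article_id", "decision", "trigger_keywords", "flags"],
        [
            [
                rec.article_id,
                "kept" if rec.article_id in kept_ids else "removed",
                ";".join(screening.removed_trigger_keywords.get(rec.article_id, ())),
                ";".join(
                    flag
                    for flag, members in (
                        ("review", screening.flagged_review),
                        ("no_positive", screening.flagged_no_positive),
                    )
                    if rec.article_id in members
                ),
            ]
            for rec in deduped
        ],
    )
    tissue_labels = {r.article_id: classify_tissue(r, lexicon) for r in kept_records}

    # --- gap analysis
    genus_counts = count_by_taxon(kept_matches, "genus")
    family_counts = count_by_taxon(kept_matches, "family")
    _write_csv(
        out / "taxon_counts.csv",
        ["taxon", "level", "n_articles"],
        [[c.taxon, c.level, c.n_articles] for c in genus_counts + family_counts],
    )

    exc_genera = {r.genus for r in exceptional}
    exc_families = {r.family for r in exceptional}
    lit_genera = {c.taxon for c in genus_counts}
    lit_families = {c.taxon for c in family_counts}
    rows = []
    for level, lit, exc in (
        ("genus", lit_genera, exc_genera),
        ("family", lit_families, exc_families),
    ):
        summary = overlap(lit, exc)
        rows.append(
            [level, summary.n_common, len(summary.literature_only),
             summary.n_exceptional_missing]
        )
    _write_csv(
        out / "overlap.csv",
        ["level", "n_common", "n_literature_only", "n_exceptional_only"],
        rows,
    )

    # within-family genus overlap for families ranking high on both sides
    exc_family_species: dict[str, int] = {}
    exc_family_genera: dict[str, set[str]] = {}
    for rec in exceptional:
        exc_family_species[rec.family] = exc_family_species.get(rec.family, 0) + 1
        exc_family_genera.setdefault(rec.family, set()).add(rec.genus)
    top_lit = {c.taxon for c in top_n(family_counts, config.family_overlap_top).entries}
    exc_ranked = sorted(exc_family_species.items(), key=lambda kv: (-kv[1], kv[0]))
    top_exc = {fam for fam, _ in exc_ranked[: config.family_overlap_top]}
    lit_genera_by_family: dict[str, set[str]] = {}
    for m in kept_matches:
        for genus in m.matched_genera:
            fam = backbone.genus_to_family.get(genus)
            if fam:
                lit_genera_by_family.setdefault(fam, set()).add(genus)
    overlap_rows = []
    for family in sorted(top_lit & top_exc):
        exc_g = exc_family_genera.get(family, set())
        lit_g = lit_genera_by_family.get(family, set())
        if not exc_g:
            continue
        pct = genera_overlap_by_family(family, len(exc_g), len(exc_g & lit_g))
        overlap_rows.append(
            [family, len(exc_g), len(lit_g), len(exc_g & lit_g), pct.percent]
        )
    _write_csv(
        out / "table3_family_overlap.csv",
        ["family", "exc_genera", "lit_genera", "n_common", "percent_in_literature"],
        overlap_rows,
    )

    # tree fractions
    tree_rows = []
    if config.tree_counts:
        for row in read_tree_counts(config.tree_counts):
            pct = percent_trees(row)
            tree_rows.append(
                [row.genus, row.gts_trees,
                 (row.wfo_accepted or 0) + (row.wfo_unchecked or 0),
                 pct.percent if pct else "", "" if pct else "no accepted/unchecked count"]
            )
    _write_csv(
        out / "table4_percent_trees.csv",
        ["genus", "gts_trees", "wfo_accepted_plus_unchecked", "percent_trees", "flag"],
        tree_rows,
    )

    # single-species article share
    family_count_map = {c.taxon: c.n_articles for c in family_counts}
    species_counts = count_species_articles(
        kept_records, [r.species for r in exceptional]
    )
    share_rows = []
    for rec in exceptional:
        n = species_counts[rec.species]
        fam_n = family_count_map.get(rec.family, 0)
        if n >= config.species_share_min_articles and fam_n > 0:
            share_rows.append(
                [rec.species, n, rec.family, exc_family_species[rec.family],
                 fam_n, species_share(n, fam_n).percent]
            )
    share_rows.sort(key=lambda r: (-r[1], r[0]))
    _write_csv(
        out / "table5_species_share.csv",
        ["species", "n_articles", "family", "n_exceptional_in_family",
         "family_articles", "percent_of_family_articles"],
        share_rows,
    )

    # EF breakdown of zero-literature families
    zero_lit = zero_literature_families(
        family_count_map, exceptional, config.min_species_zero_lit
    )
    ef_rows, ef_totals, ef_percents = (
        ef_breakdown(zero_lit, exceptional) if zero_lit else ([], None, None)
    )
    table6 = [[r.family, r.total, r.ef1, r.ef2, r.ef3, r.ef4] for r in ef_rows]
    if ef_totals:
        table6.append(["TOTAL", ef_totals.total, *ef_totals.ef_counts()])
        table6.append(["PERCENT", "", *ef_percents])
    _write_csv(
        out / "table6_ef_breakdown.csv",
        ["family", "total", "ef1", "ef2", "ef3", "ef4"],
        table6,
    )

    # category counts (tissue + non-seed), mirroring the bar-chart shapes
    tissue_population = [
        labels
        for aid, labels in tissue_labels.items()
        if not (
            config.nonseed_excluded_from_tissue
            and aid in screening.nonseed_assignments
        )
    ]
    cat_rows = [
        ["tissue", cat,
         sum(1 for labels in tissue_population if cat in labels.labels)]
        for cat in TISSUE_CATEGORIES
    ]
    nonseed_tally: dict[str, int] = {}
    for cat in screening.nonseed_assignments.values():
        nonseed_tally[cat] = nonseed_tally.get(cat, 0) + 1
    cat_rows += [
        ["nonseed", cat, n] for cat, n in sorted(nonseed_tally.items())
    ]
    _write_csv(out / "category_counts.csv", ["group", "category", "count"], cat_rows)

    # --- manifest
    inputs = {
        str(p): _digest(p)
        for p in [*config.article_exports, config.backbone]
        + [p for p in (config.exceptional_list, config.lexicon,
                       config.excluded_names, config.tree_counts) if p]
    }
    n_genus_matched = sum(1 for m in match_results if m.matched_genera)
    n_family_after = sum(1 for m in match_results if m.matched_families)
    manifest = RunManifest(
        input_digests=inputs,
        config={
            k: (list(v) if isinstance(v, (list, tuple)) else dict(v) if isinstance(v, Mapping) else v)
            for k, v in vars(config).items()
        },
        stage_counts={
            "articles_read": len(records),
            "rows_skipped": n_skipped,
            "duplicates_removed": n_dup,
            "articles_deduplicated": len(deduped),
            "articles_kept": len(kept_records),
            "articles_removed_negative": len(screening.removed_negative),
            "articles_with_genus": n_genus_matched,
            "articles_with_family_after_inference": n_family_after,
            "articles_no_genus": match_summary.n_no_genus,
            "articles_no_family_before_inference": match_summary.n_no_family_before_inference,
            "articles_no_family_after_inference": match_summary.n_no_family_after_inference,
        },
        seed=config.seed,
    )
    manifest.check_monotone()
    manifest.write(out / "manifest.json")
    return manifest


def make_figures(out_dir: str | Path, render: bool = False) -> list[Path]:
    """Produce plot-ready per-category count CSVs from a report bundle
    (and PNG bar charts when ``render`` is set and matplotlib is present)."""
    out = Path(out_dir)
    source = out / "category_counts.csv"
    if not source.exists():
        raise ConfigurationError(f"{source} not found; run the pipeline first")
    groups: dict[str, list[tuple[str, int]]] = {}
    with open(source, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            groups.setdefault(row["group"], []).append(
                (row["category"], int(row["count"]))
            )
    written = []
    for group, pairs in groups.items():
        path = out / f"figure_{group}_counts.csv"
        _write_csv(path, ["category", "count"], pairs)
        written.append(path)
        if render:
            try:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt
            except ImportError:
                continue
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.bar([p[0] for p in pairs], [p[1] for p in pairs])
            ax.set_ylabel("articles")
            ax.set_title(f"{group} category counts")
            fig.tight_layout()
            fig.savefig(out / f"figure_{group}_counts.png", dpi=150)
            plt.close(fig)
            written.append(out / f"figure_{group}_counts.png")
    return written
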