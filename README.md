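# cryogap

Align the plant-cryopreservation literature with lists of **exceptional
species** — plants that cannot be conserved in conventional seed banks
because they produce few or no seeds (EF1), desiccation-sensitive
(recalcitrant) seeds (EF2), short-lived seeds (EF3), or deeply dormant seeds
(EF4) — and quantify where cryopreservation research is missing.

The package is for conservation scientists and collection managers who have
(1) a tabular export of article titles/abstracts from a bibliographic
database, (2) a taxonomic backbone of accepted genus and family names, and
(3) an exceptional-species list, and who want reproducible, auditable gap
tables rather than a one-off spreadsheet analysis.

## What it does

**Four-pass prioritized taxon matching.** Titles and abstracts routinely
mention non-target taxa, so names are searched in priority order and the
first pass with a hit resolves the article:

1. scientific genus/family names in the title,
2. common-name aliases in the title,
3. scientific names in the abstract,
4. common-name aliases in the abstract.

Scientific names match case-sensitively as whole words (boundary = any
non-letter); homograph genera spelled like ordinary words (*Aa*, *Cotyledon*,
*Cuba*, *India*, *Ion*, *Medium*) are excluded via an editable sidecar list.
Articles with genera but no family get families through the backbone's
genus→family map.

**Lexicon screening and classification.** Positive keywords
(`cryopreserv*`, `liquid nitrogen`, ...) and negative keywords (`mammal*`,
`sperm`, `review`) screen articles in or out; articles containing `human`
are kept but flagged for manual review, as are articles with no positive
keyword. Kept articles get a non-seed-plant category (algae / fungi /
bryophyte / pteridophyte) and multi-label tissue types (Dormant Bud, Embryo,
In Vitro, Pollen, Seed). Manual curation is modelled as flags plus an
override table, never as silent automation.

**Gap analysis.** Per-taxon article counts and top-N rankings (ties at the
cutoff are expanded, not dropped), literature/exceptional overlap sets,
within-family genus-overlap percentages, the exceptionality-factor
breakdown of families with no literature at all, single-species article
shares, and per-genus tree fractions
(`trees / (accepted + unchecked species)`, round-half-up, values over 100%
allowed). All percentages are integer percents, halves rounded away from
zero.

**Synthetic data with planted truth.** Because real exports are
access-restricted, `cryogap.synthetic_data` generates backbones, lexicons,
exceptional lists and corpora in which every planting is recorded in a
sidecar truth table, so the whole pipeline is testable end to end with
recall/precision measured against known ground truth.

## Worked example

Generate a synthetic study (400 articles, 100 genera in 20 families, 120
exceptional species) and run the full pipeline:

```bash
cryogap simulate --out demo --n-articles 400 --seed 3
cryogap run-all --config demo/config.yaml --out demo/report
```

which prints:

```
pipeline complete: articles_read=400, rows_skipped=0, duplicates_removed=79,
articles_deduplicated=321, articles_kept=270, articles_removed_negative=51,
articles_with_genus=254, articles_with_family_after_inference=269,
articles_no_genus=67, articles_no_family_before_inference=306,
articles_no_family_after_inference=52
```

Reading: of 400 downloaded rows, 79 were repeat IDs, leaving 321 unique
articles; 51 were removed by negative keywords, leaving 270 for analysis;
254 articles matched at least one genus, and after genus→family inference
only 52 articles had no family. `demo/report/` then contains one CSV per
gap table (`taxon_counts.csv`, `overlap.csv`, `table3_family_overlap.csv`,
`table4_percent_trees.csv`, `table5_species_share.csv`,
`table6_ef_breakdown.csv`, `category_counts.csv`), per-article provenance
logs, and `manifest.json` with input digests and every stage count. Reruns
on identical inputs are byte-identical.

The same stages are available as library functions
(`taxonomy_matching.batch_match`, `keyword_classification.screen_articles`,
`gap_analysis.ef_breakdown`, ...) and as individual subcommands
(`match`, `screen`, `classify`, `report`).

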