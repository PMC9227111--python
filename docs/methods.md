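# Methods

## The alignment procedure

The pipeline treats a literature corpus as a bag of (id, title, abstract)
records and asks, for each record, *which taxon is this article about?* and
*is it about plant cryopreservation at all?* — then aggregates the answers
against an exceptional-species list.

### Taxon matching

Simple whole-text search over a full taxonomic backbone produces many false
positives: titles and abstracts mention comparison taxa, host plants, and
place names or ordinary words that are also genus names. Two mechanisms
contain this:

1. **Pass priority.** Names are searched in four passes — scientific names
   in the title, common-name aliases in the title, scientific names in the
   abstract, aliases in the abstract — and the *first* pass that finds
   anything resolves the article. The modelling assumption is that a taxon
   named in the title is the subject; abstract-only mentions are consulted
   only when the title names nothing. The known cost is a miss when a
   target taxon appears only in the abstract of an article whose title
   names a different taxon; the pass exit rule trades that for far fewer
   incidental matches. Any match — genus or family, scientific or common —
   stops later passes; all names found within the winning pass are kept, so
   multi-genus articles are representable.

2. **Homograph exclusion and case sensitivity.** Scientific names match
   case-sensitively as whole words, where a word boundary is any non-letter
   or the string edge (so `Malus-derived` and `Malus'` match, `Malusoid`
   does not). Lowercase collisions (`medium`, `ion` as ordinary words)
   therefore never fire; genuinely capitalized homographs are suppressed by
   an editable exclusion list shipped with six seeds (*Aa*, *Cotyledon*,
   *Cuba*, *India*, *Ion*, *Medium*). Common names match case-insensitively
   and may be multi-word.

Because scientific names are single tokens, whole-word matching is
implemented as an intersection of the text's letter-token set with the name
set; the test suite holds this equal to an independent brute-force
substring-with-boundary scan on randomized titles (10,000 titles in the
acceptance run).

Common-name hits record the alias's genus; families for genus-only articles
are then filled from the backbone's genus→family map and flagged
`family_inferred`, mirroring a workflow in which common names resolve to
scientific names first and families are derived afterwards. Families
matched directly (e.g. a family name in a title) count toward family
tallies even when no genus matched.

Out of scope by design: abbreviation expansion (`M. domestica`), fuzzy or
misspelling-tolerant matching, species-epithet matching, and synonym
resolution beyond genus→family.

### Screening and classification

Keyword matching is lowercase whole-word over the normalized title +
abstract, with an explicit `*` suffix wildcard (`cryopreserv*` covers the
inflection family). An article with a negative-keyword hit is removed
unless a review trigger (default `human`) is present, in which case it is
kept and flagged for manual review; kept articles without any positive
keyword are flagged for spot-checking. `review` as a negative keyword is
title-only by default: primary articles often discuss "an earlier review"
in the abstract, and only a title hit reliably marks the article itself as
a review.

Non-seed classification returns the category (algae, fungi, bryophyte,
pteridophyte) with keyword hits; ties break toward more distinct hits, and
a residual tie picks the alphabetically first category and flags the call.
Tissue classification is multi-label: every category with at least one hit
(Dormant Bud, Embryo, In Vitro, Pollen, Seed) is assigned, and empty label
sets are allowed and reported. Non-seed articles are assigned before tissue
tallying and excluded from tissue counts by default
(`nonseed_excluded_from_tissue`, configurable), since the tissue taxonomy
is defined for seed plants.

Manual curation enters only through flag outputs and an override table
(article_id → keep / remove / labels); the pipeline never silently
automates a human decision.

### Gap analysis

- **Counting.** An article with *k* matched taxa at a level contributes one
  article to each of the *k*. Consequently a family's count is at least the
  maximum count over its genera (asserted in tests).
- **Ranking.** Count descending, then name ascending. If ties straddle the
  top-N cutoff, all tied taxa are included and the expansion is reported
  rather than silently truncated.
- **Rounding.** Every reported percentage is an integer percent rounded
  half-up (half away from zero). This reproduces every published tree
  fraction, species share and EF percent cell tested; the single known
  exception is a published within-family overlap cell printing 52% where
  10/19 = 52.63 rounds to 53% under any standard rule — we report 53 and
  document the discrepancy here rather than special-casing it.
- **EF flags are non-exclusive.** A species can carry several
  exceptionality factors (published per-family tabulations include rows
  whose EF columns sum to more than the species total). Records therefore
  hold a tuple of flags (`EF3;EF4` in CSV); in breakdown tables the total
  column counts species while EF columns count flags.
- **Tree fractions.** `trees / (accepted + unchecked species)`, missing
  counts treated as zero; a zero denominator yields a flagged row instead
  of a number; values above 100% are legitimate (the tree database and the
  backbone circumscribe genera differently). 24 of the 25 published rows
  are computable; the remaining genus lacks both denominator counts.
- **Zero-literature selection.** Families with no matched articles and at
  least two exceptional species (threshold configurable).

## Synthetic data: what it emulates and what it does not

The generator stands in for access-restricted bibliographic exports. It
emulates *token placement*: titles/abstracts are filler-word soups into
which genus names, family names, aliases, and positive/negative/non-seed/
tissue keywords are planted with configured probabilities, and every
planting is recorded in a sidecar truth table. The filler vocabulary is
guaranteed disjoint from names and keywords, and taxon names are
pseudo-Latin syllable constructions checked against a reserved-word
blacklist, so plantings are unambiguous by construction — the generator
self-checks that each article's plantings imply its recorded intent under
the documented matching and screening rules.

Default planting rates emulate the composition of a real screened corpus of
this kind: ~59% of articles name a taxon in the title (4% a family, 55% a
genus), 8% only a common name, 17% only an abstract mention, leaving ~24%
with no identifiable taxon; 18% of raw rows are duplicate IDs (two
overlapping searches); 22% carry negative keywords; and tissue labels are
drawn as 0.73 / 0.11 / 0.09 / 0.04 / 0.02 across In Vitro, Seed, Embryo,
Pollen, Dormant Bud — the dominance of in-vitro work is the signature
feature of this literature. The default EF weights (0.02, 0.70, 0.26, 0.04)
follow the flag profile of zero-literature exceptional families, dominated
by desiccation-sensitive (EF2) species.

What the generator does **not** emulate: linguistic realism (grammar,
abbreviations such as `M. domestica`, OCR noise, mixed encodings beyond
NFC-normalizable forms), correlated mentions (a genus and its family in one
abstract), or adversarial homograph contexts beyond the decoy mechanism.
Perfect recovery on synthetic corpora therefore demonstrates that the
implementation applies its own rules exactly — not that those rules achieve
any particular accuracy on real text, where the iterative scheme is known
to miss abstract-only taxa and manual review remains necessary.

The packaged `exceptional_list_synthetic.csv` is a synthetic 775-species,
111-family stand-in for a published exceptional-species working list. It
embeds the published per-family EF tabulation of the 19 zero-literature
families exactly (152 species, including multi-flag species) and published
species totals for the largest families; epithets and the remaining small
families are generated (163 genera in total, fewer than the real list's
~366 — per-genus analyses on this fixture are structural, not biological).
`scripts/make_exceptional_fixture.py` regenerates it deterministically.

## Numerical and design choices

- **Normalization.** NFC plus whitespace collapsing before any matching;
  exports mix encodings and this is the minimal canonical form.
- **Deduplication** keeps the first occurrence of each ID; the choice is
  observationally irrelevant for counting and is made deterministic.
- **Determinism.** All generators take explicit seeds; pipeline reruns on
  identical inputs are byte-identical (the manifest contains content
  digests, no timestamps).
- **Problem sizes.** The test suite and acceptance script use 1,000-article
  corpora for end-to-end recovery and 10,000 titles for oracle equivalence
  — large enough that every pass, screening branch and label category is
  exercised hundreds of times, while the whole suite runs in seconds.
- **Error policy.** Configuration errors (missing mapped columns, unknown
  lexicon sections) and validation errors (conflicting genus→family
  assignments, unknown EF tokens, partition violations) are raised with row
  context and abort the run; the CLI maps them to exit code 2.

## Known limitations

- Genus/family assignment quality is bounded by the backbone; no synonym
  or authority resolution is attempted.
- The pass-priority scheme undercounts taxa for multi-taxon articles whose
  title names only one of them; the published workflow accepted the same
  bias and it is inherent to the method, not a bug.
- Keyword lexicons are starting points seeded with documented examples;
  real deployments are expected to edit them, and screening quality on real
  corpora depends on that curation.
- Species-level article counts (for share tables) use exact binomial phrase
  search; articles naming a species only by abbreviation or vernacular are
  missed.
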