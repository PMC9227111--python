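"""Synthetic backbones, lexicons, corpora and exceptional lists with known truth.

Real bibliographic exports are access-restricted, so every pipeline stage is
exercised on generated data in which each planting (a genus in a title, an
alias in an abstract, a negative keyword...) is recorded in a sidecar truth
table.  Titles and abstracts are token soups drawn from a filler vocabulary
that is guaranteed disjoint from taxon names, aliases and keywords, so the
intended match pass, screening outcome and tissue labels of every article
are unambiguous and checkable.

Taxon names are pronounceable pseudo-Latin tokens built from syllable
templates with a reserved-word blacklist; homograph decoys (names equal to
ordinary English words) are injected only on request and always registered
in the exclusion list.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .corpus_io import (
    ArticleRecord,
    EF_CATEGORIES,
    ExceptionalSpeciesRecord,
    TaxonBackbone,
)
from .errors import ValidationError
from .gap_analysis import EFBreakdownRow
from .keyword_classification import KeywordLexicon, TISSUE_CATEGORIES

_ONSETS = ["b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t", "v", "z",
           "br", "cr", "dr", "pl", "tr", "st"]
_VOWELS = ["a", "e", "i", "o", "u"]
_CODAS = ["", "n", "r", "s", "x", "l"]
_FAMILY_SUFFIX = "aceae"
_GENUS_SUFFIXES = ["us", "a", "um", "ia", "ora", "ix"]
_EPITHET_SUFFIXES = ["ensis", "ata", "oides", "icum", "ana", "ifolia"]

#: Words that may appear (capitalized) in generated titles/abstracts or as
#: keywords; generated taxon names must never collide with these.
_RESERVED = frozenset(
    """
    cryopreservation cryopreserved cryogenic liquid nitrogen vitrification
    plant seed seeds tissue shoot tip tips in vitro pollen embryo embryos
    dormant bud buds zygotic somatic axes mammal mammalian sperm review human
    algae alga fungi fungus fungal moss mosses fern ferns bryophyte
    pteridophyte protonemata gametophyte gametophytes study studies effect
    effects storage banking conservation protocol protocols recovery survival
    regrowth of the a an and for with using after on from were was during
    long term samples material culture cultures medium media apple coconut
    coffee mango banana potato oak papaya
    """.split()
)

_FILLER = (
    "storage banking conservation protocol recovery survival regrowth "
    "samples material culture during long term effects study"
).split()


def _syllable(rng: random.Random) -> str:
    return rng.choice(_ONSETS) + rng.choice(_VOWELS) + rng.choice(_CODAS)


def _pseudo_word(rng: random.Random, n_syllables: int, suffix: str) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables)) + suffix


def pseudo_latin_names(
    n: int,
    seed: int,
    kind: str = "genus",
    taken: Iterable[str] = (),
) -> list[str]:
    """*n* distinct capitalized pseudo-Latin names; collision-free against
    ``taken`` and the reserved English vocabulary."""
    rng = random.Random(seed)
    suffixes = {
        "genus": _GENUS_SUFFIXES,
        "family": [_FAMILY_SUFFIX],
        "epithet": _EPITHET_SUFFIXES,
    }[kind]
    out: list[str] = []
    used = {t.lower() for t in taken} | _RESERVED
    while len(out) < n:
        word = _pseudo_word(rng, rng.randint(1, 2), rng.choice(suffixes))
        if word.lower() in used:
            continue
        used.add(word.lower())
        out.append(word if kind == "epithet" else word.capitalize())
    return out


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------


def generate_backbone(
    n_families: int,
    genera_per_family: int,
    seed: int,
    decoys: Sequence[str] = (),
    alias_fraction: float = 0.25,
) -> TaxonBackbone:
    """Deterministic synthetic backbone of ``n_families * genera_per_family``
    genera.  ``decoys`` are homograph names (ordinary capitalized words)
    added as genera *and* to the exclusion list; ``alias_fraction`` of the
    genera get a lowercase common-name alias."""
    if n_families <= 0 or genera_per_family <= 0:
        raise ValidationError("backbone sizes must be positive")
    families = pseudo_latin_names(n_families, seed * 7 + 1, "family")
    genera = pseudo_latin_names(
        n_families * genera_per_family, seed * 7 + 2, "genus", taken=families
    )
    genus_to_family = {
        g: families[i // genera_per_family] for i, g in enumerate(genera)
    }
    rng = random.Random(seed * 7 + 3)
    n_alias = int(round(alias_fraction * len(genera)))
    alias_words = pseudo_latin_names(
        n_alias, seed * 7 + 4, "epithet", taken=genera + families
    )
    aliased = rng.sample(sorted(genera), n_alias) if n_alias else []
    common_names = {
        alias_words[i].lower(): (g, genus_to_family[g])
        for i, g in enumerate(aliased)
    }
    excluded = frozenset(decoys)
    for decoy in decoys:
        genus_to_family[decoy] = families[0]
    return TaxonBackbone(
        genera=frozenset(genus_to_family),
        families=frozenset(families),
        genus_to_family=genus_to_family,
        excluded_names=excluded,
        common_names=common_names,
    )


def default_lexicon_for(backbone: TaxonBackbone) -> KeywordLexicon:
    """A compact lexicon whose aliases are the backbone's own."""
    return KeywordLexicon(
        positive=frozenset({"cryopreserv*", "liquid nitrogen", "vitrification",
                            "cryogenic"}),
        negative=frozenset({"mammal*", "sperm", "review"}),
        nonseed={
            "algae": frozenset({"algae", "alga"}),
            "fungi": frozenset({"fungus", "fungi", "fungal"}),
            "bryophyte": frozenset({"moss", "bryophyte*", "protonemata"}),
            "pteridophyte": frozenset({"fern*", "pteridophyte*"}),
        },
        tissue={
            "DormantBud": frozenset({"dormant bud*"}),
            "Embryo": frozenset({"zygotic embryo*", "embryo ax*"}),
            "InVitro": frozenset({"in vitro", "shoot tip*", "somatic embryo*"}),
            "Pollen": frozenset({"pollen"}),
            "Seed": frozenset({"seed", "seeds"}),
        },
        common_names={a: gf[0] for a, gf in backbone.common_names.items()},
        excluded_names=backbone.excluded_names,
    )


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

#: Tissue-keyword phrases planted per category (must hit the default lexicon).
_TISSUE_PHRASES = {
    "DormantBud": "dormant buds",
    "Embryo": "zygotic embryo axes",
    "InVitro": "in vitro shoot tips",
    "Pollen": "pollen",
    "Seed": "seeds",
}

_NONSEED_PHRASES = {
    "algae": "algae",
    "fungi": "fungal",
    "bryophyte": "moss protonemata",
    "pteridophyte": "fern gametophytes",
}


@dataclass(frozen=True)
class CorpusConfig:
    """Planting probabilities for the synthetic corpus.

    Defaults emulate the composition of the real screened corpus: roughly
    three quarters of articles name a taxon (mostly in the title), about a
    fifth of raw downloads are duplicates across the two searches, a quarter
    are off-topic (negative keywords), and tissue labels are dominated by
    in-vitro work (0.73/0.11/0.09/0.04/0.02 across InVitro, Seed, Embryo,
    Pollen, DormantBud).
    """

    p_title_family: float = 0.04
    p_title_genus: float = 0.55
    p_common_name: float = 0.08
    p_abstract_genus: float = 0.15
    p_abstract_common: float = 0.02
    p_negative: float = 0.22
    p_review_trigger: float = 0.03
    p_nonseed: float = 0.05
    p_positive: float = 0.97
    p_distractor_abstract_genus: float = 0.30
    duplicate_rate: float = 0.18
    tissue_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "InVitro": 0.73,
            "Seed": 0.11,
            "Embryo": 0.09,
            "Pollen": 0.04,
            "DormantBud": 0.02,
        }
    )


@dataclass(frozen=True)
class ArticleTruth:
    """Ground truth for one generated article."""

    article_id: str
    title_genera: frozenset[str]
    title_families: frozenset[str]
    abstract_genera: frozenset[str]
    title_aliases: frozenset[str]
    abstract_aliases: frozenset[str]
    negative_planted: bool
    review_trigger_planted: bool
    positive_planted: bool
    nonseed_category: Optional[str]
    tissue_labels: frozenset[str]
    intended_pass: Optional[int]
    intended_screening: str  # kept | removed
    is_duplicate: bool


@dataclass(frozen=True)
class PlantingTruth:
    """Sidecar truth for a generated corpus."""

    articles: tuple[ArticleTruth, ...]
    n_duplicates: int


def _fill(rng: random.Random, n: int) -> str:
    return " ".join(rng.choice(_FILLER) for _ in range(n))


def generate_corpus(
    backbone: TaxonBackbone,
    n_articles: int,
    config: CorpusConfig | None = None,
    seed: int = 0,
) -> tuple[list[ArticleRecord], PlantingTruth]:
    """Generate ``n_articles`` records with fully recorded planted truth.

    Each article draws one taxon-planting scenario (title genus / title
    alias / abstract genus / abstract alias / none) and one screening
    scenario (negative-removed / review-flagged / clean), then assembles the
    title and abstract from filler vocabulary plus the planted tokens.  The
    generator self-checks that the plantings imply the recorded intent under
    the documented matching and screening rules.
    """
    config = config or CorpusConfig()
    rng = random.Random(seed)
    matchable = sorted(backbone.genera - backbone.excluded_names)
    aliases = sorted(backbone.common_names)
    records: list[ArticleRecord] = []
    truths: list[ArticleTruth] = []
    n_duplicates = 0

    for i in range(n_articles):
        if records and rng.random() < config.duplicate_rate:
            j = rng.randrange(len(records))
            dup = records[j]
            records.append(dup)
            truths.append(replace(truths[j], is_duplicate=True))
            n_duplicates += 1
            continue
        article_id = f"SYN:{i:07d}"

        # --- taxon planting scenario
        u = rng.random()
        title_genera: set[str] = set()
        title_families: set[str] = set()
        abstract_genera: set[str] = set()
        title_aliases: set[str] = set()
        abstract_aliases: set[str] = set()
        intended_pass: Optional[int] = None
        families = sorted(backbone.families)
        edges = [config.p_title_family, config.p_title_genus, config.p_common_name,
                 config.p_abstract_genus, config.p_abstract_common]
        cum = [sum(edges[: i + 1]) for i in range(len(edges))]
        if u < cum[0]:
            intended_pass = 1
            title_families.add(rng.choice(families))
        elif u < cum[1]:
            intended_pass = 1
            k = min(rng.choice([1, 1, 1, 2]), len(matchable))
            title_genera.update(rng.sample(matchable, k))
        elif u < cum[2] and aliases:
            intended_pass = 2
            title_aliases.add(rng.choice(aliases))
        elif u < cum[3]:
            intended_pass = 3
            abstract_genera.add(rng.choice(matchable))
        elif u < cum[4] and aliases:
            intended_pass = 4
            abstract_aliases.add(rng.choice(aliases))
        # pass-1 articles may carry an extra abstract genus that must NOT be
        # recorded (priority rule)
        distractor = ""
        if intended_pass == 1 and rng.random() < config.p_distractor_abstract_genus:
            distractor = rng.choice(matchable)

        # --- screening scenario
        v = rng.random()
        negative = v < config.p_negative
        review = negative and rng.random() < (
            config.p_review_trigger / max(config.p_negative, 1e-9)
        )
        positive = rng.random() < config.p_positive
        nonseed = None
        if not negative and rng.random() < config.p_nonseed:
            nonseed = rng.choice(sorted(_NONSEED_PHRASES))

        # --- tissue labels (only meaningful for kept articles)
        labels: set[str] = set()
        w = rng.random()
        acc = 0.0
        for cat in TISSUE_CATEGORIES:
            acc += config.tissue_weights.get(cat, 0.0)
            if w < acc:
                labels.add(cat)
                break

        # --- assemble text
        title_parts = ["Cryopreservation of"] if positive else ["Storage of"]
        title_parts += sorted(title_genera) + sorted(title_families) + sorted(title_aliases)
        title_parts.append(_fill(rng, 2))
        abstract_parts = [_fill(rng, 3)]
        abstract_parts += sorted(abstract_genera) + sorted(abstract_aliases)
        if distractor:
            abstract_parts.append(distractor)
        if positive:
            abstract_parts.append("liquid nitrogen")
        if negative:
            abstract_parts.append("mammalian sperm")
        if review:
            abstract_parts.append("human")
        if nonseed:
            abstract_parts.append(_NONSEED_PHRASES[nonseed])
        for cat in sorted(labels):
            abstract_parts.append(_TISSUE_PHRASES[cat])
        abstract_parts.append(_fill(rng, 3))

        truth = ArticleTruth(
            article_id=article_id,
            title_genera=frozenset(title_genera),
            title_families=frozenset(title_families),
            abstract_genera=frozenset(abstract_genera) | ({distractor} if distractor else set()),
            title_aliases=frozenset(title_aliases),
            abstract_aliases=frozenset(abstract_aliases),
            negative_planted=negative,
            review_trigger_planted=review,
            positive_planted=positive,
            nonseed_category=nonseed,
            tissue_labels=frozenset(labels),
            intended_pass=intended_pass,
            intended_screening="removed" if (negative and not review) else "kept",
            is_duplicate=False,
        )
        _self_check(truth, backbone)
        records.append(
            ArticleRecord(article_id, " ".join(title_parts), " ".join(abstract_parts))
        )
        truths.append(truth)
    return records, PlantingTruth(tuple(truths), n_duplicates)


def _self_check(truth: ArticleTruth, backbone: TaxonBackbone) -> None:
    """Planted tokens must imply the recorded intent under the match rules."""
    if truth.intended_pass == 1 and not (truth.title_genera or truth.title_families):
        raise ValidationError("pass-1 intent requires a planted title name")
    if truth.intended_pass == 2 and (
        truth.title_genera or truth.title_families or not truth.title_aliases
    ):
        raise ValidationError("pass-2 intent requires an alias-only title")
    if truth.intended_pass in (3, 4) and (
        truth.title_genera or truth.title_families or truth.title_aliases
    ):
        raise ValidationError("abstract-pass intent forbids title plantings")
    for alias in truth.title_aliases | truth.abstract_aliases:
        if alias not in backbone.common_names:
            raise ValidationError(f"planted alias {alias!r} missing from backbone")
    for genus in truth.title_genera | truth.abstract_genera:
        if genus not in backbone.genera - backbone.excluded_names:
            raise ValidationError(f"planted genus {genus!r} not matchable")


def truth_intended_genera(truth: ArticleTruth, backbone: TaxonBackbone) -> frozenset[str]:
    """Genus set the matcher is expected to record for this article."""
    if truth.intended_pass in (1, 3):
        return truth.title_genera if truth.intended_pass == 1 else frozenset(
            g for g in truth.abstract_genera
        )
    if truth.intended_pass in (2, 4):
        aliases = truth.title_aliases if truth.intended_pass == 2 else truth.abstract_aliases
        return frozenset(backbone.common_names[a][0] for a in aliases)
    return frozenset()


def truth_intended_families(
    truth: ArticleTruth, backbone: TaxonBackbone
) -> frozenset[str]:
    """Family set expected after matching plus genus-to-family inference."""
    if truth.intended_pass == 1 and truth.title_families:
        return truth.title_families
    genera = truth_intended_genera(truth, backbone)
    return frozenset(backbone.genus_to_family[g] for g in genera)


def write_truth(truth: PlantingTruth, path) -> None:
    """Emit the sidecar truth CSV (one row per generated article)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["article_id", "title_genera", "title_families", "abstract_genera", "title_aliases",
             "abstract_aliases", "negative", "review_trigger", "positive",
             "nonseed_category", "tissue_labels", "intended_pass",
             "intended_screening", "is_duplicate"]
        )
        for t in truth.articles:
            writer.writerow(
                [t.article_id, ";".join(sorted(t.title_genera)),
                 ";".join(sorted(t.title_families)),
                 ";".join(sorted(t.abstract_genera)),
                 ";".join(sorted(t.title_aliases)),
                 ";".join(sorted(t.abstract_aliases)),
                 int(t.negative_planted), int(t.review_trigger_planted),
                 int(t.positive_planted), t.nonseed_category or "",
                 ";".join(sorted(t.tissue_labels)),
                 t.intended_pass if t.intended_pass else "",
                 t.intended_screening, int(t.is_duplicate)]
            )


# ---------------------------------------------------------------------------
# exceptional list
# ---------------------------------------------------------------------------

#: Default EF category weights; the profile mirrors the flag shares observed
#: on published zero-literature families (EF2 desiccation-sensitive dominates).
DEFAULT_EF_WEIGHTS = (0.02, 0.70, 0.26, 0.04)


def generate_exceptional_list(
    backbone: TaxonBackbone,
    n_species: int,
    ef_weights: Sequence[float] = DEFAULT_EF_WEIGHTS,
    seed: int = 0,
) -> tuple[list[ExceptionalSpeciesRecord], dict[str, int]]:
    """Synthetic exceptional-species list drawn from the backbone's genera.

    Returns the records plus a truth dict of realized EF draw counts.
    """
    if len(ef_weights) != 4:
        raise ValidationError("ef_weights must have four entries")
    rng = random.Random(seed)
    genera = sorted(backbone.genera - backbone.excluded_names)
    epithets = pseudo_latin_names(max(n_species, 1), seed * 11 + 5, "epithet",
                                  taken=genera)
    records: list[ExceptionalSpeciesRecord] = []
    draws = {ef: 0 for ef in EF_CATEGORIES}
    for i in range(n_species):
        genus = rng.choice(genera)
        ef = rng.choices(EF_CATEGORIES, weights=ef_weights, k=1)[0]
        draws[ef] += 1
        records.append(
            ExceptionalSpeciesRecord(
                f"{genus} {epithets[i]}",
                backbone.genus_to_family[genus],
                (ef,),
            )
        )
    return records, draws


def species_records_from_ef_rows(
    rows: Sequence[EFBreakdownRow],
    genus_for_family: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> list[ExceptionalSpeciesRecord]:
    """Expand per-family EF tabulation rows into species records that
    reproduce the rows exactly, including non-exclusive EF flags.

    Each family contributes ``total`` species; each EF column's count is met
    by giving that flag to the species with the fewest flags so far (so
    excess flags beyond ``total`` become second flags on some species).
    """
    genus_for_family = genus_for_family or {}
    out: list[ExceptionalSpeciesRecord] = []
    for row in rows:
        if max(row.ef_counts()) > row.total:
            raise ValidationError(
                f"{row.family}: an EF count exceeds the species total"
            )
        if sum(row.ef_counts()) < row.total:
            raise ValidationError(
                f"{row.family}: EF flags cannot cover every species"
            )
        flags: list[set[str]] = [set() for _ in range(row.total)]
        for ef, count in zip(EF_CATEGORIES, row.ef_counts()):
            order = sorted(range(row.total), key=lambda k: (len(flags[k]), k))
            for k in order[:count]:
                flags[k].add(ef)
        genera = list(genus_for_family.get(row.family, []))
        if not genera:
            genera = [row.family.replace("aceae", "us") or "Genus"]
        epithets = pseudo_latin_names(row.total, seed * 13 + 7, "epithet",
                                      taken=genera)
        for k in range(row.total):
            efs = tuple(sorted(flags[k]))
            genus = genera[k % len(genera)]
            out.append(
                ExceptionalSpeciesRecord(f"{genus} {epithets[k]}", row.family, efs)
            )
    return out
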