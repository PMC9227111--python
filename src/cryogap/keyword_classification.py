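"""Keyword screening and multi-label tissue-type classification.

Articles that survive taxonomic matching are screened with curated lexicons:
*positive* keywords signal that an article is about plant cryopreservation
(cryopreserv*, liquid nitrogen, ...), *negative* keywords that it is not
(mammal, sperm, review).  Articles with a negative hit are removed, except
those containing a review trigger (by default the word "human"), which are
kept and flagged for manual review.  Articles with no positive keyword are
kept but flagged for spot-checking.  Kept articles are further assigned a
non-seed-plant category (algae / fungi / bryophyte / pteridophyte) and a
multi-label tissue type (Dormant Bud / Embryo / In Vitro / Pollen / Seed).

All keyword matching is case-insensitive whole-word over the normalized
title + abstract, with an explicit ``*`` suffix wildcard so that stems like
``cryopreserv*`` cover the whole inflection family.  Manual curation steps
are modelled as flags plus an optional override table, never automated away.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

from ._text import compile_phrase, normalize
from .errors import ValidationError

NONSEED_CATEGORIES = ("algae", "fungi", "bryophyte", "pteridophyte")
TISSUE_CATEGORIES = ("DormantBud", "Embryo", "InVitro", "Pollen", "Seed")

#: Negative keywords matched against the title only.  Primary articles often
#: cite "previous reviews" in the abstract; only a title hit is a reliable
#: signal that the article itself is a review.
DEFAULT_TITLE_ONLY_NEGATIVE = frozenset({"review"})


class _Matcher:
    """A compiled keyword set; reports which keywords hit a text."""

    def __init__(self, keywords: Iterable[str]):
        self.keywords = tuple(sorted({k.strip().lower() for k in keywords if k.strip()}))
        self._patterns = [(k, compile_phrase(k)) for k in self.keywords]

    def hits(self, text: str) -> tuple[str, ...]:
        return tuple(k for k, pat in self._patterns if pat.search(text))

    def __contains__(self, keyword: str) -> bool:
        return keyword in self.keywords


@dataclass(frozen=True)
class KeywordLexicon:
    """Curated keyword sets driving screening and classification.

    ``positive`` and ``negative`` must be disjoint.  ``nonseed`` and
    ``tissue`` map category names to their keyword sets.  ``common_names``
    (alias -> genus) and ``excluded_names`` ride along from the lexicon file
    so one file can configure the whole pipeline.
    """

    positive: frozenset[str]
    negative: frozenset[str]
    nonseed: Mapping[str, frozenset[str]]
    tissue: Mapping[str, frozenset[str]]
    review_triggers: frozenset[str] = frozenset({"human"})
    common_names: Mapping[str, str] = field(default_factory=dict)
    excluded_names: frozenset[str] = frozenset()
    title_only_negative: frozenset[str] = DEFAULT_TITLE_ONLY_NEGATIVE

    def __post_init__(self) -> None:
        clash = self.positive & self.negative
        if clash:
            raise ValidationError(
                f"keywords in both positive and negative sections: {sorted(clash)}"
            )
        for name, cats in (("nonseed", self.nonseed), ("tissue", self.tissue)):
            for cat in cats:
                allowed = NONSEED_CATEGORIES if name == "nonseed" else TISSUE_CATEGORIES
                if cat not in allowed:
                    raise ValidationError(f"unknown {name} category {cat!r}")

    # matchers are rebuilt lazily and cached on the instance
    def _matcher(self, key: str, words: Iterable[str]) -> _Matcher:
        cache = self.__dict__.setdefault("_matchers", {})
        if key not in cache:
            cache[key] = _Matcher(words)
        return cache[key]


@dataclass
class ScreeningResult:
    """Partition of screened article ids plus review flags.

    ``kept`` and ``removed_negative`` partition the input ids; the flag lists
    are subsets of ``kept``.  ``removed_trigger_keywords`` records, per
    removed id, the negative keywords that fired.
    """

    kept: list[str]
    removed_negative: list[str]
    flagged_review: list[str]
    flagged_no_positive: list[str]
    nonseed_assignments: dict[str, str]
    removed_trigger_keywords: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def check_partition(self, input_ids: Sequence[str]) -> None:
        kept, removed = set(self.kept), set(self.removed_negative)
        if kept & removed:
            raise ValidationError("article ids in both kept and removed sets")
        if kept | removed != set(input_ids) or len(self.kept) + len(
            self.removed_negative
        ) != len(input_ids):
            raise ValidationError("screening did not partition the input ids")


@dataclass(frozen=True)
class TissueLabels:
    """Multi-label tissue-type assignment for one article."""

    article_id: str
    labels: frozenset[str]

    def __post_init__(self) -> None:
        bad = self.labels - set(TISSUE_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown tissue categories {sorted(bad)}")


class NonseedCall(NamedTuple):
    category: Optional[str]
    tied: bool  # tie on distinct keyword hits -> flag for review


def _article_text(record) -> str:
    return normalize(record.title) + " \n " + normalize(record.abstract)


def screen_articles(records: Sequence, lexicon: KeywordLexicon) -> ScreeningResult:
    """Partition articles into kept / removed using the lexicon.

    A negative keyword (whole-word, case-insensitive, title+abstract — except
    title-only negatives such as "review") removes the article unless a
    review trigger is present, in which case it is kept and flagged.  Kept
    articles without any positive keyword are flagged for spot-checking.
    Non-seed categories are assigned to kept articles.
    """
    neg = lexicon._matcher("negative", lexicon.negative)
    pos = lexicon._matcher("positive", lexicon.positive)
    trig = lexicon._matcher("review", lexicon.review_triggers)

    result = ScreeningResult([], [], [], [], {})
    for rec in records:
        title = normalize(rec.title).lower()
        text = _article_text(rec).lower()
        neg_hits = tuple(
            k
            for k in neg.hits(text)
            if k not in lexicon.title_only_negative or compile_phrase(k).search(title)
        )
        has_trigger = bool(trig.hits(text))
        if neg_hits and not has_trigger:
            result.removed_negative.append(rec.article_id)
            result.removed_trigger_keywords[rec.article_id] = neg_hits
            continue
        result.kept.append(rec.article_id)
        if has_trigger:
            result.flagged_review.append(rec.article_id)
        if not pos.hits(text):
            result.flagged_no_positive.append(rec.article_id)
        call = classify_nonseed(rec, lexicon)
        if call.category is not None:
            result.nonseed_assignments[rec.article_id] = call.category
            if call.tied:
                result.flagged_review.append(rec.article_id)
    result.check_partition([r.article_id for r in records])
    return result


def classify_nonseed(record, lexicon: KeywordLexicon) -> NonseedCall:
    """Assign the non-seed-plant category whose keywords hit the article.

    Ties are broken by the number of distinct keyword hits; a residual tie
    picks the alphabetically first category and marks the call for review.
    """
    text = _article_text(record).lower()
    scores: dict[str, int] = {}
    for cat in NONSEED_CATEGORIES:
        words = lexicon.nonseed.get(cat, frozenset())
        if not words:
            continue
        n = len(lexicon._matcher(f"nonseed:{cat}", words).hits(text))
        if n:
            scores[cat] = n
    if not scores:
        return NonseedCall(None, False)
    best = max(scores.values())
    winners = sorted(c for c, n in scores.items() if n == best)
    return NonseedCall(winners[0], len(winners) > 1)


def classify_tissue(record, lexicon: KeywordLexicon) -> TissueLabels:
    """Multi-label tissue classification: every category with >=1 hit."""
    text = _article_text(record).lower()
    labels = set()
    for cat in TISSUE_CATEGORIES:
        words = lexicon.tissue.get(cat, frozenset())
        if words and lexicon._matcher(f"tissue:{cat}", words).hits(text):
            labels.add(cat)
    return TissueLabels(record.article_id, frozenset(labels))


def apply_overrides(
    screening: ScreeningResult,
    tissue_labels: Mapping[str, TissueLabels],
    overrides: Sequence[tuple[str, str, frozenset[str]]],
) -> tuple[ScreeningResult, dict[str, TissueLabels]]:
    """Apply a manual-review override table (article_id, action, labels).

    Actions: ``keep`` moves an id into the kept set, ``remove`` moves it out,
    ``labels`` replaces the tissue label set.  Overrides model the manual
    curation pass; they are the only way a human decision enters the run.
    """
    labels = dict(tissue_labels)
    kept = dict.fromkeys(screening.kept)
    removed = dict.fromkeys(screening.removed_negative)
    for article_id, action, new_labels in overrides:
        if action == "keep":
            removed.pop(article_id, None)
            kept.setdefault(article_id)
        elif action == "remove":
            kept.pop(article_id, None)
            removed.setdefault(article_id)
        elif action == "labels":
            labels[article_id] = TissueLabels(article_id, frozenset(new_labels))
        else:
            raise ValidationError(f"unknown override action {action!r}")
    out = ScreeningResult(
        list(kept),
        list(removed),
        [i for i in screening.flagged_review if i in kept],
        [i for i in screening.flagged_no_positive if i in kept],
        {i: c for i, c in screening.nonseed_assignments.items() if i in kept},
        screening.removed_trigger_keywords,
    )
    return out, labels
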