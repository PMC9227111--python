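"""Text normalization and tokenization shared by the matching modules.

All matching in this package operates on NFC-normalized text with runs of
whitespace collapsed to single spaces.  A "word" is a maximal run of Unicode
letters; anything that is not a letter (digits, punctuation, hyphens,
apostrophes, string edges) acts as a word boundary.  This makes hyphenated
compounds ("Malus-derived") and possessives ("Malus'") match the bare name,
which is the behaviour whole-word search tools exhibit on bibliographic text.
"""

from __future__ import annotations

import re
import unicodedata

# Maximal runs of letters (unicode-aware; digits and underscore are boundaries).
_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize(text: str | None) -> str:
    """NFC-normalize and collapse whitespace runs; None becomes ''."""
    if text is None:
        return ""
    return _WS_RE.sub(" ", unicodedata.normalize("NFC", str(text))).strip()


def letter_tokens(text: str) -> list[str]:
    """All maximal letter runs in *text*, in order, case preserved."""
    return _WORD_RE.findall(text)


def compile_phrase(phrase: str, *, casefold: bool = True) -> re.Pattern[str]:
    """Compile a (possibly multi-word) phrase into a whole-word regex.

    A trailing ``*`` on a word is a wildcard matching any letter suffix
    ("cryopreserv*" hits cryopreserve/cryopreserved/cryopreservation).
    Words inside a phrase may be separated by any non-letter run, so
    "liquid nitrogen" also matches "liquid-nitrogen".
    """
    parts = []
    for word in phrase.split():
        if word.endswith("*") and len(word) > 1:
            parts.append(re.escape(word[:-1]) + r"[^\W\d_]*")
        else:
            parts.append(re.escape(word) + r"(?![^\W\d_])")
    pattern = r"(?<![^\W\d_])" + r"[\W\d_]+".join(parts)
    flags = re.UNICODE | (re.IGNORECASE if casefold else 0)
    return re.compile(pattern, flags)
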