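"""Paragraph eligibility, rule-based sentence splitting and tokenization.

Full-text articles converted to BioC carry many passage types that are
not running prose (titles, table cells, reference lists ...).  Matching
method queries against those inflates false positives, so passages are
filtered by infon type and by a minimum word count before matching.

Sentence splitting is deliberately naive — a boundary is any period
followed by whitespace — because the downstream matcher operates on
exact character offsets and benefits from a fully predictable rule.
Abbreviations such as "e.g." therefore DO split; this is a documented
property of the rule, not a bug.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .bioc import BiocPassage

logger = logging.getLogger(__name__)

#: Passage infon types excluded from query matching.  The underlying
#: BioC conversions are inconsistent, so the set is configurable.
EXCLUDED_INFON_TYPES = frozenset(
    {"title", "table caption", "table", "ref", "footnote", "front"}
)

#: Minimum whitespace-delimited word count for an eligible paragraph.
MIN_WORDS = 5


@dataclass
class Sentence:
    """One sentence with its exact character offset in the document."""

    text: str
    offset: int
    index: int

    @property
    def end(self) -> int:
        return self.offset + len(self.text)


def eligible_paragraph(
    passage: BiocPassage,
    excluded_types: frozenset[str] | set[str] = EXCLUDED_INFON_TYPES,
    min_words: int = MIN_WORDS,
) -> bool:
    """True iff *passage* should be scanned for method passages.

    A passage is eligible when its infon ``type`` is not in
    *excluded_types* and its text has at least *min_words*
    whitespace-delimited words.  A passage without a ``type`` infon is
    treated as eligible (and logged) rather than silently dropped.
    """
    infon_type = passage.infons.get("type")
    if infon_type is None:
        logger.warning("passage at offset %d has no 'type' infon; treating as eligible",
                       passage.offset)
    elif infon_type in excluded_types:
        return False
    return len(passage.text.split()) >= min_words


def split_sentences(
    text: str,
    base_offset: int = 0,
    strict_space: bool = False,
) -> list[Sentence]:
    """Split *text* on the period-followed-by-whitespace rule.

    Each boundary occurs immediately after a ``.`` that is followed by
    whitespace (or, with ``strict_space=True``, by a literal space).
    The whitespace run after the boundary is treated as inter-sentence
    separator: it belongs to no sentence, and the next sentence's offset
    points at its first non-separator character.  Offsets are document
    coordinates (``base_offset`` + position within *text*).
    """
    sentences: list[Sentence] = []
    n = len(text)
    is_sep = (lambda c: c == " ") if strict_space else str.isspace
    start = 0
    # skip leading separators so offsets point at real text
    while start < n and text[start].isspace():
        start += 1
    i = start
    while i < n:
        if text[i] == "." and i + 1 < n and is_sep(text[i + 1]):
            sentences.append(
                Sentence(text=text[start : i + 1], offset=base_offset + start,
                         index=len(sentences))
            )
            start = i + 1
            while start < n and text[start].isspace():
                start += 1
            i = start
        else:
            i += 1
    if start < n:
        tail = text[start:]
        if tail.strip():
            sentences.append(
                Sentence(text=tail, offset=base_offset + start, index=len(sentences))
            )
    return sentences


# Characters kept inside tokens: letters, digits and the hyphen.
# Everything else (punctuation, braces, parentheses, brackets, ...) is
# removed by replacement with a space.
_NON_TOKEN_CHARS = re.compile(r"[^a-z0-9À-ɏ-]+")
_NUMERIC_TOKEN = re.compile(r"[0-9]+(?:-[0-9]+)*")


def tokenize(sentence_text: str) -> list[str]:
    """Lowercase and tokenize, dropping punctuation and numeric tokens.

    Intra-word hyphens are preserved so query terms such as
    ``pull-down`` and ``two-hybrid`` stay matchable; tokens that are
    purely digits (including float fragments like ``4.56`` → ``4 56``)
    are removed, while alphanumerics such as ``y2h`` are kept.
    Idempotent on its own (space-joined) output.
    """
    lowered = sentence_text.lower()
    cleaned = _NON_TOKEN_CHARS.sub(" ", lowered)
    tokens = []
    for raw in cleaned.split():
        token = raw.strip("-")
        if not token:
            continue
        if _NUMERIC_TOKEN.fullmatch(token):
            continue
        tokens.append(token)
    return tokens
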