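"""Input cleaning, knowledge-based completion/pruning, and hint parsing.

Free-text addresses arrive with arbitrary casing, stray punctuation, and
regional elements the gazetteer does not use (e.g. county names).  Cleaning
keeps only characters common in address strings (letters, digits, space,
``-``, ``/``, ``,``).  Completion uses region-subsumption knowledge learned
from the gazetteer: when a dependent locality appears without its post town,
the post town is inserted after it, which lets the tree search descend on
information the writer left implicit.  Pruning removes configured region
words (counties etc.) that never occur in the gazetteer.

Hint parsing extracts the pieces of structure that blocking relies on: the
last UK-format postcode in the text, and the longest known post-town and
thoroughfare values occurring verbatim.  Hints are never guessed — an absent
hint stays unset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import EmptyInputError
from .gazetteer import SubsumptionMap

__all__ = ["InputAddress", "clean", "complete_or_prune", "parse_hints",
           "DEFAULT_REMOVAL_TERMS", "POSTCODE_RE"]

#: Region words removed when absent from the gazetteer's region fields.
DEFAULT_REMOVAL_TERMS: tuple[str, ...] = (
    "FIFE", "TAYSIDE", "ANGUS", "SCOTLAND", "PERTHSHIRE", "KINROSS-SHIRE",
    "CLACKMANNANSHIRE", "LOTHIAN", "MIDLOTHIAN",
)

#: UK postcode: 1–2 letters, 1–2 digits (optional trailing letter), optional
#: space, then digit + two letters.  Matched case-insensitively on cleaned
#: (upper-case) text; normalised to "OUTCODE INCODE".
POSTCODE_RE = re.compile(
    r"(?<![A-Z0-9])([A-Z]{1,2}[0-9][0-9A-Z]?)\s?([0-9][A-Z]{2})(?![A-Z0-9])"
)

_DISALLOWED = re.compile(r"[^A-Z0-9 ,/-]+")
_MULTISPACE = re.compile(r"\s+")


@dataclass
class InputAddress:
    """A free-text input: raw text, cleaned text and parsed structural hints."""

    raw: str
    cleaned: str
    postcode: str | None = None
    post_town: str | None = None
    thoroughfare: str | None = None
    input_id: str = ""


def _tidy(text: str) -> str:
    """Collapse whitespace and drop empty comma-separated segments."""
    text = _MULTISPACE.sub(" ", text).strip()
    return ", ".join(s for seg in text.split(",") if (s := seg.strip()))


def clean(raw: str) -> str:
    """Upper-case and strip characters uncommon in address strings.

    Disallowed characters become spaces, runs of whitespace collapse to one
    space, and stray commas are tidied.  Raises :class:`EmptyInputError` when
    nothing survives.
    """
    text = _DISALLOWED.sub(" ", (raw or "").upper())
    text = _tidy(text)
    if not text:
        raise EmptyInputError("input address is empty after cleaning")
    return text


def _word_bounded(term: str) -> re.Pattern:
    return re.compile(r"(?<![A-Z0-9])" + re.escape(term) + r"(?![A-Z0-9])")


def complete_or_prune(
    cleaned: str,
    smap: SubsumptionMap,
    removal_terms: Iterable[str] = DEFAULT_REMOVAL_TERMS,
) -> str:
    """Insert missing parent regions; delete region words unknown to the gazetteer.

    Idempotent: a second application is a no-op.
    """
    text = cleaned
    # prune: configured terms that never occur as gazetteer region values
    for term in removal_terms:
        if term in smap.known_regions:
            continue
        text = _word_bounded(term).sub("", text)
    text = _tidy(text)
    # complete: child region present without its parent → append parent after it
    for _ in range(len(smap.parent) + 1):
        changed = False
        for child in sorted(smap.parent, key=lambda c: (-len(c), c)):
            parent = smap.parent[child]
            m = _word_bounded(child).search(text)
            if m and not _word_bounded(parent).search(text):
                text = text[: m.end()] + ", " + parent + text[m.end():]
                changed = True
        if not changed:
            break
    return _tidy(text)


def parse_hints(
    cleaned: str,
    known_towns: Sequence[str] = (),
    known_thoroughfares: Sequence[str] = (),
    input_id: str = "",
    raw: str | None = None,
) -> InputAddress:
    """Extract postcode / post-town / thoroughfare hints from cleaned text.

    The postcode is the *last* match of the UK pattern, normalised to a
    single internal space.  Town and thoroughfare are the longest known
    values occurring word-bounded in the text (ties alphabetical).
    """
    addr = InputAddress(raw=cleaned if raw is None else raw, cleaned=cleaned, input_id=input_id)
    matches = list(POSTCODE_RE.finditer(cleaned))
    if matches:
        addr.postcode = f"{matches[-1].group(1)} {matches[-1].group(2)}"

    def _longest(values: Sequence[str]) -> str | None:
        best = None
        for v in sorted(set(values), key=lambda v: (-len(v), v)):
            if v and _word_bounded(v).search(cleaned):
                best = v
                break
        return best

    addr.post_town = _longest(known_towns)
    addr.thoroughfare = _longest(known_thoroughfares)
    return addr
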