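"""Fuzzy alignment of a gazetteer field string inside a free-text address.

The matcher needs to locate the best occurrence of each structured field
value (e.g. a thoroughfare name) inside a semi-structured input string that
may contain typographical errors, concatenated words and unrelated flanking
text.  Two global-alignment passes are run for every (input, field) pair:

* **token-based** — both strings are tokenised on non-word characters and the
  token sequences are aligned with Needleman–Wunsch, where two tokens count
  as equal when their Damerau–Levenshtein distance, normalised by the longer
  token, is at most 0.2 (less than one error in five letters);
* **string-based** — the raw character sequences are aligned with
  Needleman–Wunsch, and afterwards every field token span whose characters
  are matched at under 80% coverage is discarded.  This pass is what rescues
  concatenations such as ``GREENBANK`` vs ``GREEN BANK``.

Each pass yields alignment-quality metrics: the fraction of input characters
aligned ``pct_input``, the fraction of field characters aligned
``pct_field``, their harmonic mean ``M``, the number of gap openings inside
the aligned region ``I``, and the character-frequency cosine similarity
``F`` between the field and the aligned input text.  A summary score

    S = M - 0.01 * I + 0.1 * F

ranks the two passes and the higher-scoring alignment is kept.

Redacted input positions (consumed by an earlier field during tree search)
are represented by the NUL character, which never matches and is not a word
character, so redacted text is invisible to both passes while character
coordinates keep referring to the original input.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

__all__ = [
    "FieldAlignment",
    "dl_distance",
    "tokens_equal",
    "nw_align",
    "token_align",
    "string_align",
    "char_cos",
    "summary_score",
    "align_field",
    "redact",
]

#: Maximum normalised DL-distance for two tokens to be considered equal.
TOKEN_DL_THRESHOLD = 0.2
#: Minimum fraction of a field token span that must be character-aligned for
#: the string-based pass to keep that span.
SPAN_KEEP_FRACTION = 0.8
#: Weights of the summary score S = M - 0.01*I + 0.1*F.
INSERTION_WEIGHT = 0.01
CHARCOS_WEIGHT = 0.1

#: NW scoring: simplest scheme, deterministic diagonal-first traceback.
NW_MATCH = 1
NW_MISMATCH = -1
NW_GAP = -1

#: Character masking a redacted input position; non-word, never equal to data.
REDACTED = "\x00"

_WORD_RE = re.compile(r"[A-Za-z0-9]+")
_COUNTED = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789")


# ---------------------------------------------------------------------------
# Edit distance


def dl_distance(a: str, b: str) -> int:
    """Unrestricted Damerau–Levenshtein distance between ``a`` and ``b``.

    Minimum number of character insertions, deletions, substitutions and
    adjacent transpositions turning one string into the other
    (Lowrance–Wagner dynamic programme).  Unlike the restricted/OSA variant
    this is a true metric and satisfies the triangle inequality.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    big = la + lb
    # d is offset by one extra row/column of sentinels (index 0 holds `big`).
    d = [[big] * (lb + 2) for _ in range(la + 2)]
    for i in range(la + 1):
        d[i + 1][1] = i
    for j in range(lb + 1):
        d[1][j + 1] = j
    last_row: dict[str, int] = {}
    for i in range(1, la + 1):
        last_col = 0
        for j in range(1, lb + 1):
            k = last_row.get(b[j - 1], 0)
            l = last_col
            if a[i - 1] == b[j - 1]:
                cost = 0
                last_col = j
            else:
                cost = 1
            d[i + 1][j + 1] = min(
                d[i][j] + cost,          # substitute / match
                d[i + 1][j] + 1,         # insert
                d[i][j + 1] + 1,         # delete
                d[k][l] + (i - k - 1) + 1 + (j - l - 1),  # transpose block
            )
        last_row[a[i - 1]] = i
    return d[la + 1][lb + 1]


@lru_cache(maxsize=1 << 17)
def _dl_cached(a: str, b: str) -> int:
    return dl_distance(a, b)


def tokens_equal(a: str, b: str) -> bool:
    """Fuzzy token equality: normalised DL-distance at most 0.2.

    The denominator is the longer token length, so the rule reads "less than
    one error in five letters" symmetrically.
    """
    if a == b:
        return True
    if a > b:  # canonical order doubles the cache hit rate
        a, b = b, a
    return _dl_cached(a, b) <= TOKEN_DL_THRESHOLD * max(len(a), len(b)) + 1e-9


# ---------------------------------------------------------------------------
# Needleman–Wunsch


def nw_align(
    seq_a: Sequence,
    seq_b: Sequence,
    equal: Callable | None = None,
    match: int = NW_MATCH,
    mismatch: int = NW_MISMATCH,
    gap: int = NW_GAP,
) -> tuple[int, list[tuple[int | None, int | None]]]:
    """Global alignment of two symbol sequences.

    Returns ``(score, columns)`` where each column is a pair of indices into
    ``seq_a`` and ``seq_b``; ``None`` marks a gap on that side.  Ties in the
    traceback prefer the diagonal (match/mismatch), then a gap in ``seq_b``,
    making the alignment deterministic.
    """
    if equal is None:
        equal = lambda x, y: x == y  # noqa: E731
    n, m = len(seq_a), len(seq_b)
    eq = [[bool(equal(seq_a[i], seq_b[j])) for j in range(m)] for i in range(n)]
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        row, prev, eqi = score[i], score[i - 1], eq[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if eqi[j - 1] else mismatch)
            up = prev[j] + gap
            left = row[j - 1] + gap
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            row[j] = best
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            match if eq[i - 1][j - 1] else mismatch
        ):
            cols.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif i > 0 and score[i][j] == score[i - 1][j] + gap:
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    cols.reverse()
    return score[n][m], cols


# ---------------------------------------------------------------------------
# Metrics


def char_cos(a: str, b: str) -> float:
    """Cosine similarity of character-count vectors over A–Z and 0–9."""
    ca = Counter(ch for ch in a.upper() if ch in _COUNTED)
    cb = Counter(ch for ch in b.upper() if ch in _COUNTED)
    if not ca or not cb:
        return 0.0
    dot = sum(v * cb[k] for k, v in ca.items())
    norm = math.sqrt(sum(v * v for v in ca.values())) * math.sqrt(
        sum(v * v for v in cb.values())
    )
    return dot / norm


def summary_score(m: float, insertions: int, f: float) -> float:
    """S = M - 0.01*I + 0.1*F."""
    return m - INSERTION_WEIGHT * insertions + CHARCOS_WEIGHT * f


def _harmonic(p: float, q: float) -> float:
    return 0.0 if p + q == 0 else 2.0 * p * q / (p + q)


@dataclass(frozen=True)
class FieldAlignment:
    """Result of aligning one gazetteer field value inside an input string.

    Character spans are half-open ``[start, end)`` intervals in the original
    coordinates of the (possibly redacted) input / field strings.
    """

    field_name: str
    method: str  # "token" | "string" | "none"
    input_spans: tuple[tuple[int, int], ...]
    field_spans: tuple[tuple[int, int], ...]
    pct_input: float
    pct_field: float
    harmonic_mean: float
    insertions: int
    char_cos: float
    score: float

    @classmethod
    def zero(cls, field_name: str, method: str = "none") -> "FieldAlignment":
        return cls(field_name, method, (), (), 0.0, 0.0, 0.0, 0, 0.0, 0.0)


def _tokens(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(), m.start(), m.end()) for m in _WORD_RE.finditer(text)]


def _gap_openings(
    cols: list[tuple[int | None, int | None]], matched_pos: list[int]
) -> int:
    """Count maximal runs of gap columns strictly inside the matched region."""
    if len(matched_pos) < 2:
        return 0
    lo, hi = matched_pos[0], matched_pos[-1]
    openings = 0
    in_gap = False
    for idx in range(lo + 1, hi):
        is_gap = cols[idx][0] is None or cols[idx][1] is None
        if is_gap and not in_gap:
            openings += 1
        in_gap = is_gap
    return openings


def _merge_spans(positions: list[int]) -> tuple[tuple[int, int], ...]:
    if not positions:
        return ()
    spans = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
            continue
        spans.append((start, prev + 1))
        start = prev = p
    spans.append((start, prev + 1))
    return tuple(spans)


def token_align(input_text: str, field_text: str, field_name: str = "") -> FieldAlignment:
    """Token-level alignment: NW over token sequences with DL-fuzzy equality."""
    itoks = _tokens(input_text)
    ftoks = _tokens(field_text)
    if not itoks or not ftoks:
        return FieldAlignment.zero(field_name, "token")
    total_in = sum(len(t) for t, _, _ in itoks)
    total_f = sum(len(t) for t, _, _ in ftoks)
    _, cols = nw_align([t for t, _, _ in itoks], [t for t, _, _ in ftoks], equal=tokens_equal)
    matched_pos = [
        idx
        for idx, (i, j) in enumerate(cols)
        if i is not None and j is not None and tokens_equal(itoks[i][0], ftoks[j][0])
    ]
    in_spans = tuple((itoks[cols[p][0]][1], itoks[cols[p][0]][2]) for p in matched_pos)
    f_spans = tuple((ftoks[cols[p][1]][1], ftoks[cols[p][1]][2]) for p in matched_pos)
    pct_in = sum(e - s for s, e in in_spans) / total_in
    pct_f = sum(e - s for s, e in f_spans) / total_f
    insertions = _gap_openings(cols, matched_pos)
    aligned_text = " ".join(itoks[cols[p][0]][0] for p in matched_pos)
    f_cos = char_cos(aligned_text, field_text)
    m = _harmonic(pct_in, pct_f)
    return FieldAlignment(
        field_name, "token", in_spans, f_spans, pct_in, pct_f, m, insertions,
        f_cos, summary_score(m, insertions, f_cos),
    )


def string_align(input_text: str, field_text: str, field_name: str = "") -> FieldAlignment:
    """Character-level alignment with the 80% field-token-span retention rule."""
    itoks = _tokens(input_text)
    ftoks = _tokens(field_text)
    if not itoks or not ftoks:
        return FieldAlignment.zero(field_name, "string")
    total_in = sum(len(t) for t, _, _ in itoks)
    total_f = sum(len(t) for t, _, _ in ftoks)
    _, cols = nw_align(input_text, field_text)
    # matched word-character columns, keyed by field position
    matched = {
        j: i
        for i, j in cols
        if i is not None and j is not None
        and input_text[i] == field_text[j]
        and field_text[j].isalnum()
    }
    keep: set[int] = set()
    for _, s, e in ftoks:
        hit = [j for j in range(s, e) if j in matched]
        if len(hit) + 1e-9 >= SPAN_KEEP_FRACTION * (e - s):
            keep.update(hit)
    matched_pos = [
        idx
        for idx, (i, j) in enumerate(cols)
        if i is not None and j is not None and j in keep and matched.get(j) == i
    ]
    in_positions = sorted(matched[j] for j in keep)
    in_spans = _merge_spans(in_positions)
    f_spans = _merge_spans(sorted(keep))
    pct_in = len(keep) / total_in
    pct_f = len(keep) / total_f
    insertions = _gap_openings(cols, matched_pos)
    aligned_text = "".join(input_text[i] for i in in_positions)
    f_cos = char_cos(aligned_text, field_text)
    m = _harmonic(pct_in, pct_f)
    return FieldAlignment(
        field_name, "string", in_spans, f_spans, pct_in, pct_f, m, insertions,
        f_cos, summary_score(m, insertions, f_cos),
    )


@lru_cache(maxsize=100_000)
def _align_field_cached(input_text: str, field_text: str, field_name: str) -> FieldAlignment:
    tok = token_align(input_text, field_text, field_name)
    chs = string_align(input_text, field_text, field_name)
    return tok if tok.score >= chs.score else chs


def align_field(input_text: str, field_text: str, field_name: str = "") -> FieldAlignment:
    """Align ``field_text`` inside ``input_text``; keep the higher-scoring pass.

    Ties go to the token-based result.  An empty field (or one without word
    characters) yields a zero-metric alignment.
    """
    if not field_text or not _WORD_RE.search(field_text):
        return FieldAlignment.zero(field_name)
    return _align_field_cached(input_text, field_text, field_name)


def redact(text: str, spans: tuple[tuple[int, int], ...]) -> str:
    """Mask the given half-open character spans with the redaction sentinel."""
    if not spans:
        return text
    chars = list(text)
    for s, e in spans:
        for k in range(s, e):
            chars[k] = REDACTED
    return "".join(chars)
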