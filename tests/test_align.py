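"""Unit and property tests for the dual fuzzy-alignment engine."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from addrlink.align import (FieldAlignment, align_field, char_cos, dl_distance,
                            nw_align, string_align, summary_score, token_align,
                            tokens_equal)

from .oracles import dl_oracle, nw_score_oracle

UPPER = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


# ---------------------------------------------------------------------------
# Damerau–Levenshtein distance


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("GREENBNAK", "GREENBANK", 1),   # adjacent transposition
        ("A", "A", 0),
        ("ST", "STREET", 4),             # four insertions
        ("", "ABC", 3),
        ("CA", "ABC", 2),                # needs the unrestricted variant
        ("KITTEN", "SITTING", 3),
    ],
)
def test_dl_distance_examples(a, b, expected):
    assert dl_distance(a, b) == expected
    assert dl_distance(b, a) == expected


def test_dl_distance_matches_bruteforce_oracle():
    rng = random.Random(42)
    for _ in range(300):
        a = "".join(rng.choice("ABCDE") for _ in range(rng.randint(0, 10)))
        b = "".join(rng.choice("ABCDE") for _ in range(rng.randint(0, 10)))
        assert dl_distance(a, b) == dl_oracle(a, b), (a, b)


@given(
    st.text(alphabet="ABC", max_size=6),
    st.text(alphabet="ABC", max_size=6),
    st.text(alphabet="ABC", max_size=6),
)
def test_dl_distance_is_a_metric(a, b, c):
    assert dl_distance(a, b) == dl_distance(b, a)
    assert (dl_distance(a, b) == 0) == (a == b)
    assert dl_distance(a, c) <= dl_distance(a, b) + dl_distance(b, c)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("BRUNSWIK", "BRUNSWICK", True),   # 1/9 <= 0.2
        ("ST", "STREET", False),           # 4/6 > 0.2
        ("ROAD", "ROAD", True),
    ],
)
def test_tokens_equal_threshold(a, b, expected):
    assert tokens_equal(a, b) is expected


# ---------------------------------------------------------------------------
# Needleman–Wunsch


def test_nw_align_identity_and_gap_examples():
    score, cols = nw_align("ABC", "ABC")
    assert score == 3 and all(i is not None and j is not None for i, j in cols)
    score, cols = nw_align("AB", "B")
    assert score == 0  # 1 match, 1 gap
    score, cols = nw_align("GREEN BANK", "GREENBANK")
    matches = sum(
        1 for i, j in cols
        if i is not None and j is not None and "GREEN BANK"[i] == "GREENBANK"[j]
    )
    gaps = sum(1 for i, j in cols if i is None or j is None)
    assert (matches, gaps) == (9, 1)


def test_nw_align_score_matches_enumeration_oracle():
    rng = random.Random(7)
    for _ in range(60):
        a = "".join(rng.choice("ABC") for _ in range(rng.randint(0, 6)))
        b = "".join(rng.choice("ABC") for _ in range(rng.randint(0, 6)))
        score, _ = nw_align(a, b)
        assert score == nw_score_oracle(a, b), (a, b)


# ---------------------------------------------------------------------------
# Metrics


@pytest.mark.parametrize(
    "a, b, expected",
    [("AB", "BA", 1.0), ("AA", "AB", 0.7071), ("ABC", "XYZ", 0.0), ("", "A", 0.0)],
)
def test_char_cos(a, b, expected):
    assert char_cos(a, b) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize(
    "m, i, f, expected", [(1.0, 0, 1.0, 1.1), (0.9, 2, 0.8, 0.96), (0.0, 0, 0.0, 0.0)]
)
def test_summary_score_formula(m, i, f, expected):
    assert summary_score(m, i, f) == pytest.approx(expected, abs=1e-12)


@given(
    st.floats(0, 1), st.floats(0, 1), st.integers(0, 20), st.integers(0, 20),
    st.floats(0, 1), st.floats(0, 1),
)
def test_summary_score_monotone(m1, m2, i1, i2, f1, f2):
    """S increases with M and F, decreases with I."""
    lo_m, hi_m = sorted((m1, m2))
    lo_i, hi_i = sorted((i1, i2))
    lo_f, hi_f = sorted((f1, f2))
    assert summary_score(hi_m, lo_i, hi_f) >= summary_score(lo_m, hi_i, lo_f)


# ---------------------------------------------------------------------------
# Token- and string-based field alignment


def test_token_align_exact_containment():
    fa = token_align("5/1 BRUNSWICK ROAD EDINBURGH", "BRUNSWICK ROAD")
    assert fa.pct_field == 1.0
    assert len(fa.input_spans) == 2


def test_token_align_fuzzy_tokens():
    fa = token_align("5/1 BRUNSWIK ROAD", "BRUNSWICK ROAD")
    assert fa.pct_field == 1.0  # both tokens matched despite the typo


def test_token_align_cannot_split_concatenation():
    fa = token_align("GREENBANK TERRACE", "GREEN BANK TERRACE")
    assert fa.pct_field < 1.0


def test_string_align_rescues_concatenation():
    fa = string_align("GREENBANK TERRACE", "GREEN BANK TERRACE")
    assert fa.pct_field == 1.0
    assert fa.pct_input == 1.0


def test_string_align_discards_low_coverage_span():
    # field token STREET aligns only "ST" (2/6 = 33% < 80%) -> span dropped
    fa = string_align("17 WILSON ST", "WILSON STREET")
    covered = set()
    for s, e in fa.field_spans:
        covered.update(range(s, e))
    street_span = set(range(7, 13))  # "STREET" in "WILSON STREET"
    assert not covered & street_span
    assert fa.pct_field == pytest.approx(6 / 12)


def test_align_field_prefers_string_for_concatenation():
    fa = align_field("GREENBANK TERRACE", "GREEN BANK TERRACE")
    assert fa.method == "string"


def test_align_field_tie_returns_token_result():
    fa = align_field("BRUNSWICK ROAD", "BRUNSWICK ROAD")
    assert fa.method == "token"


def test_align_field_empty_field_is_zero():
    fa = align_field("SOMETHING", "")
    assert fa.score == 0.0 and fa.input_spans == ()


@given(st.lists(st.text(alphabet=UPPER + "0123456789", min_size=1, max_size=8),
                min_size=1, max_size=5))
def test_align_field_self_alignment_is_perfect(tokens):
    x = " ".join(tokens)
    fa = align_field(x, x)
    assert fa.pct_input == fa.pct_field == fa.harmonic_mean == 1.0
    assert fa.char_cos == pytest.approx(1.0)
    assert fa.insertions == 0
    assert fa.score == pytest.approx(1.1)


@given(
    st.text(alphabet=UPPER + " /", min_size=1, max_size=25),
    st.text(alphabet=UPPER + " ", min_size=1, max_size=15),
)
def test_field_alignment_invariants(input_text, field_text):
    """M brackets between min and max of the pcts (and <= 2*min); S follows
    the formula exactly; spans are disjoint and in bounds."""
    fa = align_field(input_text, field_text)
    lo, hi = sorted((fa.pct_input, fa.pct_field))
    assert lo - 1e-12 <= fa.harmonic_mean <= hi + 1e-12
    assert fa.harmonic_mean <= 2 * lo + 1e-12
    if fa.pct_input == 0 or fa.pct_field == 0:
        assert fa.harmonic_mean == 0
    assert fa.score == pytest.approx(
        fa.harmonic_mean - 0.01 * fa.insertions + 0.1 * fa.char_cos, abs=1e-12
    )
    seen = set()
    for s, e in fa.input_spans:
        assert 0 <= s < e <= len(input_text)
        span = set(range(s, e))
        assert not span & seen
        seen |= span


def test_zero_alignment_constructor():
    fa = FieldAlignment.zero("POSTCODE")
    assert fa.score == 0 and fa.harmonic_mean == 0 and fa.field_name == "POSTCODE"
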