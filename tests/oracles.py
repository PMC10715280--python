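"""Independent brute-force oracles for the alignment primitives.

These re-derive expected values by different algorithms than the package
uses: the edit-distance oracle is a top-down search trying *every*
transposition anchor pair (not just the last occurrences the production
dynamic programme relies on), and the alignment-score oracle enumerates all
global alignments recursively.
"""

from functools import lru_cache


def dl_oracle(a: str, b: str) -> int:
    """Unrestricted Damerau–Levenshtein by exhaustive top-down search."""

    @lru_cache(maxsize=None)
    def rec(x: str, y: str) -> int:
        if not x:
            return len(y)
        if not y:
            return len(x)
        best = min(
            rec(x[:-1], y) + 1,
            rec(x, y[:-1]) + 1,
            rec(x[:-1], y[:-1]) + (x[-1] != y[-1]),
        )
        # transpose x[k] <-> x[-1] with deletions/insertions in between:
        # try every anchor pair, not only the nearest occurrences
        for k in range(len(x) - 1):
            if x[k] != y[-1]:
                continue
            for l in range(len(y) - 1):
                if y[l] != x[-1]:
                    continue
                cand = rec(x[:k], y[:l]) + (len(x) - k - 2) + (len(y) - l - 2) + 1
                best = min(best, cand)
        return best

    return rec(a, b)


def nw_score_oracle(a, b, equal=None, match=1, mismatch=-1, gap=-1) -> int:
    """Optimal global-alignment score by enumerating all alignments."""
    if equal is None:
        equal = lambda x, y: x == y  # noqa: E731

    def rec(i: int, j: int) -> int:
        if i == len(a):
            return (len(b) - j) * gap
        if j == len(b):
            return (len(a) - i) * gap
        return max(
            rec(i + 1, j + 1) + (match if equal(a[i], b[j]) else mismatch),
            rec(i + 1, j) + gap,
            rec(i, j + 1) + gap,
        )

    return rec(0, 0)
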