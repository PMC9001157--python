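"""Independent brute-force oracles used across the test suite.

These deliberately avoid dynamic programming: global alignment scores are
obtained by enumerating every possible alignment recursively (linear gap
costs), and local scores by maximising the enumerated global score over all
substring pairs. Exponential, so only usable on tiny sequences — which is
the point: they are independent of the implementation they check.
"""

from __future__ import annotations

import itertools
import math


def enum_global_score(a: str, b: str, match: int, mismatch: int, gap: int) -> int:
    """Best global alignment score by exhaustive enumeration (linear gaps)."""
    if not a and not b:
        return 0
    best = -math.inf
    if a and b:
        s = match if (a[0] == b[0] and a[0] != "N") else mismatch
        best = max(best, s + enum_global_score(a[1:], b[1:], match, mismatch, gap))
    if a:
        best = max(best, gap + enum_global_score(a[1:], b, match, mismatch, gap))
    if b:
        best = max(best, gap + enum_global_score(a, b[1:], match, mismatch, gap))
    return int(best)


def all_seqs(alphabet: str, max_len: int) -> list[str]:
    out = []
    for n in range(1, max_len + 1):
        out.extend("".join(t) for t in itertools.product(alphabet, repeat=n))
    return out


def global_score_table(alphabet: str, max_len: int, match: int, mismatch: int, gap: int):
    """Enumerated global scores for every ordered pair of sequences
    (including the empty sequence) over ``alphabet`` up to ``max_len``."""
    seqs = [""] + all_seqs(alphabet, max_len)
    table = {}
    for i, a in enumerate(seqs):
        for b in seqs[i:]:
            s = enum_global_score(a, b, match, mismatch, gap)
            # enumeration is mirror-symmetric by construction: every
            # alignment of (a, b) maps 1:1 onto one of (b, a)
            table[(a, b)] = s
            table[(b, a)] = s
    return table


def local_score_from_table(a: str, b: str, table) -> int:
    """Local score = best enumerated global score over all substring pairs,
    floored at zero (the empty local alignment)."""
    best = 0
    subs_a = {a[i:j] for i in range(len(a)) for j in range(i + 1, len(a) + 1)}
    subs_b = {b[i:j] for i in range(len(b)) for j in range(i + 1, len(b) + 1)}
    for sa in subs_a:
        for sb in subs_b:
            best = max(best, table[(sa, sb)])
    return best


def hamming_counts(a: str, b: str):
    """Site counts for two equal-length gapped strings, counted by hand-rule:
    skip columns with a gap or N, classify remaining differences."""
    assert len(a) == len(b)
    purines = {"A", "G"}
    pyrimidines = {"C", "T"}
    n_valid = ts = tv = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        n_valid += 1
        if x == y:
            continue
        if {x, y} <= purines or {x, y} <= pyrimidines:
            ts += 1
        else:
            tv += 1
    return n_valid, ts, tv
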