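"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the package's numerical paths: exact integer /
rational arithmetic for binomial and hypergeometric tails, and a plain
exhaustive enumeration for pattern-set selection.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def exact_binom_tail_log10(k: int, n: int, p: Fraction) -> float:
    """-log10 P(X >= k) for X ~ Binomial(n, p), exact rational tail.

    With p = a/b all probability mass terms share the denominator b**n, so
    tail and head numerators are exact integer sums.  For P < 1/2 the log of
    the tail numerator is well conditioned; for P >= 1/2 the complement is
    tiny and -log(P) = -log1p(-head/b**n) avoids catastrophic cancellation.
    """
    if k <= 0:
        return 0.0
    a, b = p.numerator, p.denominator
    num = sum(
        math.comb(n, i) * a**i * (b - a) ** (n - i) for i in range(k, n + 1)
    )
    if num == 0:
        return math.inf
    total = b**n
    if 2 * num < total:
        return -(math.log(num) - n * math.log(b)) / math.log(10)
    head = float(Fraction(total - num, total))
    return -math.log1p(-head) / math.log(10)


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided P(X >= a) for the 2x2 table [[a, b], [c, d]], exact.

    X is hypergeometric: draws of size a+c from a population of a+b+c+d with
    a+b successes.
    """
    n_pattern = a + b
    n_draw = a + c
    total = a + b + c + d
    denom = math.comb(total, n_draw)
    num = sum(
        math.comb(n_pattern, k) * math.comb(total - n_pattern, n_draw - k)
        for k in range(a, min(n_pattern, n_draw) + 1)
    )
    return num / denom


def exhaustive_best_pattern(
    fore_freqs: dict[str, float],
    back_freqs: dict[str, float],
    n_fore_total: float,
    p_floor: float,
    max_set_size: int = 3,
    alphabet: str = "ACDEFGHIKLMNPQRSTVWY",
) -> tuple[frozenset[str], float]:
    """Best residue set over ALL subsets of size <= max_set_size.

    Scores via a self-contained float log-space binomial tail (independent of
    the package implementation); same tie-break (score desc, size asc,
    alphabetical).
    """
    best_key = None
    best = None
    n = round(n_fore_total)
    for size in range(1, max_set_size + 1):
        for combo in itertools.combinations(alphabet, size):
            s = frozenset(combo)
            f = sum(fore_freqs.get(r, 0.0) for r in s)
            k = round(f * n_fore_total)
            p = max(sum(back_freqs.get(r, 0.0) for r in s), p_floor)
            score = _float_tail_log10(k, n, p)
            key = (-score, size, "".join(sorted(s)))
            if best_key is None or key < best_key:
                best_key = key
                best = (s, score)
    assert best is not None
    return best


def _float_tail_log10(k: int, n: int, p: float) -> float:
    if k <= 0:
        return 0.0
    if p >= 1.0:
        return 0.0
    if p <= 0.0:
        return math.inf
    logs = [
        math.lgamma(n + 1)
        - math.lgamma(i + 1)
        - math.lgamma(n - i + 1)
        + i * math.log(p)
        + (n - i) * math.log1p(-p)
        for i in range(k, n + 1)
    ]
    m = max(logs)
    return max(0.0, -(m + math.log(sum(math.exp(x - m) for x in logs))) / math.log(10))
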