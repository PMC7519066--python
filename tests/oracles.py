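"""Independent oracles used by the test suite.

These are deliberately naive, straight transcriptions kept separate from
the package implementation: closed-form arithmetic for the yield curves,
a direct dose-weighted sum for mixed fields, and an exhaustive
maximum-cardinality search for break pairing.
"""

from __future__ import annotations

import math
from functools import lru_cache


def eq1_oracle(p1, p2, p3, p4, p5, let):
    value = p1
    if p2 is not None:
        value = value - (p2 * let) ** p3
    if p4 is not None:
        value = value - p4 / (1.0 + math.log(let / p5) ** 2)
    return value


def eq2_oracle(p1, p2, p3, p4, p5, let):
    value = p1 + (p2 * let) ** p3
    if p4 is not None:
        value = value / (1.0 + (p4 * let) ** p5)
    return value


def params_oracle(params, let):
    """Dispatch on the stored form, reading fields directly."""
    if params.form.value == "EQ1_DECREASE":
        return eq1_oracle(params.p1, params.p2, params.p3, params.p4, params.p5, let)
    return eq2_oracle(params.p1, params.p2, params.p3, params.p4, params.p5, let)


def mixed_yield_oracle(yields, doses):
    num = sum(d * y for d, y in zip(doses, yields))
    return num / sum(doses)


def max_pairing_oracle(breaks, dsb_distance):
    """Maximum number of disjoint opposite-strand pairs within the distance.

    Exhaustive branch-and-bound over all pairings; intended for inputs of
    at most ~12 deduplicated breaks.
    """
    items = tuple(sorted({(b.position, b.strand) for b in breaks}))

    @lru_cache(maxsize=None)
    def rec(avail: frozenset) -> int:
        if not avail:
            return 0
        order = sorted(avail)
        i = order[0]
        pi, si = items[i]
        best = rec(avail - {i})  # leave i unpaired
        for j in order[1:]:
            pj, sj = items[j]
            if sj != si and abs(pj - pi) <= dsb_distance:
                best = max(best, 1 + rec(avail - {i, j}))
        return best

    result = rec(frozenset(range(len(items))))
    rec.cache_clear()
    return result
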