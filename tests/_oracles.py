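"""Independent reference computations used to check the implementation."""

import math


def brute_force_fisher(table) -> float:
    """Two-sided Fisher p by full enumeration of the hypergeometric support:
    sum the probabilities of all tables with the observed margins that are no
    more likely than the observed table."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    if min(row1, col1) == 0 or min(c + d, b + d) == 0:
        return 1.0
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {
        x: math.comb(col1, x) * math.comb(n - col1, row1 - x) / math.comb(n, row1)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))
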