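"""Independent brute-force read scorer used as a numerical oracle.

Windows are enumerated with a plain character loop and probabilities are
accumulated as exact rationals; the log is taken once at the end from the
big-integer numerator and denominator, so the only float rounding is in
the final two log calls. Deliberately shares no code with the package's
scoring path.
"""

import math
from fractions import Fraction


def brute_force_score(read, counts, total, n, alpha):
    """Exact-rational log-likelihood of `read` under a count table.

    Returns (log_likelihood or None, n_scored_kmers); -inf when alpha=0
    and any window is unseen.
    """
    read = read.upper()
    alpha = Fraction(alpha)
    denom = Fraction(total) + alpha * 4**n
    product = Fraction(1)
    n_kmers = 0
    unseen_zero = False
    for i in range(len(read) - n + 1):
        window = read[i : i + n]
        ok = True
        for ch in window:
            if ch not in "ACGT":
                ok = False
                break
        if not ok:
            continue
        n_kmers += 1
        numer = Fraction(counts.get(window, 0)) + alpha
        if numer == 0:
            unseen_zero = True
        else:
            product *= numer / denom
    if n_kmers == 0:
        return None, 0
    if unseen_zero:
        return -math.inf, n_kmers
    return math.log(product.numerator) - math.log(product.denominator), n_kmers
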