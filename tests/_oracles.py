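"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is deliberately naive (exhaustive enumeration or full
dynamic programming) and shares no code with the package.
"""

from math import comb

_MATCH, _MISMATCH, _GAP = 1, -1, -1


def n50_brute(lengths):
    """N50 by trying every realized length as the threshold."""
    total = sum(lengths)
    candidates = [
        L for L in set(lengths) if sum(x for x in lengths if x >= L) * 2 >= total
    ]
    return max(candidates)


def identity_brute(a, b):
    """Semi-global identity by full DP over (score, matches) pairs.

    The shorter sequence aligns end-to-end, the longer contributes a
    region (leading/trailing gaps in the longer are free); match +1,
    mismatch -1, gap -1; among equal-score alignments the one with the
    most matches wins; identity = matches / len(shorter).
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    short, long_ = short.upper(), long_.upper()
    m, n = len(short), len(long_)
    # cell = (score, matches), lexicographic max
    prev = [(0, 0)] * (n + 1)
    for i in range(1, m + 1):
        cur = [(0, 0)] * (n + 1)
        cur[0] = (i * _GAP, 0)
        for j in range(1, n + 1):
            is_match = short[i - 1] == long_[j - 1]
            diag_s, diag_m = prev[j - 1]
            diag = (
                diag_s + (_MATCH if is_match else _MISMATCH),
                diag_m + (1 if is_match else 0),
            )
            up = (prev[j][0] + _GAP, prev[j][1])
            left = (cur[j - 1][0] + _GAP, cur[j - 1][1])
            cur[j] = max(diag, up, left)
        prev = cur
    best = max(prev)
    return best[1] / m


def hypergeom_tail_brute(k, n, K, N):
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation."""
    denom = comb(N, n)
    total = 0
    for i in range(k, min(n, K) + 1):
        total += comb(K, i) * comb(N - K, n - i)
    return total / denom


def bh_brute(pvals):
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * n / rank)
        adjusted[i] = running_min
    return adjusted
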