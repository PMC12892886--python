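"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: digestion by regex
split + fragment joining (and full substring enumeration for short inputs),
BH by the literal step-up definition, Grubbs critical values straight from
the t quantile, and restoration by raw set algebra.
"""

import re
from itertools import combinations

import numpy as np
from scipy import stats

TRYPSIN_SPLIT = re.compile(r"(?<=[KR])(?!P)")


def digest_by_regex(sequence, max_missed, min_len, max_len):
    """Join runs of up to max_missed+1 consecutive regex-split fragments."""
    fragments = [f for f in TRYPSIN_SPLIT.split(sequence) if f]
    out = []
    start = 0
    starts = []
    for f in fragments:
        starts.append(start)
        start += len(f)
    for i in range(len(fragments)):
        for m in range(max_missed + 1):
            if i + m >= len(fragments):
                break
            pep = "".join(fragments[i : i + m + 1])
            if min_len <= len(pep) <= max_len:
                out.append((pep, m, starts[i]))
    return sorted(out, key=lambda t: (t[2], len(t[0])))


def digest_by_substrings(sequence, max_missed, min_len, max_len):
    """All substrings, filtered by the cleavage rule. O(n^2); short inputs only."""

    def is_site(k):  # cut between k and k+1
        return sequence[k] in "KR" and (k + 1 >= len(sequence) or sequence[k + 1] != "P")

    n = len(sequence)
    out = []
    for i in range(n):
        if not (i == 0 or is_site(i - 1)):
            continue
        for j in range(i + 1, n + 1):
            if not (j == n or is_site(j - 1)):
                continue
            if not (min_len <= j - i <= max_len):
                continue
            missed = sum(1 for k in range(i, j - 1) if is_site(k))
            if missed <= max_missed:
                out.append((sequence[i:j], missed, i))
    return sorted(out, key=lambda t: (t[2], len(t[0])))


def bh_stepup_literal(p):
    """q_(i) = min_{j>=i} p_(j) * m / j, capped at 1, back to input order.

    Deliberately the literal definition (a min over every j >= i), not the
    reverse-cumulative-minimum trick the implementation uses.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = sorted(range(m), key=lambda i: p[i])
    scaled = np.array([p[order[j]] * m / (j + 1) for j in range(m)])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order):
        q[idx] = min(1.0, float(np.min(scaled[rank_pos:])))
    return q


def grubbs_crit_reference(n, alpha):
    t = stats.t.isf(alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def unrestored_by_set_algebra(dep_mdx_wt_ids, dep_trt_wt_ids, dep_trt_mdx_ids):
    """The two published filter criteria as raw set operations:
    significantly altered treated-vs-WT AND not altered treated-vs-mdx,
    restricted to baseline-dysregulated proteins."""
    return (set(dep_mdx_wt_ids) & set(dep_trt_wt_ids)) - set(dep_trt_mdx_ids)
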