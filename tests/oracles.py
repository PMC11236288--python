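"""Independent brute-force oracles used to freeze expected values.

These implementations deliberately share no code with the package: the
Mann-Whitney p-value is obtained by exhaustively enumerating rank
assignments, the auROC by pair counting, the chi-squared tail for two
p-values in closed form, and the step-up adjustment by its textbook
definition.
"""

import itertools
import math

import numpy as np


def mwu_u_statistic(a, b):
    """U statistic of group a over b by direct pair counting."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mwu_exact_p_greater(a, b):
    """Exact one-sided (greater) p by enumerating all rank assignments."""
    pooled = sorted(list(a) + list(b))
    n1 = len(a)
    u_obs = mwu_u_statistic(a, b)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        grp_a = [pooled[i] for i in comb]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in comb]
        if mwu_u_statistic(grp_a, grp_b) >= u_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def brute_force_auroc(scores, labels):
    """auROC of scores for the positive class by pair counting."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    return mwu_u_statistic(pos, neg) / (len(pos) * len(neg))


def chi2_sf_4df(x):
    """Closed-form chi^2 survival with 4 df: e^{-x/2}(1 + x/2)."""
    return math.exp(-x / 2.0) * (1.0 + x / 2.0)


def bh_stepup(ps, alpha=None):
    """Textbook Benjamini-Hochberg adjusted values (step-up, monotone)."""
    ps = np.asarray(ps, dtype=float)
    m = ps.size
    order = np.argsort(ps, kind="mergesort")
    adjusted = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, ps[idx] * m / rank)
        adjusted[idx] = val
        prev = val
    return adjusted
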