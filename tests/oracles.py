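"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration (exact
rational arithmetic for the tree inducer) and stay independent of the
library code paths they check.
"""

from fractions import Fraction
from itertools import combinations, product

import numpy as np

NEGLECT = "neglect"
NO_NEGLECT = "no_neglect"


def oracle_gini(pos: int, n: int) -> Fraction:
    if n == 0:
        raise ValueError("empty node")
    p = Fraction(pos, n)
    q = 1 - p
    return 1 - p * p - q * q


def oracle_best_split(X, y, feature_names, minbucket):
    """Exhaustively enumerate every (feature, midpoint) candidate.

    Returns (feature_name, threshold) minimizing the weighted child Gini
    impurity, ties broken by (feature name, threshold); None if no candidate
    satisfies the minbucket constraint.
    """
    n = len(y)
    best = None  # (impurity, fname, threshold)
    for j, fname in enumerate(feature_names):
        values = sorted(set(X[:, j]))
        for a, b in zip(values[:-1], values[1:]):
            thr = (a + b) / 2.0
            left = X[:, j] < thr
            nl, nr = int(left.sum()), n - int(left.sum())
            if nl < minbucket or nr < minbucket:
                continue
            pl = int(y[left].sum())
            pr = int(y.sum()) - pl
            imp = Fraction(nl, n) * oracle_gini(pl, nl) + Fraction(nr, n) * oracle_gini(pr, nr)
            key = (imp, fname, thr)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[1], best[2]


def oracle_fit(X, y, feature_names, minsplit, minbucket, cp):
    """Recursive exhaustive-search CART with rpart-style cp gating.

    Returns a nested dict mirroring the library's tree structure.
    """
    root_risk = min(int(y.sum()), len(y) - int(y.sum()))
    min_gain = cp * root_risk

    def majority(pos, n):
        return NEGLECT if pos > n - pos else NO_NEGLECT

    def risk(pos, n):
        return min(pos, n - pos)

    def grow(idx):
        yi = y[idx]
        n, pos = len(yi), int(yi.sum())
        node = {"n": n, "n_neglect": pos, "prediction": majority(pos, n)}
        if n < minsplit or pos in (0, n):
            return node
        found = oracle_best_split(X[idx], yi, feature_names, minbucket)
        if found is None:
            return node
        fname, thr = found
        j = feature_names.index(fname)
        left_mask = X[idx, j] < thr
        li, ri = idx[left_mask], idx[~left_mask]
        gain = (risk(pos, n) - risk(int(y[li].sum()), len(li))
                - risk(int(y[ri].sum()), len(ri)))
        if gain < min_gain or gain <= 0:
            return node
        node.update(feature=fname, threshold=thr, left=grow(li), right=grow(ri))
        return node

    return grow(np.arange(len(y)))


def tree_to_dict(node):
    """Library TreeNode -> plain dict comparable with oracle output."""
    d = {"n": node.n, "n_neglect": node.n_neglect, "prediction": node.prediction}
    if not node.is_leaf:
        d.update(feature=node.feature, threshold=node.threshold,
                 left=tree_to_dict(node.left), right=tree_to_dict(node.right))
    return d


def oracle_signed_rank_p(ranks, signs_observed_wplus, alternative):
    """Exact signed-rank p over all sign assignments of the given ranks."""
    n = len(ranks)
    ge = le = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        ge += w >= signs_observed_wplus - 1e-9
        le += w <= signs_observed_wplus + 1e-9
    total = 2 ** n
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


def oracle_mann_whitney_p(ranks, n1, u_observed, alternative):
    """Exact Mann-Whitney p over all group assignments of the given ranks."""
    ge = le = total = 0
    for picked in combinations(range(len(ranks)), n1):
        u = sum(ranks[i] for i in picked) - n1 * (n1 + 1) / 2.0
        ge += u >= u_observed - 1e-9
        le += u <= u_observed + 1e-9
        total += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)
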