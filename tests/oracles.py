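"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's own computational paths:
dense explicit matrix inverses, exhaustive enumeration, and scipy reference
densities, so that agreement with the implementation is informative.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import multivariate_normal


# -- rooted-topology enumeration -------------------------------------------

def enumerate_rooted_topologies(labels):
    """All labeled rooted binary topologies on the given tips, as nested
    tuples; there are (2n-3)!! of them."""
    labels = list(labels)
    if len(labels) == 1:
        return [labels[0]]
    first, rest = labels[0], labels[1:]
    trees = [first]
    for lab in rest:
        trees = [t for tree in trees for t in _insert_tip(tree, lab)]
    return trees


def _insert_tip(tree, lab):
    """Attach lab on every edge of the rooted tree, including above the root."""
    out = [(tree, lab)]
    if isinstance(tree, tuple):
        left, right = tree
        out.extend((new, right) for new in _insert_tip(left, lab))
        out.extend((left, new) for new in _insert_tip(right, lab))
    return out


def topology_to_newick(topo, rng, min_bl=0.05, max_bl=2.0):
    """Random positive branch lengths on a nested-tuple topology."""

    def fmt(node):
        bl = rng.uniform(min_bl, max_bl)
        if isinstance(node, tuple):
            return f"({fmt(node[0])},{fmt(node[1])}):{bl:.6f}"
        return f"{node}:{bl:.6f}"

    if not isinstance(topo, tuple):
        raise ValueError("need at least 2 tips")
    return f"({fmt(topo[0])},{fmt(topo[1])});"


# -- dense GLS / Gaussian oracles ------------------------------------------

def dense_bm_fit(x, C):
    """(root mean, sigma2_ML, logL) via explicit inverse + scipy density."""
    Ci = np.linalg.inv(C)
    ones = np.ones(len(x))
    a = (ones @ Ci @ x) / (ones @ Ci @ ones)
    r = x - a
    s2 = (r @ Ci @ r) / len(x)
    logL = multivariate_normal.logpdf(x, mean=np.full(len(x), a), cov=s2 * C)
    return a, s2, logL


def dense_gls_beta(X, y, C):
    Ci = np.linalg.inv(C)
    return np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)


def dense_asr(x, C_tips, C_cross, d_nodes):
    """Conditional-mean ancestral states with explicit inverses.

    C_tips: tip covariance; C_cross[u, b]: cov(node u, tip b);
    d_nodes[u]: node depth (its prior variance).  Returns (estimates, variances)
    under the universal-kriging treatment of the unknown root mean.
    """
    Ci = np.linalg.inv(C_tips)
    ones = np.ones(C_tips.shape[0])
    s = ones @ Ci @ ones
    a = (ones @ Ci @ x) / s
    r = x - a
    s2 = (r @ Ci @ r) / len(x)
    est = a + C_cross @ Ci @ r
    var = np.array([
        d_nodes[u] - C_cross[u] @ Ci @ C_cross[u]
        + (1.0 - C_cross[u] @ Ci @ ones) ** 2 / s
        for u in range(C_cross.shape[0])])
    return est, s2 * var, a, s2


# -- distances --------------------------------------------------------------

def brute_force_min_curve(gc, M, bin_width=1.0):
    """All-pairs double loop: per GC-difference band, min Euclidean distance."""
    n = len(gc)
    best: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dgc = abs(gc[i] - gc[j]) * 100.0
            b = int(math.floor(dgc / bin_width))
            d = math.sqrt(float(np.sum((M[i] - M[j]) ** 2)))
            if b not in best or d < best[b]:
                best[b] = d
            counts[b] = counts.get(b, 0) + 1
    return best, counts


def hamming_distance(a, b) -> int:
    return int(np.sum(a != b))


# -- exact rank-sum test ----------------------------------------------------

def exact_ranksum_p(a, b) -> float:
    """Two-sided p by exhaustive enumeration of rank assignments (no ties)."""
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = np.argsort(np.argsort(pooled)) + 1
    na = len(a)
    w_obs = ranks[:na].sum()
    mean_w = na * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        w = ranks[list(combo)].sum()
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
        total += 1
    return count / total


# -- permutation Pearson ----------------------------------------------------

def permutation_pearson_p(x, y, n_perm=10000, seed=0) -> float:
    """Two-sided permutation p-value for a Pearson correlation."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    hits = 0
    for _ in range(n_perm):
        r = abs(np.corrcoef(x, rng.permutation(y))[0, 1])
        if r >= r_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
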