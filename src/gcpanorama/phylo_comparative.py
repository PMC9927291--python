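"""Continuous-trait phylogenetic comparative methods, from scratch.

Implements the Brownian-motion (BM) generalized-least-squares machinery and
the statistics built on it:

* ML fits of Pagel's lambda, kappa and delta branch-length transforms,
* Blomberg's K with a tip-permutation test,
* Felsenstein's phylogenetically independent contrasts (PIC),
* phylogenetic generalized least squares (PGLS) with BM or ML-lambda
  residual structure,
* ancestral state reconstruction (ASR) of a continuous trait under BM.

All estimates use the ML (not REML) likelihood so that likelihood-ratio
tests across nested transforms are coherent.  Linear algebra goes through
Cholesky factorizations; no covariance matrix is ever inverted explicitly.

A trait is any mapping ``tip label -> float`` covering the tips of the tree
it is analysed on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize_scalar

from .tree import (
    PhyloNode,
    PhyloTree,
    midpoint_root,
    parse_newick,
    read_newick,
    to_newick,
    transform_tree_kappa,
    transform_vcv,
    vcv,
    write_newick,
)

__all__ = [
    "BMFit",
    "SignalResult",
    "PGLSFit",
    "AncestralStates",
    "align_trait",
    "bm_fit",
    "fit_lambda",
    "fit_kappa",
    "fit_delta",
    "blomberg_k",
    "pic",
    "pgls",
    "asr_bm",
    # re-exported tree API (this module is the comparative-methods surface)
    "PhyloTree",
    "read_newick",
    "parse_newick",
    "write_newick",
    "to_newick",
    "vcv",
    "midpoint_root",
]

KAPPA_BOUNDS = (1e-6, 3.0)
DELTA_BOUNDS = (1e-6, 3.0)
_N_MULTISTART = 5


# -- results ----------------------------------------------------------------

@dataclass
class BMFit:
    """ML fit of single-rate BM: root mean, rate, and log-likelihood."""

    root_mean: float
    sigma2: float
    log_likelihood: float
    n_tips: int


@dataclass
class SignalResult:
    """A phylogenetic-signal estimate (K, lambda, kappa or delta)."""

    statistic: str
    estimate: float
    p_value: float | None
    log_likelihood: float
    n_tips: int
    null_log_likelihood: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


@dataclass
class PGLSFit:
    """Phylogenetic GLS regression fit."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    sigma2: float
    log_likelihood: float
    r_squared: float
    multiple_r: float
    structure: str
    n_tips: int
    lambda_hat: float | None = None
    fitted: np.ndarray = field(default=None, repr=False)
    residuals: np.ndarray = field(default=None, repr=False)


@dataclass
class AncestralStates:
    """BM ancestral reconstructions: node name -> (estimate, SE)."""

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    sigma2: float
    root_mean: float


# -- GLS core ---------------------------------------------------------------

def align_trait(trait: Mapping[str, float], labels: Sequence[str]) -> np.ndarray:
    missing = [l for l in labels if l not in trait]
    if missing:
        raise KeyError(f"trait missing values for tips: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    x = np.array([float(trait[l]) for l in labels])
    if not np.all(np.isfinite(x)):
        raise ValueError("trait contains non-finite values")
    return x


def _chol(C: np.ndarray):
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "phylogenetic covariance matrix is singular; collapse zero-length "
            "branches or drop duplicated tips"
        ) from exc


def _gls(X: np.ndarray, y: np.ndarray, C: np.ndarray):
    """GLS regression of y on X under covariance sigma2*C (sigma2 profiled).

    Returns (beta, rss, sigma2_ml, logL, XtCiX) where rss is the
    generalized residual sum of squares (y-Xb)' C^-1 (y-Xb).
    """
    n = len(y)
    cf = _chol(C)
    CiX = cho_solve(cf, X)
    Ciy = cho_solve(cf, y)
    XtCiX = X.T @ CiX
    beta = np.linalg.solve(XtCiX, X.T @ Ciy)
    resid = y - X @ beta
    rss = float(resid @ cho_solve(cf, resid))
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    logL = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return beta, rss, sigma2, logL, XtCiX


def bm_fit(trait: Mapping[str, float] | np.ndarray, C: np.ndarray,
           labels: Sequence[str] | None = None) -> BMFit:
    """ML fit of single-rate Brownian motion given a tip covariance matrix.

    The root mean is the GLS mean ``(1'C^-1 1)^-1 1'C^-1 x`` and the rate is
    the ML estimate ``sigma2 = (x - a)' C^-1 (x - a) / n``.
    """
    if isinstance(trait, Mapping):
        if labels is None:
            raise ValueError("labels required when trait is a mapping")
        x = align_trait(trait, labels)
    else:
        x = np.asarray(trait, dtype=float)
    n = len(x)
    ones = np.ones((n, 1))
    beta, _, sigma2, logL, _ = _gls(ones, x, C)
    return BMFit(root_mean=float(beta[0]), sigma2=sigma2,
                 log_likelihood=logL, n_tips=n)


# -- transform-parameter ML fits -------------------------------------------

def _profile_maximize(nll, lo: float, hi: float) -> tuple[float, float]:
    """Maximize -nll over [lo, hi] with bounded Brent from multistart brackets."""
    best_x, best_f = lo, nll(lo)
    f_hi = nll(hi)
    if f_hi < best_f:
        best_x, best_f = hi, f_hi
    edges = np.linspace(lo, hi, _N_MULTISTART + 1)
    for a, b in zip(edges[:-1], edges[1:]):
        res = minimize_scalar(nll, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-8})
        if res.fun < best_f:
            best_x, best_f = float(res.x), float(res.fun)
    return best_x, -best_f


def fit_lambda(trait: Mapping[str, float], tree: PhyloTree,
               C: np.ndarray | None = None) -> SignalResult:
    """ML estimate of Pagel's lambda in [0, 1] with an LRT against lambda=0.

    lambda multiplies the off-diagonal phylogenetic covariances; lambda=0 is
    an iid-normal (star) model, lambda=1 plain BM.  The null lies on the
    boundary, so the likelihood-ratio p-value uses the 0.5*chi2(1) mixture.
    """
    labels = tree.tip_labels
    x = align_trait(trait, labels)
    if len(x) < 4:
        raise ValueError("need at least 4 tips")
    if C is None:
        C = vcv(tree)

    def nll(lam: float) -> float:
        return -bm_fit(x, transform_vcv(C, "lambda", lam)).log_likelihood

    est, logL = _profile_maximize(nll, 0.0, 1.0)
    logL0 = -nll(0.0)
    lr = max(0.0, 2.0 * (logL - logL0))
    p = 1.0 if lr == 0.0 else 0.5 * stats.chi2.sf(lr, df=1)
    return SignalResult("lambda", est, float(p), logL, len(x),
                        null_log_likelihood=logL0)


def fit_kappa(trait: Mapping[str, float], tree: PhyloTree) -> SignalResult:
    """ML estimate of Pagel's kappa (branch lengths raised to a power).

    kappa -> 0 is the punctuational limit (every branch contributes equally);
    kappa = 1 recovers BM.  The p-value is an LRT against kappa = 1.
    """
    labels = tree.tip_labels
    x = align_trait(trait, labels)
    if len(x) < 4:
        raise ValueError("need at least 4 tips")

    def nll(kap: float) -> float:
        return -bm_fit(x, vcv(transform_tree_kappa(tree, kap))).log_likelihood

    est, logL = _profile_maximize(nll, *KAPPA_BOUNDS)
    logL1 = -nll(1.0)
    lr = max(0.0, 2.0 * (logL - logL1))
    p = stats.chi2.sf(lr, df=1)
    return SignalResult("kappa", est, float(p), logL, len(x),
                        null_log_likelihood=logL1)


def fit_delta(trait: Mapping[str, float], tree: PhyloTree,
              C: np.ndarray | None = None) -> SignalResult:
    """ML estimate of Pagel's delta (node depths raised to a power).

    delta < 1 concentrates change near the root (decelerating evolution);
    delta > 1 concentrates it near the tips (accelerating).  The p-value is
    an LRT against delta = 1.  Depths are measured from the root; on a
    strongly non-ultrametric tree this convention matters and a warning is
    issued.
    """
    labels = tree.tip_labels
    x = align_trait(trait, labels)
    if len(x) < 4:
        raise ValueError("need at least 4 tips")
    if not tree.is_ultrametric(rel_tol=1e-2):
        warnings.warn("delta transform on a non-ultrametric tree: node depths "
                      "are measured from the root", stacklevel=2)
    if C is None:
        C = vcv(tree)

    def nll(dlt: float) -> float:
        return -bm_fit(x, transform_vcv(C, "delta", dlt)).log_likelihood

    est, logL = _profile_maximize(nll, *DELTA_BOUNDS)
    logL1 = -nll(1.0)
    lr = max(0.0, 2.0 * (logL - logL1))
    p = stats.chi2.sf(lr, df=1)
    return SignalResult("delta", est, float(p), logL, len(x),
                        null_log_likelihood=logL1)


# -- Blomberg's K -----------------------------------------------------------

def _k_statistic(X: np.ndarray, C: np.ndarray, cf, expected_ratio: float
                 ) -> np.ndarray:
    """K for each row of X (vectorized over permutations)."""
    n = X.shape[1]
    CiX = cho_solve(cf, X.T)  # n x m
    s = float(np.sum(cho_solve(cf, np.ones(n))))
    a = np.sum(CiX, axis=0) / s  # GLS mean per column
    R = X.T - a[None, :]
    mse0 = np.sum(R * R, axis=0) / (n - 1)
    mse = np.einsum("ij,ij->j", R, cho_solve(cf, R)) / (n - 1)
    return (mse0 / mse) / expected_ratio


def blomberg_k(trait: Mapping[str, float], tree: PhyloTree,
               n_perm: int = 999, seed: int | None = None,
               C: np.ndarray | None = None) -> SignalResult:
    """Blomberg's K with a tip-permutation significance test.

    K compares the observed ratio of tip variance (about the GLS mean) to
    the GLS mean square against its BM expectation
    ``(tr(C) - n / 1'C^-1 1) / (n - 1)``; K = 1 under BM, K > 1 indicates
    stronger-than-BM conservatism.  The permutation p-value is one-tailed
    with +1 smoothing: ``p = (1 + #{K_perm >= K_obs}) / (n_perm + 1)``.
    """
    labels = tree.tip_labels
    x = align_trait(trait, labels)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; K undefined")
    if C is None:
        C = vcv(tree)
    cf = _chol(C)
    s = float(np.sum(cho_solve(cf, np.ones(n))))
    expected_ratio = (float(np.trace(C)) - n / s) / (n - 1)
    k_obs = float(_k_statistic(x[None, :], C, cf, expected_ratio)[0])
    p = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(x) for _ in range(n_perm)])
        k_perm = _k_statistic(perms, C, cf, expected_ratio)
        p = (1.0 + float(np.sum(k_perm >= k_obs))) / (n_perm + 1.0)
    logL = bm_fit(x, C).log_likelihood
    return SignalResult("K", k_obs, p, logL, n,
                        n_permutations=n_perm, seed=seed)


# -- independent contrasts --------------------------------------------------

def _resolve_polytomies(tree: PhyloTree) -> tuple[PhyloTree, int]:
    """Resolve polytomies into arbitrary zero-length bifurcations (left fold)."""
    out = tree.copy()
    n_resolved = 0
    for node in list(out.preorder()):
        while len(node.children) > 2:
            left = PhyloNode(length=0.0)
            first, second = node.children[0], node.children[1]
            node.children = node.children[2:]
            left.add_child(first)
            left.add_child(second)
            node.children.insert(0, left)
            left.parent = node
            n_resolved += 1
    return out, n_resolved


def pic(trait: Mapping[str, float], tree: PhyloTree,
        return_nodes: bool = False):
    """Felsenstein's phylogenetically independent contrasts.

    Returns the n-1 standardized contrasts ``(x_i - x_j)/sqrt(v_i + v_j)``
    from the pruning pass; under BM with rate sigma2 they are iid
    N(0, sigma2).  Polytomies are resolved into zero-length bifurcations
    (the extra contrasts are valid but arbitrary in sign).
    """
    work, n_resolved = _resolve_polytomies(tree)
    if n_resolved:
        warnings.warn(f"resolved {n_resolved} polytomies into zero-length "
                      "bifurcations", stacklevel=2)
    x = align_trait(trait, work.tip_labels)
    values: dict[PhyloNode, float] = {}
    extra: dict[PhyloNode, float] = {}
    tips = work.tips()
    for tip, val in zip(tips, x):
        values[tip] = val
        extra[tip] = 0.0
    contrasts: list[float] = []
    node_names: list[str] = []
    idx = 0
    for node in work.postorder():
        if node.is_tip:
            continue
        c1, c2 = node.children
        v1 = c1.length + extra[c1]
        v2 = c2.length + extra[c2]
        vsum = v1 + v2
        if vsum <= 0:
            raise ZeroDivisionError(
                "zero combined branch length at a contrast; collapse "
                "duplicate zero-length tips first")
        contrasts.append((values[c1] - values[c2]) / np.sqrt(vsum))
        node_names.append(node.name or f"node{idx}")
        idx += 1
        values[node] = (values[c1] * v2 + values[c2] * v1) / vsum
        extra[node] = v1 * v2 / vsum
    out = np.array(contrasts)
    if return_nodes:
        return out, node_names
    return out


# -- PGLS -------------------------------------------------------------------

def pgls(y: Mapping[str, float], X: "object", tree: PhyloTree,
         structure: str = "BM", term_names: Sequence[str] | None = None,
         C: np.ndarray | None = None) -> PGLSFit:
    """Phylogenetic GLS regression of a tip trait on tip-level predictors.

    ``X`` is a pandas DataFrame indexed by tip label, or a 2-D array aligned
    with ``tree.tip_labels``.  An intercept is always included.  With
    ``structure="BM"`` the residual covariance is proportional to the BM
    matrix C; with ``structure="ML-lambda"``, Pagel's lambda is estimated
    jointly by profile likelihood.  R^2 is ``1 - RSS_gls / TSS_gls`` with
    the total sum of squares taken from the GLS intercept-only fit, so it
    lies in [0, 1].
    """
    import pandas as pd

    labels = tree.tip_labels
    yv = align_trait(y, labels)
    if isinstance(X, pd.DataFrame):
        missing = [l for l in labels if l not in X.index]
        if missing:
            raise KeyError(f"predictors missing tips: {missing[:5]}")
        names = list(X.columns)
        Xm = X.loc[labels].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = list(term_names) if term_names is not None else [
            f"x{i + 1}" for i in range(Xm.shape[1])]
    n, k = Xm.shape
    if n != len(labels):
        raise ValueError("predictor rows must align with tree tips")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k}); prefilter predictors")
    design = np.column_stack([np.ones(n), Xm])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, ["(Intercept)"] + names)
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    if C is None:
        C = vcv(tree)

    lambda_hat = None
    if structure == "ML-lambda":
        def nll(lam: float) -> float:
            Cl = transform_vcv(C, "lambda", lam)
            return -_gls(design, yv, Cl)[3]
        lambda_hat, _ = _profile_maximize(nll, 0.0, 1.0)
        Cuse = transform_vcv(C, "lambda", lambda_hat)
    elif structure == "BM":
        Cuse = C
    else:
        raise ValueError("structure must be 'BM' or 'ML-lambda'")

    beta, rss, sigma2, logL, XtCiX = _gls(design, yv, Cuse)
    # t tests use the bias-corrected residual variance (n - p denominator)
    df = n - design.shape[1]
    s2_unbiased = rss / df
    cov_beta = s2_unbiased * np.linalg.inv(XtCiX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    _, tss, _, _, _ = _gls(np.ones((n, 1)), yv, Cuse)
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    fitted = design @ beta
    return PGLSFit(
        terms=["(Intercept)"] + names,
        coef=beta, se=se, t_values=tvals, p_values=pvals,
        sigma2=sigma2, log_likelihood=logL,
        r_squared=float(r2), multiple_r=float(np.sqrt(max(r2, 0.0))),
        structure=structure, n_tips=n, lambda_hat=lambda_hat,
        fitted=fitted, residuals=yv - fitted,
    )


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(1, design.shape[1]):
        sub = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(design):
            bad.append(names[j])
    return bad


# -- ancestral state reconstruction ----------------------------------------

def asr_bm(trait: Mapping[str, float], tree: PhyloTree) -> AncestralStates:
    """ML/empirical-Bayes ancestral states of a continuous trait under BM.

    The root state is the GLS mean; every internal node gets the conditional
    (kriging) expectation of its BM state given the tip values, with a
    standard error that includes the uncertainty of the estimated root mean:

        var(u | tips) = sigma2 * [ d_u - c'C^-1 c + (1 - c'C^-1 1)^2 / 1'C^-1 1 ]

    where d_u is the node's depth and c the covariance of node u with the
    tips.  Internal nodes lacking names are labelled node0, node1, ...
    (preorder).
    """
    work = tree.copy()
    work.label_internal_nodes()
    labels = work.tip_labels
    x = align_trait(trait, labels)
    n = len(x)
    depths = work.depths()
    zero_term = [t.name for t in work.tips() if t.length == 0.0]
    if zero_term:
        warnings.warn(f"zero-length terminal branches ({zero_term[:3]}...); "
                      "those tips coincide with their parent nodes",
                      stacklevel=2)
    C = vcv(work)
    cf = _chol(C)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    s = float(ones @ Ci1)
    a_hat = float(x @ Ci1) / s
    resid = x - a_hat
    Cir = cho_solve(cf, resid)
    sigma2 = float(resid @ Cir) / n

    tip_index = {t: i for i, t in enumerate(work.tips())}
    # descendant tip indices per node
    desc: dict[PhyloNode, np.ndarray] = {}
    for node in work.postorder():
        if node.is_tip:
            desc[node] = np.array([tip_index[node]])
        else:
            desc[node] = np.concatenate([desc[c] for c in node.children])

    estimates: dict[str, float] = {}
    ses: dict[str, float] = {}
    for node in work.internal_nodes():
        if node is work.root:
            estimates[node.name] = a_hat
            ses[node.name] = float(np.sqrt(sigma2 / s))
            continue
        # covariance of node u with each tip: depth of the deepest ancestor
        # of u (u included) on whose subtree the tip sits
        c = np.zeros(n)
        path = []
        p = node
        while p is not None:
            path.append(p)
            p = p.parent
        for anc in reversed(path):  # root first, node last
            c[desc[anc]] = depths[anc]
        Cic = cho_solve(cf, c)
        est = a_hat + float(c @ Cir)
        cvar = depths[node] - float(c @ Cic) + (1.0 - float(c @ Ci1)) ** 2 / s
        estimates[node.name] = est
        ses[node.name] = float(np.sqrt(sigma2 * max(cvar, 0.0)))
    return AncestralStates(estimates=estimates, standard_errors=ses,
                           sigma2=sigma2, root_mean=a_hat)
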