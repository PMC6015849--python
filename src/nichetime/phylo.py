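"""Discrete-trait ancestral states (2-state Mk/ER) and phylogenetic GLS.

The activity type of each species is a binary character (strict vs non-strict
use of the order-typical period). Its ancestral state is estimated under the
continuous-time Markov model with a single transition rate (the equal-rates
Mk model), maximum likelihood over the rate, and a configurable root prior.
Continuous traits (log body size) are handled with Pagel's lambda
transformation of the Brownian-motion covariance and lambda-GLS regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import Phylogeny

__all__ = [
    "STATES",
    "mk_transition_prob",
    "mk_loglik",
    "MkAncestralState",
    "fit_mk_er",
    "root_state_consensus",
    "PagelsLambda",
    "fit_pagels_lambda",
    "select_representative_tree",
    "PGLS",
    "pgls",
]

STATES = ("strict", "non_strict")


def _encode_states(tree: Phylogeny, tip_states) -> np.ndarray:
    """Map tip states to 0/1 in tip order. Accepts dict, Series, or array."""
    if isinstance(tip_states, pd.Series):
        tip_states = tip_states.to_dict()
    if isinstance(tip_states, dict):
        try:
            vals = [tip_states[lab] for lab in tree.tip_labels]
        except KeyError as e:
            raise KeyError(f"missing tip state for {e.args[0]!r}") from None
    else:
        vals = list(tip_states)
        if len(vals) != tree.n_tips:
            raise ValueError("tip_states length does not match tree")
    out = np.empty(tree.n_tips, dtype=np.int64)
    for i, v in enumerate(vals):
        if v in (0, 1):
            out[i] = int(v)
        elif v in STATES:
            out[i] = STATES.index(v)
        else:
            raise ValueError(f"unknown state {v!r}")
    return out


def mk_transition_prob(q: float, t: float) -> np.ndarray:
    """2x2 transition matrix of the equal-rates Mk model over a branch.

    P(stay) = (1 + exp(-2qt))/2, P(switch) = (1 - exp(-2qt))/2.
    """
    if q < 0 or t < 0:
        raise ValueError("q and t must be non-negative")
    e = np.exp(-2.0 * q * t)
    stay = 0.5 * (1.0 + e)
    switch = 0.5 * (1.0 - e)
    return np.array([[stay, switch], [switch, stay]])


def mk_loglik(tree: Phylogeny, tip_states, q: float,
              root_prior=(0.5, 0.5)) -> tuple[float, np.ndarray]:
    """Felsenstein-pruning log-likelihood of binary tip states at rate ``q``.

    Returns ``(loglik, log_root_conditional)`` where the second element holds
    the log conditional likelihood of the data given each root state.
    """
    states = _encode_states(tree, tip_states)
    prior = np.asarray(root_prior, dtype=float)
    n = tree.n_nodes
    n_tips = tree.n_tips
    logL = np.zeros((n, 2))
    L = np.ones((n, 2))
    scale = np.zeros(n)
    for i in range(n_tips):
        L[i] = 0.0
        L[i, states[i]] = 1.0
    for nd in tree.postorder():
        if nd < n_tips:
            continue
        acc = np.ones(2)
        sc = 0.0
        for c in tree.children[nd]:
            P = mk_transition_prob(q, tree.edge_length[c])
            acc = acc * (P @ L[c])
            sc += scale[c]
        m = acc.max()
        if m <= 0:
            return -np.inf, np.array([-np.inf, -np.inf])
        L[nd] = acc / m
        scale[nd] = sc + np.log(m)
    root = tree.root
    log_root = np.where(L[root] > 0, np.log(np.maximum(L[root], 1e-300)), -np.inf) + scale[root]
    with np.errstate(divide="ignore"):
        terms = np.log(prior) + log_root
    loglik = float(np.logaddexp(terms[0], terms[1]))
    return loglik, log_root


@dataclass
class MkAncestralStateResults:
    """ML fit of the equal-rates Mk model with root-state posterior."""

    q_hat: float
    loglik: float
    root_posterior: np.ndarray  # P(strict), P(non_strict)
    consensus_state: str
    monomorphic: bool = False

    def summary(self) -> str:
        lines = [
            "Mk (equal rates) ancestral state fit",
            f"  q_hat            {self.q_hat:.6g}",
            f"  loglik           {self.loglik:.6f}",
            f"  P(root=strict)   {self.root_posterior[0]:.4f}",
            f"  P(root=non_strict) {self.root_posterior[1]:.4f}",
            f"  consensus        {self.consensus_state}",
        ]
        if self.monomorphic:
            lines.append("  note: tip states monomorphic; q fixed at 0")
        return "\n".join(lines)


class MkAncestralState:
    """ML ancestral-state model for a binary character under equal-rates Mk.

    Parameters
    ----------
    tree : Phylogeny
    tip_states : mapping/array of 'strict'/'non_strict' (or 0/1) per tip
    root_prior : root state prior, default flat (0.5, 0.5); with a flat prior
        the root posterior equals the scaled root conditional likelihoods.
    """

    def __init__(self, tree: Phylogeny, tip_states, root_prior=(0.5, 0.5)):
        self.tree = tree
        self.states = _encode_states(tree, tip_states)
        self.root_prior = np.asarray(root_prior, dtype=float)
        if self.tree.n_tips < 2:
            raise ValueError("need at least 2 tips")

    def loglik(self, q: float) -> float:
        return mk_loglik(self.tree, self.states, q, self.root_prior)[0]

    def fit(self, q_max: float | None = None) -> MkAncestralStateResults:
        states = self.states
        if states.min() == states.max():  # monomorphic: no change needed
            post = np.zeros(2)
            post[states[0]] = 1.0
            ll = self.loglik(0.0)
            return MkAncestralStateResults(0.0, ll, post, STATES[states[0]],
                                           monomorphic=True)
        height = self.tree.node_depths()[: self.tree.n_tips].mean()
        if q_max is None:
            q_max = 100.0 / max(height, 1e-12)
        # log-spaced brackets so interior optima are not lost against the
        # saturation plateau at large q
        edges = np.concatenate([[1e-10],
                                np.geomspace(0.01 / max(height, 1e-12),
                                             q_max, 6)])
        best = (np.inf, 0.0)
        f = lambda q: -self.loglik(q)
        for lo, hi in zip(edges[:-1], edges[1:]):
            r = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                         options={"xatol": 1e-8})
            if r.fun < best[0]:
                best = (r.fun, float(r.x))
        for q0 in (0.0, q_max):
            v = f(q0)
            if v < best[0]:
                best = (v, q0)
        q_hat = best[1]
        ll, log_root = mk_loglik(self.tree, states, q_hat, self.root_prior)
        with np.errstate(divide="ignore"):
            lp = np.log(self.root_prior) + log_root
        lp -= lp.max()
        post = np.exp(lp)
        post /= post.sum()
        consensus = STATES[int(np.argmax(post))]
        return MkAncestralStateResults(q_hat, ll, post, consensus)


def fit_mk_er(tree: Phylogeny, tip_states, root_prior=(0.5, 0.5)) -> MkAncestralStateResults:
    """Functional wrapper: ML equal-rates Mk fit with root posterior."""
    return MkAncestralState(tree, tip_states, root_prior).fit()


def root_state_consensus(trees: list[Phylogeny], tip_states,
                         method: str = "average") -> tuple[str, np.ndarray]:
    """Consensus root state over a tree sample.

    ``method='average'`` averages per-tree root posteriors (default);
    ``'majority'`` takes the majority of per-tree argmax calls.
    Returns ``(consensus_state, mean_posterior)``.
    """
    if not trees:
        raise ValueError("need at least one tree")
    posts = []
    votes = np.zeros(2)
    for t in trees:
        res = fit_mk_er(t, tip_states)
        posts.append(res.root_posterior)
        votes[int(np.argmax(res.root_posterior))] += 1
    mean_post = np.mean(posts, axis=0)
    if method == "average":
        idx = int(np.argmax(mean_post))
    elif method == "majority":
        idx = int(np.argmax(votes))
    else:
        raise ValueError("method must be 'average' or 'majority'")
    return STATES[idx], mean_post


# ---------------------------------------------------------------------------
# Pagel's lambda and lambda-GLS
# ---------------------------------------------------------------------------

def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel transform: scale off-diagonal covariances, keep tip variances."""
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls_profile_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray,
                        reml: bool = False):
    """Profile Gaussian loglik of y ~ N(X beta, sigma2 V); sigma2, beta profiled.

    Returns (loglik, beta_hat, sigma2_hat, XtViX_inv, cho_factor).
    """
    n, p = X.shape
    cf = linalg.cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = linalg.cho_solve(cf, X)
    Vi_y = linalg.cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    XtViX_inv = np.linalg.inv(XtViX)
    beta = XtViX_inv @ (X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = linalg.cho_solve(cf, r)
    rss = float(r @ Vi_r)
    if reml:
        dof = n - p
        sigma2 = rss / dof
        s, logdetXVX = np.linalg.slogdet(XtViX)
        ll = -0.5 * (dof * np.log(2 * np.pi * sigma2) + dof
                     + logdetV + logdetXVX)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdetV)
    return ll, beta, sigma2, XtViX_inv, cf


@dataclass
class LambdaFitResults:
    """ML estimate of Pagel's lambda for one trait on one tree."""

    lambda_: float
    sigma2: float
    loglik: float
    flagged: bool = False
    note: str = ""

    def summary(self) -> str:
        s = (f"Pagel's lambda fit\n  lambda  {self.lambda_:.4f}\n"
             f"  sigma2  {self.sigma2:.6g}\n  loglik  {self.loglik:.4f}")
        if self.flagged:
            s += f"\n  note: {self.note}"
        return s


class PagelsLambda:
    """ML estimation of phylogenetic signal (Pagel's lambda) for a trait.

    The covariance is ``V(lambda)``: Brownian-motion covariance with
    off-diagonal entries multiplied by lambda in [0, 1], tip variances kept.
    """

    def __init__(self, tree: Phylogeny, trait):
        if isinstance(trait, (dict, pd.Series)):
            trait = pd.Series(trait)
            trait = trait.reindex(tree.tip_labels).to_numpy(dtype=float)
        self.y = np.asarray(trait, dtype=float)
        if len(self.y) != tree.n_tips:
            raise ValueError("trait length does not match tree tips")
        if tree.n_tips < 4:
            raise ValueError("need at least 4 tips")
        if np.var(self.y) <= 0:
            raise ValueError("trait has zero variance")
        self.tree = tree
        self.C = tree.vcv()
        if not tree.is_ultrametric():
            warnings.warn("tree is not ultrametric; lambda-GLS assumes "
                          "comparable tip heights", stacklevel=2)

    def loglik(self, lam: float) -> float:
        X = np.ones((len(self.y), 1))
        return _gls_profile_loglik(self.y, X, _lambda_cov(self.C, lam))[0]

    def fit(self) -> LambdaFitResults:
        offdiag = self.C - np.diag(np.diag(self.C))
        if np.abs(offdiag).max() < 1e-12 * max(np.diag(self.C).max(), 1.0):
            X = np.ones((len(self.y), 1))
            ll, _, s2, _, _ = _gls_profile_loglik(self.y, X, _lambda_cov(self.C, 0.0))
            return LambdaFitResults(0.0, s2, ll, flagged=True,
                                    note="star tree: lambda unidentifiable, set to 0")
        f = lambda lam: -self.loglik(lam)
        best = (f(0.0), 0.0)
        for lo, hi in ((0.0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1.0)):
            r = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                         options={"xatol": 1e-6})
            if r.fun < best[0]:
                best = (r.fun, float(r.x))
        v1 = f(1.0)
        if v1 < best[0]:
            best = (v1, 1.0)
        lam = min(max(best[1], 0.0), 1.0)
        X = np.ones((len(self.y), 1))
        ll, _, s2, _, _ = _gls_profile_loglik(self.y, X, _lambda_cov(self.C, lam))
        return LambdaFitResults(lam, s2, ll)


def fit_pagels_lambda(tree: Phylogeny, trait) -> LambdaFitResults:
    """Functional wrapper around :class:`PagelsLambda`."""
    return PagelsLambda(tree, trait).fit()


def lambda_profile(trees: list[Phylogeny], trait) -> pd.DataFrame:
    """Per-tree lambda estimates over a tree sample, with summary percentiles."""
    rows = []
    for i, t in enumerate(trees):
        res = fit_pagels_lambda(t, trait)
        rows.append({"tree": i, "lambda": res.lambda_, "sigma2": res.sigma2,
                     "loglik": res.loglik})
    df = pd.DataFrame(rows)
    df.attrs["mean"] = float(df["lambda"].mean())
    df.attrs["pct_2.5"] = float(np.percentile(df["lambda"], 2.5))
    df.attrs["pct_97.5"] = float(np.percentile(df["lambda"], 97.5))
    return df


def select_representative_tree(trees: list[Phylogeny], trait) -> int:
    """Index of the tree whose lambda estimate is the sample (lower) median."""
    lams = np.array([fit_pagels_lambda(t, trait).lambda_ for t in trees])
    order = np.argsort(lams, kind="stable")
    med_pos = (len(lams) - 1) // 2  # lower median for even counts
    return int(order[med_pos])


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSResults:
    """Lambda-GLS regression results (coefficients in original units)."""

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    sigma2: float
    lambda_: float
    loglik: float
    df_resid: int
    cov_params: np.ndarray
    exog_names: list[str]

    def summary(self) -> str:
        head = (f"Phylogenetic GLS (lambda = {self.lambda_:.4f}, "
                f"sigma2 = {self.sigma2:.5g}, loglik = {self.loglik:.3f})\n")
        rows = [f"{'':<16}{'coef':>12}{'se':>12}{'t':>10}{'P>|t|':>10}"]
        for name, b, se, t, p in zip(self.exog_names, self.params, self.bse,
                                     self.tvalues, self.pvalues):
            rows.append(f"{name:<16}{b:>12.5f}{se:>12.5f}{t:>10.3f}{p:>10.4f}")
        return head + "\n".join(rows)


class PGLS:
    """Phylogenetic generalized least squares with Pagel's lambda covariance.

    ``lambda_`` may be a fixed value in [0, 1] or ``'estimate'`` to maximize
    the profile likelihood jointly with the regression.
    """

    def __init__(self, tree: Phylogeny, endog, exog, exog_names=None,
                 add_constant: bool = True):
        if isinstance(endog, (dict, pd.Series)):
            endog = pd.Series(endog).reindex(tree.tip_labels).to_numpy(dtype=float)
        self.y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
        if exog_names is None:
            exog_names = [f"x{i}" for i in range(X.shape[1])]
        if add_constant:
            X = np.column_stack([np.ones(len(self.y)), X])
            exog_names = ["const"] + list(exog_names)
        if len(self.y) != tree.n_tips or X.shape[0] != tree.n_tips:
            raise ValueError("data length does not match tree tips")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.X = X
        self.exog_names = exog_names
        self.tree = tree
        self.C = tree.vcv()

    def _ll(self, lam: float, reml: bool = True) -> float:
        return _gls_profile_loglik(self.y, self.X, _lambda_cov(self.C, lam),
                                   reml=reml)[0]

    def fit(self, lambda_: float | str = "estimate",
            method: str = "REML") -> PGLSResults:
        """Fit the regression; lambda is estimated by REML by default (the
        restricted likelihood gives better-calibrated variance estimates)."""
        reml = method.upper() == "REML"
        if lambda_ == "estimate":
            f = lambda lam: -self._ll(lam, reml)
            best = (f(0.0), 0.0)
            for lo, hi in ((0.0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1.0)):
                r = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                             options={"xatol": 1e-6})
                if r.fun < best[0]:
                    best = (r.fun, float(r.x))
            if f(1.0) < best[0]:
                best = (f(1.0), 1.0)
            lam = best[1]
        else:
            lam = float(lambda_)
            if not 0.0 <= lam <= 1.0:
                raise ValueError("lambda must be in [0, 1]")
        V = _lambda_cov(self.C, lam)
        ll, beta, sigma2_prof, XtViX_inv, _ = _gls_profile_loglik(
            self.y, self.X, V, reml=reml)
        n, p = self.X.shape
        df = n - p
        # REML profiles sigma2 with the df correction already; rescale ML
        sigma2 = sigma2_prof if reml else sigma2_prof * n / df
        cov = sigma2 * XtViX_inv
        bse = np.sqrt(np.diag(cov))
        tvals = beta / bse
        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        return PGLSResults(beta, bse, tvals, pvals, sigma2, lam, ll, df, cov,
                           self.exog_names)


def pgls(tree: Phylogeny, response, design, lambda_: float | str = "estimate",
         exog_names=None, add_constant: bool = True) -> PGLSResults:
    """Functional wrapper around :class:`PGLS`."""
    return PGLS(tree, response, design, exog_names=exog_names,
                add_constant=add_constant).fit(lambda_=lambda_)
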