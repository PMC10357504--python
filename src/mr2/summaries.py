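"""Post-processing of sampler output.

Selection evidence comes in three flavours: the marginal posterior
probability of inclusion (mPPI) of one exposure-outcome pair, the edge
posterior probability of inclusion (ePPI) of one residual-dependence edge
between two outcomes, and the joint posterior probability of inclusion
(jPPI) of one exposure across a set of outcomes simultaneously.  A
two-component mixture model on the PPIs provides Bayesian FDR-controlled
selection, and the conditional predictive ordinate (CPO) screens single
variants for local pleiotropy / undue influence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist

from .data import StandardizedData
from .model import McmcChains

logger = logging.getLogger(__name__)


@dataclass
class PosteriorSummary:
    mppi: np.ndarray               # (q, p)
    eppi: np.ndarray               # (q, q) symmetric
    theta_mean: np.ndarray         # (q, p) unconditional (zeros count)
    theta_ci_low: np.ndarray
    theta_ci_high: np.ndarray
    theta_mean_conditional: np.ndarray   # mean given inclusion (0 if never in)
    theta_ci_low_conditional: np.ndarray
    theta_ci_high_conditional: np.ndarray
    partial_corr_mean: np.ndarray  # (q, q)
    partial_corr_ci_low: np.ndarray
    partial_corr_ci_high: np.ndarray
    credible_level: float = 0.95
    exposure_names: list = field(default_factory=list)
    outcome_names: list = field(default_factory=list)


@dataclass
class SelectionResult:
    selected_mask: np.ndarray
    ppi_threshold: float
    fdr_level: float
    mixture_params: dict


@dataclass
class CpoResult:
    cpo: np.ndarray          # (n,)
    scaled_cpo: np.ndarray   # (n,) in (0, 1]
    outlier_mask: np.ndarray
    threshold: float


def _partial_corr(R: np.ndarray) -> np.ndarray:
    K = np.linalg.inv(R)
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P


def summarize(chains: McmcChains, level: float = 0.95) -> PosteriorSummary:
    """Posterior means, credible intervals and inclusion probabilities."""
    if chains.n_draws == 0:
        raise ValueError("empty chains")
    if chains.n_draws < 100:
        logger.warning("only %d stored draws; summaries will be noisy",
                       chains.n_draws)
    alpha = (1.0 - level) / 2.0
    gam = chains.gamma.astype(bool)
    mppi = gam.mean(axis=0)
    eppi = chains.graph.mean(axis=0)
    eppi = (eppi + eppi.swapaxes(0, 1)) / 2.0

    th = chains.theta
    theta_mean = th.mean(axis=0)
    lo = np.quantile(th, alpha, axis=0)
    hi = np.quantile(th, 1.0 - alpha, axis=0)

    q, p = mppi.shape
    cmean = np.zeros((q, p))
    clo = np.zeros((q, p))
    chi = np.zeros((q, p))
    for k in range(q):
        for j in range(p):
            sel = th[gam[:, k, j], k, j]
            if sel.size:
                cmean[k, j] = sel.mean()
                clo[k, j] = np.quantile(sel, alpha)
                chi[k, j] = np.quantile(sel, 1.0 - alpha)

    pcs = np.stack([_partial_corr(R) for R in chains.R])
    return PosteriorSummary(
        mppi=mppi, eppi=eppi,
        theta_mean=theta_mean, theta_ci_low=lo, theta_ci_high=hi,
        theta_mean_conditional=cmean,
        theta_ci_low_conditional=clo, theta_ci_high_conditional=chi,
        partial_corr_mean=pcs.mean(axis=0),
        partial_corr_ci_low=np.quantile(pcs, alpha, axis=0),
        partial_corr_ci_high=np.quantile(pcs, 1.0 - alpha, axis=0),
        credible_level=level,
        exposure_names=chains.exposure_names,
        outcome_names=chains.outcome_names)


def jppi(chains: McmcChains, exposure: int, outcomes) -> float:
    """Fraction of draws in which one exposure is included for *all* the
    given outcomes simultaneously."""
    outcomes = sorted(set(int(k) for k in outcomes))
    if len(outcomes) < 2:
        raise ValueError("jPPI requires at least two outcomes; "
                         "for a single outcome use the mPPI")
    g = chains.gamma[:, outcomes, exposure].astype(bool)
    return float(g.all(axis=1).mean())


# ----- mixture-model FDR selection ----------------------------------------

def _beta_mle(x, w, n_iter=50):
    """Weighted Beta MLE via Newton on (log a, log b)."""
    from scipy.special import polygamma, psi
    sw = w.sum()
    if sw <= 0:
        return 1.0, 1.0
    t1 = np.dot(w, np.log(x)) / sw
    t2 = np.dot(w, np.log1p(-x)) / sw
    m = np.dot(w, x) / sw
    v = np.dot(w, (x - m) ** 2) / sw
    v = max(v, 1e-6)
    c = max(m * (1 - m) / v - 1.0, 0.1)
    a, b = max(m * c, 1e-2), max((1 - m) * c, 1e-2)
    for _ in range(n_iter):
        g1 = psi(a + b) - psi(a) + t1
        g2 = psi(a + b) - psi(b) + t2
        h11 = polygamma(1, a + b) - polygamma(1, a)
        h22 = polygamma(1, a + b) - polygamma(1, b)
        h12 = polygamma(1, a + b)
        det = h11 * h22 - h12 * h12
        if abs(det) < 1e-12:
            break
        da = (h22 * g1 - h12 * g2) / det
        db = (h11 * g2 - h12 * g1) / det
        a_new, b_new = a - da, b - db
        if a_new <= 0 or b_new <= 0 or not np.isfinite(a_new + b_new):
            break
        if abs(a_new - a) + abs(b_new - b) < 1e-10:
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    return a, b


def _fit_beta_mixture(x, rng, n_iter=200, tol=1e-8):
    """One EM run of a two-component Beta mixture; returns params + loglik."""
    n = x.size
    # random split initialization
    cut = np.quantile(x, rng.uniform(0.2, 0.8))
    resp = np.where(x <= cut, 0.9, 0.1)
    resp = np.clip(resp + rng.normal(0, 0.05, n), 0.01, 0.99)
    pi = resp.mean()
    a0, b0 = _beta_mle(x, resp)
    a1, b1 = _beta_mle(x, 1.0 - resp)
    ll_old = -np.inf
    for _ in range(n_iter):
        l0 = np.log(pi + 1e-300) + beta_dist.logpdf(x, a0, b0)
        l1 = np.log1p(-pi + 1e-300) + beta_dist.logpdf(x, a1, b1)
        norm = np.logaddexp(l0, l1)
        ll = norm.sum()
        resp = np.exp(l0 - norm)
        pi = resp.mean()
        pi = min(max(pi, 1e-6), 1 - 1e-6)
        a0, b0 = _beta_mle(x, resp)
        a1, b1 = _beta_mle(x, 1.0 - resp)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    # label the component with the smaller mean as "null"
    m0, m1 = a0 / (a0 + b0), a1 / (a1 + b1)
    if m0 > m1:
        pi, a0, b0, a1, b1 = 1 - pi, a1, b1, a0, b0
        resp = 1.0 - resp
    return {"pi_null": pi, "a_null": a0, "b_null": b0,
            "a_alt": a1, "b_alt": b1, "loglik": ll,
            "null_prob": resp}


def fdr_select(ppis, fdr_level: float = 0.05, n_restarts: int = 10,
               seed: int = 0, fallback_threshold: float = 0.5
               ) -> SelectionResult:
    """Bayesian FDR selection of PPIs via a two-component mixture.

    A two-component Beta mixture is fitted to the PPIs by EM (with random
    restarts); the posterior weight of the low-mean component is each
    item's local null probability.  The selection threshold is the smallest
    PPI such that the average null probability among selected items stays
    at or below ``fdr_level``.  Degenerate fits (one cluster, or all PPIs
    identical) fall back to thresholding at ``fallback_threshold`` — the
    median-probability-model rule.
    """
    ppis = np.asarray(ppis, dtype=float)
    shape = ppis.shape
    x = ppis.ravel()
    if np.any((x < 0) | (x > 1)):
        raise ValueError("PPIs must lie in [0, 1]")
    if x.size < 8:
        raise ValueError("need at least 8 PPIs for mixture fitting")

    xc = np.clip(x, 1e-4, 1.0 - 1e-4)
    rng = np.random.default_rng(seed)
    fit = None
    if np.ptp(xc) < 1e-6:
        warnings.warn("all PPIs identical; falling back to the 0.5 rule",
                      stacklevel=2)
    else:
        best_ll = -np.inf
        for _ in range(n_restarts):
            try:
                cand = _fit_beta_mixture(xc, rng)
            except (FloatingPointError, ValueError):
                continue
            if cand["loglik"] > best_ll:
                best_ll, fit = cand["loglik"], cand
        if fit is not None:
            m_null = fit["a_null"] / (fit["a_null"] + fit["b_null"])
            m_alt = fit["a_alt"] / (fit["a_alt"] + fit["b_alt"])
            degenerate = (m_alt - m_null < 0.05
                          or fit["pi_null"] < 1e-3 or fit["pi_null"] > 1 - 1e-3)
            if degenerate:
                fit = None

    if fit is None:
        mask = x >= fallback_threshold
        return SelectionResult(mask.reshape(shape),
                               float(fallback_threshold), fdr_level,
                               {"fallback": True})

    null_prob = fit.pop("null_prob")
    order = np.argsort(-x, kind="stable")
    cum_fdr = np.cumsum(null_prob[order]) / np.arange(1, x.size + 1)
    ok = np.flatnonzero(cum_fdr <= fdr_level)
    if ok.size == 0:
        mask = np.zeros_like(x, dtype=bool)
        thr = 1.0 + 1e-12
    else:
        n_sel = ok[-1] + 1
        thr = x[order[n_sel - 1]]
        mask = x >= thr
    return SelectionResult(mask.reshape(shape), float(thr), fdr_level,
                           {k: float(v) for k, v in fit.items()})


# ----- conditional predictive ordinate ------------------------------------

def compute_cpo(chains: McmcChains, data: StandardizedData,
                threshold: float = 0.01) -> CpoResult:
    """Per-variant conditional predictive ordinate.

    CPO_i is the harmonic mean over posterior draws of the variant's
    observation density f(beta_Y[i] | state) — a leave-one-out predictive
    density estimate.  Variants whose CPO, scaled by the maximum across
    variants, falls below ``threshold`` are flagged as outliers; the
    intended workflow is flag, remove, refit.
    """
    Y = data.beta_y_std
    X = data.beta_x_std
    n, q = Y.shape
    if chains.q != q or chains.p != X.shape[1]:
        raise ValueError("chains and data dimensions disagree")
    T = chains.n_draws
    logf = np.empty((T, n))
    const = -0.5 * q * np.log(2.0 * np.pi)
    for t in range(T):
        d = np.sqrt(chains.delta2[t])
        sigma = chains.R[t] * np.outer(d, d)
        L = np.linalg.cholesky(sigma)
        resid = Y - chains.mu[t][None, :] - X @ chains.theta[t].T
        Z = solve_triangular(L, resid.T, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        logf[t] = const - 0.5 * logdet - 0.5 * np.sum(Z * Z, axis=0)
    with np.errstate(over="warn"):
        log_cpo = np.log(T) - logsumexp(-logf, axis=0)
    cpo = np.exp(log_cpo)
    scaled = np.exp(log_cpo - log_cpo.max())
    return CpoResult(cpo=cpo, scaled_cpo=scaled,
                     outlier_mask=scaled < threshold, threshold=threshold)
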