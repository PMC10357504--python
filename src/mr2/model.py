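"""Sparse Bayesian multi-response MR sampler.

The model is a seemingly-unrelated-regression system on IVW-standardized
summary statistics: for variant i the q-vector of outcome associations is

    beta_Y[i] ~ N_q( mu + Theta_Gamma beta_X[i],  D^{1/2} R D^{1/2} ),

where Theta is the q x p matrix of direct causal effects with a
spike-and-slab prior (a point mass at zero for excluded exposure-outcome
pairs, a Gaussian slab for included ones, selection indicators Gamma), D is
the diagonal of per-outcome overdispersions delta_k^2, and R is a residual
correlation matrix whose inverse carries exact zeros off the edges of a
decomposable graph (hyper-inverse Wishart prior on the covariance).

The sampler cycles three blocks:

* joint selection/estimation: single-pair add/delete/swap proposals on
  Gamma in which the non-zero effects are analytically integrated out
  given the current residual covariance ("implicit marginalization"), so
  the Metropolis-Hastings ratio involves only closed-form Gaussian
  marginal likelihoods and prior odds; the accepted effects are then
  refreshed from their exact Gaussian full conditional;
* a single-edge graph move accepted with the closed-form HIW marginal
  likelihood ratio of the current residuals (the covariance integrated
  out), immediately rejecting non-decomposable proposals;
* an exact clique-wise draw of the covariance from its HIW full
  conditional, re-expressed as (delta^2, R).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from . import graphs
from .data import StandardizedData, SummaryData, ivw_standardize

logger = logging.getLogger(__name__)


@dataclass
class PriorConfig:
    """Hyperparameters of the sampler.

    slab_variance : Gaussian slab variance for included effects (on the
        IVW-standardized scale; 1.0 is weakly informative there).
    inclusion_a, inclusion_b : Beta hyperparameters of the exchangeable
        prior on the inclusion probability; integrated out, giving
        beta-binomial prior odds in the selection ratio.
    hiw_df, hiw_scale : degrees of freedom d > 2 and scalar tau of the
        HIW(d, tau I) prior on the residual covariance.
    edge_prior : Bernoulli prior probability of each residual graph edge.
    delta_shape, delta_rate : inverse-gamma prior for the overdispersions;
        used only when the graphical covariance update is disabled (fixed
        correlation structure), where delta_k^2 has an exact IG full
        conditional.  With the HIW update active the overdispersions are
        the diagonal of the covariance draw.
    intercepts : enable response-specific intercepts mu_k (off by default,
        the standard MR convention).
    """

    slab_variance: float = 1.0
    inclusion_a: float = 1.0
    inclusion_b: float = 1.0
    hiw_df: float = 3.0
    hiw_scale: float = 1.0
    edge_prior: float = 0.5
    delta_shape: float = 2.0
    delta_rate: float = 1.0
    intercepts: bool = False
    intercept_variance: float = 100.0

    def __post_init__(self):
        for name in ("slab_variance", "inclusion_a", "inclusion_b",
                     "hiw_scale", "delta_shape", "delta_rate",
                     "intercept_variance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hiw_df <= 2:
            raise ValueError("hiw_df must exceed 2 for a finite prior mean")
        if not 0.0 <= self.edge_prior <= 1.0:
            raise ValueError("edge_prior must be in [0, 1]")


@dataclass
class McmcState:
    """One draw of all model unknowns."""

    gamma: np.ndarray   # (q, p) bool selection indicators
    theta: np.ndarray   # (q, p) effects, zero off-support
    mu: np.ndarray      # (q,) intercepts
    delta2: np.ndarray  # (q,) overdispersions
    graph: np.ndarray   # (q, q) bool adjacency, no self-loops
    R: np.ndarray       # (q, q) residual correlation

    @property
    def sigma(self) -> np.ndarray:
        d = np.sqrt(self.delta2)
        return self.R * np.outer(d, d)

    def validate(self, atol=1e-8) -> None:
        q, p = self.gamma.shape
        assert self.theta.shape == (q, p)
        assert np.all(self.theta[~self.gamma] == 0.0), "theta off-support"
        assert np.all(self.delta2 > 0)
        assert self.graph.shape == (q, q)
        assert not self.graph.diagonal().any(), "self-loops"
        assert np.array_equal(self.graph, self.graph.T), "graph not symmetric"
        assert graphs.is_decomposable(self.graph), "graph not decomposable"
        assert np.allclose(self.R, self.R.T, atol=atol)
        assert np.allclose(np.diag(self.R), 1.0, atol=atol)
        np.linalg.cholesky(self.R + atol * np.eye(q))
        K = np.linalg.inv(self.R)
        off = ~self.graph & ~np.eye(q, dtype=bool)
        assert np.all(np.abs(K[off]) < 1e-6), "precision nonzero off-graph"

    def copy(self) -> "McmcState":
        return McmcState(self.gamma.copy(), self.theta.copy(),
                         self.mu.copy(), self.delta2.copy(),
                         self.graph.copy(), self.R.copy())


@dataclass
class McmcChains:
    """Post-burn-in draws plus bookkeeping."""

    gamma: np.ndarray    # (T, q, p) uint8
    theta: np.ndarray    # (T, q, p)
    mu: np.ndarray       # (T, q)
    delta2: np.ndarray   # (T, q)
    graph: np.ndarray    # (T, q, q) uint8
    R: np.ndarray        # (T, q, q)
    log_lik: np.ndarray  # (T,)
    acceptance: dict
    seed: int
    n_iter: int
    n_burnin: int
    thin: int = 1
    exposure_names: list = field(default_factory=list)
    outcome_names: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.gamma.shape[0]

    @property
    def q(self) -> int:
        return self.gamma.shape[1]

    @property
    def p(self) -> int:
        return self.gamma.shape[2]


def log_likelihood(state: McmcState, data: StandardizedData) -> float:
    """Gaussian SUR log likelihood of the standardized summary data."""
    Y = data.beta_y_std
    X = data.beta_x_std
    n, q = Y.shape
    resid = Y - state.mu[None, :] - X @ state.theta.T
    sigma = state.sigma
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise FloatingPointError(
            f"non-positive-definite residual covariance; state: "
            f"delta2={state.delta2}, R=\n{state.R}") from exc
    Z = solve_triangular(L, resid.T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (n * q * np.log(2.0 * np.pi) + n * logdet + np.sum(Z * Z))


class _Sampler:
    """Internal workhorse; holds precomputed cross-products."""

    def __init__(self, data: StandardizedData, prior: PriorConfig, rng):
        self.X = np.ascontiguousarray(data.beta_x_std)
        self.Y = np.ascontiguousarray(data.beta_y_std)
        self.n, self.p = self.X.shape
        self.q = self.Y.shape[1]
        self.prior = prior
        self.rng = rng
        self.XtX = self.X.T @ self.X
        self._set_center(np.zeros(self.q))
        self.accept = {"flip": [0, 0], "swap": [0, 0], "edge": [0, 0]}

    def _set_center(self, mu):
        """Recompute cross-products against the intercept-centred outcomes."""
        self.mu = mu
        self.Yc = self.Y - mu[None, :]
        self.XtY = self.X.T @ self.Yc

    # ----- selection block -------------------------------------------------

    def _sel_score(self, ks, js, Omega, MOm):
        """Model-dependent part of log p(Y | Gamma, Sigma).

        With effects integrated out under the N(0, w I) slab the marginal
        log likelihood differs across supports only by
            -0.5 log|I + w Z' C0^{-1} Z| + 0.5 z' (G + I/w)^{-1} z
        where G has entries Omega[k,k'] * (X'X)[j,j'] over active pairs and
        z = (X'Yc Omega)[j,k].
        """
        a = len(ks)
        if a == 0:
            return 0.0, None
        w = self.prior.slab_variance
        G = Omega[np.ix_(ks, ks)] * self.XtX[np.ix_(js, js)]
        P = G + np.eye(a) / w
        z = MOm[js, ks]
        try:
            L = np.linalg.cholesky(P)
        except np.linalg.LinAlgError:
            P = P + 1e-8 * np.eye(a)  # ridge jitter for degenerate designs
            L = np.linalg.cholesky(P)
        u = np.linalg.solve(L, z)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        score = -0.5 * (logdet + a * np.log(w)) + 0.5 * np.dot(u, u)
        return score, (L, z)

    def _prior_add_log_odds(self, m):
        """log prior odds of adding one pair when m are currently active."""
        a, b = self.prior.inclusion_a, self.prior.inclusion_b
        return np.log(a + m) - np.log(b + self.q * self.p - 1 - m)

    def update_selection(self, state: McmcState, Omega, n_moves: int):
        rng = self.rng
        q, p = self.q, self.p
        MOm = self.XtY @ Omega
        gamma = state.gamma
        ks, js = np.nonzero(gamma)
        ks, js = list(ks), list(js)
        score, _ = self._sel_score(ks, js, Omega, MOm)

        for _ in range(n_moves):
            swap = rng.random() < 0.5
            if swap:
                k = rng.integers(q)
                act = [i for i, kk in enumerate(ks) if kk == k]
                inact = np.flatnonzero(~gamma[k])
                if not act or inact.size == 0:
                    continue  # identity proposal
                drop = act[rng.integers(len(act))]
                j_new = int(inact[rng.integers(inact.size)])
                new_ks = ks[:drop] + ks[drop + 1:] + [k]
                new_js = js[:drop] + js[drop + 1:] + [j_new]
                d_prior = 0.0
                move = "swap"
            else:
                flat = rng.integers(q * p)
                k, j = divmod(int(flat), p)
                if gamma[k, j]:
                    drop = next(i for i in range(len(ks))
                                if ks[i] == k and js[i] == j)
                    new_ks = ks[:drop] + ks[drop + 1:]
                    new_js = js[:drop] + js[drop + 1:]
                    d_prior = -self._prior_add_log_odds(len(ks) - 1)
                else:
                    new_ks, new_js = ks + [k], js + [j]
                    d_prior = self._prior_add_log_odds(len(ks))
                move = "flip"
            new_score, _ = self._sel_score(new_ks, new_js, Omega, MOm)
            self.accept[move][1] += 1
            if np.log(rng.random()) < new_score - score + d_prior:
                self.accept[move][0] += 1
                score = new_score
                ks, js = new_ks, new_js
                gamma.fill(False)
                if ks:
                    gamma[ks, js] = True

        # refresh effects from the exact Gaussian full conditional
        theta = np.zeros((q, p))
        score, fac = self._sel_score(ks, js, Omega, MOm)
        if fac is not None:
            L, z = fac
            mean = np.linalg.solve(L.T, np.linalg.solve(L, z))
            draw = mean + np.linalg.solve(L.T, rng.standard_normal(len(z)))
            theta[ks, js] = draw
        state.gamma = gamma
        state.theta = theta

    # ----- graph and covariance blocks ------------------------------------

    def _residuals(self, state):
        return self.Yc - self.X @ state.theta.T

    def update_graph(self, state: McmcState):
        q = self.q
        if q < 2:
            return
        rng = self.rng
        E = self._residuals(state)
        S = E.T @ E
        scale = self.prior.hiw_scale * np.eye(q)
        i = int(rng.integers(q - 1))
        j = int(rng.integers(i + 1, q))
        new_adj = state.graph.copy()
        adding = not new_adj[i, j]
        new_adj[i, j] = new_adj[j, i] = adding
        self.accept["edge"][1] += 1
        if not graphs.is_decomposable(new_adj):
            return
        tree_old = graphs.junction_tree(state.graph)
        tree_new = graphs.junction_tree(new_adj)
        d = self.prior.hiw_df
        delta_ml = graphs.hiw_log_marginal(S, self.n, tree_new, d, scale) \
            - graphs.hiw_log_marginal(S, self.n, tree_old, d, scale)
        e = self.prior.edge_prior
        if e in (0.0, 1.0):
            d_prior = -np.inf if (adding and e == 0.0) or \
                (not adding and e == 1.0) else np.inf
        else:
            d_prior = (np.log(e) - np.log1p(-e)) * (1 if adding else -1)
        if np.log(rng.random()) < delta_ml + d_prior:
            self.accept["edge"][0] += 1
            state.graph = new_adj

    def update_covariance(self, state: McmcState):
        E = self._residuals(state)
        S = E.T @ E
        tree = graphs.junction_tree(state.graph)
        scale = self.prior.hiw_scale * np.eye(self.q) + S
        sigma = graphs.sample_hiw(self.rng, tree, self.prior.hiw_df + self.n,
                                  scale)
        d = np.sqrt(np.diag(sigma))
        state.delta2 = d ** 2
        state.R = sigma / np.outer(d, d)
        np.fill_diagonal(state.R, 1.0)

    def update_delta2_fixed_R(self, state: McmcState):
        """IG full conditional for the overdispersions when R is held at I."""
        E = self._residuals(state)
        shape = self.prior.delta_shape + 0.5 * self.n
        rate = self.prior.delta_rate + 0.5 * np.sum(E * E, axis=0)
        state.delta2 = rate / self.rng.gamma(shape, 1.0, size=self.q)

    def update_intercepts(self, state: McmcState, Omega):
        n = self.n
        resid = self.Y - self.X @ state.theta.T   # note: uncentred outcomes
        prec = n * Omega + np.eye(self.q) / self.prior.intercept_variance
        cov = np.linalg.inv(prec)
        mean = cov @ (Omega @ resid.sum(axis=0))
        L = np.linalg.cholesky(cov)
        state.mu = mean + L @ self.rng.standard_normal(self.q)
        self._set_center(state.mu)


def _coerce_data(data) -> StandardizedData:
    if isinstance(data, SummaryData):
        return ivw_standardize(data, "joint_precision")
    if isinstance(data, StandardizedData):
        return data
    raise TypeError("data must be SummaryData or StandardizedData")


def fit_mr2(data, prior: PriorConfig | None = None, n_iter: int = 15_000,
            n_burnin: int = 5_000, seed: int = 0, thin: int = 1,
            moves_per_iter: int | None = None, update_selection: bool = True,
            update_graph: bool = True, update_covariance: bool = True,
            fixed_gamma: np.ndarray | None = None,
            fixed_R: np.ndarray | None = None,
            fixed_delta2: np.ndarray | None = None,
            initial_state: McmcState | None = None) -> McmcChains:
    """Run the multi-response MR sampler.

    Parameters mirror the model description; ``n_iter`` counts post-burn-in
    iterations.  ``fixed_gamma`` pins the selection indicators (effects are
    still refreshed from their full conditional), ``fixed_R`` with
    ``update_covariance=False`` runs the fixed-correlation variant in which
    the overdispersions get an inverse-gamma Gibbs update (only R = I is
    supported there).  Deterministic given ``seed``.
    """
    sdata = _coerce_data(data)
    prior = prior or PriorConfig()
    n, p, q = sdata.n, sdata.p, sdata.q
    if n < 3:
        raise ValueError(f"need at least 3 variants, got n={n}")
    if not (np.all(np.isfinite(sdata.beta_x_std))
            and np.all(np.isfinite(sdata.beta_y_std))):
        raise ValueError("data contains non-finite values")
    conservative = q * (p + 1) + q * (q - 1) // 2
    if n <= conservative:
        warnings.warn(
            f"n={n} variants is at or below the conservative requirement "
            f"q(p+1)+q(q-1)/2={conservative}; posterior summaries may be "
            "prior-dominated", stacklevel=2)

    rng = np.random.default_rng(seed)
    smp = _Sampler(sdata, prior, rng)
    if moves_per_iter is None:
        moves_per_iter = max(10, p)

    if initial_state is not None:
        state = initial_state.copy()
    else:
        state = McmcState(
            gamma=np.zeros((q, p), dtype=bool),
            theta=np.zeros((q, p)),
            mu=np.zeros(q),
            delta2=np.maximum(sdata.beta_y_std.var(axis=0), 1e-3),
            graph=np.zeros((q, q), dtype=bool),
            R=np.eye(q))
    if fixed_gamma is not None:
        state.gamma = np.asarray(fixed_gamma, dtype=bool).copy()
    if fixed_R is not None:
        state.R = np.asarray(fixed_R, dtype=float).copy()
        if not np.allclose(state.R, np.eye(q)):
            raise ValueError("fixed_R currently supports only the identity")
    if fixed_delta2 is not None:
        state.delta2 = np.broadcast_to(
            np.asarray(fixed_delta2, dtype=float), (q,)).copy()

    total = n_burnin + n_iter
    n_store = n_iter // thin
    store = {
        "gamma": np.empty((n_store, q, p), dtype=np.uint8),
        "theta": np.empty((n_store, q, p)),
        "mu": np.empty((n_store, q)),
        "delta2": np.empty((n_store, q)),
        "graph": np.empty((n_store, q, q), dtype=np.uint8),
        "R": np.empty((n_store, q, q)),
        "log_lik": np.empty(n_store),
    }
    t = 0
    for it in range(total):
        sigma = state.sigma
        Omega = np.linalg.inv(sigma)
        if update_selection or fixed_gamma is not None:
            n_mv = 0 if fixed_gamma is not None else moves_per_iter
            smp.update_selection(state, Omega, n_mv)
        if prior.intercepts:
            smp.update_intercepts(state, Omega)
        if update_graph and q > 1 and 0.0 < prior.edge_prior:
            smp.update_graph(state)
        if update_covariance:
            smp.update_covariance(state)
        elif fixed_delta2 is None:
            smp.update_delta2_fixed_R(state)
        if it >= n_burnin and (it - n_burnin) % thin == 0 and t < n_store:
            store["gamma"][t] = state.gamma
            store["theta"][t] = state.theta
            store["mu"][t] = state.mu
            store["delta2"][t] = state.delta2
            store["graph"][t] = state.graph
            store["R"][t] = state.R
            store["log_lik"][t] = log_likelihood(state, sdata)
            t += 1

    acc = {k: (v[0] / v[1] if v[1] else 0.0) for k, v in smp.accept.items()}
    return McmcChains(
        gamma=store["gamma"][:t], theta=store["theta"][:t],
        mu=store["mu"][:t], delta2=store["delta2"][:t],
        graph=store["graph"][:t], R=store["R"][:t],
        log_lik=store["log_lik"][:t], acceptance=acc, seed=seed,
        n_iter=n_iter, n_burnin=n_burnin, thin=thin,
        exposure_names=list(getattr(sdata, "exposure_names", [])),
        outcome_names=list(getattr(sdata, "outcome_names", [])))
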