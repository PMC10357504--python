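"""Decomposable graphs and the hyper-inverse Wishart distribution.

The residual covariance between the q outcomes is constrained by an
undirected graph: missing edges are exact zeros in the precision matrix
(zero partial correlation).  Restricting the graph space to decomposable
(chordal) graphs makes the hyper-inverse Wishart (HIW) prior tractable:
both its normalizing constant and its posterior factorize over the cliques
and separators of a junction tree, giving a closed-form marginal likelihood
for graph comparison and an exact clique-wise sampler for the covariance.

Conventions.  HIW(d, Phi) on a graph G means that for every clique C of
size c the marginal Sigma_C follows an inverse Wishart with degrees of
freedom d + c - 1 and scale Phi_C in the standard parametrization
(density proportional to |S|^{-(df+c+1)/2} exp(-tr(S^{-1} Phi)/2)); this
shared-d convention makes the clique marginals consistent on separators.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy.special import multigammaln


def adjacency_to_graph(adj: np.ndarray) -> nx.Graph:
    q = adj.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(q))
    ii, jj = np.nonzero(np.triu(adj, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


@lru_cache(maxsize=4096)
def _is_decomposable_cached(key: bytes, q: int) -> bool:
    adj = np.frombuffer(key, dtype=bool).reshape(q, q)
    return nx.is_chordal(adjacency_to_graph(adj))


def is_decomposable(adj: np.ndarray) -> bool:
    """Chordality check (chordal == decomposable for undirected graphs)."""
    adj = np.asarray(adj, dtype=bool)
    return _is_decomposable_cached(adj.tobytes(), adj.shape[0])


@dataclass
class JunctionTree:
    """Cliques in perfect order with their running-intersection separators."""

    cliques: list   # list of tuples of node indices
    separators: list  # separators[j] = cliques[j] ∩ history, empty for j=0


def junction_tree(adj: np.ndarray) -> JunctionTree:
    """Cliques and separators of a decomposable graph in perfect order.

    Builds a maximum-weight spanning forest on the clique-intersection
    graph and roots each component, which yields an ordering satisfying the
    running intersection property.
    """
    adj = np.asarray(adj, dtype=bool)
    return _junction_tree_cached(adj.tobytes(), adj.shape[0])


@lru_cache(maxsize=4096)
def _junction_tree_cached(key: bytes, q: int) -> JunctionTree:
    adj = np.frombuffer(key, dtype=bool).reshape(q, q)
    g = adjacency_to_graph(adj)
    cliques = [tuple(sorted(c)) for c in nx.chordal_graph_cliques(g)]
    if len(cliques) == 1:
        return JunctionTree(cliques, [()])
    meta = nx.Graph()
    meta.add_nodes_from(range(len(cliques)))
    for i in range(len(cliques)):
        for j in range(i + 1, len(cliques)):
            w = len(set(cliques[i]) & set(cliques[j]))
            meta.add_edge(i, j, weight=w)
    tree = nx.maximum_spanning_tree(meta)
    order = list(nx.dfs_preorder_nodes(tree, source=0))
    seen: set = set()
    ordered, seps = [], []
    for idx in order:
        c = cliques[idx]
        ordered.append(c)
        seps.append(tuple(sorted(set(c) & seen)))
        seen.update(c)
    return JunctionTree(ordered, seps)


@lru_cache(maxsize=4096)
def _mgln(a: float, c: int) -> float:
    return float(multigammaln(a, c))


def _log_iw_const(df: float, scale: np.ndarray) -> float:
    """log normalizing constant K of the inverse Wishart density.

    IW(df, Psi) density = K * |S|^{-(df+c+1)/2} exp(-tr(S^{-1} Psi)/2)
    with K = |Psi|^{df/2} / (2^{df c / 2} Gamma_c(df/2)).
    """
    c = scale.shape[0]
    sign, logdet = np.linalg.slogdet(scale)
    if sign <= 0:
        raise np.linalg.LinAlgError("scale matrix not positive definite")
    return 0.5 * df * logdet - 0.5 * df * c * np.log(2.0) \
        - _mgln(0.5 * df, c)


def _log_block_ml(idx: tuple, S: np.ndarray, n: int, df: float,
                  scale: np.ndarray) -> float:
    """Marginal likelihood contribution of one clique/separator block."""
    if not idx:
        return 0.0
    c = len(idx)
    ix = np.ix_(idx, idx)
    nu = df + c - 1
    return (-0.5 * n * c * np.log(2.0 * np.pi)
            + _log_iw_const(nu, scale[ix])
            - _log_iw_const(nu + n, scale[ix] + S[ix]))


def hiw_log_marginal(S: np.ndarray, n: int, tree: JunctionTree,
                     df: float, scale: np.ndarray) -> float:
    """log p(E | G) for n iid zero-mean Gaussian rows with Sigma ~ HIW_G.

    ``S = E.T @ E`` is the residual cross-product.  Factorizes as the
    product of clique marginal likelihoods over the product of separator
    marginal likelihoods.
    """
    out = 0.0
    for c, s in zip(tree.cliques, tree.separators):
        out += _log_block_ml(c, S, n, df, scale)
        out -= _log_block_ml(s, S, n, df, scale)
    return out


def _sample_iw(rng, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse Wishart draw via the Bartlett decomposition.

    Standard parametrization: S ~ IW(df, scale) iff S^{-1} ~ Wishart(df,
    scale^{-1}); requires df >= dim.
    """
    c = scale.shape[0]
    if c == 1:
        # 1-dim: scale / chi2(df)
        return scale / rng.chisquare(df)
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((c, c))
    idx = np.tril_indices(c, -1)
    A[idx] = rng.standard_normal(len(idx[0]))
    A[np.diag_indices(c)] = np.sqrt(rng.chisquare(df - np.arange(c)))
    W = L @ A
    return np.linalg.inv(W @ W.T)


def sample_hiw(rng, tree: JunctionTree, df: float, scale: np.ndarray
               ) -> np.ndarray:
    """Draw Sigma ~ HIW_G(df, scale) by sequential clique sampling.

    Clique marginals are drawn in perfect order; each new clique's draw is
    adjusted so its separator block agrees with what has already been
    sampled (conditional regression parameterization), and the joint matrix
    is completed through the precision-matrix identity
    K = sum_C [Sigma_C^{-1}]^0 - sum_S [Sigma_S^{-1}]^0.
    """
    q = scale.shape[0]
    Sigma = np.zeros((q, q))
    for c_idx, s_idx in zip(tree.cliques, tree.separators):
        c = len(c_idx)
        nu = df + c - 1
        draw = _sample_iw(rng, nu, scale[np.ix_(c_idx, c_idx)])
        if not s_idx:
            Sigma[np.ix_(c_idx, c_idx)] = draw
            continue
        # positions of separator / residual nodes within the clique
        s_pos = [c_idx.index(v) for v in s_idx]
        r_idx = [v for v in c_idx if v not in s_idx]
        r_pos = [c_idx.index(v) for v in r_idx]
        Dss = draw[np.ix_(s_pos, s_pos)]
        Drs = draw[np.ix_(r_pos, s_pos)]
        Drr = draw[np.ix_(r_pos, r_pos)]
        B = np.linalg.solve(Dss, Drs.T).T
        Lam = Drr - B @ Dss @ B.T
        Sprev = Sigma[np.ix_(s_idx, s_idx)]
        Sigma[np.ix_(r_idx, s_idx)] = B @ Sprev
        Sigma[np.ix_(s_idx, r_idx)] = (B @ Sprev).T
        Sigma[np.ix_(r_idx, r_idx)] = Lam + B @ Sprev @ B.T
    # completion: assemble the precision from clique/separator inverses
    K = np.zeros((q, q))
    for c_idx in tree.cliques:
        ix = np.ix_(c_idx, c_idx)
        K[ix] += np.linalg.inv(Sigma[ix])
    for s_idx in tree.separators:
        if s_idx:
            ix = np.ix_(s_idx, s_idx)
            K[ix] -= np.linalg.inv(Sigma[ix])
    Sigma = np.linalg.inv(K)
    return (Sigma + Sigma.T) / 2.0
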