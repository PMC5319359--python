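"""Phylogenetic signal statistics.

Three statistics quantify how strongly trait variation follows the tree:

* Blomberg's K for a single continuous trait — the ratio of observed to
  Brownian-expected partitioning of variance. K = 1 under Brownian
  motion; K < 1 means close relatives resemble each other less than the
  Brownian expectation.
* K_mult, the multivariate generalisation, summing the numerator and
  denominator inner products over trait columns with a common
  phylogenetic mean vector.
* The evolutionary-model Mantel (EM-Mantel) test for categorical traits:
  the Mantel correlation between a 0/1 same-category distance and the
  patristic distance, tested against a null distribution simulated under
  an equal-rates Mk process whose rate is fitted to the observed labels
  by maximum likelihood (rather than by label permutation, which for
  discrete traits inflates type-I error and loses power).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .trees import PhyloCovariance, PhyloTree

__all__ = [
    "SignalResult",
    "blomberg_k",
    "k_mult",
    "em_mantel",
    "fit_mk_rate",
]


@dataclass
class SignalResult:
    """A signal statistic with its null-test summary."""

    statistic: float
    p_value: float
    n_null: int
    method: str
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _as_matrix(Y) -> np.ndarray:
    Y = Y.to_numpy() if isinstance(Y, (pd.DataFrame, pd.Series)) else np.asarray(Y)
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def _k_ratio(R: np.ndarray, Cinv: np.ndarray, expected: float) -> float:
    """K-type ratio for centred data R (columns are traits)."""
    num = float(np.sum(R * R))
    den = float(np.sum(R * (Cinv @ R)))
    return (num / den) / expected


def _k_setup(cov: PhyloCovariance):
    Cinv = cov.inv()
    n = cov.n
    w = Cinv @ np.ones(n)          # C^-1 1
    s = float(w.sum())             # 1' C^-1 1
    expected = (np.trace(cov.C) - n / s) / (n - 1)
    return Cinv, w, s, expected


def k_mult(Y, cov: PhyloCovariance, n_perm: int = 999,
           seed: int | None = None) -> SignalResult:
    """Multivariate phylogenetic signal K_mult (reduces to K at p = 1).

    The permutation null shuffles whole rows (species) of ``Y``; the
    one-sided p-value uses the (1 + count) / (1 + n_perm) convention.
    """
    Y = _as_matrix(Y)
    n, p = Y.shape
    if n != cov.n:
        raise ValueError("Y rows do not match covariance size")
    if n < 3:
        raise ValueError("signal statistics require n >= 3")
    if np.allclose(Y, Y[0], atol=0):
        raise ValueError("constant data: K undefined")
    Cinv, w, s, expected = _k_setup(cov)

    def stat(Ym: np.ndarray) -> float:
        a_hat = (w @ Ym) / s                     # per-column GLS mean
        return _k_ratio(Ym - a_hat, Cinv, expected)

    k_obs = stat(Y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat(Y[rng.permutation(n)]) >= k_obs:
            count += 1
    p_value = (1 + count) / (n_perm + 1)
    method = "K" if p == 1 else "K_mult"
    return SignalResult(k_obs, p_value, n_perm, method)


def blomberg_k(y, cov: PhyloCovariance, n_perm: int = 999,
               seed: int | None = None) -> SignalResult:
    """Blomberg's K for a single continuous trait.

    K = [(y-a)'(y-a) / (y-a)'C^-1(y-a)] / [(tr C - n/(1'C^-1 1))/(n-1)]
    with ``a`` the GLS (phylogenetic) mean; significance by tip-label
    permutation.
    """
    y = np.asarray(y, dtype=float).ravel()
    res = k_mult(y, cov, n_perm=n_perm, seed=seed)
    res.method = "K"
    return res


# ---------------------------------------------------------------------------
# equal-rates Mk likelihood and the EM-Mantel test

def _branch_arrays(tree: PhyloTree):
    """Postorder node list with parent pointers and branch lengths."""
    dtree = tree.dendropy_tree
    nodes = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    blen = np.zeros(len(nodes))
    for nd in nodes:
        if nd.parent_node is not None:
            parent[index[id(nd)]] = index[id(nd.parent_node)]
            blen[index[id(nd)]] = nd.edge.length
    leaves = {index[id(nd)]: nd.taxon.label for nd in nodes if nd.is_leaf()}
    return nodes, index, parent, blen, leaves


def mk_loglik(tree: PhyloTree, labels: pd.Series, states: list,
              rate: float) -> float:
    """Felsenstein-pruning log-likelihood of an equal-rates Mk process.

    Parameterised so that over a branch of length t,
    P(same state) = 1/k + (k-1)/k * exp(-rate * t); the root state is
    uniform over the k states.
    """
    k = len(states)
    state_ix = {s: i for i, s in enumerate(states)}
    nodes, index, parent, blen, leaves = _branch_arrays(tree)
    partial = np.ones((len(nodes), k))
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            partial[i] = 0.0
            partial[i, state_ix[labels.loc[nd.taxon.label]]] = 1.0
    scale = 0.0
    for i, nd in enumerate(nodes):
        pi = parent[i]
        if pi < 0:
            continue
        e = np.exp(-rate * blen[i])
        same = 1.0 / k + (k - 1) / k * e
        diff = 1.0 / k - e / k
        # message to parent: P(t) @ partial
        tot = partial[i].sum()
        msg = diff * tot + (same - diff) * partial[i]
        partial[pi] *= msg
        m = partial[pi].max()
        if m < 1e-280:
            partial[pi] /= m
            scale += np.log(m)
    root = partial[-1]
    return float(np.log(root.mean()) + scale)


def fit_mk_rate(tree: PhyloTree, labels: pd.Series, states: list) -> float:
    """ML transition rate of the equal-rates Mk model for observed labels."""
    height = float(np.max(tree.depths()))
    lo, hi = np.log(1e-6 / height), np.log(1e4 / height)
    res = optimize.minimize_scalar(
        lambda lr: -mk_loglik(tree, labels, states, np.exp(lr)),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def _mantel_r(same: np.ndarray, dphy_lower: np.ndarray,
              tril: tuple) -> float:
    d_trait = 1.0 - same[tril]
    # no variation in either distance (single category after simulation, or
    # a star phylogeny): no association measurable
    if d_trait.std() == 0.0 or dphy_lower.std() == 0.0:
        return 0.0
    return float(np.corrcoef(d_trait, dphy_lower)[0, 1])


def em_mantel(labels, tree: PhyloTree, n_sim: int = 999,
              seed: int | None = None) -> SignalResult:
    """Evolutionary-model Mantel test of signal in a categorical trait.

    The statistic is the Pearson correlation between the lower triangles
    of the 0/1 different-category distance and the patristic distance
    (positive r = close relatives share categories). The null comes from
    ``n_sim`` simulations of an equal-rates Mk process on the same tree
    with its rate fitted by ML to the observed labels; the one-sided
    p-value counts simulated r >= observed r.
    """
    from .synth import simulate_mk  # local import avoids a cycle at import time

    if isinstance(labels, pd.Series):
        labels = labels.reindex(tree.tips)
        if labels.isna().any():
            raise ValueError("labels missing for some tips")
    else:
        labels = pd.Series(np.asarray(labels), index=tree.tips)
    states = sorted(pd.unique(labels))
    if len(states) < 2:
        raise ValueError("need >= 2 categories for a Mantel test")

    dphy = tree.patristic_distances()
    tril = np.tril_indices(tree.n_tips, k=-1)
    dphy_lower = dphy[tril]

    codes = labels.map({s: i for i, s in enumerate(states)}).to_numpy()
    same = (codes[:, None] == codes[None, :]).astype(float)
    r_obs = _mantel_r(same, dphy_lower, tril)

    rate = fit_mk_rate(tree, labels, states)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sim):
        sim = simulate_mk(tree, states, rate,
                          seed=int(rng.integers(2**31 - 1)))
        sim_codes = sim.map({s: i for i, s in enumerate(states)}).to_numpy()
        sim_same = (sim_codes[:, None] == sim_codes[None, :]).astype(float)
        if _mantel_r(sim_same, dphy_lower, tril) >= r_obs:
            count += 1
    p_value = (1 + count) / (n_sim + 1)
    return SignalResult(r_obs, p_value, n_sim, "EM-Mantel",
                        details={"mk_rate": rate})
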