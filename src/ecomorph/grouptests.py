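"""Phylogenetic tests for ecological group differences.

Two complementary tests:

* ``phylo_anova`` — simulation-based phylogenetic ANOVA for a single
  variable (e.g. body size across diet classes). The F statistic is the
  ordinary one-way ANOVA F, but its null distribution comes from
  Brownian-motion simulations on the tree with the group factor held
  fixed, so that phylogenetic autocorrelation does not masquerade as a
  group effect.
* ``phylo_manova_pgls`` — a distance/trace MANOVA of a multivariate
  shape matrix fitted by GLS: data and design are whitened by
  ``C^{-1/2}`` so the phylogeny enters the error term, sums of squares
  are traces of residual cross-product matrices, and significance comes
  from randomising reduced-model residuals (RRPP).

Both report the number of null replicates and use the
(1 + count) / (1 + n) p-value convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import PhyloCovariance, PhyloTree, gls_mean, whitening_transform

__all__ = ["TestResult", "phylo_anova", "phylo_manova_pgls"]


@dataclass
class TestResult:
    statistic: float
    df_effect: int
    df_resid: int
    p_value: float
    n_null: int
    method: str = ""

    def __post_init__(self):
        if self.statistic < 0:
            raise ValueError("F statistic must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _group_design(groups) -> tuple[np.ndarray, list]:
    groups = pd.Series(np.asarray(groups))
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with < 2 members: {small}")
    # treatment-coded dummies (first level as baseline)
    G = np.column_stack([(groups == lv).to_numpy(float) for lv in levels[1:]])
    return G, levels


def _anova_f(y: np.ndarray, codes: np.ndarray, g: int) -> float:
    n = y.size
    grand = y.mean()
    ssb = 0.0
    ssw = 0.0
    for k in range(g):
        yk = y[codes == k]
        ssb += yk.size * (yk.mean() - grand) ** 2
        ssw += float(((yk - yk.mean()) ** 2).sum())
    return (ssb / (g - 1)) / (ssw / (n - g))


def phylo_anova(y, groups, tree: PhyloTree, n_sim: int = 999,
                seed: int | None = None) -> TestResult:
    """Simulation-based phylogenetic one-way ANOVA.

    The observed F is the ordinary ANOVA F of ``y`` on ``groups``. The
    null distribution is built by simulating ``n_sim`` Brownian-motion
    datasets on the tree (rate from the GLS estimate on ``y``) and
    recomputing F with the group assignment fixed.
    """
    cov = tree.covariance() if isinstance(tree, PhyloTree) else tree
    if isinstance(y, pd.Series):
        cov = cov.subset(list(y.index))
        if isinstance(groups, pd.Series):
            groups = groups.reindex(cov.species).to_numpy()
        y = y.reindex(cov.species).to_numpy()
    elif isinstance(groups, pd.Series):
        groups = groups.to_numpy()
    y = np.asarray(y, dtype=float)
    n = cov.n
    if y.shape != (n,):
        raise ValueError("y length does not match tree")
    if np.ptp(y) == 0:
        raise ValueError("constant y: ANOVA undefined")
    _, levels = _group_design(groups)
    g = len(levels)
    codes = pd.Series(np.asarray(groups)).map(
        {lv: k for k, lv in enumerate(levels)}).to_numpy()

    f_obs = _anova_f(y, codes, g)

    a_hat = gls_mean(y, cov)
    r = y - a_hat
    sigma2 = float(r @ np.linalg.solve(cov.C, r)) / (n - 1)
    L = np.linalg.cholesky(cov.C + 1e-12 * np.mean(np.diag(cov.C)) * np.eye(n))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sim):
        y_sim = np.sqrt(sigma2) * (L @ rng.standard_normal(n))
        if _anova_f(y_sim, codes, g) >= f_obs:
            count += 1
    p = (1 + count) / (n_sim + 1)
    return TestResult(f_obs, g - 1, n - g, p, n_sim, "phylogenetic ANOVA (BM simulation)")


def phylo_manova_pgls(Y, groups, tree: PhyloTree, n_perm: int = 999,
                      seed: int | None = None) -> TestResult:
    """Distance-based phylogenetic MANOVA via GLS whitening and RRPP.

    Rows of ``Y`` (and the group design) are whitened by the inverse
    square root of the phylogenetic covariance; sums of squares are
    traces of residual cross-products of the full (intercept + groups)
    versus reduced (intercept) linear models, and the p-value comes from
    randomising the reduced-model residual rows (RRPP).
    """
    cov = tree.covariance() if isinstance(tree, PhyloTree) else tree
    if isinstance(Y, pd.DataFrame):
        cov = cov.subset(list(Y.index))
        if isinstance(groups, pd.Series):
            groups = groups.reindex(cov.species).to_numpy()
        Y = Y.reindex(cov.species).to_numpy()
    elif isinstance(groups, pd.Series):
        groups = groups.to_numpy()
    Y = np.asarray(Y, dtype=float)
    n = cov.n
    if Y.ndim != 2 or Y.shape[0] != n:
        raise ValueError("Y must be an n x p matrix aligned to the tree")
    if Y.shape[1] < 2:
        raise ValueError("Y must have >= 2 columns")
    G, levels = _group_design(groups)
    g = len(levels)
    if n <= g + 1:
        raise ValueError("too few observations for the number of groups")

    P = whitening_transform(cov)
    Yt = P @ Y
    Xf = P @ np.column_stack([np.ones(n), G])
    Xr = P @ np.ones((n, 1))
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError("rank-deficient group design")

    def rss(X, Ym):
        beta, *_ = np.linalg.lstsq(X, Ym, rcond=None)
        R = Ym - X @ beta
        return float(np.sum(R * R)), R, X @ beta

    df_e = g - 1
    df_r = n - g

    ss_red, resid_red, fit_red = rss(Xr, Yt)
    ss_full, _, _ = rss(Xf, Yt)
    f_obs = ((ss_red - ss_full) / df_e) / (ss_full / df_r)

    # precompute hat projections for speed inside the permutation loop
    Qf, _ = np.linalg.qr(Xf)
    Qr, _ = np.linalg.qr(Xr)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        Yp = fit_red + resid_red[rng.permutation(n)]
        ss_r = float(np.sum((Yp - Qr @ (Qr.T @ Yp)) ** 2))
        ss_f = float(np.sum((Yp - Qf @ (Qf.T @ Yp)) ** 2))
        f_p = ((ss_r - ss_f) / df_e) / (ss_f / df_r)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return TestResult(f_obs, df_e, df_r, p, n_perm,
                      "phylogenetic MANOVA (GLS whitening, RRPP)")
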