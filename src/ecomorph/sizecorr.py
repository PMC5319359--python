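"""Phylogenetic size correction of morphometric traits.

Species spanning a large body-size range (rodents cover ~2000-fold in
mass) differ in trait values mostly because they differ in size. The
package removes this by regressing each log-transformed linear
measurement on log body mass with phylogenetic generalised least squares
(PGLS) under the Pagel-lambda error structure, and keeping the ordinary
(response-scale) residuals as "non-allometric shape" variables.

Because the phylogeny itself is uncertain, the regression is repeated
over an ensemble of candidate trees and the residuals averaged across
trees. The condylar-process angle (ACP) is not expected to scale with
size: it bypasses the regression and is only mean-centred.

A Mosimann log-shape-ratio transform is provided as the allometry-
preserving fallback used when body size differs among ecological groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .trees import PhyloCovariance, TreeEnsemble, lambda_transform

__all__ = [
    "TRAIT_COLUMNS",
    "RESIDUAL_COLUMNS",
    "LINEAR_VARS",
    "PGLS",
    "PGLSResults",
    "pgls_fit",
    "size_correct_ensemble",
    "log_shape_ratios",
    "validate_trait_table",
]

#: all measured characters (mm except ACP in degrees) plus body mass (g)
TRAIT_COLUMNS = [
    "mass_g", "HB", "T", "E", "Vib", "HF", "FF", "UM",
    "CBL", "LR", "ZB", "BIT", "LMT", "HMC", "ACP",
]

#: the 11 linear variables carried into downstream analyses
LINEAR_VARS = ["LR", "ZB", "BIT", "LMT", "HMC", "T", "E", "Vib", "HF", "FF", "UM"]

#: canonical column order of the size-corrected shape matrix
RESIDUAL_COLUMNS = ["LR", "ZB", "BIT", "LMT", "HMC", "ACP", "T", "E", "Vib", "HF", "FF", "UM"]


def validate_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Check a species x trait table against the measurement invariants.

    Requires unique species (index), the full column set, strictly
    positive lengths/mass, ACP in (0, 180) degrees, and no missing
    values (missing measurements are an error, not an imputation case).
    """
    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if traits.index.duplicated().any():
        raise ValueError("duplicate species in trait table")
    df = traits[TRAIT_COLUMNS].astype(float)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing measurements for species: {bad[:5]}")
    linear = df.drop(columns=["ACP"])
    if (linear <= 0).any().any():
        raise ValueError("nonpositive measurement in trait table")
    if ((df["ACP"] <= 0) | (df["ACP"] >= 180)).any():
        raise ValueError("ACP must lie strictly between 0 and 180 degrees")
    return df


class PGLS:
    """Phylogenetic generalised least squares with Pagel-lambda errors.

    The model is ``y = X @ beta + e`` with
    ``e ~ N(0, sigma2 * C_lambda)`` where ``C_lambda`` multiplies the
    off-diagonal entries of the phylogenetic covariance by ``lambda``.
    ``fit()`` profiles the likelihood over ``lambda`` in [0, 1].

    Parameters
    ----------
    endog : array-like, length n
        Response, aligned to ``cov.species``.
    exog : array-like, length n or shape (n, k)
        Predictor(s); an intercept column is added automatically.
    cov : PhyloCovariance
        Brownian covariance of the tips.
    """

    def __init__(self, endog, exog, cov: PhyloCovariance):
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        n = cov.n
        if y.shape != (n,) or x.shape[0] != n:
            raise ValueError("endog/exog length does not match covariance")
        if not (np.isfinite(y).all() and np.isfinite(x).all()):
            raise ValueError("non-finite values in endog/exog")
        if n < 4:
            raise ValueError("PGLS requires n >= 4")
        self.endog = y
        self.exog = np.column_stack([np.ones(n), x])
        self.cov = cov
        self.nobs = n

    def _profile(self, lam: float):
        """beta-hat, ML sigma2, residuals and log-likelihood at fixed lambda."""
        Cl = lambda_transform(self.cov, lam).C
        n = self.nobs
        try:
            L = np.linalg.cholesky(Cl)
        except np.linalg.LinAlgError:
            from .trees import RIDGE_FACTOR
            L = np.linalg.cholesky(Cl + RIDGE_FACTOR * np.mean(np.diag(Cl)) * np.eye(n))
        # whiten by back-substitution: solve L z = v
        zy = np.linalg.solve(L, self.endog)
        zX = np.linalg.solve(L, self.exog)
        beta, _, rank, _ = np.linalg.lstsq(zX, zy, rcond=None)
        if rank < self.exog.shape[1]:
            raise np.linalg.LinAlgError("singular design in PGLS")
        resid = self.endog - self.exog @ beta
        zr = zy - zX @ beta
        sigma2 = float(zr @ zr) / n
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        llf = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
        return beta, sigma2, resid, llf

    def fit(self, xtol: float = 1e-6) -> "PGLSResults":
        """Maximise the profile likelihood over lambda in [0, 1]."""
        res = optimize.minimize_scalar(
            lambda lam: -self._profile(lam)[3],
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": xtol},
        )
        # the profile can be monotone; compare the interior optimum
        # against both boundary values explicitly
        candidates = [(float(res.x), -float(res.fun))]
        for lam in (0.0, 1.0):
            candidates.append((lam, self._profile(lam)[3]))
        lam_hat, llf = max(candidates, key=lambda t: t[1])
        beta, sigma2, resid, _ = self._profile(lam_hat)
        return PGLSResults(self, beta, lam_hat, sigma2, llf, resid)


@dataclass
class PGLSResults:
    """Results of a PGLS fit (coefficients on the original scale).

    ``resid`` is the ordinary response-scale residual ``y - X @ params``
    (not GLS-whitened) — the quantity used as a shape variable.
    """

    model: PGLS
    params: np.ndarray
    lambda_: float
    sigma2: float
    llf: float
    resid: np.ndarray

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.params

    def bse(self) -> np.ndarray:
        """Standard errors from the lambda-profiled GLS information."""
        Cl = lambda_transform(self.model.cov, self.lambda_).C
        Xt_Cinv_X = self.model.exog.T @ np.linalg.solve(Cl, self.model.exog)
        k = self.model.exog.shape[1]
        s2 = self.sigma2 * self.model.nobs / (self.model.nobs - k)
        return np.sqrt(np.diag(s2 * np.linalg.inv(Xt_Cinv_X)))

    def summary(self) -> str:
        names = ["intercept"] + [f"x{i}" for i in range(1, len(self.params))]
        se = self.bse()
        lines = [
            "PGLS (Pagel-lambda error structure)",
            f"  n = {self.model.nobs}   lambda = {self.lambda_:.4f}   "
            f"sigma2 = {self.sigma2:.5g}   loglik = {self.llf:.3f}",
            f"  {'term':<10}{'coef':>12}{'se':>12}",
        ]
        for name, b, s in zip(names, self.params, se):
            lines.append(f"  {name:<10}{b:>12.5f}{s:>12.5f}")
        return "\n".join(lines)


def pgls_fit(y, x, cov: PhyloCovariance) -> PGLSResults:
    """Convenience wrapper: fit ``y ~ 1 + x`` by lambda-PGLS."""
    return PGLS(y, x, cov).fit()


def size_correct_ensemble(
    traits: pd.DataFrame, ensemble: TreeEnsemble, return_fits: bool = False
):
    """Tree-ensemble-averaged size correction of the 12 shape variables.

    For each tree and each of the 11 linear variables, fits
    ``log(trait) ~ log(mass_g)`` by lambda-PGLS and keeps the ordinary
    residuals; residuals are then averaged across trees. ACP is passed
    through centred on its cross-species mean (it does not scale with
    size, and centring makes all 12 columns comparable in location).

    Returns a species x 12 DataFrame in ``RESIDUAL_COLUMNS`` order,
    rows sorted by species name. With ``return_fits=True`` also returns
    a long DataFrame of the per-tree per-variable regression estimates
    (intercept, slope, lambda) for robustness reporting.
    """
    df = validate_trait_table(traits)
    species = sorted(df.index)
    missing = [s for s in species if s not in set(ensemble.tips)]
    if missing:
        raise ValueError(f"species missing from trees: {missing[:5]}")
    df = df.loc[species]
    logmass = np.log(df["mass_g"].to_numpy())

    acc = np.zeros((len(species), len(LINEAR_VARS)))
    fit_rows = []
    for t, tree in enumerate(ensemble):
        cov = tree.covariance().subset(species)
        for j, var in enumerate(LINEAR_VARS):
            res = pgls_fit(np.log(df[var].to_numpy()), logmass, cov)
            acc[:, j] += res.resid
            if return_fits:
                fit_rows.append((t, var, res.params[0], res.params[1],
                                 res.lambda_))
    acc /= len(ensemble)

    out = pd.DataFrame(acc, index=pd.Index(species, name="species"),
                       columns=LINEAR_VARS)
    out["ACP"] = df["ACP"] - df["ACP"].mean()
    out = out[RESIDUAL_COLUMNS]
    if return_fits:
        fits = pd.DataFrame(
            fit_rows, columns=["tree", "variable", "intercept", "slope", "lambda"])
        return out, fits
    return out


def log_shape_ratios(traits: pd.DataFrame) -> pd.DataFrame:
    """Mosimann log-shape ratios of the 11 linear variables.

    Each variable becomes ``log(v / g)`` with ``g`` the per-species
    geometric mean of the 11 linear measurements, preserving allometric
    shape variation (used when body size differs among groups and plain
    residuals would discard meaningful allometry).
    """
    df = validate_trait_table(traits)
    lin = df[LINEAR_VARS]
    logs = np.log(lin.to_numpy())
    ratios = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(ratios, index=df.index, columns=LINEAR_VARS)
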