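"""Flexible discriminant analysis and its phylogenetic variant.

Flexible discriminant analysis (FDA) recasts discrimination as
regression by *optimal scoring*: regress the class-indicator matrix on
the predictors, then find score vectors ``theta`` maximising the
canonical correlation between indicators and fitted values. In the
linear case the resulting discriminant variates coincide with LDA's
canonical variates, but the regression formulation makes the method
compatible with generalised least squares.

The phylogenetic variant (pFDA) whitens both predictors and indicators
by ``P_lambda = C_lambda^{-1/2}`` — the inverse square root of the
Pagel-lambda-transformed phylogenetic covariance — before optimal
scoring, so that projections into discriminant space are evolutionarily
orthogonal. The amount of phylogenetic correction, ``lambda``, is chosen
by minimising the residual sum of squares of the whitened
indicator-on-predictor regression; ``lambda = 0`` on an ultrametric tree
reduces exactly to the non-phylogenetic analysis.

Also here: stratified cross-validation of classification accuracy,
per-variable Wilks'-lambda discriminant power with its F approximation,
and variable-versus-discriminant-function structure correlations with
Holm-corrected significance flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

from .trees import PhyloCovariance, lambda_transform, whitening_transform

__all__ = [
    "FlexibleDiscriminant",
    "PhylogeneticFDA",
    "DiscriminantResults",
    "CVResult",
    "StructureCorrelations",
    "fda_fit",
    "pfda_fit",
    "fda_predict",
    "cross_validate",
    "optimal_lambda",
    "wilks_power",
    "structure_correlations",
    "DIET_CODES",
    "LOCOMOTION_CODES",
]

DIET_CODES = ["C", "I", "GH", "SH", "U"]
LOCOMOTION_CODES = ["T", "Sa", "A", "Sf", "F", "R", "G", "U"]

_EPS = 1e-12


def _check_xy(X, labels):
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        index = list(X.index)
        Xv = X.to_numpy(float)
    else:
        Xv = np.asarray(X, dtype=float)
        columns = [f"x{j + 1}" for j in range(Xv.shape[1])]
        index = list(range(Xv.shape[0]))
    labels = pd.Series(np.asarray(labels), index=index)
    if "U" in set(labels):
        raise ValueError('training labels contain "U" (unknown); drop them first')
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"classes with < 2 members: {counts[counts < 2].index.tolist()}")
    if Xv.shape[0] <= len(classes):
        raise ValueError("need more observations than classes")
    if not np.isfinite(Xv).all():
        raise ValueError("non-finite predictor values")
    return Xv, labels, classes, columns, index


def _indicator(labels: pd.Series, classes: list) -> np.ndarray:
    return np.column_stack([(labels == c).to_numpy(float) for c in classes])


def _optimal_scoring(Xd: np.ndarray, Yt: np.ndarray):
    """Optimal scoring of (possibly whitened) indicators on a design.

    Returns regression coefficients ``B`` (design x g), score vectors
    ``Theta`` (g x K) excluding the trivial constant score, and the
    squared canonical correlations ``alpha2`` (K, nonincreasing).
    """
    B, _, rank, _ = np.linalg.lstsq(Xd, Yt, rcond=None)
    Yhat = Xd @ B
    A = Yt.T @ Yhat          # symmetric PSD (hat matrix quadratic form)
    Bm = Yt.T @ Yt
    g = Yt.shape[1]
    # deflate the trivial score theta = 1 (eigenvalue 1): restrict theta
    # to the complement of 1 under the Bm inner product, i.e. m' theta = 0
    # with m = Bm @ 1
    m = Bm @ np.ones(g)
    Hc = linalg.null_space(m[None, :])
    Ar = Hc.T @ ((A + A.T) / 2) @ Hc
    Br = Hc.T @ Bm @ Hc
    alpha2, V = linalg.eigh(Ar, Br)
    order = np.argsort(alpha2)[::-1]
    alpha2 = np.clip(alpha2[order], 0.0, 1.0 - 1e-10)
    Theta = Hc @ V[:, order]
    return B, Theta, alpha2


@dataclass
class DiscriminantResults:
    """Fitted discriminant model (FDA or pFDA).

    ``coefficients`` maps centred predictors to discriminant scores
    (species-level, response scale); within-class covariance of the
    training scores is spherical, so classification is nearest-centroid
    Euclidean distance in score space.
    """

    coefficients: pd.DataFrame          # p x K
    const: np.ndarray                   # K offsets
    class_centroids: pd.DataFrame       # g x K
    eigenvalues: np.ndarray             # K, nonincreasing
    percent_between: np.ndarray         # K, sums to 100
    canonical_corr2: np.ndarray         # alpha_k^2
    lambda_used: float
    training_species: list
    classes: list
    x_mean: pd.Series
    scores: pd.DataFrame                # training species x K

    @property
    def n_functions(self) -> int:
        return self.coefficients.shape[1]

    def transform(self, X_new) -> pd.DataFrame:
        """Discriminant scores for new data (columns checked/reordered)."""
        cols = list(self.coefficients.index)
        if isinstance(X_new, pd.DataFrame):
            missing = [c for c in cols if c not in X_new.columns]
            if missing:
                raise ValueError(f"missing predictor columns: {missing}")
            Xv = X_new[cols].to_numpy(float)
            index = X_new.index
        else:
            Xv = np.asarray(X_new, dtype=float)
            if Xv.ndim == 1:
                Xv = Xv[None, :]
            if Xv.shape[1] != len(cols):
                raise ValueError(
                    f"expected {len(cols)} predictor columns, got {Xv.shape[1]}")
            index = pd.RangeIndex(Xv.shape[0])
        S = (Xv - self.x_mean.to_numpy()) @ self.coefficients.to_numpy() + self.const
        return pd.DataFrame(S, index=index, columns=self.coefficients.columns)

    def predict(self, X_new) -> pd.Series:
        """Nearest-centroid classification; ties break lexicographically."""
        S_df = self.transform(X_new)
        S = S_df.to_numpy()
        cents = self.class_centroids.to_numpy()
        d2 = ((S[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        # classes are stored sorted, so argmin's first minimum is the
        # lexicographic tie-break
        d2r = np.round(d2, 12)
        pred = [self.classes[k] for k in d2r.argmin(axis=1)]
        return pd.Series(pred, index=S_df.index, name="predicted")

    def summary(self) -> str:
        kind = "pFDA" if self.lambda_used > 0 else "FDA"
        lines = [
            f"Flexible discriminant analysis ({kind}, lambda = {self.lambda_used:.4f})",
            f"  classes: {self.classes}   n = {len(self.training_species)}",
            "  " + "".join(f"{c:>10}" for c in self.coefficients.columns),
            "  eigenvalue" + "".join(f"{v:>10.4f}" for v in self.eigenvalues),
            "  % between" + " " + "".join(f"{v:>10.2f}" for v in self.percent_between),
        ]
        return "\n".join(lines)


class FlexibleDiscriminant:
    """FDA model: optimal scoring of class indicators on predictors."""

    def __init__(self, X, labels):
        (self.X, self.labels, self.classes,
         self.columns, self.index) = _check_xy(X, labels)

    def _finish(self, B, Theta, alpha2, lambda_used: float) -> DiscriminantResults:
        K = min(len(self.classes) - 1, Theta.shape[1])
        Theta = Theta[:, :K]
        alpha2 = alpha2[:K]
        coef = (B @ Theta)[1:, :]
        const = (B @ Theta)[0, :]
        xmean = self.X.mean(axis=0)
        scores = (self.X - xmean) @ coef + const
        # rescale each variate to unit pooled within-class variance so the
        # discriminant space is spherical for nearest-centroid rules
        g = len(self.classes)
        resid = scores.copy()
        for c in self.classes:
            mask = (self.labels == c).to_numpy()
            resid[mask] -= scores[mask].mean(axis=0)
        wvar = (resid**2).sum(axis=0) / (scores.shape[0] - g)
        scale = 1.0 / np.sqrt(np.maximum(wvar, _EPS))
        coef = coef * scale
        const = const * scale
        scores = scores * scale

        dfn = [f"DF{k + 1}" for k in range(K)]
        scores_df = pd.DataFrame(scores, index=self.index, columns=dfn)
        centroids = scores_df.groupby(self.labels.to_numpy()).mean()
        centroids = centroids.loc[self.classes]
        eig = alpha2 / (1.0 - alpha2)
        pct = 100.0 * eig / eig.sum()
        return DiscriminantResults(
            coefficients=pd.DataFrame(coef, index=self.columns, columns=dfn),
            const=const,
            class_centroids=centroids,
            eigenvalues=eig,
            percent_between=pct,
            canonical_corr2=alpha2,
            lambda_used=lambda_used,
            training_species=list(self.index),
            classes=self.classes,
            x_mean=pd.Series(xmean, index=self.columns),
            scores=scores_df,
        )

    def fit(self) -> DiscriminantResults:
        n = self.X.shape[0]
        Xc = self.X - self.X.mean(axis=0)
        Xd = np.column_stack([np.ones(n), Xc])
        Y = _indicator(self.labels, self.classes)
        B, Theta, alpha2 = _optimal_scoring(Xd, Y)
        # express coefficients w.r.t. raw (uncentred) design for _finish:
        # design used centred X, so B rows align with [1, Xc]
        return self._finish(B, Theta, alpha2, 0.0)


class PhylogeneticFDA(FlexibleDiscriminant):
    """pFDA model: optimal scoring after phylogenetic whitening.

    Predictors (centred), intercept and indicators are premultiplied by
    ``P_lambda = C_lambda^{-1/2}`` before optimal scoring. Coefficients
    are reported on the untransformed scale and applied to centred new
    data directly (unknown species' phylogenetic positions are not
    re-whitened; with the small optimal lambdas typical of weakly
    conserved ecologies the correction to predictions is negligible).
    """

    def __init__(self, X, labels, cov: PhyloCovariance, lam: float):
        super().__init__(X, labels)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        if list(cov.species) != list(self.index):
            raise ValueError("covariance species do not match X rows")
        self.cov = cov
        self.lam = float(lam)

    def fit(self) -> DiscriminantResults:
        n = self.X.shape[0]
        P = whitening_transform(lambda_transform(self.cov, self.lam))
        Xc = self.X - self.X.mean(axis=0)
        Xd = P @ np.column_stack([np.ones(n), Xc])
        Yt = P @ _indicator(self.labels, self.classes)
        B, Theta, alpha2 = _optimal_scoring(Xd, Yt)
        return self._finish(B, Theta, alpha2, self.lam)


def fda_fit(X, labels) -> DiscriminantResults:
    """Fit a standard (non-phylogenetic) flexible discriminant analysis."""
    return FlexibleDiscriminant(X, labels).fit()


def pfda_fit(X, labels, cov: PhyloCovariance, lam: float) -> DiscriminantResults:
    """Fit a phylogenetic FDA at a given Pagel's lambda."""
    return PhylogeneticFDA(X, labels, cov, lam).fit()


def fda_predict(model: DiscriminantResults, X_new):
    """Predicted labels and discriminant scores for new observations."""
    return model.predict(X_new), model.transform(X_new)


@dataclass
class CVResult:
    """Pooled cross-validation classification summary."""

    overall_correct: float
    per_class_correct: pd.Series
    confusion: pd.DataFrame            # rows = true class, cols = predicted
    n_partitions: int


def cross_validate(X, labels, n_partitions: int = 10,
                   seed: int | None = None,
                   fitter=None) -> CVResult:
    """Stratified k-fold cross-validated classification accuracy.

    Species are partitioned within each class (so folds preserve class
    frequencies), the model is fitted on k-1 folds and evaluated on the
    held-out fold, and the confusion counts are pooled. If the smallest
    class has fewer members than ``n_partitions`` the fold count is
    reduced to that size with a warning; classes with fewer than 3
    members cannot be both trained on and held out and are dropped with
    a warning.
    """
    Xv, lab, classes, columns, index = _check_xy(X, labels)
    if Xv.shape[0] < 2 * len(classes):
        raise ValueError("too few observations for cross-validation")
    fitter = fitter or fda_fit
    counts = lab.value_counts()
    tiny = counts.index[counts < 3]
    if len(tiny):
        warnings.warn(
            f"dropping classes with < 3 members from cross-validation: "
            f"{sorted(tiny)}", RuntimeWarning, stacklevel=2)
        keep = ~lab.isin(tiny).to_numpy()
        Xv, lab = Xv[keep], lab[keep]
        index = [i for i, k_ in zip(index, keep) if k_]
        classes = sorted(lab.unique())
        counts = lab.value_counts()
    k = int(min(n_partitions, counts.min()))
    if k < n_partitions:
        warnings.warn(
            f"reducing folds from {n_partitions} to {k} "
            f"(smallest class has {counts.min()} members)",
            RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    fold = np.empty(Xv.shape[0], dtype=int)
    for c in classes:
        ix = np.flatnonzero((lab == c).to_numpy())
        rng.shuffle(ix)
        fold[ix] = np.arange(ix.size) % k

    Xdf = pd.DataFrame(Xv, index=index, columns=columns)
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for f in range(k):
        train = fold != f
        model = fitter(Xdf.iloc[train], lab.iloc[train])
        pred = model.predict(Xdf.iloc[~train])
        for true_c, pred_c in zip(lab.iloc[~train], pred):
            confusion.loc[true_c, pred_c] += 1
    correct = np.diag(confusion.to_numpy()).sum()
    per_class = pd.Series(
        np.diag(confusion.to_numpy()) / confusion.sum(axis=1).to_numpy(),
        index=classes, name="proportion_correct")
    return CVResult(correct / confusion.to_numpy().sum(), per_class, confusion, k)


def _pfda_rss(X: np.ndarray, Y: np.ndarray, cov: PhyloCovariance,
              lam: float) -> float:
    n = X.shape[0]
    P = whitening_transform(lambda_transform(cov, lam))
    Xd = P @ np.column_stack([np.ones(n), X])
    Yt = P @ Y
    Bh, *_ = np.linalg.lstsq(Xd, Yt, rcond=None)
    R = Yt - Xd @ Bh
    return float(np.sum(R * R))


def optimal_lambda(X, labels, cov: PhyloCovariance,
                   grid_step: float = 0.01) -> float:
    """Profile the pFDA residual sum of squares over lambda in [0, 1].

    A full grid pre-scan (the profile can be multimodal) is followed by
    bounded scalar refinement around the best grid point. A flat profile
    (e.g. a star phylogeny, where the whitening is constant) returns 0
    by convention.
    """
    Xv, lab, classes, _, index = _check_xy(X, labels)
    if list(cov.species) != list(index):
        raise ValueError("covariance species do not match X rows")
    Xc = Xv - Xv.mean(axis=0)
    Y = _indicator(lab, classes)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rss = np.array([_pfda_rss(Xc, Y, cov, l) for l in grid])
        if rss.max() - rss.min() <= 1e-10 * max(rss.max(), 1.0):
            return 0.0
        j = int(rss.argmin())
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda l: _pfda_rss(Xc, Y, cov, l),
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-6})
    return float(res.x) if res.fun <= rss[j] else float(grid[j])


def wilks_power(X, labels) -> pd.DataFrame:
    """Per-variable Wilks' lambda, F approximation and p-value.

    For variable j, ``Lambda_j = SSW_j / SST_j`` from a one-way
    decomposition over the classes; small values indicate high
    discriminant power. ``F = ((1 - L)/L) * ((n - g)/(g - 1))`` is
    referred to the F(g-1, n-g) upper tail. A constant variable gets
    Lambda = 1, F = 0, p = 1 with a warning.
    """
    Xv, lab, classes, columns, _ = _check_xy(X, labels)
    n = Xv.shape[0]
    g = len(classes)
    rows = []
    for j, var in enumerate(columns):
        x = Xv[:, j]
        sst = float(((x - x.mean()) ** 2).sum())
        if sst == 0.0:
            warnings.warn(f"constant variable {var!r}: Wilks' lambda undefined",
                          RuntimeWarning, stacklevel=2)
            rows.append((var, 1.0, 0.0, 1.0))
            continue
        ssw = 0.0
        for c in classes:
            xc = x[(lab == c).to_numpy()]
            ssw += float(((xc - xc.mean()) ** 2).sum())
        lam = ssw / sst
        F = ((1.0 - lam) / lam) * ((n - g) / (g - 1))
        p = float(stats.f.sf(F, g - 1, n - g))
        rows.append((var, lam, F, p))
    return pd.DataFrame(rows, columns=["variable", "wilks_lambda", "F", "p"]
                        ).set_index("variable")


@dataclass
class StructureCorrelations:
    """Variable x discriminant-function correlation table."""

    r: pd.DataFrame
    p: pd.DataFrame
    p_holm: pd.DataFrame
    significant: pd.DataFrame           # Holm-adjusted p < 0.05


def structure_correlations(model: DiscriminantResults, X,
                           alpha: float = 0.05) -> StructureCorrelations:
    """Pearson correlations between variables and discriminant scores.

    Computed over the training species; two-sided p-values per cell with
    a Holm correction applied across the entire variable x DF table.
    """
    cols = list(model.coefficients.index)
    if isinstance(X, pd.DataFrame):
        X = X.loc[model.training_species, cols]
        Xv = X.to_numpy(float)
    else:
        Xv = np.asarray(X, dtype=float)
    if Xv.shape[0] < 3:
        raise ValueError("need >= 3 training rows for correlations")
    S = model.scores.to_numpy()
    dfn = list(model.scores.columns)
    r = np.empty((len(cols), len(dfn)))
    p = np.empty_like(r)
    for i in range(len(cols)):
        for k in range(len(dfn)):
            r[i, k], p[i, k] = stats.pearsonr(Xv[:, i], S[:, k])
    flat_adj = multipletests(p.ravel(), alpha=alpha, method="holm")[1]
    p_holm = flat_adj.reshape(p.shape)
    mk = lambda M: pd.DataFrame(M, index=cols, columns=dfn)
    return StructureCorrelations(mk(r), mk(p), mk(p_holm),
                                 mk(p_holm < alpha))
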