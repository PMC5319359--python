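"""Two-dimensional morphospace via Sammon's nonlinear mapping.

Sammon mapping embeds points in the plane by minimising

    E = (1 / sum d_ij) * sum (d_ij - e_ij)^2 / d_ij

over pairs i < j, where ``d`` are the input (high-dimensional
Euclidean) distances and ``e`` the embedded 2-D distances. The
1/d weighting preserves small distances preferentially, which suits
morphospace interpretation where local neighbourhoods matter most.

Minimisation follows Sammon's diagonal-Newton iteration with the
classical step factor 0.3, halved whenever a step would increase the
stress, starting from the (deterministic) first two principal
coordinates. Stress is invariant to a global rescaling of the input
distances and to rigid motions of the configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["OrdinationResult", "sammon", "plot_morphospace"]


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame       # points x 2
    stress: float
    n_iter: int
    converged: bool
    #: stress after each accepted iteration (nonincreasing)
    stress_path: np.ndarray


def _pcoa_init(D: np.ndarray) -> np.ndarray:
    """Classical-scaling (principal coordinates) 2-D start configuration."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, E = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1][:2]
    w2 = np.clip(w[order], 0.0, None)
    Y = E[:, order] * np.sqrt(w2)
    if np.allclose(Y[:, 1], 0.0):       # collinear input: break the tie
        Y[:, 1] = 1e-6 * np.arange(n)
    return Y


def sammon(X, seed: int | None = None, max_iter: int = 500,
           tol: float = 1e-9, magic: float = 0.3) -> OrdinationResult:
    """Sammon nonlinear mapping of data (or a distance matrix) to 2-D.

    Parameters
    ----------
    X
        Either an n x p data matrix (DataFrame or array; Euclidean
        distances are taken) or an n x n symmetric distance matrix.
    seed
        Only used to jitter exact duplicate points (zero input
        distance), which the 1/d weighting cannot accommodate.
    max_iter, tol
        Iteration cap and relative stress-change convergence tolerance.
    magic
        Sammon's step-size factor; halved on any stress increase.
    """
    if isinstance(X, pd.DataFrame):
        index = X.index
        A = X.to_numpy(float)
    else:
        A = np.asarray(X, dtype=float)
        index = pd.RangeIndex(A.shape[0])
    if not np.isfinite(A).all():
        raise ValueError("non-finite input")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need >= 3 points")
    is_dist = (A.shape[0] == A.shape[1] and np.allclose(A, A.T)
               and np.allclose(np.diag(A), 0.0))
    D = A.copy() if is_dist else squareform(pdist(A))

    off = D[~np.eye(n, dtype=bool)]
    if (off <= 0).any():
        rng = np.random.default_rng(seed)
        jit = 1e-8 * off[off > 0].mean() if (off > 0).any() else 1e-8
        warnings.warn("zero distance between distinct points; jittering",
                      RuntimeWarning, stacklevel=2)
        D = D + jit * (1 + rng.random((n, n)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)

    iu = np.triu_indices(n, k=1)
    d = D[iu]
    c = d.sum()

    def stress(Y: np.ndarray) -> float:
        e = pdist(Y)
        return float(np.sum((d - e) ** 2 / d) / c)

    Y = _pcoa_init(D)
    E = stress(Y)
    path = [E]
    step = magic
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        e_mat = squareform(pdist(Y))
        np.fill_diagonal(e_mat, 1.0)
        e_mat = np.maximum(e_mat, 1e-12)  # coincident embedded points
        Dm = D.copy()
        np.fill_diagonal(Dm, 1.0)
        diff = Dm - e_mat
        # first and (absolute) second partial derivatives, Sammon (1969)
        w1 = diff / (Dm * e_mat)
        np.fill_diagonal(w1, 0.0)
        delta = Y[:, None, :] - Y[None, :, :]
        grad = -2.0 / c * np.einsum("ij,ijk->ik", w1, delta)
        w2 = (1.0 / (Dm * e_mat))
        np.fill_diagonal(w2, 0.0)
        term = (diff[..., None]
                - (delta**2) / e_mat[..., None]
                * (1.0 + diff[..., None] / e_mat[..., None]))
        hess = -2.0 / c * (w2[..., None] * term).sum(axis=1)
        denom = np.abs(hess)
        denom[denom < 1e-12] = 1e-12
        direction = grad / denom

        accepted = False
        s = step
        for _ in range(30):
            Y_new = Y - s * direction
            E_new = stress(Y_new)
            if E_new < E:
                accepted = True
                break
            s /= 2.0
        if not accepted:
            converged = True
            break
        rel = (E - E_new) / max(E, 1e-300)
        Y, E = Y_new, E_new
        path.append(E)
        if rel < tol:
            converged = True
            break

    coords = pd.DataFrame(Y, index=index, columns=["axis1", "axis2"])
    return OrdinationResult(coords, E, it, converged, np.asarray(path))


def plot_morphospace(result: OrdinationResult, labels=None, ax=None):
    """Minimal scatter of the 2-D morphospace, coloured by category.

    Requires matplotlib (the ``plot`` extra). Note the affine-morphospace
    caveat: with mixed angular/linear inputs, distances in the plot are
    similarity rankings, not strict Euclidean dissimilarities.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xy = result.coordinates
    if labels is None:
        ax.scatter(xy["axis1"], xy["axis2"], s=12, color="0.4")
    else:
        labels = pd.Series(labels).reindex(xy.index)
        for cat in sorted(labels.dropna().unique()):
            m = (labels == cat).to_numpy()
            ax.scatter(xy["axis1"][m], xy["axis2"][m], s=12, label=str(cat))
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("nMDS axis 1")
    ax.set_ylabel("nMDS axis 2")
    ax.set_title(f"Sammon morphospace (stress = {result.stress:.4f})")
    return ax
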