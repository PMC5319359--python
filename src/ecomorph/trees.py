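"""Tree I/O and phylogenetic covariance structures.

A rooted tree with branch lengths induces the Brownian-motion covariance
matrix ``C`` of tip values: ``C[i, j]`` is the shared root-to-MRCA path
length of tips *i* and *j*, and ``C[i, i]`` is the root-to-tip depth.
Everything downstream (PGLS, signal statistics, phylogenetic discriminant
analysis) is expressed in terms of ``C`` and two of its transforms:

* Pagel's lambda transform, which shrinks off-diagonal entries toward zero
  (``lam = 0`` removes all phylogenetic dependence, ``lam = 1`` keeps full
  Brownian structure);
* the symmetric whitening matrix ``P = C^{-1/2}`` satisfying
  ``P @ C @ P.T = I``, used to de-correlate data before ordinary
  least-squares machinery is applied.

All matrices follow a single tip-order convention: species sorted by name.
Data tables must be re-indexed to this order before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "TreeEnsemble",
    "read_trees",
    "phylo_covariance",
    "lambda_transform",
    "whitening_transform",
    "gls_mean",
]

#: relative ridge added to a numerically singular covariance diagonal
RIDGE_FACTOR = 1e-8


class PhyloTree:
    """Rooted, tip-labelled phylogenetic tree with branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the
    package's invariants (unique tip names, non-negative branch lengths,
    at least 3 tips) and exposes the matrices the comparative methods
    need. Multifurcations are allowed; trees need not be ultrametric.
    """

    def __init__(self, tree: dendropy.Tree):
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) < 3:
            raise ValueError(f"tree must have >= 3 tips, got {len(tips)}")
        if len(set(tips)) != len(tips):
            raise ValueError("tip names are not unique")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has missing branch lengths")
            if edge.length < 0:
                raise ValueError(f"negative branch length: {edge.length}")
        self._tree = tree
        #: tip names in the canonical (sorted) order
        self.tips: list[str] = sorted(tips)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def depths(self) -> np.ndarray:
        """Root-to-tip path lengths in canonical tip order."""
        return np.diag(self.covariance().C)

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = self.depths()
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1.0))

    def covariance(self) -> "PhyloCovariance":
        return phylo_covariance(self)

    def prune_to(self, species) -> "PhyloTree":
        """Subtree induced by a species subset (branch lengths preserved)."""
        keep = set(species)
        missing = keep - set(self.tips)
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)[:5]}")
        sub = self._tree.extract_tree_with_taxa_labels(labels=keep)
        return PhyloTree(sub)

    def patristic_distances(self) -> np.ndarray:
        """Pairwise path-length (patristic) distance matrix, tip order."""
        C = self.covariance().C
        depth = np.diag(C)
        return depth[:, None] + depth[None, :] - 2.0 * C


@dataclass
class PhyloCovariance:
    """Phylogenetic covariance matrix with its species ordering."""

    species: list[str]
    C: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.species)
        if self.C.shape != (n, n):
            raise ValueError("C shape does not match species list")
        if not np.allclose(self.C, self.C.T, atol=1e-10):
            raise ValueError("C is not symmetric")

    @property
    def n(self) -> int:
        return len(self.species)

    def subset(self, species) -> "PhyloCovariance":
        """Marginal covariance of a species subset (kept in sorted order)."""
        species = sorted(species)
        pos = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in species if s not in pos]
        if missing:
            raise ValueError(f"species not in covariance: {missing[:5]}")
        idx = [pos[s] for s in species]
        return PhyloCovariance(species, self.C[np.ix_(idx, idx)])

    def lambda_transform(self, lam: float) -> "PhyloCovariance":
        return lambda_transform(self, lam)

    def whitening(self) -> np.ndarray:
        return whitening_transform(self)

    def inv(self) -> np.ndarray:
        """Inverse of C, applying the ridge policy if C is singular."""
        P = whitening_transform(self)
        return P @ P


class TreeEnsemble:
    """A list of trees over an identical tip set (phylogenetic uncertainty).

    Comparative analyses are repeated over every member so that
    conclusions do not hinge on any single phylogenetic hypothesis.
    """

    def __init__(self, trees: list[PhyloTree]):
        if len(trees) < 1:
            raise ValueError("ensemble must contain at least one tree")
        ref = set(trees[0].tips)
        for i, t in enumerate(trees[1:], start=1):
            if set(t.tips) != ref:
                extra = set(t.tips) ^ ref
                raise ValueError(
                    f"tree {i} tip set differs from tree 0 "
                    f"(symmetric difference: {sorted(extra)[:5]} ...)"
                )
        self.trees = list(trees)
        self.tips = trees[0].tips

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    def write(self, path: str, schema: str = "newick") -> None:
        tl = dendropy.TreeList([t.dendropy_tree for t in self.trees])
        tl.write(path=path, schema=schema)


def read_trees(source, schema: str = "newick") -> TreeEnsemble:
    """Read one or more trees from a file path, file object or text.

    Parameters
    ----------
    source
        Path to a file, an open file object, or the tree text itself.
    schema
        ``"newick"`` or ``"nexus"``.

    Returns
    -------
    TreeEnsemble
        All trees found in the source; their tip sets must be identical.
    """
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unsupported schema: {schema!r}")
    if hasattr(source, "read"):
        text = source.read()
    else:
        src = str(source)
        looks_like_tree = src.lstrip().startswith(("(", "#NEXUS"))
        if looks_like_tree:
            text = src
        else:
            with open(src) as fh:
                text = fh.read()
    tl = dendropy.TreeList.get(
        data=text, schema=schema, preserve_underscores=True
    )
    if len(tl) == 0:
        raise ValueError("no trees found in source")
    return TreeEnsemble([PhyloTree(t) for t in tl])


def phylo_covariance(tree: PhyloTree) -> PhyloCovariance:
    """Brownian covariance: shared root-to-MRCA path lengths.

    ``C[i, j]`` is the depth of the most recent common ancestor of tips
    *i* and *j*; ``C[i, i]`` is the root-to-tip distance. Computed in a
    single postorder pass: at each internal node of depth *h*, every tip
    pair split across distinct child subtrees has MRCA depth *h*.
    """
    dtree = tree.dendropy_tree
    order = {name: i for i, name in enumerate(tree.tips)}
    n = len(tree.tips)
    C = np.zeros((n, n))

    # node depths via preorder accumulation
    depth: dict[int, float] = {id(dtree.seed_node): 0.0}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    # postorder: collect tip indices per subtree, fill cross-pairs
    tipsets: dict[int, np.ndarray] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = order[node.taxon.label]
            C[i, i] = depth[id(node)]
            tipsets[id(node)] = np.array([i])
        else:
            h = depth[id(node)]
            child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ia = child_sets[a][:, None]
                    ib = child_sets[b][None, :]
                    C[ia, ib] = h
                    C[ib.T, ia.T] = h
            tipsets[id(node)] = np.concatenate(child_sets)
    return PhyloCovariance(tree.tips, C)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda transform: multiply off-diagonal entries by ``lam``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    d = np.diag(np.diag(cov.C))
    C = lam * (cov.C - d) + d
    return PhyloCovariance(cov.species, C)


def whitening_transform(cov: PhyloCovariance) -> np.ndarray:
    """Symmetric inverse square root ``P = C^{-1/2}``.

    Satisfies ``P @ C @ P.T = I``. If C is singular to numerical
    tolerance (e.g. zero-length terminal branches producing duplicated
    rows), a ridge of ``RIDGE_FACTOR * mean(diag(C))`` is added with a
    warning rather than failing.
    """
    C = cov.C
    w, E = np.linalg.eigh(C)
    tol = 1e-10 * max(abs(w).max(), 1.0)
    if w.min() < tol:
        ridge = RIDGE_FACTOR * float(np.mean(np.diag(C)))
        warnings.warn(
            f"covariance numerically singular (min eig {w.min():.3g}); "
            f"adding ridge {ridge:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        w, E = np.linalg.eigh(C + ridge * np.eye(cov.n))
        if w.min() <= 0:
            raise np.linalg.LinAlgError(
                "covariance singular beyond ridge tolerance"
            )
    return (E * (1.0 / np.sqrt(w))) @ E.T


def gls_mean(y: np.ndarray, cov: PhyloCovariance) -> float:
    """Generalised-least-squares (phylogenetic) mean of a tip vector.

    ``a_hat = (1' C^-1 1)^-1 1' C^-1 y`` — the root-state estimate under
    Brownian motion, used by the K statistic and the phylogenetic ANOVA.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (cov.n,):
        raise ValueError(f"y must have length {cov.n}")
    Cinv_1 = np.linalg.solve(cov.C, np.ones(cov.n))
    return float(Cinv_1 @ y / Cinv_1.sum())
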