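"""Synthetic ecomorphological datasets.

Generates trees, traits and ecological labels with the statistical
structure the analysis pipeline assumes, so every stage can be exercised
end-to-end without external data:

* a pure-birth (Yule) tree of ~200 tips — the taxon sample scale of a
  multi-family rodent dataset;
* log body mass evolving by Brownian motion spanning roughly three
  orders of magnitude in grams;
* 13 linear measurements generated as allometric functions of log mass
  (isometry slope 1/3 by default) plus a Brownian deviation whose
  phylogenetic signal is tuned by Pagel's lambda, plus class-specific
  mean shifts; the condylar angle ACP is generated in degrees around a
  120-degree baseline;
* diet and locomotion categories evolved by an equal-rates Mk process —
  a fast rate produces the near-zero phylogenetic signal typical of
  diet, a slow rate the moderate signal of locomotion. Class membership
  then shifts the morphology, which decouples phylogenetic signal in
  ecology from the ecology-morphology association itself;
* a configurable fraction of labels replaced by "U" (unknown), to be
  predicted from morphology.

The alternative trees of an ensemble are emulated by jittering branch
lengths and swapping a few tip labels of the generating tree — the kind
of local uncertainty in the placement of data-poor species that a set of
Bayesian tree draws exhibits.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import PhyloTree, TreeEnsemble, lambda_transform

__all__ = [
    "SimConfig",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_mk",
    "perturb_tree",
    "simulate_ecomorph_dataset",
    "DIET_CLASSES",
    "LOCOMOTION_CLASSES",
]

DIET_CLASSES = ["C", "I", "GH", "SH"]
LOCOMOTION_CLASSES = ["T", "Sa", "A", "Sf", "F", "R", "G"]

#: craniodental variables shifted by diet class
_DIET_VARS = ["LR", "ZB", "BIT", "LMT", "HMC", "ACP"]
#: external variables shifted by locomotion class
_LOCO_VARS = ["T", "E", "Vib", "HF", "FF", "UM"]

#: typical measurement (mm) at log-mass = 5 (~150 g), used as intercept anchors
_ANCHORS_MM = {
    "HB": 130.0, "T": 110.0, "E": 16.0, "Vib": 30.0, "HF": 26.0,
    "FF": 12.0, "UM": 3.0, "CBL": 32.0, "LR": 12.0, "ZB": 17.0,
    "BIT": 4.5, "LMT": 6.0, "HMC": 5.0,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset generator.

    Defaults emulate the magnitudes of the rodent study: weak
    phylogenetic signal in the shape deviations (lambda ~ 0.2), strong
    class structure in morphology (3-SD class shifts), a fast Mk process
    for diet (near-zero categorical signal) and a slow one for
    locomotion (moderate signal), and ~20% / ~17% of species with
    unknown diet / locomotion.
    """

    n_tips: int = 200
    birth_rate: float = 1.0
    n_trees: int = 1
    lambda_signal: float = 0.2
    allometric_slopes: dict = field(
        default_factory=lambda: {v: 1.0 / 3.0 for v in _ANCHORS_MM}
    )
    sigma2: float | None = None        # BM rate of trait deviations; None =>
    trait_sd: float = 0.15             # ... derived so tip deviation sd = trait_sd
    mass_sd: float = 1.5               # tip sd of log body mass
    noise_sd: float = 0.05             # iid measurement noise, log units
    acp_baseline: float = 120.0        # degrees
    acp_sd: float = 8.0                # degrees
    mk_rate_diet: float = 2.0          # per unit branch length: fast => no signal
    mk_rate_locomotion: float = 0.25   # slow => conserved locomotion
    class_shift: float = 3.0           # class mean offsets, in trait-SD units
    unknown_frac_diet: float = 0.20
    unknown_frac_locomotion: float = 0.17
    jitter_sd: float = 0.10            # lognormal branch-length jitter of extra trees
    n_tip_swaps: int = 2               # tip-label swaps per extra tree
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if not 0.0 <= self.lambda_signal <= 1.0:
            raise ValueError("lambda_signal must be in [0, 1]")
        for name in ("birth_rate", "mk_rate_diet", "mk_rate_locomotion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def simulate_tree(n_tips: int, birth_rate: float = 1.0,
                  seed: int | None = None) -> PhyloTree:
    """Pure-birth (Yule) tree with exponential waiting times, ultrametric.

    Each splitting interval with k extant lineages lasts
    Exp(k * birth_rate), and a final Exp(n * birth_rate) stretch follows
    the last split. The returned tree starts at the root bifurcation (no
    root edge), so its expected height is
    ``(sum_{k=2}^{n-1} 1/k + 1/n) / birth_rate``. Tips are labelled
    ``sp0001`` ...
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    parent: dict[int, int | None] = {0: None}
    birth: dict[int, float] = {0: 0.0}
    children: dict[int, list[int]] = {}
    active = [0]
    t = 0.0
    nxt = 1
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = active.pop(int(rng.integers(len(active))))
        kids = [nxt, nxt + 1]
        nxt += 2
        for c in kids:
            parent[c] = i
            birth[c] = t
        children[i] = kids
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))

    labels = {node: f"sp{k + 1:04d}" for k, node in enumerate(sorted(active))}

    # branch length of node c = (time c splits, or t_end) - birth[c]
    def bl(c: int) -> float:
        end = birth[children[c][0]] if c in children else t_end
        return end - birth[c]

    def nwk(node: int) -> str:
        if node in children:
            sub = ",".join(f"{nwk(c)}:{bl(c):.12g}" for c in children[node])
            return f"({sub})"
        return labels[node]

    return PhyloTree.from_newick(nwk(0) + ";")


def simulate_bm_traits(tree: PhyloTree, sigma2: float,
                       lambda_signal: float = 1.0,
                       seed: int | None = None,
                       n_traits: int = 1) -> pd.DataFrame:
    """Tip values from N(0, sigma2 * C_lambda), one column per trait.

    Rows are in the tree's canonical tip order. ``lambda_signal = 0``
    gives i.i.d. tips with variance sigma2 * depth; ``1`` gives full
    Brownian covariance.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    cov = lambda_transform(tree.covariance(), lambda_signal)
    L = np.linalg.cholesky(cov.C + 1e-12 * np.mean(np.diag(cov.C)) * np.eye(cov.n))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((cov.n, n_traits))
    X = np.sqrt(sigma2) * (L @ Z)
    return pd.DataFrame(X, index=pd.Index(tree.tips, name="species"),
                        columns=[f"trait_{j + 1}" for j in range(n_traits)])


def simulate_mk(tree: PhyloTree, states: list, mk_rate: float,
                seed: int | None = None) -> pd.Series:
    """Equal-rates Mk character evolved along the tree.

    The root state is uniform; along each branch the state jumps at rate
    ``mk_rate * (k-1)/k`` to a uniformly chosen other state (so the
    expected number of changes over a branch of length t is
    ``mk_rate * t * (k-1)/k`` and P(same state after t) =
    ``1/k + (k-1)/k * exp(-mk_rate * t)``).
    """
    if len(states) < 2:
        raise ValueError("need >= 2 states")
    if mk_rate <= 0:
        raise ValueError("mk_rate must be > 0")
    k = len(states)
    jump_rate = mk_rate * (k - 1) / k
    rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    state: dict[int, int] = {id(dtree.seed_node): int(rng.integers(k))}
    tips: dict[str, int] = {}
    for nd in dtree.preorder_node_iter():
        if nd is not dtree.seed_node:
            s = state[id(nd.parent_node)]
            t_remaining = nd.edge.length
            while True:
                wait = rng.exponential(1.0 / jump_rate)
                if wait >= t_remaining:
                    break
                t_remaining -= wait
                s = (s + 1 + int(rng.integers(k - 1))) % k
            state[id(nd)] = s
        if nd.is_leaf():
            tips[nd.taxon.label] = state[id(nd)]
    return pd.Series({sp: states[tips[sp]] for sp in tree.tips},
                     name="state").reindex(tree.tips)


def perturb_tree(tree: PhyloTree, jitter_sd: float = 0.10,
                 n_tip_swaps: int = 2, seed: int | None = None) -> PhyloTree:
    """An alternative phylogenetic hypothesis: jittered lengths, swapped tips.

    Branch lengths are multiplied by lognormal(0, jitter_sd) factors and
    ``n_tip_swaps`` random tip-label pairs are exchanged — emulating the
    uncertain placement of data-poor species across posterior tree draws.
    """
    rng = np.random.default_rng(seed)
    clone = PhyloTree.from_newick(tree.to_newick())
    dtree = clone.dendropy_tree
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length * rng.lognormal(0.0, jitter_sd))
    leaves = list(dtree.leaf_node_iter())
    for _ in range(n_tip_swaps):
        i, j = rng.choice(len(leaves), size=2, replace=False)
        leaves[i].taxon, leaves[j].taxon = leaves[j].taxon, leaves[i].taxon
    return PhyloTree(dtree)


def _class_offsets(classes: list, variables: list, shift: float,
                   scales: dict, rng) -> pd.DataFrame:
    """Per-class per-variable mean offsets with RMS = shift * scale."""
    U = rng.standard_normal((len(classes), len(variables)))
    U /= np.sqrt(np.mean(U**2, axis=1, keepdims=True))
    off = U * shift * np.array([scales[v] for v in variables])
    return pd.DataFrame(off, index=classes, columns=variables)


def simulate_ecomorph_dataset(
    config: SimConfig,
) -> tuple[TreeEnsemble, pd.DataFrame, pd.DataFrame]:
    """Full synthetic dataset: tree ensemble, trait table, ecology table.

    Returns ``(ensemble, traits, ecology)`` where ``traits`` has the
    measurement columns on their natural scales (grams, millimetres,
    degrees) and ``ecology`` has ``diet`` / ``locomotion`` columns with
    some entries replaced by ``"U"``. The first tree of the ensemble is
    the generating tree.
    """
    cfg = config
    root = np.random.default_rng(cfg.seed)
    seeds = iter(root.integers(2**31 - 1, size=64))

    tree = simulate_tree(cfg.n_tips, cfg.birth_rate, seed=int(next(seeds)))
    height = float(np.max(tree.depths()))
    sigma2_dev = cfg.sigma2 if cfg.sigma2 is not None else cfg.trait_sd**2 / height
    sigma2_mass = cfg.mass_sd**2 / height

    # body mass: BM around log(150 g)
    logmass = (np.log(150.0)
               + simulate_bm_traits(tree, sigma2_mass, 1.0,
                                    seed=int(next(seeds))).iloc[:, 0])

    # ecology by Mk, then unknowns
    diet = simulate_mk(tree, DIET_CLASSES, cfg.mk_rate_diet,
                       seed=int(next(seeds)))
    loco = simulate_mk(tree, LOCOMOTION_CLASSES, cfg.mk_rate_locomotion,
                       seed=int(next(seeds)))

    # class-specific mean shifts (in deviation-SD units)
    scales = {v: cfg.trait_sd for v in _ANCHORS_MM}
    scales["ACP"] = cfg.acp_sd
    pat_rng = np.random.default_rng(int(next(seeds)))
    diet_off = _class_offsets(DIET_CLASSES, _DIET_VARS, cfg.class_shift,
                              scales, pat_rng)
    loco_off = _class_offsets(LOCOMOTION_CLASSES, _LOCO_VARS, cfg.class_shift,
                              scales, pat_rng)

    noise_rng = np.random.default_rng(int(next(seeds)))
    dev = simulate_bm_traits(tree, sigma2_dev, cfg.lambda_signal,
                             seed=int(next(seeds)),
                             n_traits=len(_ANCHORS_MM))
    traits = pd.DataFrame(index=logmass.index)
    traits["mass_g"] = np.exp(logmass)
    for j, var in enumerate(_ANCHORS_MM):
        slope = cfg.allometric_slopes[var]
        intercept = np.log(_ANCHORS_MM[var]) - slope * np.log(150.0)
        logv = (intercept + slope * logmass + dev.iloc[:, j]
                + noise_rng.normal(0.0, cfg.noise_sd, cfg.n_tips))
        if var in _DIET_VARS:
            logv = logv + diet.map(diet_off[var]).astype(float)
        if var in _LOCO_VARS:
            logv = logv + loco.map(loco_off[var]).astype(float)
        traits[var] = np.exp(logv)

    acp_dev = simulate_bm_traits(tree, cfg.acp_sd**2 / height,
                                 cfg.lambda_signal,
                                 seed=int(next(seeds))).iloc[:, 0]
    acp = (cfg.acp_baseline + acp_dev
           + diet.map(diet_off["ACP"]).astype(float)
           + noise_rng.normal(0.0, 2.0, cfg.n_tips))
    traits["ACP"] = np.clip(acp, 1.0, 179.0)

    ecology = pd.DataFrame({"diet": diet, "locomotion": loco})
    unk_rng = np.random.default_rng(int(next(seeds)))
    for col, frac in (("diet", cfg.unknown_frac_diet),
                      ("locomotion", cfg.unknown_frac_locomotion)):
        n_u = int(round(frac * cfg.n_tips))
        if n_u:
            drop = unk_rng.choice(cfg.n_tips, size=n_u, replace=False)
            ecology.iloc[drop, ecology.columns.get_loc(col)] = "U"

    trees = [tree]
    ens_rng = np.random.default_rng(int(next(seeds)))
    for _ in range(cfg.n_trees - 1):
        trees.append(perturb_tree(tree, cfg.jitter_sd, cfg.n_tip_swaps,
                                  seed=int(ens_rng.integers(2**31 - 1))))
    ecology.index.name = "species"
    traits.index.name = "species"
    return TreeEnsemble(trees), traits, ecology
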