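import numpy as np
import pandas as pd
import pytest

import ecomorph as em


@pytest.fixture(scope="session")
def three_taxon():
    """((A:1,B:1):1,C:2); with C = [[2,1,0],[1,2,0],[0,0,2]]."""
    return em.read_trees("((A:1,B:1):1,C:2);")[0]


def star_newick(n, length=1.0):
    tips = ",".join(f"t{i:02d}:{length}" for i in range(n))
    return f"({tips});"


@pytest.fixture(scope="session")
def star10():
    """10-tip star tree with unit branches: covariance = identity."""
    return em.read_trees(star_newick(10))[0]


@pytest.fixture(scope="session")
def oracle_tree_data():
    """8-taxon fixture with frozen externally verified statistics."""
    nwk = ("((((A:0.3,B:0.3):0.4,(C:0.5,D:0.5):0.2):0.3,"
           "(E:0.6,F:0.6):0.4):0.5,(G:0.9,H:0.9):0.6);")
    tree = em.read_trees(nwk)[0]
    y = {"A": 1.2, "B": 0.9, "C": 2.1, "D": 1.7,
         "E": -0.4, "F": 0.1, "G": 3.0, "H": 2.4}
    x = {"A": 0.5, "B": 0.3, "C": 1.1, "D": 0.8,
         "E": -0.2, "F": 0.0, "G": 1.9, "H": 1.5}
    cov = tree.covariance()
    yv = np.array([y[s] for s in cov.species])
    xv = np.array([x[s] for s in cov.species])
    return tree, cov, yv, xv


@pytest.fixture(scope="session")
def small_dataset():
    """Frozen synthetic dataset: 60 tips, 2 trees, seed 7."""
    cfg = em.SimConfig(n_tips=60, n_trees=2, seed=7)
    return em.simulate_ecomorph_dataset(cfg)


@pytest.fixture(scope="session")
def small_residuals(small_dataset):
    ensemble, traits, _ = small_dataset
    return em.size_correct_ensemble(traits, ensemble)


@pytest.fixture(scope="session")
def diet_training(small_dataset, small_residuals):
    """Residual matrix and diet labels restricted to known species."""
    _, _, ecology = small_dataset
    keep = sorted(ecology.index[ecology["diet"] != "U"])
    return small_residuals.loc[keep], ecology.loc[keep, "diet"]
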