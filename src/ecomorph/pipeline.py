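"""Full analysis pipeline over a tree ensemble.

Reproduces the comparative workflow end to end: ensemble PGLS size
correction, body-size phylogenetic ANOVAs, the phylogenetic-signal suite
(K, K_mult, EM-Mantel) per tree, phylogenetic MANOVAs per tree, FDA and
pFDA of diet and locomotion with cross-validation, Wilks discriminant
power and structure correlations, prediction of unknown ("U") species,
and the Sammon morphospace. Per-tree statistics are aggregated as
median / min / max plus the count of trees reaching significance at
alpha = 0.05, so conclusions do not hinge on a single phylogenetic
hypothesis.

Every stochastic stage receives its own seed derived from the master
seed, recorded in the report, so a report is reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discriminant import (cross_validate, fda_fit, optimal_lambda, pfda_fit,
                           structure_correlations, wilks_power)
from .grouptests import phylo_anova, phylo_manova_pgls
from .ordination import sammon
from .signal import blomberg_k, em_mantel, k_mult
from .sizecorr import size_correct_ensemble, validate_trait_table
from .trees import TreeEnsemble

__all__ = ["AnalysisReport", "run_full_analysis"]

CRANIODENTAL = ["LR", "ZB", "BIT", "LMT", "HMC", "ACP"]
EXTERNAL = ["T", "E", "Vib", "HF", "FF", "UM"]
ALPHA = 0.05


@dataclass
class AnalysisReport:
    """All per-tree and aggregated results of one pipeline run."""

    n_trees: int
    seed: int
    stage_seeds: dict
    residuals: pd.DataFrame
    pgls_fits: pd.DataFrame
    body_size_anova: pd.DataFrame
    signal_per_tree: pd.DataFrame
    signal_summary: pd.DataFrame
    manova: pd.DataFrame
    optimal_lambdas: pd.DataFrame
    fda: dict = field(default_factory=dict)
    pfda: dict = field(default_factory=dict)
    predictions: pd.DataFrame | None = None
    ordination: object = None
    sections: tuple = (
        "residuals", "pgls_fits", "body_size_anova", "signal",
        "manova", "optimal_lambda", "fda", "pfda", "predictions",
        "ordination",
    )

    def summary_dict(self) -> dict:
        """Scalar summaries of every section (JSON-serialisable)."""
        out = {
            "n_trees": self.n_trees,
            "seed": self.seed,
            "body_size_anova": {
                f"{r.variable}_{r.grouping}": {
                    "trees_p_gt_alpha": int(r.n_not_significant),
                    "median_p": float(r.median_p),
                }
                for r in self.body_size_anova.itertuples()
            },
            "signal": {
                r.Index: {
                    "median": float(r.median), "min": float(r.min),
                    "max": float(r.max),
                    "n_significant": int(r.n_significant),
                }
                for r in self.signal_summary.itertuples()
            },
            "manova": {
                r.grouping: {
                    "median_F": float(r.median_F),
                    "n_significant": int(r.n_significant),
                }
                for r in self.manova.itertuples()
            },
            "optimal_lambda": {
                g: {
                    "median": float(d["lambda"].median()),
                    "min": float(d["lambda"].min()),
                    "max": float(d["lambda"].max()),
                }
                for g, d in self.optimal_lambdas.groupby("grouping")
            },
        }
        for name, store in (("fda", self.fda), ("pfda", self.pfda)):
            out[name] = {}
            for grouping, entry in store.items():
                e = {}
                if "model" in entry:
                    m = entry["model"]
                    e["percent_between"] = [float(v) for v in m.percent_between]
                    e["lambda_used"] = float(m.lambda_used)
                if "cv" in entry:
                    e["cv_overall_correct"] = float(entry["cv"].overall_correct)
                    e["cv_per_class"] = {
                        k: float(v)
                        for k, v in entry["cv"].per_class_correct.items()
                    }
                if "score_correlation_with_fda" in entry:
                    sc = entry["score_correlation_with_fda"]
                    e["score_correlation_min"] = float(np.min(sc))
                    e["score_correlation_median"] = float(np.median(sc))
                out[name][grouping] = e
        if self.predictions is not None:
            out["predictions"] = {
                "n_predicted": int(len(self.predictions)),
            }
        if self.ordination is not None:
            out["ordination"] = {
                "stress": float(self.ordination.stress),
                "n_iter": int(self.ordination.n_iter),
            }
        return out

    def save(self, outdir) -> None:
        """Write CSV tables and a machine-readable summary.json."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.residuals.to_csv(outdir / "residuals.csv")
        self.pgls_fits.to_csv(outdir / "pgls_fits.csv", index=False)
        self.body_size_anova.to_csv(outdir / "body_size_anova.csv", index=False)
        self.signal_per_tree.to_csv(outdir / "signal_per_tree.csv", index=False)
        self.signal_summary.to_csv(outdir / "signal_summary.csv")
        self.manova.to_csv(outdir / "manova.csv", index=False)
        self.optimal_lambdas.to_csv(outdir / "optimal_lambdas.csv", index=False)
        for grouping, entry in self.fda.items():
            if "wilks" in entry:
                entry["wilks"].to_csv(outdir / f"wilks_{grouping}.csv")
            if "structure" in entry:
                entry["structure"].r.to_csv(
                    outdir / f"structure_r_{grouping}.csv")
                entry["structure"].p_holm.to_csv(
                    outdir / f"structure_p_holm_{grouping}.csv")
            if "cv" in entry:
                entry["cv"].confusion.to_csv(
                    outdir / f"confusion_{grouping}.csv")
        if self.predictions is not None:
            self.predictions.to_csv(outdir / "predicted_ecologies.csv")
        if self.ordination is not None:
            coords = self.ordination.coordinates.copy()
            coords.to_csv(outdir / "ordination.csv")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)


def _aggregate_signal(per_tree: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for name, d in per_tree.groupby("measure"):
        rows[name] = {
            "median": d["statistic"].median(),
            "min": d["statistic"].min(),
            "max": d["statistic"].max(),
            "n_significant": int((d["p_value"] < ALPHA).sum()),
            "n_trees": len(d),
        }
    return pd.DataFrame(rows).T


def run_full_analysis(
    ensemble: TreeEnsemble,
    traits: pd.DataFrame,
    ecology: pd.DataFrame,
    seed: int = 0,
    n_perm: int = 999,
    n_sim_mantel: int = 199,
    n_folds: int = 10,
    signal_trees: int | None = None,
    drop_missing: bool = False,
) -> AnalysisReport:
    """Run the whole comparative analysis and aggregate over the ensemble.

    Parameters
    ----------
    ensemble, traits, ecology
        Tree ensemble, species x measurement table (natural units) and
        species x {diet, locomotion} table ("U" = unknown).
    seed
        Master seed; each stochastic stage draws a child seed from it.
    n_perm
        Null replicates for K/K_mult permutations, ANOVA simulations and
        MANOVA RRPP permutations.
    n_sim_mantel
        Mk simulations per tree for the EM-Mantel test (its null is the
        costliest to simulate, hence the separate knob).
    signal_trees
        If set, the per-tree signal/MANOVA/lambda loops use only the
        first ``signal_trees`` trees (size correction always uses all).
    drop_missing
        Drop data species absent from the trees instead of raising.
    """
    traits = validate_trait_table(traits)
    species = sorted(traits.index)
    if sorted(ecology.index) != species:
        raise ValueError("traits and ecology tables list different species")
    absent = [s for s in species if s not in set(ensemble.tips)]
    if absent:
        if not drop_missing:
            raise ValueError(f"species not in trees: {absent}")
        warnings.warn(f"dropping {len(absent)} species absent from trees",
                      RuntimeWarning, stacklevel=2)
        species = [s for s in species if s not in set(absent)]
        traits = traits.loc[species]
    ecology = ecology.loc[species]

    rng = np.random.default_rng(seed)
    stage_seed = {
        name: int(rng.integers(2**31 - 1))
        for name in ("signal", "mantel", "anova", "manova", "cv", "sammon")
    }

    # ---- size correction over the full ensemble -------------------------
    residuals, pgls_fits = size_correct_ensemble(traits, ensemble,
                                                 return_fits=True)

    loop_trees = list(ensemble)[: signal_trees or len(ensemble)]

    def _usable(grouping: str):
        lab = ecology[grouping]
        knn = lab[lab != "U"]
        counts = knn.value_counts()
        small = counts.index[counts < 2]
        if len(small):
            warnings.warn(
                f"{grouping}: dropping singleton classes {sorted(small)} "
                "from group-based analyses", RuntimeWarning, stacklevel=2)
        return knn.index[~knn.isin(small)]

    known = {"diet": _usable("diet"), "locomotion": _usable("locomotion")}

    # ---- body-size phylogenetic ANOVAs ---------------------------------
    anova_rows = []
    size_proxies = {
        "log_mass": pd.Series(np.log(traits["mass_g"]), index=traits.index),
        "log_CBL": pd.Series(np.log(traits["CBL"]), index=traits.index),
    }
    a_rng = np.random.default_rng(stage_seed["anova"])
    for grouping in ("diet", "locomotion"):
        groups = ecology.loc[known[grouping], grouping]
        for vname, y in size_proxies.items():
            pvals = []
            for tree in loop_trees:
                res = phylo_anova(
                    y.loc[known[grouping]], groups,
                    tree.covariance(), n_sim=n_perm,
                    seed=int(a_rng.integers(2**31 - 1)))
                pvals.append(res.p_value)
            pvals = np.array(pvals)
            anova_rows.append({
                "variable": vname, "grouping": grouping,
                "n_trees": len(pvals),
                "n_not_significant": int((pvals > ALPHA).sum()),
                "median_p": float(np.median(pvals)),
            })
    body_size_anova = pd.DataFrame(anova_rows)

    # ---- phylogenetic signal suite per tree -----------------------------
    s_rng = np.random.default_rng(stage_seed["signal"])
    m_rng = np.random.default_rng(stage_seed["mantel"])
    sig_rows = []
    logmass = pd.Series(np.log(traits["mass_g"]), index=traits.index)
    for t, tree in enumerate(loop_trees):
        cov = tree.covariance().subset(species)
        r = blomberg_k(logmass.reindex(cov.species).to_numpy(), cov,
                       n_perm=n_perm, seed=int(s_rng.integers(2**31 - 1)))
        sig_rows.append(("body_size_K", t, r.statistic, r.p_value))
        for mname, cols in (("craniodental_Kmult", CRANIODENTAL),
                            ("external_Kmult", EXTERNAL)):
            r = k_mult(residuals.reindex(cov.species)[cols], cov,
                       n_perm=n_perm, seed=int(s_rng.integers(2**31 - 1)))
            sig_rows.append((mname, t, r.statistic, r.p_value))
        for grouping in ("diet", "locomotion"):
            sub = tree.prune_to(known[grouping])
            r = em_mantel(ecology.loc[known[grouping], grouping], sub,
                          n_sim=n_sim_mantel,
                          seed=int(m_rng.integers(2**31 - 1)))
            sig_rows.append((f"{grouping}_EM_Mantel", t,
                             r.statistic, r.p_value))
    signal_per_tree = pd.DataFrame(
        sig_rows, columns=["measure", "tree", "statistic", "p_value"])
    signal_summary = _aggregate_signal(signal_per_tree)

    # ---- MANOVA and optimal lambda per tree ------------------------------
    mn_rng = np.random.default_rng(stage_seed["manova"])
    manova_rows = []
    lam_rows = []
    for grouping in ("diet", "locomotion"):
        idx = known[grouping]
        Y = residuals.loc[idx]
        groups = ecology.loc[idx, grouping]
        stats_, pvals = [], []
        for t, tree in enumerate(loop_trees):
            cov = tree.covariance().subset(idx)
            res = phylo_manova_pgls(Y, groups, cov, n_perm=n_perm,
                                    seed=int(mn_rng.integers(2**31 - 1)))
            stats_.append(res.statistic)
            pvals.append(res.p_value)
            lam_rows.append({"grouping": grouping, "tree": t,
                             "lambda": optimal_lambda(
                                 Y.reindex(cov.species), groups, cov)})
        manova_rows.append({
            "grouping": grouping,
            "df_effect": res.df_effect,
            "median_F": float(np.median(stats_)),
            "n_significant": int((np.array(pvals) < ALPHA).sum()),
            "n_trees": len(pvals),
        })
    manova = pd.DataFrame(manova_rows)
    optimal_lambdas = pd.DataFrame(lam_rows)

    # ---- discriminant analyses -----------------------------------------
    cv_rng = np.random.default_rng(stage_seed["cv"])
    fda_store: dict = {}
    pfda_store: dict = {}
    predictions = []
    for grouping in ("diet", "locomotion"):
        idx = known[grouping]
        X = residuals.loc[sorted(idx)]
        labels = ecology.loc[sorted(idx), grouping]
        model = fda_fit(X, labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cv = cross_validate(X, labels, n_partitions=n_folds,
                                seed=int(cv_rng.integers(2**31 - 1)))
        fda_store[grouping] = {
            "model": model,
            "cv": cv,
            "wilks": wilks_power(X, labels).sort_values("wilks_lambda"),
            "structure": structure_correlations(model, X),
        }
        # pFDA per tree at that tree's optimal lambda; correlation of DF1
        # scores with the standard FDA measures the phylogenetic shift
        lam_g = optimal_lambdas.query("grouping == @grouping")
        score_corr = []
        pmodel = None
        for t, tree in enumerate(loop_trees):
            cov = tree.covariance().subset(idx)
            lam = float(lam_g.loc[lam_g["tree"] == t, "lambda"].iloc[0])
            pm = pfda_fit(X.reindex(cov.species),
                          labels.reindex(cov.species), cov, lam)
            c = abs(np.corrcoef(
                model.scores["DF1"].reindex(pm.scores.index),
                pm.scores["DF1"])[0, 1])
            score_corr.append(c)
            if pmodel is None:
                pmodel = pm
        pfda_store[grouping] = {
            "model": pmodel,
            "score_correlation_with_fda": np.array(score_corr),
        }
        # predict unknowns with the standard FDA (pFDA is indistinguishable
        # at the small optimal lambdas; see methods note)
        unknown = ecology.index[ecology[grouping] == "U"]
        if len(unknown):
            pred = model.predict(residuals.loc[unknown])
            predictions.append(pd.DataFrame({
                "species": unknown, "grouping": grouping,
                "predicted": pred.to_numpy(),
                "provenance": "FDA prediction",
            }))
    predictions = (pd.concat(predictions).set_index("species")
                   if predictions else None)

    # ---- morphospace ----------------------------------------------------
    ordination = sammon(residuals, seed=stage_seed["sammon"])

    return AnalysisReport(
        n_trees=len(ensemble),
        seed=seed,
        stage_seeds=stage_seed,
        residuals=residuals,
        pgls_fits=pgls_fits,
        body_size_anova=body_size_anova,
        signal_per_tree=signal_per_tree,
        signal_summary=signal_summary,
        manova=manova,
        optimal_lambdas=optimal_lambdas,
        fda=fda_store,
        pfda=pfda_store,
        predictions=predictions,
        ordination=ordination,
    )
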