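"""False-positive study: how often competition models beat a true OU process.

Traits are simulated under OU (the generating truth) on depth-standardized
trees; OU and the competition models (DDlin, DDexp, MC — optionally
restricted by ecoguild stochastic maps) are fitted to every replicate, and
a false positive is scored whenever a competition model's AICc undercuts
OU's by more than the threshold (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .fitting import fit_model
from .likelihoods import CovarianceWorkspace
from .models import ModelParams, ModelSpec, simulate_traits
from .simmap import fit_mk, sample_maps
from .synthdata import simulate_mk_history, simulate_tree
from .treeio import Phylogeny, standardize_depth

__all__ = ["FPConfig", "FPResult", "run_fp_study"]


@dataclass
class FPConfig:
    """Design of the false-positive experiment.

    The defaults are the generating conditions of the study this package
    reproduces: sigma^2 = 0.1, alpha in {1, 5}, trees standardized to depth
    1 before simulation, and a delta-AICc threshold of 2. Trees default to
    seeded pure-birth trees of the requested sizes; pass ``trees`` to use
    your own.
    """

    tree_sizes: tuple = (25, 51, 112, 195)
    trees: list | None = None
    alpha_values: tuple = (1.0, 5.0)
    sig2: float = 0.1
    n_reps: int = 1000
    use_guilds: bool = False
    n_maps: int = 10
    n_guilds: int = 4
    guild_rate: float = 0.5  # Mk rate per unit depth in the guild arm
    delta_threshold: float = 2.0
    models: tuple = ("DDlin", "DDexp", "MC")
    birth: float = 1.0
    n_starts: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class FPResult:
    """Replicate-level records plus false-positive rates with Wilson CIs."""

    records: pd.DataFrame  # one row per (size, alpha, rep, model)
    config: FPConfig

    def rates(self, delta_threshold: float | None = None) -> pd.DataFrame:
        """FP rate per (tree size, alpha, model) at the given threshold.

        A replicate counts as a false positive for a model when that model's
        AICc is below OU's by more than the threshold. Replicates whose OU
        fit failed to converge are excluded from the denominator.
        """
        thr = self.config.delta_threshold if delta_threshold is None else delta_threshold
        df = self.records
        rows = []
        for (size, alpha, model), grp in df.groupby(["n_tips", "alpha", "model"]):
            ok = grp[grp["ou_converged"]]
            n = len(ok)
            fp = int(((ok["aicc_ou"] - ok["aicc"]) > thr).sum())
            lo, hi = proportion_confint(fp, n, alpha=0.05, method="wilson") if n else (0, 1)
            rows.append(
                {
                    "n_tips": size,
                    "alpha": alpha,
                    "model": model,
                    "n_reps": n,
                    "n_fp": fp,
                    "fp_rate": fp / n if n else np.nan,
                    "wilson_low": float(lo),
                    "wilson_high": float(hi),
                    "nonconverged": int((~grp["converged"]).sum()),
                }
            )
        return pd.DataFrame(rows)


def _study_trees(config: FPConfig, rng_seeds) -> list[Phylogeny]:
    if config.trees is not None:
        return [standardize_depth(t, 1.0) for t in config.trees]
    trees = []
    for size, s in zip(config.tree_sizes, rng_seeds):
        tree = simulate_tree(size, birth=config.birth, death=0.0, seed=s)
        trees.append(standardize_depth(tree, 1.0))
    return trees


def run_fp_study(config: FPConfig) -> FPResult:
    """Run the full false-positive experiment described by ``config``."""
    ss = np.random.SeedSequence(config.seed)
    n_trees = len(config.trees) if config.trees is not None else len(config.tree_sizes)
    tree_seeds = ss.spawn(n_trees)
    trees = _study_trees(config, [s.spawn(1)[0] for s in tree_seeds])
    records = []
    for tree, tseed in zip(trees, tree_seeds):
        children = tseed.spawn(3 + len(config.alpha_values))
        guild_seed, map_seed = children[1], children[2]
        alpha_seeds = children[3:]
        maps = None
        map_workspaces = None
        if config.use_guilds:
            states = [f"g{k + 1}" for k in range(config.n_guilds)]
            truth = simulate_mk_history(tree, states, config.guild_rate, seed=guild_seed)
            tip_states = [states[truth.tip_state(i)] for i in range(tree.n_tips)]
            mk = fit_mk(tree, tip_states, model="ER", states=states)
            maps = sample_maps(tree, mk, tip_states, n_maps=config.n_maps, seed=map_seed)
            map_workspaces = [CovarianceWorkspace(tree, m) for m in maps]
        ws_plain = CovarianceWorkspace(tree)
        for alpha, aseed in zip(config.alpha_values, alpha_seeds):
            gen = ModelSpec("OU", ModelParams(sig2=config.sig2, alpha=alpha, z0=0.0))
            data = simulate_traits(tree, gen, config.n_reps, seed=aseed)
            for rep in range(config.n_reps):
                x = data[rep]
                ou = fit_model(
                    tree, x, "OU", n_starts=config.n_starts, workspace=ws_plain
                )
                for name in config.models:
                    f = fit_model(
                        tree,
                        x,
                        name,
                        regimes=maps if config.use_guilds else None,
                        n_starts=config.n_starts,
                        workspace=map_workspaces if config.use_guilds else ws_plain,
                    )
                    records.append(
                        {
                            "n_tips": tree.n_tips,
                            "alpha": alpha,
                            "rep": rep,
                            "model": name,
                            "aicc": f.aicc,
                            "aicc_ou": ou.aicc,
                            "loglik": f.loglik,
                            "loglik_ou": ou.loglik,
                            "converged": bool(f.converged),
                            "ou_converged": bool(ou.converged),
                            "param_S": f.spec.params.S,
                            "param_slope_n": f.spec.params.slope_n,
                            "param_rate_n": f.spec.params.rate_n,
                        }
                    )
    return FPResult(pd.DataFrame(records), config)
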