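"""Seeded synthetic data with the statistical structure the analysis assumes.

Stands in for an empirical comparative dataset: birth-death trees
conditioned on a tip count, discrete guild histories evolved under an Mk
process (true regime maps retained), guild-consistent diet/forage labels,
and continuous traits simulated under any of the seven models. Every output
is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .guilds import DIET_LABELS, FORAGE_LABELS
from .models import ModelSpec, simulate_trait
from .simmap import RegimeMap, write_simmap
from .treeio import Phylogeny, standardize_depth

__all__ = [
    "SimulationError",
    "simulate_tree",
    "simulate_mk_history",
    "FixtureConfig",
    "make_fixture",
]


class SimulationError(RuntimeError):
    pass


def simulate_tree(
    n_tips: int,
    birth: float = 1.0,
    death: float = 0.0,
    seed=None,
    max_tries: int = 100,
) -> Phylogeny:
    """Birth-death tree conditioned on ``n_tips`` extant tips.

    Forward (Gillespie) simulation from a crown pair until ``n_tips``
    lineages coexist, plus one exponential holding time so the stopping
    instant is exchangeable with the inter-event times; extinct lineages are
    then pruned (reconstructed tree). Pure birth reproduces the Yule crown
    expectation sum_{k=2..n} 1/(birth*k) for the depth.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not (birth > death >= 0):
        raise ValueError("need birth > death >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        tree = _simulate_bd_once(n_tips, birth, death, rng)
        if tree is not None:
            return tree
    raise SimulationError(f"failed to condition on {n_tips} tips in {max_tries} tries")


def _simulate_bd_once(n_tips, birth, death, rng):
    # lineage records: birth_time, parent id, end_time (None while alive)
    birth_time = [0.0, 0.0]
    parent_id = [-1, -1]
    end_time = [None, None]
    alive = [0, 1]
    t = 0.0
    while len(alive) < n_tips:
        if not alive or len(alive) < 2 and len(birth_time) > 2:
            return None
        total = (birth + death) * len(alive)
        t += rng.exponential(1.0 / total)
        lineage = alive[rng.integers(len(alive))]
        if rng.random() < birth / (birth + death):
            end_time[lineage] = t
            for _ in range(2):
                birth_time.append(t)
                parent_id.append(lineage)
                end_time.append(None)
                alive.append(len(birth_time) - 1)
            alive.remove(lineage)
        else:
            end_time[lineage] = t
            alive.remove(lineage)
            if len(alive) < 2:
                return None
    t += rng.exponential(1.0 / ((birth + death) * len(alive)))
    for lineage in alive:
        end_time[lineage] = t
    # terminal lineages = never split; splits are internal nodes
    is_internal = [False] * len(birth_time)
    for pid in parent_id:
        if pid >= 0:
            is_internal[pid] = True
    terminals = [i for i in range(len(birth_time)) if not is_internal[i]]
    internals = [i for i in range(len(birth_time)) if is_internal[i]]
    index = {rec: j for j, rec in enumerate(terminals)}
    for rec in internals:
        index[rec] = len(index)
    n_nodes = len(index)
    parent = np.full(n_nodes, -1, dtype=int)
    elen = np.zeros(n_nodes)
    labels = [f"t{j + 1}" for j in range(len(terminals))]
    # the two crown lineages share a virtual root at time 0
    root_slot = n_nodes  # appended below
    parent = np.append(parent, -1)
    elen = np.append(elen, 0.0)
    for rec in range(len(birth_time)):
        j = index[rec]
        parent[j] = index[parent_id[rec]] if parent_id[rec] >= 0 else root_slot
        elen[j] = end_time[rec] - birth_time[rec]
    full = Phylogeny(labels, parent, elen)
    extant = [
        labels[j]
        for rec, j in index.items()
        if not is_internal[rec] and abs(end_time[rec] - t) < 1e-12
    ]
    if len(extant) != n_tips:
        return None
    if len(extant) < full.n_tips:
        full = full.prune_to_tips(extant)
    # relabel tips deterministically after pruning
    full.tip_labels = [f"t{j + 1}" for j in range(full.n_tips)]
    return full


def simulate_mk_history(
    tree: Phylogeny, states, rate: float, seed=None
) -> RegimeMap:
    """Forward-simulate an ER Mk process; returns the true regime map.

    ``rate`` is the per-state transition rate to each other state
    (off-diagonal entry of Q) in units of 1/time.
    """
    K = len(states)
    rng = np.random.default_rng(seed)
    node_state = np.empty(tree.n_nodes, dtype=int)
    node_state[tree.root] = rng.integers(K)
    segments = {}
    total_rate = rate * (K - 1)
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = node_state[tree.parent[v]]
        remaining = tree.edge_length[v]
        segs = []
        while True:
            if total_rate <= 0:
                segs.append((s, remaining))
                break
            wait = rng.exponential(1.0 / total_rate)
            if wait >= remaining:
                segs.append((int(s), float(remaining)))
                break
            segs.append((int(s), float(wait)))
            remaining -= wait
            others = [k for k in range(K) if k != s]
            s = others[rng.integers(K - 1)]
        node_state[v] = s
        segments[v] = segs
    return RegimeMap(tree, list(states), segments)


@dataclass
class FixtureConfig:
    """Study conditions for a synthetic clade bundle.

    Defaults mirror the scale of the empirical study this emulates: clades
    of 21-195 tips, pure-birth trees standardized to depth 1, four guilds
    under an ER Mk process, and six traits (four shape PCs, size, mass).
    """

    n_clades: int = 2
    tips_per_clade: tuple = (25, 51)
    birth: float = 1.0
    death: float = 0.0
    depth: float = 1.0
    guild_rate: float = 0.5  # per unit depth, to each other guild
    n_guilds: int = 4
    label_noise: float = 0.0
    trait_models: dict = field(default_factory=dict)  # trait -> ModelSpec
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.tips_per_clade) != self.n_clades:
            raise ValueError("tips_per_clade must have n_clades entries")
        if min(self.tips_per_clade) < 21:
            raise ValueError("clades must have at least 21 tips")

    def resolved_trait_models(self) -> dict:
        if self.trait_models:
            return self.trait_models
        default = {}
        for name in ("shape_pc1", "shape_pc2", "shape_pc3", "shape_pc4"):
            default[name] = ModelSpec("BM", _mp(sig2=0.1))
        default["size"] = ModelSpec("BM", _mp(sig2=0.1))
        default["mass"] = ModelSpec("BM", _mp(sig2=0.1))
        return default


def _mp(**kw):
    from .models import ModelParams

    return ModelParams(**kw)


def _spec_to_record(spec: ModelSpec) -> dict:
    p = spec.params
    return {
        "name": spec.name,
        "interaction_structured": bool(spec.interaction_structured),
        "sig2": p.sig2,
        "alpha": p.alpha,
        "slope_t": p.slope_t,
        "rate_t": p.rate_t,
        "slope_n": p.slope_n,
        "rate_n": p.rate_n,
        "S": p.S,
        "z0": p.z0,
    }


def make_fixture(config: FixtureConfig, out_dir) -> dict:
    """Write a clade dataset bundle; returns the in-memory objects too.

    Per clade: Newick tree, trait table (CSV), diet/forage category table
    consistent with the true guilds, the true regime map (SIMMAP text), and
    a manifest recording every generating parameter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    clade_seeds = ss.spawn(config.n_clades)
    trait_models = config.resolved_trait_models()
    manifest = {"seed": int(config.seed), "clades": {}}
    bundle = {}
    for ci in range(config.n_clades):
        clade = f"clade{ci + 1}"
        sub = clade_seeds[ci].spawn(3 + len(trait_models))
        tree = simulate_tree(
            config.tips_per_clade[ci], config.birth, config.death, seed=sub[0]
        )
        tree = standardize_depth(tree, config.depth)
        guild_states = [f"g{k + 1}" for k in range(config.n_guilds)]
        regime = simulate_mk_history(tree, guild_states, config.guild_rate, seed=sub[1])
        tip_guilds = [regime.tip_state(i) for i in range(tree.n_tips)]
        noise_rng = np.random.default_rng(sub[2])
        diet, forage = [], []
        for g in tip_guilds:
            gi = g
            if config.label_noise > 0 and noise_rng.random() < config.label_noise:
                gi = int(noise_rng.integers(config.n_guilds))
            diet.append(DIET_LABELS[gi])
            forage.append(FORAGE_LABELS[gi])
        traits = {}
        model_records = {}
        for ti, (tname, spec) in enumerate(sorted(trait_models.items())):
            tv = simulate_trait(
                tree,
                spec,
                regimes=regime if spec.interaction_structured else None,
                seed=sub[3 + ti],
                trait_name=tname,
            )
            traits[tname] = tv
            model_records[tname] = _spec_to_record(spec)
        trait_df = pd.DataFrame({"species": tree.tip_labels})
        for tname in sorted(traits):
            trait_df[tname] = traits[tname].values
        cat_df = pd.DataFrame(
            {"species": tree.tip_labels, "diet": diet, "forage": forage}
        )
        cdir = out / clade
        cdir.mkdir(exist_ok=True)
        (cdir / "tree.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")
        trait_df.to_csv(cdir / "traits.csv", index=False)
        cat_df.to_csv(cdir / "categories.csv", index=False)
        (cdir / "true_regimes.simmap").write_text(
            write_simmap(regime) + "\n", encoding="utf-8"
        )
        manifest["clades"][clade] = {
            "n_tips": int(tree.n_tips),
            "birth": config.birth,
            "death": config.death,
            "depth": config.depth,
            "guild_rate": config.guild_rate,
            "n_guilds": config.n_guilds,
            "label_noise": config.label_noise,
            "trait_models": model_records,
        }
        bundle[clade] = {
            "tree": tree,
            "regimes": regime,
            "traits": traits,
            "categories": cat_df,
        }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
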