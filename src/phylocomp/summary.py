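"""Clade-level synthesis: D statistic and competition-prevalence tables.

The D statistic (Fritz & Purvis) measures phylogenetic signal in a binary
trait — here, the per-clade competition flag placed on a clade-level tree.
The observed sister-clade sum of state contrasts is calibrated against two
null distributions: random label shuffles (D -> 1) and a threshold-Brownian
process matched to the observed prevalence (D -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import ComparisonTable
from .treeio import Phylogeny

__all__ = [
    "DStatResult",
    "PrevalenceTable",
    "d_statistic",
    "prevalence",
    "collapse_to_clade_tree",
]


@dataclass
class DStatResult:
    D: float
    p_random: float  # fraction of shuffles with d <= observed
    p_brownian: float  # fraction of threshold-BM replicates with d >= observed
    n_perm: int
    d_obs: float


def _sister_sum(tree: Phylogeny, values: np.ndarray) -> float:
    """Sum over internal nodes of |contrast between daughter node values|,
    with node values estimated as means of their daughters (tips: data)."""
    node_val = np.zeros(tree.n_nodes)
    node_val[: tree.n_tips] = values
    d = 0.0
    for v in tree.postorder():
        if v < tree.n_tips:
            continue
        kids = tree.children[v]
        node_val[v] = float(np.mean([node_val[c] for c in kids]))
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                d += abs(node_val[kids[a]] - node_val[kids[b]])
    return d


def _simulate_bm_tips(tree: Phylogeny, rng, n_reps: int) -> np.ndarray:
    out = np.zeros((n_reps, tree.n_nodes))
    for v in tree.preorder():
        if v == tree.root:
            continue
        out[:, v] = out[:, tree.parent[v]] + rng.normal(
            0.0, np.sqrt(max(tree.edge_length[v], 0.0)), size=n_reps
        )
    return out[:, : tree.n_tips]


def d_statistic(
    tree: Phylogeny, flags, n_perm: int = 1000, seed=None
) -> DStatResult:
    """Fritz-Purvis D for a binary trait on a (clade-level) tree.

    D = (d_obs - mean d_BM) / (mean d_random - mean d_BM), where d_random
    comes from label permutations and d_BM from threshold-Brownian
    simulations matched to the observed number of 1s. D is ~1 for
    phylogenetically random flags and ~0 for Brownian-clumped flags.
    """
    flags = np.asarray(flags, dtype=float)
    if len(flags) != tree.n_tips:
        raise ValueError("flags not aligned to tree tips")
    ones = int(flags.sum())
    if ones == 0 or ones == len(flags):
        raise ValueError("D statistic needs both states present")
    rng = np.random.default_rng(seed)
    d_obs = _sister_sum(tree, flags)
    d_rand = np.empty(n_perm)
    for i in range(n_perm):
        d_rand[i] = _sister_sum(tree, rng.permutation(flags))
    bm_tips = _simulate_bm_tips(tree, rng, n_perm)
    d_bm = np.empty(n_perm)
    for i in range(n_perm):
        # threshold at the observed prevalence: top `ones` tips get 1
        cut = np.partition(bm_tips[i], -ones)[-ones]
        d_bm[i] = _sister_sum(tree, (bm_tips[i] >= cut).astype(float))
    denom = d_rand.mean() - d_bm.mean()
    D = (d_obs - d_bm.mean()) / denom if denom != 0 else np.nan
    return DStatResult(
        D=float(D),
        p_random=float(np.mean(d_rand <= d_obs)),
        p_brownian=float(np.mean(d_bm >= d_obs)),
        n_perm=n_perm,
        d_obs=float(d_obs),
    )


@dataclass
class PrevalenceTable:
    counts: pd.DataFrame  # trait, n_flagged, n_total
    flagged: dict  # trait -> sorted clade list

    def fraction(self, trait: str) -> float:
        row = self.counts[self.counts["trait"] == trait].iloc[0]
        return row["n_flagged"] / row["n_total"]


def prevalence(tables: list[ComparisonTable]) -> PrevalenceTable:
    """Count flagged clades per trait and for 'any trait' across clades.

    Each input table must cover a distinct set of clades (one table per
    clade is typical); duplicate clade ids raise.
    """
    clade_trait_flags: dict[str, dict[str, bool]] = {}
    for tab in tables:
        clades = {c for c, _ in tab.flags}
        for c in clades:
            if c in clade_trait_flags:
                raise ValueError(f"duplicate clade id {c!r}")
            clade_trait_flags[c] = {}
        for (c, tr), fl in tab.flags.items():
            clade_trait_flags[c][tr] = fl
    traits = sorted({tr for d in clade_trait_flags.values() for tr in d})
    total = len(clade_trait_flags)
    rows, flagged = [], {}
    for tr in traits:
        who = sorted(c for c, d in clade_trait_flags.items() if d.get(tr, False))
        rows.append({"trait": tr, "n_flagged": len(who), "n_total": total})
        flagged[tr] = who
    any_who = sorted(
        c for c, d in clade_trait_flags.items() if any(d.values())
    )
    rows.append({"trait": "any", "n_flagged": len(any_who), "n_total": total})
    flagged["any"] = any_who
    return PrevalenceTable(pd.DataFrame(rows), flagged)


def collapse_to_clade_tree(tree: Phylogeny, clade_tips: dict) -> Phylogeny:
    """Replace each named monophyletic clade with a single tip.

    ``clade_tips`` maps clade name -> list of member tip labels. Each clade
    is collapsed onto one representative lineage (stem attachment preserved,
    collapsed tip terminating at the present), and the tip is renamed to the
    clade. Tips not claimed by any clade are dropped.
    """
    reps = []
    rename = {}
    for clade, members in clade_tips.items():
        if not members:
            raise ValueError(f"clade {clade!r} has no members")
        rep = sorted(members)[0]
        reps.append(rep)
        rename[rep] = clade
    collapsed = tree.prune_to_tips(reps)
    collapsed.tip_labels = [rename[lab] for lab in collapsed.tip_labels]
    return collapsed
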