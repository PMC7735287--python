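"""Shared event-mesh plumbing for diversity- and interaction-aware models.

An event mesh slices [0, T] (time from the crown root) at every branching
time and every regime-change time, so that within one interval the set of
alive lineages and their discrete states are both constant. Diversity-
dependent rate integrals and matching-competition propagation both consume
these intervals.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .treeio import Phylogeny

_EPS_REL = 1e-12


def build_event_mesh(tree: Phylogeny, regimes=None):
    """Intervals (t0, t1, alive_nodes, state_codes) covering (0, T].

    ``alive_nodes`` lists the child node of every edge crossing the interval;
    ``state_codes`` gives each such lineage's regime state (all 0 without a
    regime map). Zero-length edges never appear.
    """
    T = tree.depth
    eps = _EPS_REL * max(T, 1.0)
    times = {0.0, T}
    for v in range(tree.n_tips, tree.n_nodes):
        if v != tree.root:
            times.add(float(tree.node_time[v]))
    if regimes is not None:
        times.update(regimes.change_times())
    ts = sorted(times)
    merged = [ts[0]]
    for t in ts[1:]:
        if t - merged[-1] > eps:
            merged.append(t)
    merged[-1] = T
    intervals = []
    for t0, t1 in zip(merged[:-1], merged[1:]):
        tau = 0.5 * (t0 + t1)
        alive = [
            v
            for v in range(tree.n_nodes)
            if v != tree.root
            and tree.node_time[tree.parent[v]] < tau < tree.node_time[v]
        ]
        if regimes is not None:
            states = [regimes.state_code_at(v, tau) for v in alive]
        else:
            states = [0] * len(alive)
        intervals.append((t0, t1, np.array(alive, dtype=int), np.array(states, dtype=int)))
    return intervals


def edge_rate_segments(tree: Phylogeny, regimes=None):
    """Per non-root node: (durations, same-state lineage counts) along its edge.

    The count attached to a segment is the number of lineages alive in that
    segment that share the focal lineage's regime state (the global lineage
    count when no regime map is given). These are the piecewise-constant
    drivers of diversity-dependent rates.
    """
    mesh = build_event_mesh(tree, regimes)
    durs: dict[int, list[float]] = {v: [] for v in range(tree.n_nodes)}
    cnts: dict[int, list[int]] = {v: [] for v in range(tree.n_nodes)}
    for t0, t1, alive, states in mesh:
        by_state = Counter(states.tolist())
        for v, s in zip(alive, states):
            durs[v].append(t1 - t0)
            cnts[v].append(by_state[s])
    return {
        v: (np.asarray(durs[v]), np.asarray(cnts[v], dtype=float))
        for v in range(tree.n_nodes)
    }


def node_path_values(tree: Phylogeny, edge_values: dict[int, float]) -> np.ndarray:
    """Cumulative sums of per-edge values along each root-to-node path."""
    out = np.zeros(tree.n_nodes)
    for v in tree.preorder():
        if v != tree.root:
            out[v] = out[tree.parent[v]] + edge_values[v]
    return out


def pair_matrix_from_node_values(tree: Phylogeny, node_values: np.ndarray) -> np.ndarray:
    """Tip-pair matrix M_ij = value at the MRCA of tips i and j.

    The diagonal carries each tip's own value. Generalizes the shared-time
    matrix: node_values = node_time reproduces it.
    """
    n = tree.n_tips
    M = np.zeros((n, n))
    desc = tree.tip_descendants()
    for node in tree.preorder():
        if node < n:
            M[node, node] = node_values[node]
            continue
        kids = tree.children[node]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                da, db = desc[kids[a]], desc[kids[b]]
                M[np.ix_(da, db)] = node_values[node]
                M[np.ix_(db, da)] = node_values[node]
    return M
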