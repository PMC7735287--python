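"""Mk models and stochastic character maps of discrete regimes on trees.

A continuous-time Markov (Mk) model is fitted to tip states (guild
membership) by Felsenstein pruning; stochastic maps are then sampled by
drawing internal-node states from their joint conditional distribution and
filling in each edge's substitution history by endpoint-conditioned
uniformization. A RegimeMap records the piecewise-constant state along
every edge and is what structured DD/MC models consume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar, minimize

from .treeio import Phylogeny

__all__ = [
    "MkModel",
    "RegimeMap",
    "SamplingError",
    "fit_mk",
    "sample_maps",
    "write_simmap",
    "read_simmap",
    "flag_suspect",
]

MAX_UNIFORMIZATION_JUMPS = 1000


class SamplingError(RuntimeError):
    """Edge-history sampling failed; carries diagnostic context."""


@dataclass
class MkModel:
    """Continuous-time Markov model on <= a handful of discrete states."""

    states: list
    Q: np.ndarray
    root_prior: np.ndarray
    loglik: float | None = None

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        K = len(self.states)
        if self.Q.shape != (K, K):
            raise ValueError("Q dimension mismatch")
        if np.abs(self.Q.sum(axis=1)).max() > 1e-10 * max(np.abs(self.Q).max(), 1.0):
            raise ValueError("Q rows must sum to 0")
        if abs(self.root_prior.sum() - 1.0) > 1e-10:
            raise ValueError("root prior must sum to 1")

    def transition(self, t: float) -> np.ndarray:
        return expm(self.Q * t)


class RegimeMap:
    """Piecewise-constant discrete-state assignment along every edge.

    ``segments[node]`` lists (state_code, duration) pairs running from the
    parent end of the edge above ``node`` toward ``node``. State codes index
    ``states``.
    """

    def __init__(self, tree: Phylogeny, states: list, segments: dict):
        self.tree = tree
        self.states = list(states)
        self.segments = {}
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            segs = [(int(s), float(d)) for s, d in segments[v]]
            merged = []
            for s, d in segs:
                if merged and merged[-1][0] == s:
                    merged[-1] = (s, merged[-1][1] + d)
                else:
                    merged.append((s, d))
            total = sum(d for _, d in merged)
            if abs(total - tree.edge_length[v]) > 1e-9 * max(tree.depth, 1.0):
                raise ValueError(
                    f"segment durations on edge above node {v} sum to {total}, "
                    f"edge length {tree.edge_length[v]}"
                )
            self.segments[v] = merged

    def state_code_at(self, node: int, t: float) -> int:
        """State code on the edge above ``node`` at absolute time ``t``."""
        t0 = self.tree.node_time[self.tree.parent[node]]
        offset = t - t0
        acc = 0.0
        segs = self.segments[node]
        for s, d in segs:
            acc += d
            if offset <= acc:
                return s
        return segs[-1][0]

    def tip_state(self, tip: int) -> int:
        return self.segments[tip][-1][0]

    def change_times(self) -> list[float]:
        """Absolute times (from the root) of every state change on the tree."""
        out = []
        for v, segs in self.segments.items():
            t = float(self.tree.node_time[self.tree.parent[v]])
            for s, d in segs[:-1]:
                t += d
                out.append(t)
        return out

    def n_changes(self) -> int:
        return sum(len(segs) - 1 for segs in self.segments.values())


# ---------------------------------------------------------------------------
# Mk likelihood


def _as_state_codes(tree, tip_states, states):
    if isinstance(tip_states, dict):
        obs = [tip_states[lab] for lab in tree.tip_labels]
    else:
        obs = list(tip_states)
        if len(obs) != tree.n_tips:
            raise ValueError("tip_states not aligned to tree")
    if states is None:
        states = sorted(set(obs))
    index = {s: i for i, s in enumerate(states)}
    return np.array([index[s] for s in obs], dtype=int), list(states)


def _er_transition(K: int, q: float, t: float) -> np.ndarray:
    decay = math.exp(-K * q * t)
    P = np.full((K, K), (1.0 - decay) / K)
    np.fill_diagonal(P, 1.0 / K + (K - 1) / K * decay)
    return P


def _mk_loglik(tree, codes, K, trans_fn, root_prior):
    """Felsenstein pruning with per-node rescaling."""
    L = np.zeros((tree.n_nodes, K))
    logscale = 0.0
    L[np.arange(tree.n_tips), codes] = 1.0
    for v in tree.postorder():
        if v < tree.n_tips:
            continue
        part = np.ones(K)
        for c in tree.children[v]:
            P = trans_fn(tree.edge_length[c])
            part = part * (P @ L[c])
        m = part.max()
        if m <= 0 or not np.isfinite(m):
            return -np.inf, L, logscale
        L[v] = part / m
        logscale += math.log(m)
    lik = float(root_prior @ L[tree.root])
    if lik <= 0:
        return -np.inf, L, logscale
    return math.log(lik) + logscale, L, logscale


def _build_Q(model: str, K: int, rates: np.ndarray) -> np.ndarray:
    Q = np.zeros((K, K))
    if model == "ER":
        Q[:] = rates[0]
    elif model == "SYM":
        idx = 0
        for i in range(K):
            for j in range(i + 1, K):
                Q[i, j] = Q[j, i] = rates[idx]
                idx += 1
    elif model == "ARD":
        idx = 0
        for i in range(K):
            for j in range(K):
                if i != j:
                    Q[i, j] = rates[idx]
                    idx += 1
    else:
        raise ValueError(f"unknown Mk flavor {model!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _n_rates(model: str, K: int) -> int:
    return {"ER": 1, "SYM": K * (K - 1) // 2, "ARD": K * (K - 1)}[model]


def fit_mk(
    tree: Phylogeny,
    tip_states,
    model: str = "ER",
    states=None,
    root_prior: str = "equal",
) -> MkModel:
    """ML fit of an Mk model to tip states.

    With a single observed state the rate is exactly zero (warning). The
    default flavor is ER (one symmetric rate): with four guild states on
    clades of a few dozen tips, richer flavors are rarely identifiable.
    """
    codes, states = _as_state_codes(tree, tip_states, states)
    K = len(states)
    prior = np.full(K, 1.0 / K)
    if len(set(codes.tolist())) < 2:
        warnings.warn("single observed state: zero-rate Mk model")
        return MkModel(states, np.zeros((K, K)), prior, loglik=0.0)

    nr = _n_rates(model, K)

    def nll(log_rates):
        rates = np.exp(np.atleast_1d(log_rates))
        Q = _build_Q(model, K, rates)
        if model == "ER":
            trans = lambda t: _er_transition(K, rates[0], t)
        else:
            trans = lambda t: expm(Q * t)
        ll, _, _ = _mk_loglik(tree, codes, K, trans, prior)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    scale = max(tree.depth, 1e-12)
    lo, hi = math.log(1e-6 / scale), math.log(1e4 / scale)
    if model == "ER":
        grid = np.linspace(lo, hi, 9)
        vals = [nll(g) for g in grid]
        best = int(np.argmin(vals))
        res = minimize_scalar(
            nll,
            bounds=(grid[max(best - 1, 0)], grid[min(best + 1, len(grid) - 1)]),
            method="bounded",
            options={"xatol": 1e-7 * (hi - lo)},
        )
        log_rates = np.array([res.x if res.fun <= min(vals) else grid[best]])
    else:
        x0 = np.full(nr, math.log(1.0 / scale))
        res = minimize(nll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * nr)
        log_rates = res.x
    rates = np.exp(log_rates)
    Q = _build_Q(model, K, rates)
    if root_prior == "stationary":
        w, vr = np.linalg.eig(Q.T)
        pi = np.real(vr[:, np.argmin(np.abs(w))])
        prior = np.abs(pi) / np.abs(pi).sum()
    ll = -nll(log_rates if model != "ER" else log_rates[0])
    return MkModel(states, Q, prior, loglik=float(ll))


# ---------------------------------------------------------------------------
# stochastic map sampling


def _conditional_partials(tree, codes, mk: MkModel):
    K = len(mk.states)
    if np.allclose(mk.Q, 0.0):
        trans = lambda t: np.eye(K)
    else:
        cache = {}

        def trans(t):
            if t not in cache:
                cache[t] = mk.transition(t)
            return cache[t]

    _, L, _ = _mk_loglik(tree, codes, K, trans, mk.root_prior)
    return L, trans


def _sample_edge_history(Q, a, b, t, rng, max_jumps=MAX_UNIFORMIZATION_JUMPS):
    """Endpoint-conditioned substitution history by exact uniformization.

    Returns the list of (state, duration) segments from the parent end (state
    ``a``) to the child end (state ``b``) over duration ``t``.
    """
    K = Q.shape[0]
    if t <= 0:
        if a != b:
            raise SamplingError(f"zero-length edge with endpoint change {a}->{b}")
        return [(a, 0.0)]
    omega = float(np.max(-np.diag(Q)))
    if omega <= 0:
        if a != b:
            raise SamplingError("zero-rate model cannot connect differing endpoints")
        return [(a, t)]
    R = np.eye(K) + Q / omega
    # sample the number of uniformized jumps N from its exact conditional law
    powers = [np.eye(K)]
    pois = math.exp(-omega * t)
    target = rng.random()
    total = 0.0
    weights = []
    p_ab = None
    n_jumps = None
    for k in range(max_jumps + 1):
        if k > 0:
            powers.append(powers[-1] @ R)
            pois *= omega * t / k
        w = pois * powers[k][a, b]
        weights.append(w)
        total += w
        # normalizer converges to P_ab(t); stop once the tail is negligible
        if total > 0 and k >= 3:
            tail = pois * (omega * t) / (k + 1) / max(1.0 - omega * t / (k + 2), 0.5)
            if tail < 1e-12 * total:
                p_ab = total
                break
    else:
        raise SamplingError(
            f"uniformization did not converge within {max_jumps} jumps "
            f"(omega*t={omega * t:.3g}, endpoints {a}->{b})"
        )
    cum = 0.0
    for k, w in enumerate(weights):
        cum += w / p_ab
        if target <= cum:
            n_jumps = k
            break
    if n_jumps is None:
        n_jumps = len(weights) - 1
    if n_jumps == 0:
        return [(a, t)]
    # jump times: ordered uniforms; states: bridge through R powers
    times = np.sort(rng.random(n_jumps)) * t
    states = [a]
    for j in range(1, n_jumps):
        prev = states[-1]
        probs = R[prev] * powers[n_jumps - j][:, b]
        s = probs.sum()
        if s <= 0:
            raise SamplingError("inconsistent bridge probabilities")
        states.append(int(rng.choice(K, p=probs / s)))
    states.append(b)
    segments = []
    t_prev = 0.0
    for j in range(n_jumps):
        segments.append((states[j], float(times[j] - t_prev)))
        t_prev = float(times[j])
    segments.append((states[-1], float(t - t_prev)))
    return segments


def sample_maps(
    tree: Phylogeny,
    mk: MkModel,
    tip_states,
    n_maps: int = 50,
    seed=None,
) -> list[RegimeMap]:
    """Sample stochastic character maps conditioned on the tip states.

    For each map, internal-node states are drawn from the joint conditional
    distribution (pruning pass, root draw, preorder draws), then each edge's
    history is filled in conditional on its endpoints. Deterministic given
    ``seed``.
    """
    codes, _ = _as_state_codes(tree, tip_states, mk.states)
    K = len(mk.states)
    L, trans = _conditional_partials(tree, codes, mk)
    rng = np.random.default_rng(seed)
    edge_P = {
        v: trans(tree.edge_length[v]) for v in range(tree.n_nodes) if v != tree.root
    }
    maps = []
    for _ in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=int)
        pr = mk.root_prior * L[tree.root]
        node_state[tree.root] = rng.choice(K, p=pr / pr.sum())
        for v in tree.preorder():
            for c in tree.children[v]:
                if c < tree.n_tips:
                    node_state[c] = codes[c]
                    continue
                probs = edge_P[c][node_state[v]] * L[c]
                s = probs.sum()
                node_state[c] = rng.choice(K, p=probs / s)
        segments = {}
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            segments[v] = _sample_edge_history(
                mk.Q, int(node_state[tree.parent[v]]), int(node_state[v]),
                float(tree.edge_length[v]), rng,
            )
        maps.append(RegimeMap(tree, mk.states, segments))
    return maps


def flag_suspect(maps: list[RegimeMap], threshold: float = 10.0) -> bool:
    """Flag unreliable reconstructions: too many back-and-forth changes.

    The map-mean number of state changes, per unit of total branch length
    measured in tree depths, must stay below ``threshold`` (default 10
    changes per tree depth of branch).
    """
    if not maps:
        return False
    tree = maps[0].tree
    mean_changes = float(np.mean([m.n_changes() for m in maps]))
    depth_equivalents = tree.total_branch_length() / tree.depth
    return mean_changes / depth_equivalents > threshold


# ---------------------------------------------------------------------------
# SIMMAP text round-trip


def write_simmap(rmap: RegimeMap, tree: Phylogeny | None = None) -> str:
    """SIMMAP-dialect Newick: edges annotated {state,dur:state,dur:...}.

    Segments run from the parent end of each edge toward the tip, matching
    the internal representation.
    """
    tree = tree if tree is not None else rmap.tree
    if tree is not rmap.tree and tree.tip_labels != rmap.tree.tip_labels:
        raise ValueError("map/tree mismatch")

    def annot(v):
        return ":".join(
            f"{rmap.states[s]},{d:.17g}" for s, d in rmap.segments[v]
        )

    def rec(v):
        if v < tree.n_tips:
            return f"{tree.tip_labels[v]}:{{{annot(v)}}}"
        inner = ",".join(rec(c) for c in tree.children[v])
        if v == tree.root:
            return f"({inner})"
        return f"({inner}):{{{annot(v)}}}"

    return rec(tree.root) + ";"


def read_simmap(text: str) -> tuple[Phylogeny, RegimeMap]:
    """Parse a SIMMAP-dialect Newick string back into a tree plus map."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse_annot():
        nonlocal pos
        assert text[pos] == "{"
        end = text.index("}", pos)
        body = text[pos + 1 : end]
        pos = end + 1
        segs = []
        for piece in body.split(":"):
            state, dur = piece.rsplit(",", 1)
            segs.append((state, float(dur)))
        return segs

    def parse_node():
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = [parse_node()]
            while text[pos] == ",":
                pos += 1
                children.append(parse_node())
            assert text[pos] == ")"
            pos += 1
            label = ""
            node = ("internal", children, None)
        else:
            start = pos
            while pos < len(text) and text[pos] not in ":,(){}":
                pos += 1
            node = ("tip", text[start:pos], None)
        segs = None
        if pos < len(text) and text[pos] == ":":
            pos += 1
            segs = parse_annot()
        return (node[0], node[1], segs)

    root = parse_node()
    tips, parents, elens, segdata = [], [], [], []
    nodes = []  # (kind, payload, segs, parent_slot)

    def collect(node, parent_slot):
        kind, payload, segs = node
        slot = len(nodes)
        nodes.append([kind, payload, segs, parent_slot])
        if kind == "internal":
            for c in payload:
                collect(c, slot)

    collect(root, -1)
    tip_slots = [i for i, nd in enumerate(nodes) if nd[0] == "tip"]
    internal_slots = [i for i, nd in enumerate(nodes) if nd[0] == "internal"]
    index = {slot: i for i, slot in enumerate(tip_slots)}
    for slot in internal_slots:
        index[slot] = len(index)
    n_nodes = len(nodes)
    parent = np.full(n_nodes, -1, dtype=int)
    elen = np.zeros(n_nodes)
    state_labels = []
    for slot, nd in enumerate(nodes):
        if nd[3] >= 0:
            parent[index[slot]] = index[nd[3]]
            elen[index[slot]] = sum(d for _, d in nd[2])
            for s, _ in nd[2]:
                if s not in state_labels:
                    state_labels.append(s)
    labels = [nodes[s][1] for s in tip_slots]
    tree = Phylogeny(labels, parent, elen)
    state_labels = sorted(state_labels)
    code = {s: i for i, s in enumerate(state_labels)}
    segments = {}
    for slot, nd in enumerate(nodes):
        if nd[3] >= 0:
            segments[index[slot]] = [(code[s], d) for s, d in nd[2]]
    return tree, RegimeMap(tree, state_labels, segments)
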