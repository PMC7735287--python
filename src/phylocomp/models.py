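"""The seven trait-evolution models and trait simulation on trees.

Independent-evolution models: BM (random walk), OU (constraint of strength
alpha toward the root state), TDlin/TDexp (rate a linear/exponential
function of time since the root). Competition-consistent models: DDlin/DDexp
(rate a linear/exponential function of the number of coexisting lineages)
and MC, the matching-competition model, in which each lineage's trait is
pushed away from the mean of its interacting contemporaries with strength
S <= 0. DD and MC optionally restrict interactions/counts to lineages that
share a discrete regime state (ecoguild) supplied as a RegimeMap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _paths
from .treeio import LineageCountFunction, Phylogeny, TraitVector, lineage_count

__all__ = [
    "MODEL_NAMES",
    "COMPETITION_MODELS",
    "INDEPENDENT_MODELS",
    "ModelParams",
    "ModelSpec",
    "ParameterDomainError",
    "effective_rate",
    "simulate_trait",
    "simulate_traits",
]

MODEL_NAMES = ("BM", "OU", "TDlin", "TDexp", "DDlin", "DDexp", "MC")
INDEPENDENT_MODELS = ("BM", "OU", "TDlin", "TDexp")
COMPETITION_MODELS = ("DDlin", "DDexp", "MC")

RATE_CLAMP = 1e-8  # effective rates below this (relative) are rejected
MC_DEFAULT_STEPS = 2000  # Euler grid steps over the tree depth


class ParameterDomainError(ValueError):
    """Parameter combination outside a model's admissible domain."""


@dataclass
class ModelParams:
    """Natural-scale parameters; only the fields a model uses are read.

    sig2 : base rate sigma^2 (trait^2 / time), > 0
    alpha : OU constraint (1/time), >= 0
    slope_t, rate_t : linear slope / exponential exponent of time dependence
    slope_n, rate_n : linear slope / exponential exponent of diversity
        dependence (per lineage)
    S : matching-competition strength (1/time), <= 0 (repulsion)
    z0 : root trait value
    """

    sig2: float = 1.0
    alpha: float = 0.0
    slope_t: float = 0.0
    rate_t: float = 0.0
    slope_n: float = 0.0
    rate_n: float = 0.0
    S: float = 0.0
    z0: float = 0.0

    def __post_init__(self):
        if self.sig2 <= 0:
            raise ParameterDomainError("sig2 must be positive")
        if self.alpha < 0:
            raise ParameterDomainError("alpha must be nonnegative")
        if self.S > 0:
            raise ParameterDomainError("S must be <= 0 (repulsion convention)")


@dataclass
class ModelSpec:
    name: str
    params: ModelParams = field(default_factory=ModelParams)
    interaction_structured: bool = False

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        if self.interaction_structured and self.name not in ("DDlin", "DDexp", "MC"):
            raise ValueError(
                f"interaction_structured is only valid for DDlin/DDexp/MC, not {self.name}"
            )

    @property
    def is_competition(self) -> bool:
        return self.name in COMPETITION_MODELS


def effective_rate(spec: ModelSpec, t: float, n: LineageCountFunction | None = None) -> float:
    """Instantaneous rate sigma^2(t) of the diffusion part of the model."""
    p = spec.params
    if spec.name in ("BM", "OU", "MC"):
        return p.sig2
    if spec.name == "TDlin":
        rate = p.sig2 + p.slope_t * t
    elif spec.name == "TDexp":
        rate = p.sig2 * math.exp(p.rate_t * t)
    elif spec.name in ("DDlin", "DDexp"):
        if n is None:
            raise ValueError("diversity-dependent rate needs a LineageCountFunction")
        count = n.count_at(t)
        if spec.name == "DDlin":
            rate = p.sig2 + p.slope_n * count
        else:
            rate = p.sig2 * math.exp(p.rate_n * count)
    else:  # pragma: no cover
        raise ValueError(spec.name)
    if rate < RATE_CLAMP * p.sig2:
        raise ParameterDomainError(
            f"{spec.name} effective rate {rate:.3g} at t={t:.3g} below clamp"
        )
    return rate


# ---------------------------------------------------------------------------
# simulation


def _edge_variances(tree: Phylogeny, spec: ModelSpec, regimes) -> np.ndarray:
    """Integrated rate over each edge (Gaussian increment variance)."""
    p = spec.params
    out = np.zeros(tree.n_nodes)
    if spec.name == "BM":
        return p.sig2 * tree.edge_length
    if spec.name in ("TDlin", "TDexp"):
        t0 = tree.node_time[tree.parent]
        t1 = tree.node_time
        if spec.name == "TDlin":
            out = p.sig2 * (t1 - t0) + 0.5 * p.slope_t * (t1**2 - t0**2)
            if np.any(p.sig2 + p.slope_t * np.maximum(t0, t1) < RATE_CLAMP * p.sig2):
                raise ParameterDomainError("TDlin rate below clamp on some edge")
        else:
            r = p.rate_t
            if abs(r) < 1e-14:
                out = p.sig2 * (t1 - t0)
            else:
                out = p.sig2 * (np.exp(r * t1) - np.exp(r * t0)) / r
        out[tree.root] = 0.0
        return out
    if spec.name in ("DDlin", "DDexp"):
        segs = _paths.edge_rate_segments(tree, regimes if spec.interaction_structured else None)
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            d, c = segs[v]
            if len(d) == 0:
                out[v] = 0.0
            elif spec.name == "DDlin":
                rates = p.sig2 + p.slope_n * c
                if np.any(rates < RATE_CLAMP * p.sig2):
                    raise ParameterDomainError("DDlin rate below clamp")
                out[v] = float(np.sum(rates * d))
            else:
                out[v] = float(p.sig2 * np.sum(np.exp(p.rate_n * c) * d))
        return out
    raise ValueError(f"no closed-form edge variance for {spec.name}")


def _simulate_gaussian(tree, spec, regimes, rng, n_reps):
    p = spec.params
    vals = np.empty((n_reps, tree.n_nodes))
    vals[:, tree.root] = p.z0
    if spec.name == "OU" and p.alpha > 0:
        a = p.alpha
        for v in tree.preorder():
            if v == tree.root:
                continue
            dt = tree.edge_length[v]
            decay = math.exp(-a * dt)
            var = p.sig2 / (2 * a) * (1 - math.exp(-2 * a * dt))
            parent = vals[:, tree.parent[v]]
            vals[:, v] = p.z0 + (parent - p.z0) * decay + rng.normal(
                0.0, math.sqrt(var), size=n_reps
            )
    else:
        spec_eff = spec if spec.name != "OU" else replace(spec, name="BM")
        evar = _edge_variances(tree, spec_eff, regimes)
        for v in tree.preorder():
            if v == tree.root:
                continue
            vals[:, v] = vals[:, tree.parent[v]] + rng.normal(
                0.0, math.sqrt(max(evar[v], 0.0)), size=n_reps
            )
    return vals[:, : tree.n_tips]


def _mc_grid_steps(spec: ModelSpec, depth: float, n_steps: int) -> int:
    # refine the grid when |S| h > 0.01 for drift stability
    h = depth / n_steps
    if abs(spec.params.S) * h > 0.01:
        n_steps = int(math.ceil(abs(spec.params.S) * depth / 0.01))
    return n_steps


def _simulate_interacting(tree, spec, regimes, rng, n_reps, n_steps):
    """Euler-Maruyama on a shared global time grid for MC (or gridded BM)."""
    p = spec.params
    T = tree.depth
    n_steps = _mc_grid_steps(spec, T, n_steps)
    h = T / n_steps
    sqrt_noise = math.sqrt(p.sig2 * h)
    # branching schedule: internal nodes (excluding root) in time order
    order = sorted(
        (v for v in range(tree.n_tips, tree.n_nodes) if v != tree.root),
        key=lambda v: (tree.node_time[v], v),
    )
    alive = list(tree.children[tree.root])
    z = np.full((n_reps, len(alive)), float(p.z0))
    next_event = 0
    for step in range(n_steps):
        t_mid = (step + 0.5) * h
        # process branchings that occur before this step's midpoint
        while next_event < len(order) and tree.node_time[order[next_event]] <= t_mid:
            u = order[next_event]
            idx = alive.index(u)
            kids = tree.children[u]
            alive[idx] = kids[0]
            alive.append(kids[1])
            z = np.column_stack([z, z[:, idx]])
            next_event += 1
        k = len(alive)
        if p.S != 0.0:
            if spec.interaction_structured and regimes is not None:
                states = np.array([regimes.state_code_at(v, t_mid) for v in alive])
                mu = np.empty_like(z)
                for s in np.unique(states):
                    cols = np.flatnonzero(states == s)
                    mu[:, cols] = z[:, cols].mean(axis=1, keepdims=True)
            else:
                mu = z.mean(axis=1, keepdims=True) * np.ones((1, k))
            z = z + p.S * (mu - z) * h + sqrt_noise * rng.standard_normal((n_reps, k))
        else:
            z = z + sqrt_noise * rng.standard_normal((n_reps, k))
    while next_event < len(order):  # branchings in the final half-step
        u = order[next_event]
        idx = alive.index(u)
        kids = tree.children[u]
        alive[idx] = kids[0]
        alive.append(kids[1])
        z = np.column_stack([z, z[:, idx]])
        next_event += 1
    out = np.empty((n_reps, tree.n_tips))
    for j, v in enumerate(alive):
        out[:, v] = z[:, j]
    return out


def simulate_traits(
    tree: Phylogeny,
    spec: ModelSpec,
    n_reps: int,
    regimes=None,
    seed=None,
    n_steps: int = MC_DEFAULT_STEPS,
    method: str = "exact",
) -> np.ndarray:
    """Simulate ``n_reps`` independent trait vectors; rows align to tip order.

    Gaussian models use exact per-branch increments; MC uses Euler-Maruyama
    on a shared global grid (``n_steps`` over the depth, refined when
    |S|*h > 0.01). ``method='euler'`` forces the gridded path for BM too,
    which reproduces MC with S=0 step for step.
    """
    if spec.interaction_structured and regimes is None:
        raise ValueError(f"{spec.name} with interaction_structured needs a RegimeMap")
    if spec.name in ("DDlin", "DDexp", "MC"):
        tree.require_ultrametric(spec.name + " simulation")
    rng = np.random.default_rng(seed)
    if spec.name == "MC" or (method == "euler" and spec.name == "BM"):
        sim_spec = spec if spec.name == "MC" else replace(spec, name="MC")
        return _simulate_interacting(tree, sim_spec, regimes, rng, n_reps, n_steps)
    if method != "exact":
        raise ValueError("method='euler' is only supported for BM and MC")
    return _simulate_gaussian(tree, spec, regimes, rng, n_reps)


def simulate_trait(
    tree: Phylogeny,
    spec: ModelSpec,
    regimes=None,
    seed=None,
    n_steps: int = MC_DEFAULT_STEPS,
    method: str = "exact",
    trait_name: str = "trait",
) -> TraitVector:
    """One simulated trait vector (deterministic given ``seed``)."""
    row = simulate_traits(
        tree, spec, 1, regimes=regimes, seed=seed, n_steps=n_steps, method=method
    )[0]
    return TraitVector(row, trait_name=trait_name, tip_labels=tree.tip_labels)
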