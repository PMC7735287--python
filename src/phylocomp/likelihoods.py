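"""Exact tip moments and Gaussian log-likelihoods for every model.

All seven models imply a multivariate normal distribution of tip traits
x ~ N(z0 * 1, V). For BM/OU/TD, V has textbook closed forms in the shared
times t_ij from the root to each pair's MRCA. For DD, V_ij is the integral
of the (possibly regime-structured) rate along the shared root-to-MRCA
path. For MC, the joint covariance of all alive lineages is propagated
through time: within an interval between events the interaction matrix
A = S (P - I) is block diagonal by regime with P_g = J/n_g inside a block,
so exp(A dt) and the accumulated noise integral have exact projector forms
(no numerical ODE solve is needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from . import _paths
from .models import ModelSpec, ParameterDomainError, RATE_CLAMP
from .treeio import LineageCountFunction, Phylogeny, TraitVector

__all__ = [
    "TipMoments",
    "NumericalError",
    "CovarianceWorkspace",
    "moments_independent",
    "moments_diversity",
    "moments_mc",
    "moments",
    "loglik",
]


class NumericalError(RuntimeError):
    """Covariance not positive definite even after jitter."""


@dataclass
class TipMoments:
    """Mean vector and covariance matrix of tip traits under a model."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        n = len(self.mean)
        if self.cov.shape != (n, n):
            raise ValueError("mean/cov dimension mismatch")
        scale = max(np.abs(self.cov).max(), 1e-300)
        if np.abs(self.cov - self.cov.T).max() > 1e-10 * scale:
            raise ValueError("covariance not symmetric")


class CovarianceWorkspace:
    """Cached per-(tree, regime-map) structures for fast covariance builds.

    ``unit_cov(name, shape)`` returns the covariance for sigma^2 = 1 with
    linear slopes expressed *relative* to sigma^2 (so every model's V is
    proportional to sigma^2, which is what lets the fitter concentrate
    sigma^2 out of the likelihood).
    """

    def __init__(self, tree: Phylogeny, regimes=None):
        self.tree = tree
        self.regimes = regimes
        self.T = tree.depth
        self._desc = tree.tip_descendants()
        self._tstar = None
        self._segs = None
        self._mc_program = None
        counts = None

    @property
    def tstar(self) -> np.ndarray:
        if self._tstar is None:
            self._tstar = self.tree.shared_time_matrix()
        return self._tstar

    @property
    def n_max(self) -> int:
        return self.tree.n_tips

    # -- diversity-dependent path integrals ---------------------------------

    def _segments(self):
        if self._segs is None:
            self._segs = _paths.edge_rate_segments(self.tree, self.regimes)
        return self._segs

    def _pair_matrix(self, node_values: np.ndarray) -> np.ndarray:
        tree = self.tree
        n = tree.n_tips
        M = np.zeros((n, n))
        for node in tree.preorder():
            if node < n:
                M[node, node] = node_values[node]
                continue
            kids = tree.children[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    da, db = self._desc[kids[a]], self._desc[kids[b]]
                    M[np.ix_(da, db)] = node_values[node]
                    M[np.ix_(db, da)] = node_values[node]
        return M

    def _dd_unit_cov(self, name: str, shape: float) -> np.ndarray:
        segs = self._segments()
        tree = self.tree
        edge_int = {}
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            d, c = segs[v]
            if len(d) == 0:
                edge_int[v] = 0.0
            elif name == "DDlin":
                rates = 1.0 + shape * c
                if np.any(rates < RATE_CLAMP):
                    raise ParameterDomainError("DDlin relative rate below clamp")
                edge_int[v] = float(np.sum(rates * d))
            else:
                edge_int[v] = float(np.sum(np.exp(shape * c) * d))
        vals = _paths.node_path_values(tree, edge_int)
        return self._pair_matrix(vals)

    # -- matching competition ------------------------------------------------

    def _build_mc_program(self):
        """Event-ordered ops replayed for each S: ('prop', dt, groups) and
        ('branch', idx); ends with the permutation mapping alive order to
        tip order."""
        tree, regimes = self.tree, self.regimes
        T = tree.depth
        eps = 1e-12 * max(T, 1.0)
        pre_rank = {v: i for i, v in enumerate(tree.preorder())}
        events = sorted(
            (v for v in range(tree.n_tips, tree.n_nodes) if v != tree.root),
            key=lambda v: (tree.node_time[v], pre_rank[v]),
        )
        change_times = sorted(regimes.change_times()) if regimes is not None else []
        ops = []
        alive = list(tree.children[tree.root])
        t_cur = 0.0
        ev_i = 0
        while True:
            t_next = tree.node_time[events[ev_i]] if ev_i < len(events) else T
            # propagate t_cur -> t_next, split at regime changes
            cuts = [t for t in change_times if t_cur + eps < t < t_next - eps]
            for a, b in zip([t_cur] + cuts, cuts + [t_next]):
                if b - a <= eps:
                    continue
                tau = 0.5 * (a + b)
                if regimes is not None:
                    states = np.array(
                        [regimes.state_code_at(v, tau) for v in alive]
                    )
                else:
                    states = np.zeros(len(alive), dtype=int)
                groups = [
                    np.flatnonzero(states == s) for s in np.unique(states)
                ]
                ops.append(("prop", b - a, groups))
            if ev_i >= len(events):
                break
            # all branchings at (numerically) this time, parents first
            while ev_i < len(events) and tree.node_time[events[ev_i]] <= t_next + eps:
                u = events[ev_i]
                idx = alive.index(u)
                kids = tree.children[u]
                alive[idx] = kids[0]
                alive.append(kids[1])
                ops.append(("branch", idx))
                ev_i += 1
            t_cur = t_next
        perm = np.empty(tree.n_tips, dtype=int)
        for pos, v in enumerate(alive):
            perm[v] = pos
        return ops, perm

    def _mc_unit_cov(self, S: float) -> np.ndarray:
        if self._mc_program is None:
            self._mc_program = self._build_mc_program()
        ops, perm = self._mc_program
        k = 2
        V = np.zeros((2, 2))
        for op in ops:
            if op[0] == "branch":
                idx = op[1]
                V = np.vstack([V, V[idx]])
                V = np.column_stack([V, V[:, idx]])
                k += 1
            else:
                _, dt, groups = op
                phi = math.exp(-S * dt)  # S <= 0 so phi >= 1
                if S != 0.0:
                    psi = (math.exp(-2 * S * dt) - 1.0) / (-2.0 * S)
                else:
                    psi = dt
                E = np.zeros((k, k))
                np.fill_diagonal(E, phi)
                W = np.zeros((k, k))
                np.fill_diagonal(W, psi)
                for g in groups:
                    ng = len(g)
                    E[np.ix_(g, g)] += (1.0 - phi) / ng
                    W[np.ix_(g, g)] += (dt - psi) / ng
                V = E @ V @ E.T + W
        V = V[np.ix_(perm, perm)]
        return 0.5 * (V + V.T)

    # -- dispatch -------------------------------------------------------------

    def unit_cov(self, name: str, shape: float | None = None) -> np.ndarray:
        """Unit-sigma^2 covariance; ``shape`` is the model's free shape
        parameter (alpha, r_t, r_n, S, or a sigma^2-relative linear slope)."""
        t = self.tstar
        T = self.T
        if name == "BM" or shape is None or (name != "MC" and abs(shape) < 1e-14):
            if name == "OU":
                self.tree.require_ultrametric("OU covariance")
            return t.copy()
        if name == "OU":
            self.tree.require_ultrametric("OU covariance")
            a = shape
            return (1.0 / (2 * a)) * (1 - np.exp(-2 * a * t)) * np.exp(-2 * a * (T - t))
        if name == "TDlin":
            if 1.0 + shape * T < RATE_CLAMP or 1.0 + shape * 0.0 < RATE_CLAMP:
                raise ParameterDomainError("TDlin relative rate below clamp")
            return t + 0.5 * shape * t * t
        if name == "TDexp":
            return (np.exp(shape * t) - 1.0) / shape
        if name in ("DDlin", "DDexp"):
            self.tree.require_ultrametric("diversity-dependent covariance")
            return self._dd_unit_cov(name, shape)
        if name == "MC":
            self.tree.require_ultrametric("MC covariance")
            if shape > 0:
                raise ParameterDomainError("MC requires S <= 0")
            return self._mc_unit_cov(shape)
        raise ValueError(f"unknown model {name!r}")


def _shape_of(spec: ModelSpec) -> float | None:
    p = spec.params
    return {
        "BM": None,
        "OU": p.alpha,
        "TDlin": p.slope_t / p.sig2,
        "TDexp": p.rate_t,
        "DDlin": p.slope_n / p.sig2,
        "DDexp": p.rate_n,
        "MC": p.S,
    }[spec.name]


def moments_independent(tree: Phylogeny, spec: ModelSpec) -> TipMoments:
    """Tip moments under BM, OU, TDlin or TDexp."""
    if spec.name not in ("BM", "OU", "TDlin", "TDexp"):
        raise ValueError(f"moments_independent does not handle {spec.name}")
    ws = CovarianceWorkspace(tree)
    V = spec.params.sig2 * ws.unit_cov(spec.name, _shape_of(spec))
    mean = np.full(tree.n_tips, spec.params.z0)
    return TipMoments(mean, V)


def moments_diversity(
    tree: Phylogeny,
    spec: ModelSpec,
    n: LineageCountFunction | None = None,
    regimes=None,
) -> TipMoments:
    """Tip moments under DDlin/DDexp, optionally regime-structured.

    ``n`` may be passed for interface symmetry but the lineage counts are
    always rebuilt from the tree (and regime map) so the per-lineage
    structured counts stay consistent.
    """
    if spec.name not in ("DDlin", "DDexp"):
        raise ValueError(f"moments_diversity does not handle {spec.name}")
    ws = CovarianceWorkspace(tree, regimes if spec.interaction_structured else None)
    V = spec.params.sig2 * ws.unit_cov(spec.name, _shape_of(spec))
    return TipMoments(np.full(tree.n_tips, spec.params.z0), V)


def moments_mc(tree: Phylogeny, spec: ModelSpec, regimes=None) -> TipMoments:
    """Tip moments under the matching-competition model."""
    if spec.name != "MC":
        raise ValueError(f"moments_mc does not handle {spec.name}")
    ws = CovarianceWorkspace(tree, regimes if spec.interaction_structured else None)
    V = spec.params.sig2 * ws.unit_cov("MC", spec.params.S)
    return TipMoments(np.full(tree.n_tips, spec.params.z0), V)


def moments(tree: Phylogeny, spec: ModelSpec, regimes=None) -> TipMoments:
    """Dispatch to the right moments routine for any model."""
    if spec.name in ("BM", "OU", "TDlin", "TDexp"):
        return moments_independent(tree, spec)
    if spec.name in ("DDlin", "DDexp"):
        return moments_diversity(tree, spec, regimes=regimes)
    return moments_mc(tree, spec, regimes=regimes)


def chol_with_jitter(V: np.ndarray):
    """Cholesky factor of V, adding a trace-scaled jitter once if needed."""
    try:
        return cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-10 * np.trace(V) / max(len(V), 1)
    try:
        return cho_factor(V + jitter * np.eye(len(V)), lower=True)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("covariance indefinite after jitter") from exc


def loglik(x, m: TipMoments) -> float:
    """Multivariate-normal log density of tip data under the model moments."""
    vals = x.values if isinstance(x, TraitVector) else np.asarray(x, dtype=float)
    n = len(vals)
    if len(m.mean) != n:
        raise ValueError("dimension mismatch between data and moments")
    cf = chol_with_jitter(m.cov)
    r = vals - m.mean
    q = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (n * math.log(2 * math.pi) + logdet + q)
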