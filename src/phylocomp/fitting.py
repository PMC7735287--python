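"""Maximum-likelihood fitting, AICc comparison and competition flagging.

Every model's tip covariance is proportional to sigma^2 once linear slopes
are expressed relative to sigma^2, and the root state z0 enters only the
mean. Both are therefore concentrated out analytically (z0 by GLS, sigma^2
by its closed-form ML value), leaving at most one free shape parameter per
model. That parameter is maximized by a deterministic coarse-grid scan over
documented transformed bounds followed by bounded Brent refinement.

The competition flag follows the AICc rule: a clade x trait is flagged when
the best model is DDlin, DDexp or MC and its AICc beats the best
independent-evolution model (BM/OU/TDlin/TDexp) by more than two units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import cho_solve
from scipy.optimize import minimize_scalar

from .likelihoods import CovarianceWorkspace, NumericalError, chol_with_jitter
from .models import (
    COMPETITION_MODELS,
    INDEPENDENT_MODELS,
    MODEL_NAMES,
    ModelParams,
    ModelSpec,
    ParameterDomainError,
)
from .treeio import Phylogeny, TraitVector

__all__ = [
    "FitResult",
    "ModelComparison",
    "ComparisonTable",
    "fit_model",
    "fit_all_models",
    "aicc",
    "compare_models",
    "comparison_table",
    "pgls_residuals",
]

N_PARAMS = {name: (2 if name == "BM" else 3) for name in MODEL_NAMES}

# transformed-scale envelopes: log alpha, S, and log relative-rate factors
LOG_ALPHA_BOUNDS = (-10.0, 7.0)
S_BOUNDS = (-50.0, 0.0)
LOG_RATE_FACTOR_BOUNDS = (math.log(1e-8), math.log(1e6))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n-k-1 <= 0)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    """One maximum-likelihood fit of one model to one clade x trait."""

    spec: ModelSpec
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    n_restarts_used: int = 0
    map_id: str | None = None
    clade: str | None = None
    trait: str | None = None
    per_map: list | None = None

    @property
    def model(self) -> str:
        return self.spec.name


def _profile_loglik(x: np.ndarray, M: np.ndarray):
    """Concentrated log-likelihood: z0 by GLS, sigma^2 by its ML value."""
    n = len(x)
    cf = chol_with_jitter(M)
    ones = np.ones(n)
    Mi_one = cho_solve(cf, ones)
    Mi_x = cho_solve(cf, x)
    z0 = float(ones @ Mi_x) / float(ones @ Mi_one)
    r = x - z0
    q = float(r @ cho_solve(cf, r))
    sig2 = max(q / n, 1e-300)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ll = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sig2) + logdet + n)
    return ll, z0, sig2


def _shape_transform(name: str, T: float, n_max: int):
    """(bounds in transformed coordinate g, g -> natural shape parameter)."""
    lo, hi = LOG_RATE_FACTOR_BOUNDS
    if name == "OU":
        return LOG_ALPHA_BOUNDS, lambda g: math.exp(g)
    if name == "TDexp":
        return (lo / T, hi / T), lambda g: g  # g is r_t, factor bound at t=T
    if name == "TDlin":
        return (lo, hi), lambda g: (math.exp(g) - 1.0) / T
    if name == "DDexp":
        return (lo / n_max, hi / n_max), lambda g: g
    if name == "DDlin":
        return (lo, hi), lambda g: (math.exp(g) - 1.0) / n_max
    if name == "MC":
        # dense near S=0: S = -(e^g - 1), g in [0, log(1+50)]
        return (0.0, math.log(1.0 - S_BOUNDS[0])), lambda g: -(math.expm1(g))
    raise ValueError(name)


def _params_from(name: str, shape, sig2: float, z0: float) -> ModelParams:
    p = ModelParams(sig2=sig2, z0=z0)
    if name == "OU":
        p.alpha = shape
    elif name == "TDlin":
        p.slope_t = sig2 * shape
    elif name == "TDexp":
        p.rate_t = shape
    elif name == "DDlin":
        p.slope_n = sig2 * shape
    elif name == "DDexp":
        p.rate_n = shape
    elif name == "MC":
        p.S = shape
    return p


def _fit_single(tree, x, name, ws, n_starts, map_id=None, clade=None, trait=None):
    n = tree.n_tips
    k = N_PARAMS[name]

    def nll(shape):
        # extreme shapes can render the covariance numerically singular
        # (condition ~ e^{2|S|T}); treat that as out-of-domain, not fatal
        try:
            M = ws.unit_cov(name, shape)
            ll, _, _ = _profile_loglik(x, M)
        except (ParameterDomainError, NumericalError, FloatingPointError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    if name == "BM":
        M = ws.unit_cov("BM")
        ll, z0, sig2 = _profile_loglik(x, M)
        spec = ModelSpec("BM", ModelParams(sig2=sig2, z0=z0))
        return FitResult(spec, ll, k, n, aicc(ll, k, n), True, 0, map_id, clade, trait)

    (g_lo, g_hi), to_shape = _shape_transform(name, tree.depth, n)
    grid = np.linspace(g_lo, g_hi, n_starts)
    vals = [nll(to_shape(g)) for g in grid]
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda g: nll(to_shape(g)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6 * (g_hi - g_lo)},
    )
    g_best, f_best = (res.x, res.fun) if res.fun <= min(vals) else (grid[best], vals[best])
    converged = bool(res.success) and f_best < 1e11
    shape = to_shape(g_best)
    M = ws.unit_cov(name, shape)
    ll, z0, sig2 = _profile_loglik(x, M)
    spec = ModelSpec(
        name,
        _params_from(name, shape, sig2, z0),
        interaction_structured=ws.regimes is not None and name in COMPETITION_MODELS,
    )
    return FitResult(spec, ll, k, n, aicc(ll, k, n), converged, n_starts, map_id, clade, trait)


def fit_model(
    tree: Phylogeny,
    x,
    name: str,
    regimes=None,
    n_starts: int = 8,
    clade: str | None = None,
    trait: str | None = None,
    workspace=None,
) -> FitResult:
    """Fit one model by maximum likelihood.

    ``regimes`` may be a single RegimeMap, a list of maps (the model is then
    fitted separately per map and the map-mean AICc/log-likelihood/parameters
    reported, per-map fits retained in ``per_map``), or None.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}")
    vals = x.values if isinstance(x, TraitVector) else np.asarray(x, dtype=float)
    if trait is None and isinstance(x, TraitVector):
        trait = x.trait_name
    n = tree.n_tips
    if n < 4:
        raise ValueError("model fitting requires at least 4 tips")
    if len(vals) != n:
        raise ValueError("trait not aligned to tree")
    k = N_PARAMS[name]
    if n - k - 1 <= 0:
        raise ValueError(f"n={n} too small for k={k}")

    if isinstance(regimes, (list, tuple)):
        if isinstance(workspace, (list, tuple)):
            if len(workspace) != len(regimes):
                raise ValueError("one workspace per regime map required")
            ws_list = list(workspace)
        else:
            ws_list = [
                CovarianceWorkspace(tree, rm if name in COMPETITION_MODELS else None)
                for rm in regimes
            ]
        per_map = []
        for i, ws in enumerate(ws_list):
            per_map.append(
                _fit_single(tree, vals, name, ws, n_starts, map_id=str(i), clade=clade, trait=trait)
            )
        mean_ll = float(np.mean([f.loglik for f in per_map]))
        mean_aicc = float(np.mean([f.aicc for f in per_map]))
        mean_params = ModelParams(
            sig2=float(np.mean([f.spec.params.sig2 for f in per_map])),
            alpha=float(np.mean([f.spec.params.alpha for f in per_map])),
            slope_t=float(np.mean([f.spec.params.slope_t for f in per_map])),
            rate_t=float(np.mean([f.spec.params.rate_t for f in per_map])),
            slope_n=float(np.mean([f.spec.params.slope_n for f in per_map])),
            rate_n=float(np.mean([f.spec.params.rate_n for f in per_map])),
            S=float(np.mean([f.spec.params.S for f in per_map])),
            z0=float(np.mean([f.spec.params.z0 for f in per_map])),
        )
        spec = ModelSpec(
            name, mean_params, interaction_structured=name in COMPETITION_MODELS
        )
        return FitResult(
            spec,
            mean_ll,
            k,
            n,
            mean_aicc,
            converged=all(f.converged for f in per_map),
            n_restarts_used=n_starts,
            map_id=f"mean-of-{len(per_map)}",
            clade=clade,
            trait=trait,
            per_map=per_map,
        )

    if workspace is None:
        workspace = CovarianceWorkspace(
            tree, regimes if name in COMPETITION_MODELS else None
        )
    return _fit_single(tree, vals, name, workspace, n_starts, clade=clade, trait=trait)


def fit_all_models(
    tree, x, names=MODEL_NAMES, regimes=None, n_starts: int = 8, clade=None, trait=None
) -> list[FitResult]:
    """Fit several models to the same clade x trait; shares workspaces."""
    ws_plain = CovarianceWorkspace(tree)
    out = []
    for name in names:
        if name in COMPETITION_MODELS and regimes is not None:
            out.append(
                fit_model(tree, x, name, regimes=regimes, n_starts=n_starts, clade=clade, trait=trait)
            )
        else:
            out.append(
                fit_model(tree, x, name, n_starts=n_starts, clade=clade, trait=trait, workspace=ws_plain)
            )
    return out


@dataclass
class ModelComparison:
    """AICc comparison of several models on one clade x trait."""

    clade: str | None
    trait: str | None
    fits: dict
    delta_aicc: dict
    best_model: str
    competition_flag: bool


def compare_models(fits: list[FitResult]) -> ModelComparison:
    """Rank fits by AICc and apply the delta-AICc > 2 competition rule.

    Ties within 1e-8 AICc prefer fewer parameters, then alphabetical model
    name, so the result is a pure function of the fit set.
    """
    if not fits:
        raise ValueError("compare_models needs at least one fit")
    key0 = (fits[0].clade, fits[0].trait, fits[0].n)
    for f in fits[1:]:
        if (f.clade, f.trait, f.n) != key0:
            raise ValueError("all fits must share (clade, trait, n)")
    by_name = {}
    for f in fits:
        if f.model in by_name:
            raise ValueError(f"duplicate fit for model {f.model}")
        by_name[f.model] = f
    min_aicc = min(f.aicc for f in fits)
    ranked = sorted(
        fits, key=lambda f: (round((f.aicc - min_aicc) / 1e-8) * 1e-8, f.k, f.model)
    )
    best = ranked[0]
    delta = {f.model: f.aicc - best.aicc for f in fits}
    flag = False
    indep = [f for f in fits if f.model in INDEPENDENT_MODELS]
    if best.model in COMPETITION_MODELS and indep:
        flag = bool(min(f.aicc for f in indep) - best.aicc > 2.0)
    return ModelComparison(fits[0].clade, fits[0].trait, by_name, delta, best.model, flag)


@dataclass
class ComparisonTable:
    """Per clade x trait x model summary with competition flags."""

    rows: pd.DataFrame
    flags: dict  # (clade, trait) -> bool
    any_trait_flag: dict = field(default_factory=dict)  # clade -> bool

    def flagged_clades(self) -> list[str]:
        return sorted(c for c, v in self.any_trait_flag.items() if v)


def comparison_table(comparisons: list[ModelComparison]) -> ComparisonTable:
    """Assemble per-(clade, trait) comparisons into one table."""
    seen = set()
    records, flags = [], {}
    for comp in comparisons:
        key = (comp.clade, comp.trait)
        if key in seen:
            raise ValueError(f"duplicate comparison for {key}")
        seen.add(key)
        flags[key] = comp.competition_flag
        for name, f in sorted(comp.fits.items()):
            records.append(
                {
                    "clade": comp.clade,
                    "trait": comp.trait,
                    "model": name,
                    "loglik": f.loglik,
                    "k": f.k,
                    "n": f.n,
                    "aicc": f.aicc,
                    "delta_aicc": comp.delta_aicc[name],
                    "converged": f.converged,
                    "best_model": comp.best_model,
                    "competition_flag": comp.competition_flag,
                }
            )
    any_trait = {}
    for (clade, _), fl in flags.items():
        any_trait[clade] = any_trait.get(clade, False) or fl
    return ComparisonTable(pd.DataFrame(records), flags, any_trait)


def pgls_residuals(tree: Phylogeny, y: TraitVector, x: TraitVector) -> TraitVector:
    """Residuals of y on x under phylogenetic GLS with BM correlation.

    Used to express beak size relative to body mass: the GLS slope and
    intercept are estimated with error covariance proportional to shared
    evolutionary time, and the raw residuals are returned.
    """
    yv = y.values
    xv = x.values
    if np.ptp(xv) == 0:
        raise ValueError("predictor is constant: singular design")
    C = tree.shared_time_matrix()
    X = sm.add_constant(xv)
    fit = sm.GLS(yv, X, sigma=C).fit()
    resid = yv - fit.predict(X)
    return TraitVector(resid, trait_name=f"{y.trait_name}_rel", tip_labels=y.tip_labels)
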