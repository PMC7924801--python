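"""Parameter estimation: adaptive Metropolis MCMC, MLE and MAP.

The posterior over the seven model probabilities (or five, when the
baseline model ties duplication and speciation gain/loss) is sampled by a
random-walk Metropolis chain on the unit hypercube.  The proposal
covariance adapts to the running empirical covariance of the chain
(Haario-style, scaled by 2.38^2/d plus a small jitter) and proposals
leaving [0, 1] are folded back by reflection, which is symmetric and so
leaves the acceptance ratio untouched.  Following common practice for
this model family we run several chains, discard the first half as
burn-in, keep every tenth draw, and report the mean of the kept draws,
with convergence monitored by the Gelman-Rubin potential scale reduction
factor (PSRF < 1.1).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .likelihood import AnnotatedTreeSet, pooled_loglik
from .model import PARAM_NAMES, ModelParameters, PriorSet

#: free names of the 5-parameter (baseline) model; mu pairs are tied
BASELINE_NAMES = ("pi", "mu01", "mu10", "psi01", "psi10")


class ParameterSpace:
    """Maps a free parameter vector to a full :class:`ModelParameters`.

    Handles the baseline tie (mu01_d = mu01_s, mu10_d = mu10_s) and
    parameters fixed at known values (e.g. psi = 0 when annotations are
    known to be error-free).
    """

    def __init__(self, baseline: bool = False,
                 fix: Optional[Dict[str, float]] = None):
        self.baseline = baseline
        self.fix = dict(fix or {})
        names = BASELINE_NAMES if baseline else PARAM_NAMES
        for k in self.fix:
            if k not in names:
                raise ValueError(f"cannot fix unknown parameter {k!r}")
        self.free_names: Tuple[str, ...] = tuple(n for n in names if n not in self.fix)

    @property
    def dim(self) -> int:
        return len(self.free_names)

    def to_params(self, free: Sequence[float]) -> ModelParameters:
        vals = dict(zip(self.free_names, map(float, free)))
        vals.update(self.fix)
        if self.baseline:
            return ModelParameters.baseline(
                vals["pi"], vals["mu01"], vals["mu10"], vals["psi01"], vals["psi10"])
        return ModelParameters(**vals)

    def prior_name(self, name: str) -> str:
        """Prior lookup key; tied baseline pairs use the speciation prior."""
        return {"mu01": "mu01_s", "mu10": "mu10_s"}.get(name, name)

    def log_prior(self, priors: PriorSet, free: Sequence[float]) -> float:
        return sum(priors[self.prior_name(n)].logpdf(v)
                   for n, v in zip(self.free_names, free))

    def initial(self, priors: Optional[PriorSet] = None) -> np.ndarray:
        if priors is None:
            return np.full(self.dim, 0.5)
        return np.array([priors[self.prior_name(n)].mean for n in self.free_names])


def log_posterior(params: ModelParameters, priors: PriorSet,
                  data: AnnotatedTreeSet) -> float:
    """Pooled log-likelihood plus the sum of Beta prior log-densities."""
    lp = priors.log_density(params)
    if not np.isfinite(lp):
        return -np.inf
    return pooled_loglik(data, params) + lp


@dataclass
class MCMCSettings:
    """Sampler configuration.

    Defaults follow the estimation protocol this model family uses in
    practice: 4 chains, half-sample burn-in, thinning of 10.  Adaptation
    starts after ``adapt_start`` iterations; before that an isotropic
    Gaussian proposal of sd ``initial_scale`` is used.
    """

    n_iter: int = 10_000
    n_chains: int = 4
    burn_in: float = 0.5
    thin: int = 10
    adapt_start: int = 500
    adapt_interval: int = 50
    eps: float = 1e-6
    initial_scale: float = 0.05
    baseline: bool = False
    fix: Dict[str, float] = field(default_factory=dict)
    initial: Optional[ModelParameters] = None


@dataclass
class MCMCTrace:
    """Kept posterior draws, chains x iterations x free parameters."""

    draws: np.ndarray
    param_names: Tuple[str, ...]
    meta: Dict

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def stacked(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def space(self) -> ParameterSpace:
        return ParameterSpace(self.meta.get("baseline", False),
                              self.meta.get("fix", {}))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=list(self.param_names))
            df.insert(0, "iteration", np.arange(self.n_kept))
            df.insert(0, "chain", c)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, meta: Optional[Dict] = None) -> "MCMCTrace":
        df = pd.read_csv(path_or_buf)
        names = tuple(c for c in df.columns if c not in ("chain", "iteration"))
        chains = sorted(df["chain"].unique())
        draws = np.stack([
            df[df["chain"] == c].sort_values("iteration")[list(names)].to_numpy()
            for c in chains
        ])
        return cls(draws, names, meta or {})


@dataclass
class EstimateResult:
    """A point estimate with method tag and diagnostics."""

    point: ModelParameters
    method: str  # mcmc_mean | mle | map
    converged: Optional[bool] = None
    psrf: Optional[Dict[str, float]] = None
    loglik: Optional[float] = None
    identifiable: bool = True


def _reflect(x: np.ndarray) -> np.ndarray:
    """Fold coordinates back into [0, 1] by repeated boundary reflection."""
    y = np.mod(x, 2.0)
    return np.where(y > 1.0, 2.0 - y, y)


def _make_logpost(data: AnnotatedTreeSet, priors: PriorSet,
                  space: ParameterSpace) -> Callable[[np.ndarray], float]:
    if len(data) == 0:
        return lambda free: space.log_prior(priors, free)
    forest = data.forest()

    def logpost(free: np.ndarray) -> float:
        lp = space.log_prior(priors, free)
        if not np.isfinite(lp):
            return -np.inf
        return forest.loglik(space.to_params(free)) + lp

    return logpost


def mcmc(data: AnnotatedTreeSet, priors: Optional[PriorSet] = None,
         settings: Optional[MCMCSettings] = None, seed: int = 0) -> MCMCTrace:
    """Adaptive Metropolis sampling of the posterior; reproducible by seed."""
    priors = priors or PriorSet.uniform()
    settings = settings or MCMCSettings()
    if settings.n_iter < 1000:
        raise ValueError("n_iter must be at least 1000")
    if settings.n_chains < 1:
        raise ValueError("need at least one chain")
    space = ParameterSpace(settings.baseline, settings.fix)
    d = space.dim
    logpost = _make_logpost(data, priors, space)
    sd = 2.38 ** 2 / d

    if settings.initial is not None:
        full = settings.initial.to_dict()
        if settings.baseline:
            full["mu01"], full["mu10"] = full["mu01_s"], full["mu10_s"]
        x0 = np.array([full[n] for n in space.free_names])
    else:
        x0 = space.initial(priors)
    x0 = np.clip(x0, 1e-6, 1 - 1e-6)

    child_seeds = np.random.SeedSequence(seed).spawn(settings.n_chains)
    all_kept = []
    acc_rates = []
    for c in range(settings.n_chains):
        rng = np.random.default_rng(child_seeds[c])
        x = x0.copy()
        lp = logpost(x)
        chain = np.empty((settings.n_iter, d))
        # running moments for adaptation (Welford)
        mean = x.copy()
        m2 = np.zeros((d, d))
        chol = None
        accepted = 0
        for it in range(settings.n_iter):
            if chol is not None:
                prop = x + chol @ rng.standard_normal(d)
            else:
                prop = x + settings.initial_scale * rng.standard_normal(d)
            prop = _reflect(prop)
            lp_prop = logpost(prop)
            if lp_prop - lp > math.log(rng.random()):
                x, lp = prop, lp_prop
                accepted += 1
            chain[it] = x
            delta = x - mean
            mean += delta / (it + 2)
            m2 += np.outer(delta, x - mean)
            if it + 1 >= settings.adapt_start and (it + 1) % settings.adapt_interval == 0:
                cov = m2 / (it + 1)
                chol = np.linalg.cholesky(sd * cov + sd * settings.eps * np.eye(d))
        post_burn = chain[int(round(settings.n_iter * settings.burn_in)):]
        all_kept.append(post_burn[settings.thin - 1::settings.thin])
        acc_rates.append(accepted / settings.n_iter)

    meta = {
        "n_chains": settings.n_chains, "n_iter": settings.n_iter,
        "burn_in": settings.burn_in, "thin": settings.thin, "seed": seed,
        "baseline": settings.baseline, "fix": dict(settings.fix),
        "acceptance_rates": acc_rates,
        "zero_acceptance": any(a == 0.0 for a in acc_rates),
    }
    return MCMCTrace(np.stack(all_kept), space.free_names, meta)


def gelman_rubin(trace: MCMCTrace) -> Dict[str, float]:
    """Classical between/within-chain PSRF per free parameter."""
    m, n, d = trace.draws.shape
    if m < 2:
        raise ValueError("PSRF requires at least two chains")
    if n < 10:
        raise ValueError("PSRF requires at least 10 kept draws per chain")
    out = {}
    for j, name in enumerate(trace.param_names):
        x = trace.draws[:, :, j]
        w = x.var(axis=1, ddof=1).mean()
        b_over_n = x.mean(axis=1).var(ddof=1)
        if w == 0.0:
            out[name] = 1.0 if b_over_n == 0.0 else np.inf
            continue
        var_plus = (n - 1) / n * w + b_over_n
        out[name] = float(np.sqrt(var_plus / w))
    return out


def summarize(trace: MCMCTrace) -> EstimateResult:
    """Posterior mean over all kept draws of all chains, with PSRF."""
    if trace.n_kept == 0:
        raise ValueError("empty trace")
    space = trace.space()
    point = space.to_params(trace.stacked().mean(axis=0))
    psrf = None
    converged = None
    if trace.n_chains >= 2 and trace.n_kept >= 10:
        psrf = gelman_rubin(trace)
        converged = all(v < 1.1 for v in psrf.values())
    return EstimateResult(point, "mcmc_mean", converged, psrf)


@dataclass
class OptimSettings:
    """Multi-start bounded optimization settings for MLE/MAP."""

    n_starts: int = 10
    baseline: bool = False
    fix: Dict[str, float] = field(default_factory=dict)
    maxiter: int = 500
    #: loglik slack and parameter distance defining the ridge/flatness flag
    ridge_tol: float = 1e-6
    ridge_dist: float = 0.05


def _optimize(objective: Callable[[np.ndarray], float], space: ParameterSpace,
              settings: OptimSettings, seed: int,
              start_hint: Optional[np.ndarray] = None):
    """Maximize ``objective`` over the unit cube via logit-space L-BFGS-B."""
    rng = np.random.default_rng(seed)
    d = space.dim

    def neg(y: np.ndarray) -> float:
        val = objective(expit(y))
        return -val if np.isfinite(val) else 1e300

    starts = [start_hint if start_hint is not None else np.full(d, 0.5)]
    starts += [rng.uniform(0.05, 0.95, size=d) for _ in range(settings.n_starts - 1)]
    results = []
    for s in starts:
        y0 = logit(np.clip(s, 1e-6, 1 - 1e-6))
        res = minimize(neg, y0, method="L-BFGS-B",
                       options={"maxiter": settings.maxiter})
        results.append((res.fun, expit(res.x), res.success))
    results.sort(key=lambda r: r[0])
    best_val, best_x, best_ok = results[0]
    near = [x for v, x, _ in results if v - best_val <= settings.ridge_tol]
    identifiable = True
    if len(near) > 1:
        spread = max(np.max(np.abs(a - b)) for a in near for b in near)
        identifiable = spread <= settings.ridge_dist
    converged = any(ok for v, _, ok in results if v - best_val <= 1e-8)
    return best_x, -best_val, converged, identifiable


def mle(data: AnnotatedTreeSet, settings: Optional[OptimSettings] = None,
        seed: int = 0) -> EstimateResult:
    """Maximum-likelihood estimate of the pooled model."""
    settings = settings or OptimSettings()
    if len(data) == 0 or all(len(ann) == 0 for _, ann, _ in data):
        raise ValueError("MLE requires at least one annotated leaf")
    space = ParameterSpace(settings.baseline, settings.fix)
    forest = data.forest()
    objective = lambda free: forest.loglik(space.to_params(free))
    x, ll, converged, ident = _optimize(objective, space, settings, seed)
    return EstimateResult(space.to_params(x), "mle", converged,
                          loglik=ll, identifiable=ident)


def map_estimate(data: AnnotatedTreeSet, priors: Optional[PriorSet] = None,
                 settings: Optional[OptimSettings] = None,
                 seed: int = 0) -> EstimateResult:
    """Maximum a posteriori estimate (posterior mode in probability space)."""
    priors = priors or PriorSet.uniform()
    settings = settings or OptimSettings()
    space = ParameterSpace(settings.baseline, settings.fix)
    if len(data) == 0:
        objective = lambda free: space.log_prior(priors, free)
    else:
        forest = data.forest()

        def objective(free):
            lp = space.log_prior(priors, free)
            if not np.isfinite(lp):
                return -np.inf
            return forest.loglik(space.to_params(free)) + lp

    x, lp, converged, ident = _optimize(objective, space, settings, seed,
                                        start_hint=space.initial(priors))
    return EstimateResult(space.to_params(x), "map", converged,
                          loglik=lp, identifiable=ident)
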