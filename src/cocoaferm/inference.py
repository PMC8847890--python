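"""Bayesian estimation of variant parameters on a scaled dataset.

The observation model treats every scaled observation as Normal around the
ODE solution with one shared standard deviation sigma.  Priors are weakly
informative on the scaled space: each kinetic parameter has a Normal(0.5,
0.3) prior truncated to the positive axis, sigma a Cauchy(0, 1) truncated
likewise.  Posteriors are sampled with emcee's affine-invariant ensemble
sampler; convergence is judged by split R-hat < 1.05, bulk/tail ESS > 100
and a mean bulk-ESS/N_draws ratio above 12.5%, with a single rerun at
doubled length before declaring non-convergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import stats

from .model_core import (
    DEFAULT_SOLVER,
    STATE_NAMES,
    MechanismSet,
    ModelVariant,
    SimulationError,
    SolverConfig,
    build_variant,
    simulate,
)
from .preprocessing import ScaledDataset

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "ObservationModel",
    "PosteriorFit",
    "ConvergenceReport",
    "log_prior",
    "log_likelihood",
    "fit",
    "check_convergence",
    "posterior_predict",
]

_LOG_2PI = math.log(2.0 * math.pi)

RHAT_MAX = 1.05
ESS_MIN = 100.0
ESS_RATIO_MIN = 0.125


@dataclass(frozen=True)
class PriorSpec:
    """Truncated priors on the scaled space.

    theta_k ~ Normal(theta_mean, theta_sd) truncated to theta_k > 0;
    sigma ~ Cauchy(0, sigma_scale) truncated to sigma > 0.
    """

    theta_mean: float = 0.5
    theta_sd: float = 0.3
    sigma_scale: float = 1.0

    @property
    def is_default(self) -> bool:
        return self == PriorSpec()

    @property
    def _log_trunc_norm(self) -> float:
        # log P(X > 0) for X ~ N(mean, sd): the truncation normalizer.
        return stats.norm.logcdf(self.theta_mean / self.theta_sd)


DEFAULT_PRIOR = PriorSpec()


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run lengths and seeding.

    ``chains`` is the nominal chain count (it also bounds the walker count
    from below); ``iterations`` is the total steps per walker, of which
    ``warmup`` are discarded.  On an effective-sample-size failure the fit
    is rerun once with both numbers doubled.  ``n_walkers`` defaults to
    2 * ndim + 2 walkers, the minimum for a healthy ensemble; diagnostics
    treat each walker as a chain.
    """

    chains: int = 4
    iterations: int = 3000
    warmup: int = 1000
    seed: int = 0
    n_walkers: int | None = None
    thin_target: int | None = None  # default: chains * (iterations - warmup)
    rerun_on_ess_failure: bool = True

    def __post_init__(self):
        if self.iterations <= self.warmup:
            raise ValueError("iterations must exceed warmup")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for split R-hat")

    def walkers_for(self, ndim: int) -> int:
        n = self.n_walkers or max(2 * ndim + 2, 2 * self.chains)
        if n % 2:
            n += 1
        return max(n, 2 * ndim + 2)

    def doubled(self) -> "SamplerConfig":
        return replace(self, iterations=2 * self.iterations, warmup=2 * self.warmup)


DEFAULT_SAMPLER = SamplerConfig()


@dataclass(frozen=True)
class ObservationModel:
    """Shared Gaussian noise level across all series and times (scaled units)."""

    sigma: float

    def __post_init__(self):
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")


def log_prior(theta, sigma: float, prior: PriorSpec = DEFAULT_PRIOR) -> float:
    """Joint log prior density; -inf outside the positive support."""
    theta = np.asarray(theta, dtype=float)
    if sigma <= 0 or np.any(theta <= 0):
        return -np.inf
    z = (theta - prior.theta_mean) / prior.theta_sd
    lp = np.sum(
        -math.log(prior.theta_sd) - 0.5 * _LOG_2PI - 0.5 * z**2 - prior._log_trunc_norm
    )
    # half-Cauchy: 2 / (pi * s * (1 + (x/s)^2))
    s = prior.sigma_scale
    lp += math.log(2.0 / (math.pi * s)) - math.log1p((sigma / s) ** 2)
    return float(lp)


def _observation_layout(dataset: ScaledDataset):
    """Indices of non-missing observations, series-major then time-minor."""
    obs = dataset.scaled
    layout = []
    for i in range(len(STATE_NAMES)):
        for j in range(obs.shape[0]):
            if np.isfinite(obs[j, i]):
                layout.append((i, j))
    return layout


class _Likelihood:
    """Precompiled Gaussian likelihood for one (variant, dataset) pair.

    Caches the observation layout and the parameter embedding so that the
    sampler's inner loop is a single ODE solve plus vector arithmetic.
    """

    def __init__(self, variant: ModelVariant, dataset: ScaledDataset,
                 solver: SolverConfig = DEFAULT_SOLVER):
        from .model_core import PARAM_INDEX, N_PARAMS_FULL

        self.variant = variant
        self.dataset = dataset
        self.solver = solver
        self.layout = _observation_layout(dataset)
        self._series = np.array([i for i, _ in self.layout])
        self._times_idx = np.array([j for _, j in self.layout])
        self._obs = dataset.scaled[self._times_idx, self._series]
        self._times = np.asarray(dataset.times, dtype=float)
        self._init = dataset.initial_state
        self._embed = np.array([PARAM_INDEX[n] for n in variant.parameter_names])
        self._n_full = N_PARAMS_FULL

    @property
    def n_obs(self) -> int:
        return len(self.layout)

    def __call__(self, theta_vec: np.ndarray, sigma: float):
        from ._integrate import dp45_integrate

        if sigma <= 0 or np.any(theta_vec < 0):
            return -np.inf, None
        p = np.zeros(self._n_full)
        p[self._embed] = theta_vec
        s = self.solver
        traj, status, _ = dp45_integrate(
            p, self._init, self._times, s.rtol, s.atol, s.max_steps, s.neg_slack
        )
        if status != 0:
            return -np.inf, None
        resid = self._obs - traj[self._times_idx, self._series]
        pointwise = -math.log(sigma) - 0.5 * _LOG_2PI - 0.5 * (resid / sigma) ** 2
        return float(np.sum(pointwise)), pointwise


class _ConstantLikelihood:
    """Flat likelihood: sampling the prior (used when no dataset is given)."""

    n_obs = 0

    def __call__(self, theta_vec, sigma):
        if sigma <= 0 or np.any(theta_vec <= 0):
            return -np.inf, None
        return 0.0, np.zeros(0)


def log_likelihood(
    theta,
    sigma: float,
    variant: ModelVariant,
    dataset: ScaledDataset,
    solver: SolverConfig = DEFAULT_SOLVER,
):
    """Gaussian log likelihood of the scaled observations.

    The variant is integrated from the first scaled observation; every
    non-missing observation contributes a Normal(prediction, sigma) term.
    Returns ``(total, pointwise)`` with the pointwise vector ordered
    series-major, time-minor; on integration failure returns
    ``(-inf, None)``.
    """
    if isinstance(variant, (str, MechanismSet)):
        variant = build_variant(variant)
    if isinstance(theta, dict):
        theta_vec = np.array([theta[n] for n in variant.parameter_names], dtype=float)
    else:
        theta_vec = np.asarray(theta, dtype=float)
    return _Likelihood(variant, dataset, solver)(theta_vec, sigma)


@dataclass(frozen=True)
class ConvergenceReport:
    success: bool
    reasons: tuple[str, ...]
    metrics: dict

    def __bool__(self) -> bool:
        return self.success


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one (variant, dataset) fit.

    ``draws`` is (n_draws, n_params + 1) with sigma in the last column,
    pooled over chains after warmup removal and thinning; ``chain_ids``
    maps each row to its chain (walker).  ``pointwise_loglik`` has one
    column per non-missing observation in series-major order.
    """

    variant_label: str
    param_names: tuple[str, ...]  # kinetic parameters, then "sigma"
    draws: np.ndarray
    chain_ids: np.ndarray
    pointwise_loglik: np.ndarray
    diagnostics: dict
    success: bool
    reasons: tuple[str, ...]
    summary: pd.DataFrame
    seed: int
    dataset_code: str = ""
    features: dict = field(default_factory=dict)
    scale_factors: np.ndarray | None = None
    prior_default: bool = True
    rerun: bool = False
    n_failed_draws: int = 0

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def n_chains(self) -> int:
        return int(np.unique(self.chain_ids).size)

    def draws_by_chain(self) -> np.ndarray:
        """Draws reshaped to (chains, draws_per_chain, ndim)."""
        chains = np.unique(self.chain_ids)
        per = [self.draws[self.chain_ids == c] for c in chains]
        n = min(len(x) for x in per)
        return np.stack([x[:n] for x in per])

    def save(self, directory, stem: str | None = None) -> str:
        """Serialize to ``{stem}.json`` + two CSV tables in ``directory``."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or f"{self.variant_label}_{self.dataset_code or 'fit'}"
        meta = {
            "variant_label": self.variant_label,
            "param_names": list(self.param_names),
            "diagnostics": self.diagnostics,
            "success": bool(self.success),
            "reasons": list(self.reasons),
            "summary": self.summary.to_dict(),
            "seed": int(self.seed),
            "dataset_code": self.dataset_code,
            "features": self.features,
            "scale_factors": (
                None if self.scale_factors is None else list(map(float, self.scale_factors))
            ),
            "prior_default": bool(self.prior_default),
            "rerun": bool(self.rerun),
            "n_failed_draws": int(self.n_failed_draws),
        }
        (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))
        draws = pd.DataFrame(self.draws, columns=list(self.param_names))
        draws.insert(0, "chain", self.chain_ids)
        draws.to_csv(directory / f"{stem}_draws.csv", index=False)
        pd.DataFrame(self.pointwise_loglik).to_csv(
            directory / f"{stem}_loglik.csv", index=False
        )
        return stem

    @classmethod
    def load(cls, directory, stem: str) -> "PosteriorFit":
        import json
        from pathlib import Path

        directory = Path(directory)
        meta = json.loads((directory / f"{stem}.json").read_text())
        draws = pd.read_csv(directory / f"{stem}_draws.csv")
        loglik = pd.read_csv(directory / f"{stem}_loglik.csv").to_numpy(dtype=float)
        chain_ids = draws.pop("chain").to_numpy()
        return cls(
            variant_label=meta["variant_label"],
            param_names=tuple(meta["param_names"]),
            draws=draws.to_numpy(dtype=float),
            chain_ids=chain_ids,
            pointwise_loglik=loglik,
            diagnostics=meta["diagnostics"],
            success=meta["success"],
            reasons=tuple(meta["reasons"]),
            summary=pd.DataFrame(meta["summary"]),
            seed=meta["seed"],
            dataset_code=meta["dataset_code"],
            features=meta["features"],
            scale_factors=(
                None
                if meta["scale_factors"] is None
                else np.asarray(meta["scale_factors"], dtype=float)
            ),
            prior_default=meta["prior_default"],
            rerun=meta["rerun"],
            n_failed_draws=meta["n_failed_draws"],
        )


def _summarize(draws: np.ndarray, names) -> pd.DataFrame:
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1),
            "ci_2.5%": lo,
            "ci_97.5%": hi,
        },
        index=list(names),
    )


def _diagnostics_from_chain(chain: np.ndarray, names) -> dict:
    """R-hat and ESS diagnostics; ``chain`` is (n_chains, n_draws, ndim)."""
    data = {name: chain[:, :, k] for k, name in enumerate(names)}
    idata = az.from_dict(posterior=data)
    rhat = az.rhat(idata)
    bulk = az.ess(idata, method="bulk")
    tail = az.ess(idata, method="tail")
    rhat_vals = np.array([float(rhat[n].values) for n in names])
    bulk_vals = np.array([float(bulk[n].values) for n in names])
    tail_vals = np.array([float(tail[n].values) for n in names])
    n_total = chain.shape[0] * chain.shape[1]
    return {
        "rhat": dict(zip(names, rhat_vals)),
        "bulk_ess": dict(zip(names, bulk_vals)),
        "tail_ess": dict(zip(names, tail_vals)),
        "max_rhat": float(np.nanmax(rhat_vals)),
        "min_bulk_ess": float(np.nanmin(bulk_vals)),
        "min_tail_ess": float(np.nanmin(tail_vals)),
        "mean_ess_ratio": float(np.nanmean(bulk_vals) / n_total),
        "n_draws": int(n_total),
    }


def _convergence_reasons(diag: dict) -> tuple[str, ...]:
    reasons = []
    if not diag["max_rhat"] < RHAT_MAX:
        reasons.append(f"R-hat {diag['max_rhat']:.3f} >= {RHAT_MAX}")
    if not diag["min_bulk_ess"] > ESS_MIN:
        reasons.append(f"bulk-ESS {diag['min_bulk_ess']:.1f} <= {ESS_MIN:.0f}")
    if not diag["min_tail_ess"] > ESS_MIN:
        reasons.append(f"tail-ESS {diag['min_tail_ess']:.1f} <= {ESS_MIN:.0f}")
    if not diag["mean_ess_ratio"] > ESS_RATIO_MIN:
        reasons.append(
            f"mean ESS/N_draws {diag['mean_ess_ratio']:.3f} <= {ESS_RATIO_MIN}"
        )
    return tuple(reasons)


def check_convergence(fit: PosteriorFit) -> ConvergenceReport:
    """Apply the convergence criteria to a fit's stored diagnostics.

    A run is successful only if it also used the default priors (a fit
    rescued by reparametrization or bespoke priors does not count).
    """
    reasons = list(_convergence_reasons(fit.diagnostics))
    if not fit.prior_default:
        reasons.append("non-default prior")
    return ConvergenceReport(
        success=not reasons, reasons=tuple(reasons), metrics=dict(fit.diagnostics)
    )


def _find_modes(log_post, ndim, prior, rng, n_starts: int = 6, keep_within: float = 25.0):
    """Distinct posterior modes from multi-start L-BFGS-B in log space.

    ODE posteriors here are often nearly degenerate across a few modes
    (e.g. exchanged sugar roles); retaining every local optimum whose
    height is within ``keep_within`` log units of the best lets the
    ensemble be seeded across all relevant basins instead of collapsing
    into one.
    """
    from scipy.optimize import minimize

    def neg_lp(u):
        value = log_post(np.exp(u))
        # the +u.sum() Jacobian makes this the mode of the log-space density
        return -(value + u.sum()) if np.isfinite(value) else 1e10

    solutions = []
    for attempt in range(n_starts):
        if attempt == 0:
            z0 = np.full(ndim, prior.theta_mean)
            z0[-1] = 0.1
        else:
            z0 = np.clip(
                rng.normal(prior.theta_mean, prior.theta_sd, ndim), 0.05, 1.5
            )
            z0[-1] = 10.0 ** rng.uniform(-2.0, -0.5)
        res = minimize(
            neg_lp, np.log(z0), method="L-BFGS-B",
            options={"maxiter": 1000, "maxfun": 15000},
        )
        if np.isfinite(res.fun) and res.fun < 1e9:
            solutions.append((res.fun, np.exp(res.x)))
    if not solutions:
        raise RuntimeError("posterior mode search failed from every start")
    solutions.sort(key=lambda s: s[0])
    best_fun = solutions[0][0]
    modes = []
    for fun, z in solutions:
        if fun - best_fun > keep_within:
            continue
        if any(np.max(np.abs(np.log(z) - np.log(m))) < 0.05 for m in modes):
            continue
        modes.append(z)
    return modes


def _prior_draws(n, ndim, prior, rng):
    a = (0 - prior.theta_mean) / prior.theta_sd
    theta = stats.truncnorm.rvs(
        a, np.inf, loc=prior.theta_mean, scale=prior.theta_sd,
        size=(n, ndim - 1), random_state=rng,
    )
    sigma = np.abs(stats.cauchy.rvs(0, prior.sigma_scale, size=(n, 1), random_state=rng))
    return np.hstack([theta, sigma])


def _init_walkers(n_walkers, ndim, prior, log_post, rng, prior_only=False):
    """Start walkers in tight log-normal balls spread over the found modes.

    With a flat likelihood the prior is the posterior, so walkers start at
    exact prior draws and the chain is stationary from the first step.
    """
    if prior_only:
        return _prior_draws(n_walkers, ndim, prior, rng)
    modes = _find_modes(log_post, ndim, prior, rng)
    pos = np.empty((n_walkers, ndim))
    for w in range(n_walkers):
        z_map = modes[w % len(modes)]
        for _ in range(200):
            cand = z_map * np.exp(rng.normal(0.0, 0.05, ndim))
            if np.isfinite(log_post(cand)):
                pos[w] = cand
                break
        else:
            raise RuntimeError("could not initialize walkers at finite posterior")
    return pos


#: Differential-evolution moves mix far better than the stretch move alone
#: in the 25–44 dimensional, correlated posteriors here; a stretch
#: component is retained for ergodicity across scales.  (The snooker move
#: is deliberately absent: in this emcee version it visibly contracts a
#: stationary Gaussian ensemble.)
def _moves():
    return [(emcee.moves.DEMove(), 0.8), (emcee.moves.StretchMove(), 0.2)]


def _run_ensemble(log_post, ndim, sampler_cfg: SamplerConfig, prior, rng, prior_only=False):
    n_walkers = sampler_cfg.walkers_for(ndim)
    p0 = _init_walkers(n_walkers, ndim, prior, log_post, rng, prior_only=prior_only)
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_post, moves=_moves())
    sampler.random_state = rng.get_state()
    sampler.run_mcmc(p0, sampler_cfg.iterations, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=sampler_cfg.warmup)  # (steps, walkers, ndim)
    kept, walkers, _ = chain.shape
    target = sampler_cfg.thin_target or sampler_cfg.chains * (
        sampler_cfg.iterations - sampler_cfg.warmup
    )
    thin = max(1, int(np.ceil(kept * walkers / target)))
    chain = chain[::thin]
    return np.transpose(chain, (1, 0, 2))  # (walkers, draws, ndim)


def fit(
    variant: ModelVariant | MechanismSet | str,
    dataset: ScaledDataset | None,
    prior: PriorSpec = DEFAULT_PRIOR,
    sampler: SamplerConfig = DEFAULT_SAMPLER,
    solver: SolverConfig = DEFAULT_SOLVER,
) -> PosteriorFit:
    """Sample the posterior of a variant on a scaled dataset.

    Deterministic for a fixed seed.  Applies the rerun-once-at-doubled-
    length policy on an ESS failure before declaring non-convergence.
    Integration failures inside sampling are treated as log posterior
    -inf (rejection).
    """
    if isinstance(variant, (str, MechanismSet)):
        variant = build_variant(variant)
    names = tuple(variant.parameter_names) + ("sigma",)
    ndim = len(names)
    if dataset is None:
        likelihood = _ConstantLikelihood()  # prior-only sampling
    else:
        likelihood = _Likelihood(variant, dataset, solver)

    def log_post(z):
        theta, sigma = z[:-1], z[-1]
        lp = log_prior(theta, sigma, prior)
        if not np.isfinite(lp):
            return -np.inf
        ll, _ = likelihood(theta, sigma)
        return lp + ll

    prior_only = dataset is None

    def run(cfg, rerun_flag):
        rng = np.random.RandomState(cfg.seed)
        chain = _run_ensemble(log_post, ndim, cfg, prior, rng, prior_only=prior_only)
        diag = _diagnostics_from_chain(chain, names)
        return chain, diag, rerun_flag

    chain, diag, rerun = run(sampler, False)
    reasons = _convergence_reasons(diag)
    # rerun once at doubled length if bulk- or tail-ESS was rejected
    if sampler.rerun_on_ess_failure and any(
        r.startswith(("bulk-ESS", "tail-ESS")) for r in reasons
    ):
        chain, diag, rerun = run(sampler.doubled(), True)
        reasons = _convergence_reasons(diag)

    walkers, per_chain, _ = chain.shape
    draws = chain.reshape(walkers * per_chain, ndim)
    chain_ids = np.repeat(np.arange(walkers), per_chain)

    # pointwise log likelihood for the retained draws (for PSIS-LOO)
    pointwise = np.empty((draws.shape[0], likelihood.n_obs))
    n_failed = 0
    for r, z in enumerate(draws):
        _, pw = likelihood(z[:-1], z[-1])
        if pw is None:
            pointwise[r] = -np.inf
            n_failed += 1
        else:
            pointwise[r] = pw

    result = PosteriorFit(
        variant_label=variant.label,
        param_names=names,
        draws=draws,
        chain_ids=chain_ids,
        pointwise_loglik=pointwise,
        diagnostics=diag,
        success=False,
        reasons=(),
        summary=_summarize(draws, names),
        seed=sampler.seed,
        dataset_code=dataset.code if dataset is not None else "",
        features=dict(dataset.features) if dataset is not None else {},
        scale_factors=(
            np.asarray(dataset.scale_factors, dtype=float) if dataset is not None else None
        ),
        prior_default=prior.is_default,
        rerun=rerun,
        n_failed_draws=n_failed,
    )
    report = check_convergence(result)
    result.success = report.success
    result.reasons = report.reasons
    return result


def posterior_predict(
    fit_result: PosteriorFit,
    variant: ModelVariant | None = None,
    times=None,
    dataset: ScaledDataset | None = None,
    initial_state=None,
    include_noise: bool = False,
    max_draws: int = 500,
    solver: SolverConfig = DEFAULT_SOLVER,
    seed: int = 0,
):
    """Median and central 95% band of posterior trajectory predictions.

    Each retained draw (subsampled to at most ``max_draws``) is simulated;
    with ``include_noise`` the observation noise sigma of each draw is
    added, giving a posterior-predictive band for new observations rather
    than for the latent trajectory.  Draws whose integration fails are
    dropped and counted.
    """
    if variant is None:
        variant = build_variant(fit_result.variant_label)
    if dataset is not None:
        if times is None:
            times = dataset.times
        if initial_state is None:
            initial_state = dataset.initial_state
    if times is None or initial_state is None:
        raise ValueError("need either a dataset or explicit times and initial_state")
    times = np.asarray(times, dtype=float)

    rng = np.random.default_rng(seed)
    draws = fit_result.draws
    if draws.shape[0] > max_draws:
        idx = rng.choice(draws.shape[0], size=max_draws, replace=False)
        idx.sort()
        draws = draws[idx]

    order = fit_result.param_names[:-1]
    sims, dropped = [], 0
    for z in draws:
        try:
            traj = simulate(variant, dict(zip(order, z[:-1])), initial_state, times, solver)
        except SimulationError:
            dropped += 1
            continue
        if include_noise:
            traj = traj + rng.normal(0.0, z[-1], size=traj.shape)
        sims.append(traj)
    if not sims:
        raise RuntimeError("all posterior draws failed to integrate")
    stack = np.stack(sims)
    lo, med, hi = np.percentile(stack, [2.5, 50.0, 97.5], axis=0)
    return {
        "times": times,
        "median": med,
        "lower": lo,
        "upper": hi,
        "n_draws": len(sims),
        "n_dropped": dropped,
    }
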