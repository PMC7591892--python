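"""Shared ensemble-MCMC machinery.

All Bayesian fits in this package sample an unconstrained parameter vector with
:mod:`emcee` (affine-invariant / differential-evolution ensemble moves), using

- a vectorized log-posterior ``logp(theta) -> (nwalkers,)`` for speed,
- MAP initialisation via L-BFGS from several random restarts, walkers started
  in a small ball around the optimum,
- rank-normalised split R-hat (arviz) over walker chains as the convergence
  diagnostic.

Positive parameters are sampled on the log scale; the Jacobian terms live in
each model's log-posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import arviz as az
import emcee
import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler configuration.

    ``chains`` and ``iterations``/``warmup`` describe the target posterior
    sample in conventional chain terms: the sampler keeps
    ``chains * (iterations - warmup)`` post-warmup draws in total
    (default 4 x 2000 with 1000 warmup -> 4,000 draws).  Internally an
    ensemble of walkers realises those draws; ``warmup`` scales the number
    of discarded ensemble steps.
    """

    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    rhat_threshold: float = 1.01
    seed: int = 20201027
    nwalkers: int | None = None  # default: chosen from dimensionality
    thin: int = 8

    def __post_init__(self):
        if self.iterations <= self.warmup:
            raise ValueError("iterations must exceed warmup")
        if self.chains < 1 or self.thin < 1:
            raise ValueError("chains and thin must be positive")

    @property
    def n_draws(self) -> int:
        return self.chains * (self.iterations - self.warmup)

    def with_(self, **kw) -> "MCMCSettings":
        d = self.__dict__.copy()
        d.update(kw)
        return MCMCSettings(**d)


@dataclass
class EnsembleResult:
    """Posterior draws plus diagnostics for one fit."""

    draws: np.ndarray          # (n_draws, ndim), flattened post-warmup
    chain: np.ndarray          # (nwalkers, nsteps_kept, ndim) for diagnostics
    names: list[str]
    rhat: dict[str, float]
    map_estimate: np.ndarray
    log_prob_max: float
    settings: MCMCSettings
    acceptance_fraction: float = float("nan")
    notes: list[str] = field(default_factory=list)

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]


def _find_map(
    logp: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    rng: np.random.Generator,
    n_restarts: int = 4,
    jitter: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Maximise the log posterior from several jittered starts.

    The objective and its forward-difference gradient are evaluated through
    the vectorized ``logp`` in a single batched call per iteration, which is
    what makes L-BFGS affordable in the hierarchical fits.
    """
    ndim = x0.size
    eps = 1e-6

    def neg(x: np.ndarray) -> float:
        v = float(logp(x[None, :])[0])
        return np.inf if not np.isfinite(v) else -v

    def neg_and_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        pts = np.concatenate([x[None, :], x[None, :] + eps * np.eye(ndim)])
        vals = logp(pts)
        f0 = vals[0]
        if not np.isfinite(f0):
            return np.inf, np.zeros(ndim)
        grad = (vals[1:] - f0) / eps
        grad = np.where(np.isfinite(grad), grad, 0.0)
        return -float(f0), -grad

    if ndim > 20:
        n_restarts = min(n_restarts, 2)
    best_x, best_f = x0, neg(x0)
    starts = [x0] + [
        x0 + jitter * rng.standard_normal(ndim) for _ in range(n_restarts - 1)
    ]
    for s in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    neg_and_grad, s, method="L-BFGS-B", jac=True,
                    options={"maxiter": 500},
                )
        except (ValueError, FloatingPointError):  # pragma: no cover - rare
            continue
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = res.x, res.fun
    return best_x, -best_f


def run_ensemble(
    logp: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    names: list[str],
    settings: MCMCSettings,
    *,
    rhat_names: list[str] | None = None,
    init_scale: float = 0.02,
) -> EnsembleResult:
    """Sample ``logp`` (vectorized over rows) starting near the MAP.

    Parameters
    ----------
    logp
        Maps an ``(m, ndim)`` array of parameter vectors to ``(m,)`` log
        posterior values; ``-inf`` marks out-of-support points.
    x0
        Initial guess in the unconstrained space.
    names
        Parameter names, one per dimension.
    rhat_names
        Subset of names whose R-hat enters :attr:`EnsembleResult.max_rhat`
        bookkeeping (all are always computed).
    """
    ndim = x0.size
    if len(names) != ndim:
        raise ValueError("names must match parameter dimensionality")
    rng = np.random.default_rng(settings.seed)

    map_x, lp_max = _find_map(logp, x0, rng)

    nwalkers = settings.nwalkers or max(2 * ndim + 2, 96)
    if nwalkers % 2:
        nwalkers += 1
    # ensemble step budget: enough kept steps to realise the requested draws
    keep_steps = max(int(np.ceil(settings.n_draws / nwalkers)), 40)
    burn_steps = max(int(np.ceil(settings.warmup / 2)), 12 * max(ndim // 4, 1), 250)

    p0 = map_x[None, :] + init_scale * rng.standard_normal((nwalkers, ndim))
    lp0 = logp(p0)
    bad = ~np.isfinite(lp0)
    tries = 0
    while bad.any() and tries < 50:
        p0[bad] = map_x[None, :] + 0.5 * init_scale * rng.standard_normal(
            (int(bad.sum()), ndim)
        )
        lp0 = logp(p0)
        bad = ~np.isfinite(lp0)
        tries += 1
    if bad.any():
        raise RuntimeError("could not initialise walkers in the posterior support")

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, logp, vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(settings.seed % (2**32)).get_state()
    state = sampler.run_mcmc(p0, burn_steps, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, keep_steps, thin_by=settings.thin, progress=False)

    chain = np.swapaxes(sampler.get_chain(), 0, 1)  # (nwalkers, nsteps, ndim)
    flat = chain.reshape(-1, ndim)
    draws = flat[-settings.n_draws :] if flat.shape[0] >= settings.n_draws else flat

    # R-hat over walker groups: pooling many walkers per pseudo-chain makes the
    # diagnostic robust to per-walker autocorrelation of the ensemble moves.
    k = settings.chains
    g = nwalkers // k
    grouped = chain[: g * k].reshape(k, -1, ndim)
    rhat = compute_rhat(grouped, names)
    return EnsembleResult(
        draws=draws,
        chain=chain,
        names=list(names),
        rhat=rhat,
        map_estimate=map_x,
        log_prob_max=lp_max,
        settings=settings,
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
    )


def compute_rhat(chain: np.ndarray, names: list[str]) -> dict[str, float]:
    """Rank-normalised split R-hat per parameter from a (chains, draws, ndim) array."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(
            {n: chain[:, :, i] for i, n in enumerate(names)}
        )
        r = az.rhat(ds)
    return {n: float(r[n].values) for n in names}
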