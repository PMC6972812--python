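"""Bayesian exponential time-to-event model with right-censoring.

Each group j (residency x age class x site) has a constant weekly hazard
lambda_j = exp(beta_j).  An observed death at t contributes the density
f(t) = lambda * exp(-lambda t); a right-censored animal contributes only
the survivor function S(t) = exp(-lambda t).  The full log-likelihood is

    sum_deaths [beta_j - exp(beta_j) t_i]  +  sum_censored [-exp(beta_j) t_i]
  = sum_j [ D_j beta_j - exp(beta_j) T_j ]

with D_j deaths and T_j total exposure weeks in group j, so the per-group
(D_j, T_j) pairs are sufficient.  Groups are parameterized independently —
no hierarchical pooling — so the posterior factorizes over coordinates.

Priors are vague normals on the beta (log weekly hazard) scale by default.
A Gamma prior on the hazard scale is also supported: lambda_j ~ Gamma(a, b)
is conjugate to this likelihood, giving the exact posterior
Gamma(a + D_j, b + T_j) that serves as an independent oracle for the
Metropolis sampler.

Sampling is per-coordinate adaptive random-walk Metropolis; proposal scales
are tuned toward 0.44 acceptance by Robbins-Monro recursion during burn-in
only, so the post-burn-in chain is a fixed-kernel Markov chain with the
posterior invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import GROUP_LABELS, N_GROUPS
from .tte import TimeToEventData, TimeToEventRecord, sufficient_statistics

#: Convergence threshold on the potential scale reduction factor.
RHAT_THRESHOLD = 1.01

#: Total exposure (weeks) below which a group is reported inestimable.
MIN_ESTIMABLE_EXPOSURE_WEEKS = 1.0


@dataclass(frozen=True)
class HazardModelSpec:
    """Priors for the 8 log-hazard coefficients.

    ``prior`` selects the family: "normal" puts N(prior_mean, prior_sd) on
    each beta_j; "gamma" puts Gamma(gamma_shape, gamma_rate) on each
    lambda_j = exp(beta_j) (conjugate; used mainly for validation).
    """

    n_groups: int = N_GROUPS
    prior: str = "normal"
    prior_mean: float = 0.0
    prior_sd: float = 10.0
    gamma_shape: float = 1.0
    gamma_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.prior not in ("normal", "gamma"):
            raise ValueError(f"unknown prior family {self.prior!r}")
        if self.prior == "normal" and self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.prior == "gamma" and (self.gamma_shape <= 0 or self.gamma_rate <= 0):
            raise ValueError("gamma prior parameters must be positive")

    def log_prior(self, beta: np.ndarray) -> np.ndarray:
        """Unnormalized log prior density, elementwise over beta."""
        if self.prior == "normal":
            return -0.5 * ((beta - self.prior_mean) / self.prior_sd) ** 2
        # lambda ~ Gamma(a, b)  =>  p(beta) ∝ exp(a beta - b e^beta)
        return self.gamma_shape * beta - self.gamma_rate * np.exp(beta)


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    Defaults are desk-scale: 3 chains x 20,000 iterations, 5,000 burn-in,
    thin 5.  Long production runs (e.g. 1e7 draws, thin 1e3) are available
    by overriding the fields; memory use is bounded by block-wise proposal
    generation.
    """

    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    target_acceptance: float = 0.44
    initial_scale: float = 0.5
    adapt_decay: float = 0.6
    block: int = 10_000

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >=2 chains for split R-hat")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must be in [0, iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


def log_likelihood(
    data: TimeToEventData | Iterable[TimeToEventRecord] | tuple[np.ndarray, np.ndarray],
    beta: np.ndarray,
) -> float:
    """Exponential right-censoring log-likelihood at coefficient vector beta.

    ``data`` may be built time-to-event data, an iterable of records, or a
    precomputed ``(deaths, exposure)`` pair.  Non-finite beta yields -inf
    (rejectable by a sampler) rather than raising.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        return -np.inf
    if isinstance(data, tuple):
        deaths, exposure = data
    else:
        deaths, exposure = sufficient_statistics(data)
    return float(np.sum(deaths * beta - np.exp(beta) * exposure))


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus convergence diagnostics.

    ``beta`` has shape (chains, draws_per_chain, n_groups).
    """

    beta: np.ndarray
    group_labels: tuple[str, ...]
    estimable: np.ndarray  # bool per group
    rhat: np.ndarray
    ess: np.ndarray
    acceptance_rate: np.ndarray  # per chain x group, post burn-in
    seed: int
    config: McmcConfig
    spec: HazardModelSpec

    @property
    def converged(self) -> bool:
        finite = self.rhat[np.isfinite(self.rhat)]
        return bool(np.all(finite < RHAT_THRESHOLD)) if finite.size else False

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def flat_beta(self) -> np.ndarray:
        """(total draws, n_groups) with chains concatenated."""
        return self.beta.reshape(-1, self.beta.shape[2])

    def lambda_draws(self) -> np.ndarray:
        """Weekly hazard draws, chains concatenated."""
        return np.exp(self.flat_beta())

    def to_frame(self) -> pd.DataFrame:
        chains, draws, groups = self.beta.shape
        frame = pd.DataFrame(
            self.flat_beta(), columns=[f"beta.{g}" for g in self.group_labels]
        )
        frame.insert(0, "chain", np.repeat(np.arange(chains), draws))
        frame.insert(1, "draw", np.tile(np.arange(draws), chains))
        return frame

    def save(self, path: str | Path) -> None:
        """Columnar text persistence (one column per coefficient)."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def diagnostics(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "rhat": [None if not np.isfinite(v) else float(v) for v in self.rhat],
            "ess": [None if not np.isfinite(v) else float(v) for v in self.ess],
            "estimable": [bool(v) for v in self.estimable],
            "converged": self.converged,
            "n_draws": int(self.n_draws),
            "mean_acceptance": float(self.acceptance_rate.mean()),
            "seed": int(self.seed),
        }


def _log_posterior(
    beta: np.ndarray, deaths: np.ndarray, exposure: np.ndarray, spec: HazardModelSpec
) -> np.ndarray:
    """Per-coordinate log posterior terms; shape of beta preserved."""
    return deaths * beta - np.exp(beta) * exposure + spec.log_prior(beta)


def _mcmc_block_numpy(
    beta, lp, log_scale, z, logu, deaths, exposure,
    prior_normal, p1, p2, t_start, burn_in, target, decay, thin,
    retained, kept, accept_post,
):
    """One block of per-coordinate Metropolis updates (reference path)."""
    n_post_add = 0
    for b in range(z.shape[0]):
        t = t_start + b + 1
        prop = beta + np.exp(log_scale) * z[b]
        if prior_normal:
            prior = -0.5 * ((prop - p1) / p2) ** 2
        else:
            prior = p1 * prop - p2 * np.exp(prop)
        lp_prop = deaths * prop - np.exp(prop) * exposure + prior
        acc = logu[b] < (lp_prop - lp)
        beta[acc] = prop[acc]
        lp[acc] = lp_prop[acc]
        if t <= burn_in:
            log_scale += t ** (-decay) * (acc - target)
        else:
            accept_post += acc
            n_post_add += 1
            if (t - burn_in) % thin == 0 and kept < retained.shape[1]:
                retained[:, kept, :] = beta
                kept += 1
    return kept, n_post_add


try:  # compiled fast path; semantics identical to _mcmc_block_numpy
    from numba import njit

    @njit(cache=False)
    def _mcmc_block_numba(  # pragma: no cover - exercised via sample_posterior
        beta, lp, log_scale, z, logu, deaths, exposure,
        prior_normal, p1, p2, t_start, burn_in, target, decay, thin,
        retained, kept, accept_post,
    ):
        n_post_add = 0
        C, G = beta.shape
        for b in range(z.shape[0]):
            t = t_start + b + 1
            for c in range(C):
                for g in range(G):
                    prop = beta[c, g] + np.exp(log_scale[c, g]) * z[b, c, g]
                    if prior_normal:
                        prior = -0.5 * ((prop - p1) / p2) ** 2
                    else:
                        prior = p1 * prop - p2 * np.exp(prop)
                    lpp = deaths[g] * prop - np.exp(prop) * exposure[g] + prior
                    a = 0.0
                    if logu[b, c, g] < lpp - lp[c, g]:
                        beta[c, g] = prop
                        lp[c, g] = lpp
                        a = 1.0
                    if t <= burn_in:
                        log_scale[c, g] += t ** (-decay) * (a - target)
                    else:
                        accept_post[c, g] += a
            if t > burn_in:
                n_post_add += 1
                if (t - burn_in) % thin == 0 and kept < retained.shape[1]:
                    for c in range(C):
                        for g in range(G):
                            retained[c, kept, g] = beta[c, g]
                    kept += 1
        return kept, n_post_add

    _mcmc_block = _mcmc_block_numba
except ImportError:  # pragma: no cover
    _mcmc_block = _mcmc_block_numpy


def sample_posterior(
    data: TimeToEventData | Iterable[TimeToEventRecord] | tuple[np.ndarray, np.ndarray],
    spec: HazardModelSpec | None = None,
    config: McmcConfig | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Draw from the posterior of the 8 log hazards.

    Because groups are independent a priori and in the likelihood, each
    coordinate's Metropolis update is a valid independent sampler; updates
    are therefore vectorized across chains and coordinates.  Per-chain
    random substreams are spawned deterministically from ``seed``, so a
    fixed (seed, config) pair gives bit-identical draws.

    Groups with total exposure below ~1 week are flagged inestimable;
    their draws are prior-dominated and summaries should not report them.
    """
    spec = spec or HazardModelSpec()
    config = config or McmcConfig()
    if isinstance(data, tuple):
        deaths, exposure = (np.asarray(a, float) for a in data)
    else:
        deaths, exposure = sufficient_statistics(data)
    if deaths.shape != (spec.n_groups,):
        raise ValueError(
            f"data have {deaths.shape[0]} groups, spec expects {spec.n_groups}"
        )
    estimable = exposure >= MIN_ESTIMABLE_EXPOSURE_WEEKS

    C, G = config.chains, spec.n_groups
    rngs = [
        np.random.Generator(np.random.Philox(s))
        for s in np.random.SeedSequence(seed).spawn(C)
    ]

    # start at a crude stabilized hazard estimate, jittered per chain
    beta0 = np.log((deaths + 0.5) / (exposure + 1.0))
    beta = np.stack([beta0 + rngs[c].normal(0, 0.1, G) for c in range(C)])
    lp = _log_posterior(beta, deaths, exposure, spec)

    log_scale = np.full((C, G), np.log(config.initial_scale))
    retained = np.empty((C, config.retained_per_chain, G))
    accept_post = np.zeros((C, G))
    n_post = 0
    kept = 0
    prior_normal = spec.prior == "normal"
    p1 = spec.prior_mean if prior_normal else spec.gamma_shape
    p2 = spec.prior_sd if prior_normal else spec.gamma_rate

    it = 0
    while it < config.iterations:
        nblk = min(config.block, config.iterations - it)
        # per-chain substreams, stacked to (nblk, C, G)
        z = np.stack([r.standard_normal((nblk, G)) for r in rngs], axis=1)
        logu = np.log(
            np.stack([r.random((nblk, G)) for r in rngs], axis=1)
        )
        kept, n_add = _mcmc_block(
            beta, lp, log_scale, z, logu, deaths, exposure,
            prior_normal, float(p1), float(p2), it, config.burn_in,
            config.target_acceptance, config.adapt_decay, config.thin,
            retained, kept, accept_post,
        )
        n_post += n_add
        it += nblk

    retained = retained[:, :kept, :]
    rhat_vals = rhat(retained)
    ess_vals = ess(retained)
    draws = PosteriorDraws(
        beta=retained,
        group_labels=GROUP_LABELS[:G] if G == N_GROUPS else tuple(map(str, range(G))),
        estimable=estimable,
        rhat=rhat_vals,
        ess=ess_vals,
        acceptance_rate=accept_post / max(n_post, 1),
        seed=seed,
        config=config,
        spec=spec,
    )
    if not draws.converged:
        bad = [
            draws.group_labels[j]
            for j in range(G)
            if not np.isfinite(rhat_vals[j]) or rhat_vals[j] >= RHAT_THRESHOLD
        ]
        warnings.warn(
            f"MCMC not converged (R-hat >= {RHAT_THRESHOLD} or undefined) for: "
            + ", ".join(bad),
            RuntimeWarning,
            stacklevel=2,
        )
    return draws


def conjugate_posterior_oracle(
    data: TimeToEventData | Iterable[TimeToEventRecord] | tuple[np.ndarray, np.ndarray],
    gamma_shape: float = 1.0,
    gamma_rate: float = 1.0,
) -> list[stats.rv_continuous]:
    """Exact per-group posterior Gamma(a + D_j, b + T_j) for the hazards.

    Under lambda_j ~ Gamma(a, b) the exponential right-censoring likelihood
    is conjugate; with no data the prior itself is returned.  Returned as
    frozen scipy distributions (scale = 1 / rate).
    """
    if gamma_shape <= 0 or gamma_rate <= 0:
        raise ValueError("gamma prior parameters must be positive")
    if isinstance(data, tuple):
        deaths, exposure = (np.asarray(a, float) for a in data)
    else:
        deaths, exposure = sufficient_statistics(data)
    return [
        stats.gamma(gamma_shape + d, scale=1.0 / (gamma_rate + t))
        for d, t in zip(deaths, exposure)
    ]


def mle_hazard(
    data: TimeToEventData | Iterable[TimeToEventRecord] | tuple[np.ndarray, np.ndarray],
) -> pd.DataFrame:
    """Closed-form per-group hazard MLE D_j / T_j with degeneracy flags."""
    if isinstance(data, tuple):
        deaths, exposure = (np.asarray(a, float) for a in data)
    else:
        deaths, exposure = sufficient_statistics(data)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.where(exposure > 0, deaths / np.where(exposure > 0, exposure, 1), np.nan)
    return pd.DataFrame(
        {
            "group_label": GROUP_LABELS[: len(deaths)],
            "deaths": deaths,
            "exposure_weeks": exposure,
            "lambda_hat": est,
            "degenerate": (deaths == 0) & (exposure > 0),
            "inestimable": exposure == 0,
        }
    ).set_index("group_label")


# --- diagnostics -----------------------------------------------------------


def _per_parameter(chains: np.ndarray, fn) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("need >=2 chains and >=4 draws per chain")
    out = np.empty(arr.shape[2])
    for p in range(arr.shape[2]):
        x = arr[:, :, p]
        # constant chains: scale reduction is undefined, flag with NaN
        out[p] = np.nan if np.ptp(x) == 0 else fn(x)
    return out


def rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain Gelman-Rubin potential scale reduction, per parameter.

    ``chains`` is (n_chains, n_draws) or (n_chains, n_draws, n_params).
    Degenerate (constant) chains yield NaN.
    """
    import arviz as az

    return _per_parameter(chains, lambda x: float(az.rhat(x)))


def ess(chains: np.ndarray) -> np.ndarray:
    """Autocorrelation-based bulk effective sample size, per parameter."""
    import arviz as az

    return _per_parameter(chains, lambda x: float(az.ess(x)))
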