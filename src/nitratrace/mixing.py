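"""Bayesian isotope mixing model with Dirichlet-constrained source proportions.

Each observed tracer value is modelled as a proportion-weighted mixture of
source signatures plus fractionation and residual error:

    X_ij = Σ_k P_k (S_jk + C_jk) + ε_jk,
    S_jk ~ N(μ_jk, ω_jk²),  C_jk ~ N(λ_jk, τ_jk²),  ε_jk ~ N(0, σ_j²),

with the proportion vector P on the K-simplex.  The likelihood used here is
the marginal normal obtained by integrating out the per-observation source
and fractionation realizations:

    X_ij ~ N( Σ_k P_k (μ_jk + λ_jk),  Σ_k P_k² (ω_jk² + τ_jk²) + σ_j² ).

Priors are Dirichlet(1, …, 1) on P (uniform over the simplex) and
independent half-normal(s₀) on each residual scale σ_j.

Inference is by seeded random-walk Metropolis on an unconstrained
reparameterization — additive log-ratio (softmax) coordinates for P and
log coordinates for σ — with per-block proposal scales adapted during
burn-in only, so the post-burn-in kernel satisfies detailed balance.
Multiple independent chains are pooled after burn-in and thinning, and
convergence is checked with the split-R̂ statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import (
    TRACERS,
    MCMCConfig,
    SampleRecord,
    SourceProfile,
    order_sources,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MixingPosterior",
    "BayesianMixingModel",
    "log_likelihood",
    "log_prior",
    "fit_mixing_model",
    "summarize_posterior",
    "convergence_diagnostics",
    "split_rhat",
    "pack_sources",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def pack_sources(
    sources: list[SourceProfile], tracers: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Stack source profiles into (J, K) arrays μ, ω, λ, τ in tracer order."""
    ordered = order_sources(sources)
    for s in ordered:
        if not s.covers(tracers):
            raise ValueError(f"source {s.source_id!r} does not cover tracers {tracers}")
    mu = np.array([[s.mean[t] for s in ordered] for t in tracers], dtype=float)
    omega = np.array([[s.sd[t] for s in ordered] for t in tracers], dtype=float)
    lam = np.array([[s.frac_mean[t] for s in ordered] for t in tracers], dtype=float)
    tau = np.array([[s.frac_sd[t] for s in ordered] for t in tracers], dtype=float)
    return mu, omega, lam, tau, [s.source_id for s in ordered]


def _check_simplex(P: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 1 or np.any(P < -atol) or abs(P.sum() - 1.0) > atol:
        raise ValueError("P must be a point on the probability simplex")
    return np.clip(P, 0.0, None)


def log_likelihood(
    P: np.ndarray,
    sigma: np.ndarray,
    X: np.ndarray,
    mu: np.ndarray,
    omega: np.ndarray,
    lam: np.ndarray | None = None,
    tau: np.ndarray | None = None,
) -> float:
    """Marginal log-likelihood of tracer matrix ``X`` (n samples × J tracers).

    Mean_j = Σ_k P_k (μ_jk + λ_jk); Var_j = Σ_k P_k² (ω_jk² + τ_jk²) + σ_j².
    A zero total variance yields −inf when any observation is off the mean
    (a valid log-density), and 0 per exactly-matching observation.
    """
    P = _check_simplex(P)
    sigma = np.asarray(sigma, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if lam is None:
        lam = np.zeros_like(mu)
    if tau is None:
        tau = np.zeros_like(omega)
    mean = (mu + lam) @ P  # (J,)
    var = (omega**2 + tau**2) @ (P**2) + sigma**2  # (J,)
    resid2 = (X - mean) ** 2  # (n, J)
    out = 0.0
    for j in range(X.shape[1]):
        if var[j] <= 0.0:
            if np.any(resid2[:, j] > 0.0):
                return -np.inf
            continue
        out += float(
            -0.5 * (resid2[:, j] / var[j] + np.log(var[j]) + _LOG_2PI).sum()
        )
    return out


def log_prior(P: np.ndarray, sigma: np.ndarray, sigma_scale: float = 20.0) -> float:
    """Dirichlet(1,…,1) on P plus independent half-normal(s₀) on each σ_j,
    with additive constants dropped.  −inf off the open simplex or for σ ≤ 0."""
    P = np.asarray(P, dtype=float)
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if np.any(P <= 0.0) or abs(P.sum() - 1.0) > 1e-9:
        return -np.inf
    if np.any(sigma <= 0.0):
        return -np.inf
    return float(-0.5 * np.sum(sigma**2) / sigma_scale**2)


# ---------------------------------------------------------------------------
# unconstrained parameterization: theta = (z_1..z_{K-1}, log sigma_1..J)
# P = softmax([z, 0]); the ALR Jacobian contributes sum_k log P_k and the
# log transform contributes sum_j log sigma_j.


def _theta_to_params(theta: np.ndarray, K: int, J: int) -> tuple[np.ndarray, np.ndarray]:
    z = np.append(theta[: K - 1], 0.0)
    z = z - z.max()
    expz = np.exp(z)
    P = expz / expz.sum()
    sigma = np.exp(theta[K - 1 :])
    return P, sigma


def _log_posterior_theta(
    theta: np.ndarray,
    X: np.ndarray,
    mu: np.ndarray,
    omega: np.ndarray,
    lam: np.ndarray,
    tau: np.ndarray,
    sigma_scale: float,
) -> float:
    K = mu.shape[1]
    J = mu.shape[0]
    P, sigma = _theta_to_params(theta, K, J)
    if np.any(P <= 0.0):
        return -np.inf
    lp = log_prior(P, sigma, sigma_scale)
    if not np.isfinite(lp):
        return lp
    jac = float(np.log(P).sum()) if K > 1 else 0.0
    jac += float(np.log(sigma).sum())
    return lp + jac + log_likelihood(P, sigma, X, mu, omega, lam, tau)


def _run_chain(
    rng: np.random.Generator,
    X: np.ndarray,
    mu: np.ndarray,
    omega: np.ndarray,
    lam: np.ndarray,
    tau: np.ndarray,
    sigma_scale: float,
    cfg: MCMCConfig,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One random-walk Metropolis chain; returns retained (P, σ) draws and
    the post-burn-in acceptance rate."""
    K, J = mu.shape[1], mu.shape[0]
    n_free = (K - 1) + J
    resid_scale = max(float(np.std(X)), 1e-3)
    theta = np.concatenate(
        [0.1 * rng.standard_normal(K - 1), np.log(resid_scale) + 0.1 * rng.standard_normal(J)]
    )
    # Proposal mix per iteration: a component-wise sweep (one adaptive
    # scale per coordinate) plus one joint move drawn from the empirical
    # posterior covariance estimated during burn-in.  The joint move is
    # what travels along the ridge left by the mean-map degeneracy of
    # K sources seen through J < K - 1 tracers.
    scales = np.full(n_free, cfg.proposal_scale)
    joint_scale = 2.38 / np.sqrt(n_free)
    chol = np.eye(n_free) * cfg.proposal_scale
    lp = _log_posterior_theta(theta, X, mu, omega, lam, tau, sigma_scale)
    adapt_every = 100
    accepted_window = np.zeros(n_free)
    accepted_post = 0
    post_steps = 0
    history = np.empty((cfg.n_burn, n_free))
    n_keep = (cfg.n_iter - cfg.n_burn) // cfg.thin
    keep_P = np.empty((n_keep, K))
    keep_sigma = np.empty((n_keep, J))
    kept = 0
    for it in range(cfg.n_iter):
        for c in range(n_free):
            prop = theta.copy()
            prop[c] += scales[c] * rng.standard_normal()
            lp_prop = _log_posterior_theta(prop, X, mu, omega, lam, tau, sigma_scale)
            if np.log(rng.random()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                accepted_window[c] += 1
                if it >= cfg.n_burn:
                    accepted_post += 1
        prop = theta + joint_scale * (chol @ rng.standard_normal(n_free))
        lp_prop = _log_posterior_theta(prop, X, mu, omega, lam, tau, sigma_scale)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            if it >= cfg.n_burn:
                accepted_post += 1
        if it >= cfg.n_burn:
            post_steps += n_free + 1
        if it < cfg.n_burn:
            history[it] = theta
            if (it + 1) % adapt_every == 0:
                # nudge each coordinate scale toward ~44% acceptance (the
                # single-coordinate optimum) and refresh the joint-proposal
                # covariance; all adaptation freezes at the end of burn-in,
                # leaving the stationary kernel untouched.
                rates = accepted_window / adapt_every
                scales *= np.exp(np.clip(rates - 0.44, -0.5, 0.5))
                accepted_window[:] = 0.0
                if it + 1 >= 500:
                    cov = np.cov(history[it // 2 : it + 1].T)
                    cov = np.atleast_2d(cov) + 1e-8 * np.eye(n_free)
                    try:
                        chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
        if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0 and kept < n_keep:
            P, sigma = _theta_to_params(theta, K, J)
            keep_P[kept] = P
            keep_sigma[kept] = sigma
            kept += 1
    acc = accepted_post / max(post_steps, 1)
    return keep_P[:kept], keep_sigma[:kept], acc


def split_rhat(chains: np.ndarray) -> float:
    """Plain split-R̂ of one scalar parameter from an (n_chains, n_draws) array."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("split_rhat needs >= 2 chains of draws")
    n = chains.shape[1] // 2
    if n < 5:
        raise ValueError("split_rhat needs >= 10 draws per chain")
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    means = halves.mean(axis=1)
    vars_ = halves.var(axis=1, ddof=1)
    W = vars_.mean()
    B = n * means.var(ddof=1)
    if W <= 0.0:
        return 1.0 if B <= 1e-300 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def convergence_diagnostics(draws_per_chain: np.ndarray) -> dict[int, float]:
    """Split-R̂ per parameter from an (n_chains, n_draws, n_params) array."""
    arr = np.asarray(draws_per_chain, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("need draws from >= 2 chains, shape (chains, draws, params)")
    return {p: split_rhat(arr[:, :, p]) for p in range(arr.shape[2])}


@dataclass
class MixingPosterior:
    """Pooled posterior draws of source proportions and residual scales."""

    draws_P: np.ndarray  # (n_draws, K)
    draws_sigma: np.ndarray  # (n_draws, J)
    chain: np.ndarray  # (n_draws,) chain index per draw
    source_ids: list[str]
    tracers: tuple[str, ...]
    rhat: dict[str, float]
    acceptance: list[float]
    group_label: str = ""
    converged: bool = True
    summary: pd.DataFrame | None = None


def summarize_posterior(posterior: MixingPosterior) -> pd.DataFrame:
    """Contribution table: per source the posterior mean ± SD of P_k × 100,
    rounded to one decimal, plus per-tracer mean residual scale."""
    if posterior.draws_P.shape[0] == 0:
        raise ValueError("posterior has no retained draws")
    rows = []
    for k, sid in enumerate(posterior.source_ids):
        pct = posterior.draws_P[:, k] * 100.0
        rows.append(
            {
                "source": sid,
                "mean_pct": round(float(pct.mean()), 1),
                "sd_pct": round(float(pct.std(ddof=0)), 1),
            }
        )
    table = pd.DataFrame(rows)
    for j, t in enumerate(posterior.tracers):
        table.attrs[f"mean_sigma_{t}"] = float(posterior.draws_sigma[:, j].mean())
    table.attrs["group"] = posterior.group_label
    return table


class BayesianMixingModel(BaseEstimator):
    """Dirichlet-prior Bayesian mixing model fit by random-walk Metropolis.

    scikit-learn-style estimator.  ``fit(X)`` takes the n × J tracer matrix
    of one sample group (tracer columns in the order of ``tracers``) and
    draws from the posterior of the source proportions P and residual
    scales σ.

    Parameters
    ----------
    sources : list[SourceProfile]
        Endmember signatures (means, SDs, optional fractionation).
    tracers : tuple[str, ...]
        Tracer order defining the columns of X.
    sigma_prior_scale : float, default=20.0
        Half-normal prior scale for each residual σ_j, in ‰.
    mcmc : MCMCConfig, optional
        Sampler settings (chains, iterations, burn-in, thinning, seed).

    Attributes
    ----------
    draws_P_ : ndarray of shape (n_draws, K)
        Pooled retained proportion draws; every row sums to one.
    draws_sigma_ : ndarray of shape (n_draws, J)
        Pooled retained residual-scale draws.
    rhat_ : dict[str, float]
        Split-R̂ per reported parameter.
    summary_ : DataFrame or None
        Contribution table (mean ± SD, %); None if any R̂ exceeds the
        configured threshold.
    """

    def __init__(
        self,
        sources: list[SourceProfile] | None = None,
        tracers: tuple[str, ...] = TRACERS,
        sigma_prior_scale: float = 20.0,
        mcmc: MCMCConfig | None = None,
    ):
        self.sources = sources
        self.tracers = tracers
        self.sigma_prior_scale = sigma_prior_scale
        self.mcmc = mcmc

    def fit(self, X, y=None, group_label: str = ""):
        if not self.sources:
            raise ValueError("sources must be provided")
        cfg = self.mcmc or MCMCConfig()
        X = check_array(np.asarray(X, dtype=float), ensure_min_samples=1)
        if not np.isfinite(X).all():
            raise ValueError("tracer matrix contains non-finite values")
        mu, omega, lam, tau, source_ids = pack_sources(list(self.sources), tuple(self.tracers))
        if X.shape[1] != mu.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} tracer columns but sources define {mu.shape[0]}"
            )
        K, J = mu.shape[1], mu.shape[0]
        if K == 1:
            # degenerate single-source model: P = 1 identically
            n_keep = (cfg.n_iter - cfg.n_burn) // cfg.thin
            self._finalize(
                MixingPosterior(
                    draws_P=np.ones((max(n_keep, 1) * cfg.n_chains, 1)),
                    draws_sigma=self._fit_sigma_only(X, mu, omega, lam, tau, cfg),
                    chain=np.repeat(np.arange(cfg.n_chains), max(n_keep, 1)),
                    source_ids=source_ids,
                    tracers=tuple(self.tracers),
                    rhat={},
                    acceptance=[],
                    group_label=group_label,
                ),
                cfg,
            )
            return self

        per_chain_P, per_chain_sigma, acc = [], [], []
        for c in range(cfg.n_chains):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(c,))
            )
            dP, dS, a = _run_chain(
                rng, X, mu, omega, lam, tau, self.sigma_prior_scale, cfg
            )
            if dP.shape[0] == 0:
                raise RuntimeError("zero retained draws; increase n_iter or reduce n_burn")
            per_chain_P.append(dP)
            per_chain_sigma.append(dS)
            acc.append(a)

        n_keep = min(d.shape[0] for d in per_chain_P)
        stacked_P = np.stack([d[:n_keep] for d in per_chain_P])  # (C, n, K)
        stacked_S = np.stack([d[:n_keep] for d in per_chain_sigma])  # (C, n, J)
        rhat: dict[str, float] = {}
        for k, sid in enumerate(source_ids):
            rhat[f"P[{sid}]"] = split_rhat(stacked_P[:, :, k])
        for j, t in enumerate(self.tracers):
            rhat[f"sigma[{t}]"] = split_rhat(stacked_S[:, :, j])

        posterior = MixingPosterior(
            draws_P=stacked_P.reshape(-1, K),
            draws_sigma=stacked_S.reshape(-1, J),
            chain=np.repeat(np.arange(cfg.n_chains), n_keep),
            source_ids=source_ids,
            tracers=tuple(self.tracers),
            rhat=rhat,
            acceptance=acc,
            group_label=group_label,
        )
        self._finalize(posterior, cfg)
        return self

    def _fit_sigma_only(self, X, mu, omega, lam, tau, cfg) -> np.ndarray:
        draws = []
        for c in range(cfg.n_chains):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(c,))
            )
            _, dS, _ = _run_chain(rng, X, mu, omega, lam, tau, self.sigma_prior_scale, cfg)
            draws.append(dS)
        n_keep = max(min(d.shape[0] for d in draws), 1)
        return np.concatenate([d[:n_keep] for d in draws], axis=0)

    def _finalize(self, posterior: MixingPosterior, cfg: MCMCConfig) -> None:
        bad = {k: v for k, v in posterior.rhat.items() if v > cfg.rhat_threshold}
        posterior.converged = not bad
        if bad:
            logger.warning(
                "chains not converged (R-hat > %.3f): %s; summary withheld",
                cfg.rhat_threshold,
                bad,
            )
        else:
            posterior.summary = summarize_posterior(posterior)
        self.posterior_ = posterior
        self.draws_P_ = posterior.draws_P
        self.draws_sigma_ = posterior.draws_sigma
        self.rhat_ = posterior.rhat
        self.summary_ = posterior.summary
        self.converged_ = posterior.converged
        self.source_ids_ = posterior.source_ids
        self.n_features_in_ = len(posterior.tracers)

    def posterior_mean_(self) -> dict[str, float]:
        check_is_fitted(self, "draws_P_")
        return {
            sid: float(self.draws_P_[:, k].mean())
            for k, sid in enumerate(self.source_ids_)
        }


def fit_mixing_model(
    samples: list[SampleRecord],
    sources: list[SourceProfile],
    mcmc: MCMCConfig | None = None,
    tracers: tuple[str, ...] = TRACERS,
    sigma_prior_scale: float = 20.0,
    group_label: str = "",
) -> MixingPosterior:
    """Fit the mixing model to one group of samples and return the posterior.

    Samples missing any tracer are excluded with a logged notice.
    """
    rows, dropped = [], []
    for s in samples:
        vals = [s.tracer(t) for t in tracers]
        if any(v is None for v in vals):
            dropped.append(s.sample_id)
        else:
            rows.append(vals)
    if dropped:
        logger.info("excluded %d samples with missing tracers: %s", len(dropped), dropped)
    if not rows:
        raise ValueError("no samples with complete tracer data")
    model = BayesianMixingModel(
        sources=sources, tracers=tracers, sigma_prior_scale=sigma_prior_scale, mcmc=mcmc
    )
    model.fit(np.asarray(rows, dtype=float), group_label=group_label)
    return model.posterior_
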