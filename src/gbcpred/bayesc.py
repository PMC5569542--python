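"""MCMC Bayes-C: spike-and-slab Gibbs sampler over SNP effects.

Model: ``y = 1*mu + M Q q + e`` where each SNP effect is zero with prior
probability ``1 - pi`` and ``N(0, sigma2_q)`` with probability ``pi``.  By
default the slab and residual variances are FIXED (see :class:`BayesCConfig`);
sampling them from scaled-inverse-chi-square full conditionals is available
behind ``sample_variances``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import bayesc_sweep
from .core import CenteredGenotypes
from .gblup import TraitParams

__all__ = ["BayesCConfig", "BayesCFit", "run_bayesc_gibbs", "bayesc_gebv", "slab_variance"]


@dataclass(frozen=True)
class BayesCConfig:
    """Chain settings; defaults follow a 20,000-iteration chain with 2000
    burn-in and thinning interval 100."""

    pi: float = 0.05
    n_iter: int = 20_000
    burn_in: int = 2_000
    thin: int = 100
    seed: int = 0
    sample_variances: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.pi <= 1:
            raise ValueError(f"pi must be in (0, 1]; got {self.pi}")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_samples_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class BayesCFit:
    q_hat: np.ndarray
    inclusion_prob: np.ndarray
    mu_hat: float
    n_samples_kept: int
    snp_ids: np.ndarray
    freqs: np.ndarray
    q_samples: np.ndarray
    mu_samples: np.ndarray


def slab_variance(pi: float, sigma2_g: float, scale_c: float) -> float:
    """Fixed slab variance sigma2_q = sigma2_g / (pi * scale_c): the expected
    genetic variance contributed by included SNPs then equals sigma2_g."""
    return sigma2_g / (pi * scale_c)


def run_bayesc_gibbs(
    y: np.ndarray,
    cg_ref: CenteredGenotypes,
    params: TraitParams,
    config: BayesCConfig,
) -> BayesCFit:
    """Run the single-site Gibbs chain and return posterior-mean effects and
    inclusion frequencies.

    SNPs are updated in fixed ascending index order each sweep; the intercept
    has a flat prior and is sampled from its Gaussian full conditional.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("response vector contains non-finite values")
    M = np.asfortranarray(cg_ref.M)
    n, m = M.shape
    if len(y) != n:
        raise ValueError(f"{len(y)} records for {n} genotyped animals")

    s2q = slab_variance(config.pi, params.sigma2_g, cg_ref.scale_c)
    if s2q <= 0:
        raise ValueError("slab variance must be strictly positive")
    s2e = params.sigma2_e
    diag_mm = np.einsum("ij,ij->j", M, M)

    rng = np.random.default_rng(config.seed)
    if config.pi >= 1.0:
        log_prior_odds = np.inf
    else:
        log_prior_odds = math.log(config.pi) - math.log1p(-config.pi)

    mu = float(y.mean())
    q = np.zeros(m)
    delta = np.zeros(m)
    resid = y - mu

    kept = config.n_samples_kept
    q_samples = np.empty((kept, m))
    delta_sum = np.zeros(m)
    mu_samples = np.empty(kept)
    k = 0
    for it in range(config.n_iter):
        # intercept: flat prior, Gaussian full conditional
        resid += mu
        mu = resid.mean() + rng.standard_normal() * math.sqrt(s2e / n)
        resid -= mu

        lam = s2e / s2q
        bayesc_sweep(
            M, resid, q, delta, diag_mm, lam, log_prior_odds, 1.0 / s2e, s2e,
            rng.standard_normal(m), rng.random(m),
        )

        if config.sample_variances:
            k_in = delta.sum()
            nu_q, s0_q = 4.0, s2q
            ssq = float(q @ q)
            s2q = (nu_q * s0_q + ssq) / rng.chisquare(nu_q + k_in)
            nu_e, s0_e = 4.0, params.sigma2_e
            sse = float(resid @ resid)
            s2e = (nu_e * s0_e + sse) / rng.chisquare(nu_e + n)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
            if k < kept:
                q_samples[k] = q
                mu_samples[k] = mu
                delta_sum += delta
                k += 1

    q_samples = q_samples[:k]
    mu_samples = mu_samples[:k]
    return BayesCFit(
        q_hat=q_samples.mean(axis=0),
        inclusion_prob=delta_sum / max(k, 1),
        mu_hat=float(mu_samples.mean()),
        n_samples_kept=k,
        snp_ids=cg_ref.snp_ids,
        freqs=cg_ref.freqs,
        q_samples=q_samples,
        mu_samples=mu_samples,
    )


def bayesc_gebv(fit: BayesCFit, cg_val: CenteredGenotypes) -> np.ndarray:
    """Validation GEBV = M_v q_hat (intercept excluded)."""
    if len(fit.snp_ids) != len(cg_val.snp_ids) or (fit.snp_ids != cg_val.snp_ids).any():
        for a, b in zip(fit.snp_ids, cg_val.snp_ids):
            if a != b:
                raise ValueError(f"SNP mismatch between fit and genotypes: {a!r} vs {b!r}")
        raise ValueError("SNP sets differ in length between fit and genotypes")
    if not np.allclose(fit.freqs, cg_val.freqs):
        raise ValueError("centering frequencies differ between fit and genotypes")
    return cg_val.M @ fit.q_hat
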