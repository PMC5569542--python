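"""Simultaneous fit of a G-BLUP background term and a Bayes-C large-effect SNP
term by iterative conditional expectation (ICE).

Each SNP's effect is replaced by its conditional posterior mean: the
probability that SNP j carries a large effect is

    PostProb = PPR * LR / (PPR * LR + 1),     PPR = pi / (1 - pi)

with the log likelihood ratio

    log(LR_j) = 1/2 log(lambda) - 1/2 log(m_j'm_j + lambda)
              + 1/2 ((m_j'y*)^2 + m_j' PEV m_j) / sigma2_e / (m_j'm_j + lambda),

where y* is the record vector corrected for every effect except SNP j and the
``m_j' PEV m_j`` term corrects for the uncertainty about the other genetic
effects in the model.  The effect update is the posterior probability times
the BLUP solution, ``q_j = PostProb * m_j'y* / (m_j'm_j + lambda)``.

The PEV matrix comes from a one-time G-BLUP-only fit and is held fixed
across outer iterations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from ._kernels import ice_sweep
from .core import CenteredGenotypes, Grm
from .gblup import MixedModelFit, TraitParams, build_coefficient_matrix, solve_gblup, _inverse_with_ridge

__all__ = [
    "GbcConfig",
    "GbcFit",
    "log_likelihood_ratio",
    "posterior_probability",
    "snp_effect_update",
    "fit_gbc",
    "gbc_gebv",
    "select_hyperparameters_cv",
    "DEFAULT_PI_GRID",
]

logger = logging.getLogger(__name__)

#: search between 1% and then 5 to 30% in increments of 5%
DEFAULT_PI_GRID = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass(frozen=True)
class GbcConfig:
    pi: float = 0.01
    large_effect_fraction: float = 0.001
    max_outer_iter: int = 1000
    tol: float = 1e-6
    pev_correction: bool = True
    ppr_literal: bool = False  # reproduce the printed PPR = pi*(1-pi) form

    def __post_init__(self) -> None:
        if not 0 < self.pi < 1:
            raise ValueError(f"pi must be in (0, 1); got {self.pi}")
        if not 0 < self.large_effect_fraction < 1:
            raise ValueError(
                f"large_effect_fraction must be in (0, 1); got {self.large_effect_fraction}"
            )
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_outer_iter < 1:
            raise ValueError("max_outer_iter must be >= 1")


@dataclass
class GbcFit:
    q_hat: np.ndarray
    postprob: np.ndarray
    g_hat: np.ndarray
    mu_hat: float
    working_residuals: np.ndarray
    lambda_: float
    sigma2_q: float
    converged: bool
    n_outer_iter: int
    snp_ids: np.ndarray = None
    freqs: np.ndarray = None
    animal_ids: np.ndarray = None
    gblup_fit: MixedModelFit | None = None


def log_likelihood_ratio(
    m_j: np.ndarray,
    y_star: np.ndarray,
    lam: float,
    sigma2_e: float,
    pev_quadform: float = 0.0,
) -> float:
    """log likelihood ratio for SNP j carrying a large effect vs not.

    ``pev_quadform`` is the precomputed quadratic form ``m_j' PEV m_j``; pass 0
    to disable the uncertainty correction.
    """
    if lam <= 0 or sigma2_e <= 0:
        raise ValueError("lambda and sigma2_e must be strictly positive")
    if pev_quadform < 0:
        raise ValueError("pev_quadform must be non-negative")
    m_j = np.asarray(m_j, dtype=float)
    y_star = np.asarray(y_star, dtype=float)
    mm = float(m_j @ m_j)
    my = float(m_j @ y_star)
    return (
        0.5 * math.log(lam)
        - 0.5 * math.log(mm + lam)
        + 0.5 * (my * my + pev_quadform) / sigma2_e / (mm + lam)
    )


def posterior_probability(log_lr: float, pi: float, ppr_literal: bool = False) -> float:
    """PostProb = PPR*LR / (PPR*LR + 1), evaluated in log space.

    ``PPR`` is the prior odds ``pi/(1-pi)``; ``ppr_literal=True`` uses
    ``pi*(1-pi)`` instead, for comparison.
    """
    if not 0 < pi < 1:
        raise ValueError(f"pi must be in (0, 1); got {pi}")
    if ppr_literal:
        log_ppr = math.log(pi * (1.0 - pi))
    else:
        log_ppr = math.log(pi) - math.log1p(-pi)
    return float(expit(log_ppr + log_lr))


def snp_effect_update(
    m_j: np.ndarray, y_star: np.ndarray, lam: float, postprob: float
) -> float:
    """Conditional-expectation effect: PostProb times the BLUP solution."""
    m_j = np.asarray(m_j, dtype=float)
    y_star = np.asarray(y_star, dtype=float)
    mm = float(m_j @ m_j)
    return postprob * float(m_j @ y_star) / (mm + lam)


def _sigma2_q(config: GbcConfig, params: TraitParams, cg: CenteredGenotypes) -> float:
    """Slab variance such that an average-variance SNP explains a fraction
    ``large_effect_fraction`` of sigma2_g: sigma2_q = f*sigma2_g/vbar with
    vbar = scale_c/m."""
    vbar = cg.scale_c / cg.n_snps
    return config.large_effect_fraction * params.sigma2_g / vbar


def fit_gbc(
    y: np.ndarray,
    cg: CenteredGenotypes,
    grm: Grm | None,
    params: TraitParams,
    config: GbcConfig,
    ref_ids=None,
    val_ids=None,
) -> GbcFit:
    """Fit the combined model ``y = 1*mu + M q + g + e`` on the reference
    animals by ICE.

    ``grm=None`` drops the background term entirely (pure large-effect model);
    the PEV correction then has no source and is skipped.  ``ref_ids`` selects
    the reference rows of ``cg``/``grm``; default is all rows of ``cg``.
    Non-convergence at ``max_outer_iter`` is flagged, not raised.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("response vector contains non-finite values")

    if ref_ids is not None:
        cg_ref = cg.rows_for(ref_ids)
    else:
        cg_ref = cg
    if val_ids is not None:
        overlap = set(val_ids) & set(cg_ref.animal_ids)
        if overlap:
            raise ValueError(f"reference/validation overlap: {sorted(overlap)[:5]}")

    M = np.asfortranarray(cg_ref.M)
    n, m = M.shape
    if len(y) != n:
        raise ValueError(f"{len(y)} records for {n} reference animals")

    s2q = _sigma2_q(config, params, cg)
    lam = params.sigma2_e / s2q
    s2e = params.sigma2_e
    diag_mm = np.einsum("ij,ij->j", M, M)
    if config.ppr_literal:
        log_ppr = math.log(config.pi * (1.0 - config.pi))
    else:
        log_ppr = math.log(config.pi) - math.log1p(-config.pi)

    gblup_fit = None
    pev_quad = np.zeros(m)
    chol = None
    if grm is not None:
        G_rr = grm.block(cg_ref.animal_ids, cg_ref.animal_ids)
        # one-time G-BLUP-only fit: source of the (static) PEV correction
        gblup_fit = solve_gblup(y, G_rr, params)
        if config.pev_correction:
            pev_quad = np.einsum("ij,ij->j", M, gblup_fit.pev @ M)
            np.maximum(pev_quad, 0.0, out=pev_quad)
        C = build_coefficient_matrix(G_rr, params.lambda_g)
        chol = cho_factor(C)

    mu = float(y.mean())
    q = np.zeros(m)
    postprob = np.zeros(m)
    g = np.zeros(n)
    gebv_prev = np.zeros(n)
    sd_y = float(y.std()) or 1.0
    converged = False
    n_outer = 0
    resid = y - mu

    for it in range(config.max_outer_iter):
        n_outer = it + 1
        r = y - M @ q
        if chol is not None:
            sol = cho_solve(chol, np.concatenate(([r.sum()], r)))
            mu, g = float(sol[0]), sol[1:]
        else:
            mu = float(r.mean())
        resid = r - mu - g
        ice_sweep(M, resid, q, postprob, diag_mm, lam, log_ppr, 1.0 / s2e, pev_quad)
        gebv = M @ q + g
        delta = float(np.max(np.abs(gebv - gebv_prev)))
        gebv_prev = gebv
        logger.debug(
            "ICE iter %d: max GEBV change %.3e, %d SNPs with PostProb > 0.5",
            n_outer, delta, int((postprob > 0.5).sum()),
        )
        if delta < config.tol * sd_y:
            converged = True
            break

    if not converged:
        logger.warning(
            "ICE did not converge in %d iterations (last max GEBV change %.3e)",
            config.max_outer_iter, delta,
        )

    return GbcFit(
        q_hat=q,
        postprob=postprob,
        g_hat=g,
        mu_hat=mu,
        working_residuals=resid,
        lambda_=lam,
        sigma2_q=s2q,
        converged=converged,
        n_outer_iter=n_outer,
        snp_ids=cg.snp_ids,
        freqs=cg.freqs,
        animal_ids=cg_ref.animal_ids,
        gblup_fit=gblup_fit,
    )


def gbc_gebv(
    fit: GbcFit,
    cg_val: CenteredGenotypes,
    grm_vr: np.ndarray | None = None,
    grm_rr: np.ndarray | None = None,
) -> np.ndarray:
    """Total validation prediction ``M_v q_hat + G_vr G_rr^-1 g_hat``.

    The background projection term is skipped when the blocks are omitted
    (e.g. a fit with ``grm=None``).
    """
    if len(fit.snp_ids) != len(cg_val.snp_ids) or (fit.snp_ids != cg_val.snp_ids).any():
        raise ValueError("SNP sets differ between fit and validation genotypes")
    if not np.allclose(fit.freqs, cg_val.freqs):
        raise ValueError("centering frequencies differ between fit and validation genotypes")
    gebv = cg_val.M @ fit.q_hat
    if grm_vr is not None and grm_rr is not None:
        grm_vr = np.asarray(grm_vr, dtype=float)
        grm_rr = np.asarray(grm_rr, dtype=float)
        if grm_vr.shape != (cg_val.n_animals, len(fit.g_hat)):
            raise ValueError(
                f"validation x reference block {grm_vr.shape} does not conform"
            )
        Ginv = _inverse_with_ridge(grm_rr)
        gebv = gebv + grm_vr @ (Ginv @ fit.g_hat)
    return gebv


def select_hyperparameters_cv(
    y: np.ndarray,
    cg: CenteredGenotypes,
    grm: Grm | None,
    params: TraitParams,
    pi_grid=DEFAULT_PI_GRID,
    f_grid=(0.001,),
    k_folds: int = 5,
    seed: int = 0,
    base_config: GbcConfig | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Grid-search (pi, large_effect_fraction) by k-fold cross-validation on
    the reference animals; the score is the mean across folds of the
    correlation between hold-out predictions and hold-out responses."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = np.asarray(y, dtype=float)
    n = cg.n_animals
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)
    if min(len(f) for f in folds) < 2:
        raise ValueError(f"{k_folds} folds leave a fold with < 2 animals")

    rows = []
    for pi, f in product(pi_grid, f_grid):
        cfg_kwargs = dict(pi=pi, large_effect_fraction=f)
        if base_config is not None:
            cfg = GbcConfig(
                **cfg_kwargs,
                max_outer_iter=base_config.max_outer_iter,
                tol=base_config.tol,
                pev_correction=base_config.pev_correction,
                ppr_literal=base_config.ppr_literal,
            )
        else:
            cfg = GbcConfig(**cfg_kwargs)
        scores = []
        for hold in folds:
            train = np.setdiff1d(perm, hold)
            cg_train = cg.rows(train)
            cg_hold = cg.rows(hold)
            if grm is not None:
                fit = fit_gbc(y[train], cg_train, grm, params, cfg,
                              ref_ids=cg_train.animal_ids)
                pred = gbc_gebv(
                    fit,
                    cg_hold,
                    grm.block(cg_hold.animal_ids, cg_train.animal_ids),
                    grm.block(cg_train.animal_ids, cg_train.animal_ids),
                )
            else:
                fit = fit_gbc(y[train], cg_train, None, params, cfg)
                pred = gbc_gebv(fit, cg_hold)
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(pred, y[hold])[0, 1]
            scores.append(0.0 if not np.isfinite(c) else float(c))
        rows.append(dict(pi=pi, large_effect_fraction=f, score=float(np.mean(scores))))

    table = pd.DataFrame(rows)
    best = table.loc[table["score"].idxmax()]
    return float(best["pi"]), float(best["large_effect_fraction"]), table
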