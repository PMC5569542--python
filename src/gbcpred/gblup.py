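"""Mixed-model (G-BLUP) solver.

Solves ``y = 1*mu + g + e`` with ``g ~ MVN(0, sigma2_g * G)`` and
``e ~ MVN(0, sigma2_e * I)`` by direct inversion of the mixed-model
equations, returning the full prediction-error-variance (PEV) matrix of the
breeding-value solutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Grm

__all__ = ["TraitParams", "MixedModelFit", "solve_gblup", "predict_validation_gblup"]

logger = logging.getLogger(__name__)

_RIDGE = 1e-6


@dataclass(frozen=True)
class TraitParams:
    """Trait variance components.

    ``h2`` enters only through the reliability constant ``K = (4 - h2)/h2``;
    ``sigma2_g``/``sigma2_e`` are the genetic and residual variances of the
    response model.
    """

    h2: float
    sigma2_g: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if not 0 < self.h2 <= 1:
            raise ValueError(f"h2 must be in (0, 1]; got {self.h2}")
        if self.sigma2_g <= 0 or self.sigma2_e <= 0:
            raise ValueError("variances must be strictly positive")

    @property
    def K(self) -> float:
        return (4.0 - self.h2) / self.h2

    @property
    def lambda_g(self) -> float:
        return self.sigma2_e / self.sigma2_g


@dataclass
class MixedModelFit:
    mu_hat: float
    g_hat: np.ndarray
    pev: np.ndarray
    lambda_g: float
    animal_ids: np.ndarray | None = None


def _inverse_with_ridge(G: np.ndarray) -> np.ndarray:
    """Invert a (possibly rank-deficient) relationship matrix, retrying once
    with a small diagonal ridge."""
    try:
        return _chol_inv(G)
    except np.linalg.LinAlgError:
        logger.warning("singular relationship matrix; adding %g ridge to diagonal", _RIDGE)
        try:
            return _chol_inv(G + _RIDGE * np.eye(len(G)))
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "relationship matrix singular even after ridge"
            ) from e


def _chol_inv(G: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(G)
    Linv = np.linalg.solve(L, np.eye(len(G)))
    return Linv.T @ Linv


def build_coefficient_matrix(
    grm_rr: np.ndarray, lambda_g: float, weights: np.ndarray | None = None
) -> np.ndarray:
    """Dense MME coefficient matrix ``[[1'W1, 1'W], [W1, W + G^-1 lambda]]``
    for identity incidence; ``weights`` (optional) scale residual precision."""
    n = len(grm_rr)
    Ginv = _inverse_with_ridge(grm_rr)
    C = np.empty((n + 1, n + 1))
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w <= 0).any():
            raise ValueError("weights must be positive and match the record count")
    C[0, 0] = w.sum()
    C[0, 1:] = w
    C[1:, 0] = w
    C[1:, 1:] = np.diag(w) + Ginv * lambda_g
    return C


def solve_gblup(
    y: np.ndarray,
    grm_rr: Grm | np.ndarray,
    params: TraitParams,
    weights: np.ndarray | None = None,
) -> MixedModelFit:
    """Solve the mixed-model equations for (mu, g) and return the fit with the
    full PEV matrix of ``g_hat``.

    ``weights``, if given, make residual variance proportional to ``1/w_i``
    (off by default: the response model is homoscedastic).
    """
    ids = None
    if isinstance(grm_rr, Grm):
        ids = grm_rr.animal_ids
        G = grm_rr.values
    else:
        G = np.asarray(grm_rr, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if G.shape != (n, n):
        raise ValueError(f"GRM block {G.shape} does not match {n} records")
    if not np.isfinite(y).all():
        raise ValueError("response vector contains non-finite values")
    lam = params.lambda_g
    C = build_coefficient_matrix(G, lam, weights)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    rhs = np.concatenate(([w @ y], w * y))
    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs
    pev = params.sigma2_e * Cinv[1:, 1:]
    pev = (pev + pev.T) / 2.0
    return MixedModelFit(
        mu_hat=float(sol[0]),
        g_hat=sol[1:],
        pev=pev,
        lambda_g=lam,
        animal_ids=ids,
    )


def predict_validation_gblup(
    fit: MixedModelFit, grm_vr: np.ndarray, grm_rr: np.ndarray
) -> np.ndarray:
    """Project reference breeding values onto validation animals:
    ``g_v = G_vr G_rr^-1 g_r``."""
    grm_vr = np.asarray(grm_vr, dtype=float)
    grm_rr = np.asarray(grm_rr, dtype=float)
    n_ref = len(fit.g_hat)
    if grm_rr.shape != (n_ref, n_ref) or grm_vr.shape[1] != n_ref:
        raise ValueError(
            f"block shapes {grm_vr.shape}, {grm_rr.shape} do not conform "
            f"with {n_ref} reference solutions"
        )
    Ginv = _inverse_with_ridge(grm_rr)
    return grm_vr @ (Ginv @ fit.g_hat)
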