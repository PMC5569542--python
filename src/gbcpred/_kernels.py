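"""Hot loops shared by the Gibbs sampler and the ICE solver.

Compiled with numba when available; the pure-Python fallbacks are exact but
slow and exist only so the package imports everywhere.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def ice_sweep(M, resid, q, postprob, diag_mm, lam, log_ppr, inv_s2e, pev_quad):
    """One deterministic coordinate sweep over all SNPs, ascending index order.

    For SNP j the corrected right-hand side m_j'y* is rebuilt from the running
    residual by adding the SNP's own contribution back; the residual is updated
    in place after each effect update.
    """
    n, m = M.shape
    for j in range(m):
        mm = diag_mm[j]
        rhs = mm * q[j]
        for i in range(n):
            rhs += M[i, j] * resid[i]
        denom = mm + lam
        log_lr = (
            0.5 * np.log(lam)
            - 0.5 * np.log(denom)
            + 0.5 * (rhs * rhs + pev_quad[j]) * inv_s2e / denom
        )
        lo = log_ppr + log_lr
        if lo > 35.0:
            p = 1.0
        elif lo < -35.0:
            p = 0.0
        else:
            p = 1.0 / (1.0 + np.exp(-lo))
        postprob[j] = p
        q_new = p * rhs / denom
        delta = q[j] - q_new
        if delta != 0.0:
            for i in range(n):
                resid[i] += M[i, j] * delta
        q[j] = q_new


@njit(cache=True)
def bayesc_sweep(M, resid, q, delta, diag_mm, lam, log_prior_odds, inv_s2e,
                 s2e, normals, uniforms):
    """One single-site Gibbs sweep over SNP inclusion indicators and effects.

    ``normals``/``uniforms`` are pre-drawn length-m arrays so the caller owns
    the random stream.
    """
    n, m = M.shape
    for j in range(m):
        mm = diag_mm[j]
        rhs = mm * q[j]
        for i in range(n):
            rhs += M[i, j] * resid[i]
        denom = mm + lam
        log_bf = (
            0.5 * np.log(lam)
            - 0.5 * np.log(denom)
            + 0.5 * rhs * rhs * inv_s2e / denom
        )
        lo = log_prior_odds + log_bf
        if lo > 35.0:
            p = 1.0
        elif lo < -35.0:
            p = 0.0
        else:
            p = 1.0 / (1.0 + np.exp(-lo))
        if uniforms[j] < p:
            q_new = rhs / denom + np.sqrt(s2e / denom) * normals[j]
            delta[j] = 1.0
        else:
            q_new = 0.0
            delta[j] = 0.0
        diff = q[j] - q_new
        if diff != 0.0:
            for i in range(n):
                resid[i] += M[i, j] * diff
        q[j] = q_new
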