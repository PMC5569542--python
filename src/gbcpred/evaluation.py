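"""Predictive-ability statistics: response reliability, accuracy, bias,
bootstrap standard errors, and the Hotelling-Williams test for dependent
correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable",
    "EvaluationReport",
    "dyd_reliability",
    "prediction_accuracy",
    "prediction_bias",
    "bootstrap_se",
    "hotelling_williams",
]


@dataclass
class PhenotypeTable:
    """Per-animal response records: DYD-like value and effective record count
    ``d_e``; ``reliability`` is filled by :func:`dyd_reliability`."""

    animal_id: np.ndarray
    dyd: np.ndarray
    d_e: np.ndarray
    reliability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.animal_id = np.asarray(self.animal_id, dtype=object)
        self.dyd = np.asarray(self.dyd, dtype=float)
        self.d_e = np.asarray(self.d_e, dtype=float)
        if not (len(self.animal_id) == len(self.dyd) == len(self.d_e)):
            raise ValueError("phenotype columns have unequal lengths")
        if len(self.animal_id) != len(set(self.animal_id)):
            raise ValueError("duplicate animal ids in phenotype table")
        if (self.d_e < 0).any():
            raise ValueError("d_e must be non-negative")
        if self.reliability is not None:
            self.reliability = np.asarray(self.reliability, dtype=float)
            if ((self.reliability < 0) | (self.reliability > 1)).any():
                raise ValueError("reliability must lie in [0, 1]")

    def with_reliability(self, h2: float) -> "PhenotypeTable":
        return PhenotypeTable(
            animal_id=self.animal_id,
            dyd=self.dyd,
            d_e=self.d_e,
            reliability=dyd_reliability(self.d_e, h2),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"animal_id": self.animal_id, "dyd": self.dyd, "de": self.d_e}
        )
        if self.reliability is not None:
            df["reliability"] = self.reliability
        return df

    def subset(self, ids) -> "PhenotypeTable":
        lookup = {a: i for i, a in enumerate(self.animal_id)}
        try:
            idx = np.array([lookup[a] for a in ids])
        except KeyError as e:
            raise KeyError(f"animal id {e.args[0]!r} not in phenotype table") from None
        return PhenotypeTable(
            animal_id=self.animal_id[idx],
            dyd=self.dyd[idx],
            d_e=self.d_e[idx],
            reliability=None if self.reliability is None else self.reliability[idx],
        )


@dataclass
class EvaluationReport:
    method_label: str
    accuracy: float
    accuracy_se: float
    bias: float
    bias_se: float
    n_validation: int
    mean_reliability: float

    def __post_init__(self) -> None:
        if self.n_validation < 3:
            raise ValueError("need at least 3 validation animals")
        if self.accuracy_se < 0 or self.bias_se < 0:
            raise ValueError("standard errors must be non-negative")


def dyd_reliability(d_e, h2: float):
    """Reliability ``d_e / (d_e + K)`` with ``K = (4 - h2) / h2``."""
    if not 0 < h2 <= 1:
        raise ValueError(f"h2 must be in (0, 1]; got {h2}")
    d_e = np.asarray(d_e, dtype=float)
    if (d_e < 0).any():
        raise ValueError("d_e must be non-negative")
    K = (4.0 - h2) / h2
    out = d_e / (d_e + K)
    return float(out) if out.ndim == 0 else out


def prediction_accuracy(gebv, dyd, mean_reliability: float) -> float:
    """corr(GEBV, DYD) divided by the square root of the mean DYD reliability."""
    gebv = np.asarray(gebv, dtype=float)
    dyd = np.asarray(dyd, dtype=float)
    if len(gebv) != len(dyd) or len(gebv) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not 0 < mean_reliability <= 1:
        raise ValueError(f"mean reliability must be in (0, 1]; got {mean_reliability}")
    if gebv.std() == 0 or dyd.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(gebv, dyd)[0, 1])
    return r / np.sqrt(mean_reliability)


def prediction_bias(gebv, dyd) -> float:
    """OLS slope (with intercept) of DYD on GEBV; 1 = unbiased, < 1 = GEBV
    spread too large, > 1 = too small."""
    gebv = np.asarray(gebv, dtype=float)
    dyd = np.asarray(dyd, dtype=float)
    if len(gebv) != len(dyd) or len(gebv) < 3:
        raise ValueError("need paired vectors of length >= 3")
    v = gebv.var()
    if v == 0:
        raise ValueError("regression undefined for zero-variance predictions")
    return float(np.cov(gebv, dyd, ddof=0)[0, 1] / v)


def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_se(
    gebv,
    dyd,
    mean_reliability: float,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap standard errors of accuracy and bias.

    GEBV-DYD pairs are resampled jointly (the link between an animal's GEBV
    and its DYD is kept).  Degenerate resamples (a constant vector) are redrawn;
    more than 1% of them is an error.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    gebv = np.asarray(gebv, dtype=float)
    dyd = np.asarray(dyd, dtype=float)
    n = len(gebv)
    if len(dyd) != n or n < 3:
        raise ValueError("need paired vectors of length >= 3")
    rng = np.random.default_rng(seed)

    idx = rng.integers(0, n, size=(n_boot, n))
    g = gebv[idx]
    d = dyd[idx]
    bad = (g.std(axis=1) == 0) | (d.std(axis=1) == 0)
    n_degenerate = int(bad.sum())
    redraws = 0
    while bad.any():
        if redraws > 100:
            break
        idx2 = rng.integers(0, n, size=(int(bad.sum()), n))
        g[bad] = gebv[idx2]
        d[bad] = dyd[idx2]
        bad2 = (g.std(axis=1) == 0) | (d.std(axis=1) == 0)
        n_degenerate += int(bad2[bad].sum()) if bad2.any() else 0
        bad = bad2
        redraws += 1
    if n_degenerate > 0.01 * n_boot:
        raise ValueError(
            f"{n_degenerate} degenerate bootstrap resamples out of {n_boot}; "
            "increase the validation sample size"
        )

    acc = _row_corr(g, d) / np.sqrt(mean_reliability)
    gc = g - g.mean(axis=1, keepdims=True)
    dc = d - d.mean(axis=1, keepdims=True)
    slope = (gc * dc).sum(axis=1) / (gc**2).sum(axis=1)
    return float(np.std(acc, ddof=1)), float(np.std(slope, ddof=1))


def hotelling_williams(
    r12: float, r13: float, r23: float, n: int
) -> tuple[float, float]:
    """Two-sided test of equality of the dependent correlations r12 and r13
    (sharing variable 1), observed on the same n subjects.

    Returns (t statistic, p value) with n - 3 degrees of freedom.
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must be in (-1, 1); got {r}")
    if n < 4:
        raise ValueError("need n >= 4")
    detR = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if detR < -1e-10:
        raise ValueError(
            f"correlation triple is not positive semi-definite (|R| = {detR:.3e})"
        )
    detR = max(detR, 0.0)
    rbar = (r12 + r13) / 2.0
    denom = 2 * ((n - 1) / (n - 3)) * detR + rbar**2 * (1 - r23) ** 3
    if denom <= 0:
        return 0.0, 1.0
    t = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    p = 2.0 * stats.t.sf(abs(t), df=n - 3)
    return float(t), float(min(p, 1.0))
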