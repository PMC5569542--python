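"""Synthetic data generator: half-sib families, MAF-bounded unlinked SNPs, a
few large QTL on a polygenic background, and DYD-like responses whose
precision is driven by an effective record count d_e.

The default preset targets the regime of a progeny-tested dairy population:
validation animals are offspring of reference-set sires (top relationships
near 0.5), d_e ~ N(177, 31) truncated at 108, MAF >= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    CenteredGenotypes,
    GenotypeMatrix,
    center_genotypes,
    filter_by_maf,
)
from .evaluation import PhenotypeTable, dyd_reliability

__all__ = ["SimConfig", "SimDataset", "simulate_genotypes", "simulate_architecture",
           "simulate_phenotypes", "make_scenario", "PAPER_LIKE", "TINY"]


@dataclass(frozen=True)
class SimConfig:
    n_ref: int = 1000
    n_val: int = 124
    n_sires: int = 50
    m_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_large_qtl: int = 2
    large_qtl_fraction: float = 0.1
    h2: float = 0.25
    sigma2_g: float = 1.0
    d_e_mean: float = 177.0
    d_e_sd: float = 31.0
    d_e_min: float = 108.0
    seed: int = 0
    ld_block_size: int = 1  # >1: exchangeable correlation within windows
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n_ref <= 0 or self.n_val <= 0 or self.m_snps <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError(f"maf_range must lie within (0, 0.5]; got {self.maf_range}")
        if self.n_large_qtl * self.large_qtl_fraction > 1:
            raise ValueError("large QTL cannot explain more than the genetic variance")
        if self.n_large_qtl > self.m_snps:
            raise ValueError("more large QTL than SNPs")
        if self.n_sires < 0:
            raise ValueError("n_sires must be >= 0")


#: scaled-down analogue of the study data (n_ref reference bulls, 124
#: validation bulls, d_e ~ N(177, 31) truncated at 108)
PAPER_LIKE = SimConfig()

TINY = SimConfig(n_ref=50, n_val=10, n_sires=5, m_snps=100, n_large_qtl=1,
                 large_qtl_fraction=0.2, d_e_mean=50.0, d_e_sd=10.0, d_e_min=20.0)


@dataclass
class SimDataset:
    genotypes: GenotypeMatrix
    centered: CenteredGenotypes
    tbv: np.ndarray
    qtl_effects: np.ndarray
    qtl_indices: np.ndarray
    phenotypes: PhenotypeTable
    ref_ids: np.ndarray
    val_ids: np.ndarray
    config: SimConfig


def _population_gametes(rng, p: np.ndarray, n: int) -> np.ndarray:
    return (rng.random((n, len(p))) < p).astype(np.float64)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Biallelic unlinked SNP genotypes.

    With ``n_sires = 0`` all animals are unrelated draws Binomial(2, p_j).
    Otherwise sires are drawn first and every non-sire animal receives one
    gamete from a (random) sire and one population gamete; the sires are
    placed in the reference set, so validation animals are half-sibs of the
    reference family they belong to and carry top relationships near 0.5.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=config.m_snps)
    n_total = config.n_ref + config.n_val

    if config.ld_block_size > 1 and config.ld_rho > 0:
        counts = _blockcorr_genotypes(rng, p, n_total, config)
    elif config.n_sires == 0:
        counts = rng.binomial(2, p, size=(n_total, config.m_snps)).astype(np.float64)
    else:
        n_sires = min(config.n_sires, config.n_ref)
        sire_g1 = _population_gametes(rng, p, n_sires)
        sire_g2 = _population_gametes(rng, p, n_sires)
        n_off = n_total - n_sires
        sire_of = rng.integers(0, n_sires, size=n_off)
        pick = rng.random((n_off, config.m_snps)) < 0.5
        paternal = np.where(pick, sire_g1[sire_of], sire_g2[sire_of])
        maternal = _population_gametes(rng, p, n_off)
        counts = np.vstack([sire_g1 + sire_g2, paternal + maternal])

    ids = np.array([f"A{i:05d}" for i in range(n_total)], dtype=object)
    snps = np.array([f"snp{j:05d}" for j in range(config.m_snps)], dtype=object)
    return GenotypeMatrix(animal_ids=ids, snp_ids=snps, counts=counts)


def _blockcorr_genotypes(rng, p, n_total, config: SimConfig) -> np.ndarray:
    """Gaussian-copula genotypes with exchangeable correlation inside windows
    of ``ld_block_size`` SNPs (qualitative LD mode)."""
    m = len(p)
    rho = config.ld_rho
    z = np.empty((2, n_total, m))
    for hap in range(2):
        shared = rng.standard_normal((n_total, (m + config.ld_block_size - 1) // config.ld_block_size))
        block = np.repeat(shared, config.ld_block_size, axis=1)[:, :m]
        own = rng.standard_normal((n_total, m))
        z[hap] = np.sqrt(rho) * block + np.sqrt(1 - rho) * own
    thresh = stats.norm.ppf(p)
    return ((z[0] < thresh).astype(float) + (z[1] < thresh).astype(float))


def simulate_architecture(
    config: SimConfig, cg: CenteredGenotypes, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """True SNP effect vector: ``n_large_qtl`` SNPs each sized to contribute
    ``large_qtl_fraction * sigma2_g``; the remaining variance is spread over
    all other SNPs as i.i.d. normal effects.

    Returns ``(effects, qtl_indices)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    m = cg.n_snps
    col_var = cg.M.var(axis=0)
    effects = np.zeros(m)
    qtl = rng.choice(m, size=config.n_large_qtl, replace=False) if config.n_large_qtl else np.array([], dtype=int)
    for j in qtl:
        if col_var[j] <= 0:
            raise ValueError(f"QTL column {j} has zero variance")
        effects[j] = rng.choice([-1.0, 1.0]) * np.sqrt(
            config.large_qtl_fraction * config.sigma2_g / col_var[j]
        )
    remaining = config.sigma2_g * (1.0 - config.n_large_qtl * config.large_qtl_fraction)
    others = np.setdiff1d(np.arange(m), qtl)
    if remaining > 0 and len(others):
        total_v = col_var[others].sum()
        s2 = remaining / total_v
        effects[others] = rng.standard_normal(len(others)) * np.sqrt(s2)
    return effects, np.sort(qtl)


def simulate_phenotypes(
    tbv: np.ndarray,
    config: SimConfig,
    animal_ids: np.ndarray,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """DYD-like records ``tbv + noise`` with per-animal noise variance
    ``sigma2_g * (1 - r2) / r2`` where ``r2 = d_e/(d_e + K)``; d_e is drawn
    from a truncated normal."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(tbv)
    a = (config.d_e_min - config.d_e_mean) / config.d_e_sd
    d_e = stats.truncnorm.rvs(
        a, np.inf, loc=config.d_e_mean, scale=config.d_e_sd, size=n, random_state=rng
    )
    r2 = dyd_reliability(d_e, config.h2)
    noise_var = config.sigma2_g * (1.0 - r2) / r2
    dyd = tbv + rng.standard_normal(n) * np.sqrt(noise_var)
    return PhenotypeTable(
        animal_id=animal_ids, dyd=dyd, d_e=d_e, reliability=r2
    )


def make_scenario(config: SimConfig) -> SimDataset:
    """Compose genotypes -> MAF filter (0.05) -> architecture -> TBV -> DYD and
    split animals into reference and validation sets."""
    geno = simulate_genotypes(config)
    geno = filter_by_maf(geno, 0.05)
    cg = center_genotypes(geno)
    effects, qtl = simulate_architecture(config, cg)
    tbv = cg.M @ effects
    pheno = simulate_phenotypes(tbv, config, geno.animal_ids)
    ref_ids = geno.animal_ids[: config.n_ref]
    val_ids = geno.animal_ids[config.n_ref:]
    return SimDataset(
        genotypes=geno,
        centered=cg,
        tbv=tbv,
        qtl_effects=effects,
        qtl_indices=qtl,
        phenotypes=pheno,
        ref_ids=ref_ids,
        val_ids=val_ids,
        config=config,
    )
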