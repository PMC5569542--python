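import numpy as np
import pytest

from gbcpred import (
    GenotypeMatrix,
    SimConfig,
    TraitParams,
    build_grm,
    center_genotypes,
    make_scenario,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_genotypes(rng, n, m, maf_low=0.1, prefix=""):
    p = rng.uniform(maf_low, 0.5, size=m)
    counts = rng.binomial(2, p, size=(n, m)).astype(float)
    # guarantee polymorphism so centering never degenerates
    fixed = (counts == counts[0]).all(axis=0)
    counts[0, fixed] = 0.0
    counts[1, fixed] = 1.0
    return GenotypeMatrix(
        animal_ids=np.array([f"{prefix}a{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"{prefix}s{j}" for j in range(m)], dtype=object),
        counts=counts,
    )


@pytest.fixture
def small_geno():
    rng = np.random.default_rng(7)
    return random_genotypes(rng, 12, 30)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small half-sib scenario reused across modules."""
    cfg = SimConfig(
        n_ref=80, n_val=20, n_sires=8, m_snps=120, n_large_qtl=1,
        large_qtl_fraction=0.3, h2=0.25, d_e_mean=60.0, d_e_sd=10.0,
        d_e_min=30.0, seed=11,
    )
    return make_scenario(cfg)


@pytest.fixture(scope="session")
def tiny_fit_inputs(tiny_dataset):
    ds = tiny_dataset
    rbar = float(ds.phenotypes.reliability.mean())
    params = TraitParams(
        h2=ds.config.h2,
        sigma2_g=ds.config.sigma2_g,
        sigma2_e=ds.config.sigma2_g * (1 - rbar) / rbar,
    )
    grm = build_grm(ds.centered)
    return ds, params, grm
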