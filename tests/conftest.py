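import numpy as np
import pandas as pd
import pytest

from menvgp import (
    GRM,
    GenotypeMatrix,
    SimConfig,
    center_standardize,
    grm_vanraden,
    simulate_breeding_values,
    simulate_genotypes,
)
from menvgp.sim import exchangeable_cov


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_lines=60, n_markers=400, n_envs=4, seed=7,
                     missing_cell_fraction=0.1)


@pytest.fixture(scope="session")
def small_grm(small_cfg) -> GRM:
    geno = simulate_genotypes(small_cfg)
    poly = geno.dosages.std(axis=0) > 0
    W = center_standardize(geno.dosages[:, poly])
    return grm_vanraden(W, line_ids=geno.line_ids)


@pytest.fixture(scope="session")
def recovery_data():
    """Line-mean phenotypes at h2 = 0.5 with genetic correlation 0.8."""
    cfg = SimConfig(n_lines=300, n_markers=2000, n_envs=4,
                    env_cov_matrix=exchangeable_cov(4, 1.0, 0.8),
                    h2_per_env=np.full(4, 0.5), seed=11)
    geno = simulate_genotypes(cfg)
    W = center_standardize(geno)
    K = grm_vanraden(W, line_ids=geno.line_ids)
    U = simulate_breeding_values(K, cfg.env_cov_matrix, rng=cfg.rng(4),
                                 env_ids=cfg.env_ids)
    Y = U + cfg.rng(5).normal(0.0, 1.0, U.shape)
    Y = Y + np.array([0.0, 0.5, -0.5, 0.25])
    return {"cfg": cfg, "K": K, "U": U, "Y": Y}


def toy_qc_matrix() -> GenotypeMatrix:
    """Six markers: two fail MAF, one fails missing rate, two are duplicates.

    Exactly two markers survive the default thresholds.
    """
    rng = np.random.default_rng(42)
    n = 50
    rare = np.zeros(n)
    rare[:2] = 2.0  # MAF = 2*2 / (2*50) = 0.04
    rare2 = np.zeros(n)
    rare2[5:7] = 2.0
    common = 2.0 * (rng.random(n) < 0.5)
    gappy = common.copy()
    gappy[:6] = np.nan  # 12% missing
    dup_a = 2.0 * (rng.random(n) < 0.4)
    dup_b = dup_a.copy()  # perfectly correlated with dup_a
    dosages = np.column_stack([rare, rare2, gappy, dup_a, dup_b, common])
    return GenotypeMatrix(
        line_ids=np.array([f"L{i}" for i in range(n)]),
        marker_ids=np.array(["rare1", "rare2", "gappy", "dupA", "dupB", "good"]),
        dosages=dosages,
    )


@pytest.fixture
def qc_toy() -> GenotypeMatrix:
    return toy_qc_matrix()
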