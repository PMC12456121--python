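"""Marker quality control, the genomic relationship matrix, and the EC kernel.

QC removes markers with minor allele frequency <= 5%, missing rate >= 10%,
and one of every pair correlated at |r| >= 0.99; the VanRaden kinship
K = WW'/p is then built from the centered, standardized dosages, and an
analogous kernel Omega summarizes environment similarity from weather
covariates.
"""

import numpy as np

from menvgp import (
    SimConfig,
    center_standardize,
    ec_kernel,
    grm_vanraden,
    qc_markers,
    simulate_env_covariates,
    simulate_genotypes,
)

cfg = SimConfig(n_lines=150, n_markers=1000, seed=7)
geno = simulate_genotypes(cfg)
filtered, report = qc_markers(geno)
print(report.to_frame().to_string(index=False))

W = center_standardize(filtered)
K = grm_vanraden(W, line_ids=filtered.line_ids)
print(f"\nK: {K.K.shape}, diagonal mean {np.diag(K.K).mean():.3f}, "
      f"grand sum {K.K.sum():.2e} (centering), "
      f"min eigenvalue {np.linalg.eigvalsh(K.K).min():.2e} (PSD)")

ec = simulate_env_covariates(cfg, n_covs=3)
print("\nenvironmental covariates (per environment):")
print(ec.to_frame().round(2))
Omega = ec_kernel(ec)
print("\nenvironment kernel Omega (positive = similar growing conditions):")
print(Omega.to_frame().round(2))
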