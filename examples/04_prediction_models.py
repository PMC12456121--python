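"""The five genomic-prediction models and their posterior summaries.

Single-environment GBLUP gives per-environment genomic heritabilities; the
multi-trait model estimates between-environment genetic correlations; the
reaction-norm (G x C) and marker-by-environment (M x E) models partition
variance into main, interaction and residual shares.
"""

import numpy as np

from menvgp import (
    MCMCConfig,
    SimConfig,
    center_standardize,
    ec_kernel,
    fit_gblup_single_env,
    fit_gxc,
    fit_mtm,
    fit_mxe,
    genetic_correlations,
    grm_vanraden,
    heritability,
    simulate_breeding_values,
    simulate_env_covariates,
    simulate_genotypes,
    variance_proportions,
)
from menvgp.sim import exchangeable_cov

cfg = SimConfig(n_lines=200, n_markers=1000, n_envs=4,
                env_cov_matrix=exchangeable_cov(4, 1.0, 0.8),
                h2_per_env=np.full(4, 0.5), seed=5)
geno = simulate_genotypes(cfg)
K = grm_vanraden(center_standardize(geno), line_ids=geno.line_ids)
U = simulate_breeding_values(K, cfg.env_cov_matrix, rng=cfg.rng(4),
                             env_ids=cfg.env_ids)
Y = U + cfg.rng(5).normal(0, 1.0, U.shape)  # line means at h2 = 0.5
Omega = ec_kernel(simulate_env_covariates(cfg))

mcmc = MCMCConfig(n_iter=4000, burn_in=1500, thin=2, seed=1)

print("single-environment GBLUP genomic heritabilities (truth 0.5):")
for env in Y.columns:
    fit = fit_gblup_single_env(Y[env], K, mcmc)
    print(f"  {env}: h2 = {heritability(fit):.2f}")

mt = fit_mtm(Y, K, mcmc)
print("\nmulti-trait genetic correlations (truth 0.8 off-diagonal):")
print(genetic_correlations(mt).round(2))

gxc = fit_gxc(Y, K, Omega, mcmc)
print("\nG x C variance shares (g = genetic, E = environment, w = EC, "
      "gE / gw = interactions):")
print(variance_proportions(gxc).round(3).to_dict())

mxe = fit_mxe(Y, K, mcmc)
print("\nM x E variance shares (main = stable across environments):")
print(variance_proportions(mxe).round(3).to_dict())
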