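"""Synthetic multi-environment trial generator with known ground truth.

Emulates the data a maize inbred diversity panel produces when evaluated in
a handful of location-year environments: homozygous dosage genotypes,
environment covariates, a randomized complete block row-column field layout
with smooth spatial trends, breeding values correlated across environments,
and cell-wise unbalancedness in which lines are not observed everywhere.
Every generator is deterministic given the configuration seed, and the
truth (breeding values, spatial surfaces, variance components) is returned
so downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from menvgp.kernels import GRM, EnvCovariateTable, GenotypeMatrix


def exchangeable_cov(n_envs: int, var: float = 1.0, corr: float = 0.8) -> np.ndarray:
    """Equicorrelated environment covariance for breeding values."""
    E = np.full((n_envs, n_envs), corr * var)
    np.fill_diagonal(E, var)
    return E


@dataclass
class SimConfig:
    """Study conditions for the synthetic multi-environment trial.

    Defaults describe a mid-size inbred diversity panel: ~400 lines scored
    in 4 environments x 2 replicates, a few thousand independent biallelic
    SNPs, per-environment heritabilities between 0.2 and 0.55, high
    positive genetic correlations between environments, and a tenth of the
    line x environment cells unobserved.
    """

    n_lines: int = 400
    n_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_envs: int = 4
    env_cov_matrix: np.ndarray | None = None  # default: equicorrelated, corr 0.8
    env_means: np.ndarray | None = None  # default: evenly spread intercepts
    h2_per_env: np.ndarray | None = None  # default: (0.25, 0.4, 0.5, 0.35)[:J]
    n_reps: int = 2
    field_rows: int | None = None  # default: near-square layout
    field_cols: int | None = None
    spatial_amplitude: float = 1.0
    rep_effect_sd: float = 0.25
    missing_cell_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines <= 0 or self.n_markers <= 0 or self.n_envs <= 0 or self.n_reps <= 0:
            raise ValueError("dimensions must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.env_cov_matrix is None:
            self.env_cov_matrix = exchangeable_cov(self.n_envs)
        self.env_cov_matrix = np.asarray(self.env_cov_matrix, dtype=float)
        if self.env_cov_matrix.shape != (self.n_envs, self.n_envs):
            raise ValueError("env_cov_matrix must be J x J")
        if not np.allclose(self.env_cov_matrix, self.env_cov_matrix.T):
            raise ValueError("env_cov_matrix must be symmetric")
        if np.linalg.eigvalsh(self.env_cov_matrix).min() <= -1e-10:
            raise ValueError("env_cov_matrix must be positive (semi)definite")
        if self.env_means is None:
            self.env_means = np.linspace(-0.5, 0.5, self.n_envs)
        self.env_means = np.asarray(self.env_means, dtype=float)
        if self.h2_per_env is None:
            base = np.array([0.25, 0.40, 0.50, 0.35])
            self.h2_per_env = np.resize(base, self.n_envs)
        self.h2_per_env = np.asarray(self.h2_per_env, dtype=float)
        if np.any(self.h2_per_env <= 0.0) or np.any(self.h2_per_env >= 1.0):
            raise ValueError("heritabilities must lie strictly in (0, 1)")
        n_plots = self.n_lines * self.n_reps
        if self.field_rows is None and self.field_cols is None:
            self.field_rows = int(math.ceil(math.sqrt(n_plots)))
            self.field_cols = int(math.ceil(n_plots / self.field_rows))
        elif self.field_rows is None or self.field_cols is None:
            known = self.field_rows or self.field_cols
            other = int(math.ceil(n_plots / known))
            if self.field_rows is None:
                self.field_rows = other
            else:
                self.field_cols = other
        if self.field_rows * self.field_cols < n_plots:
            raise ValueError("field layout too small for all plots")
        if not (0.0 <= self.missing_cell_fraction < 1.0):
            raise ValueError("missing_cell_fraction must lie in [0, 1)")

    @property
    def env_ids(self) -> np.ndarray:
        return np.array([f"E{j + 1}" for j in range(self.n_envs)])

    @property
    def line_ids(self) -> np.ndarray:
        width = len(str(self.n_lines))
        return np.array([f"L{str(i + 1).zfill(width)}" for i in range(self.n_lines)])

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-specific stream derived from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass
class TruthSet:
    """Ground truth of a simulated study, for parameter-recovery tests."""

    true_u: pd.DataFrame  # n_lines x J breeding values
    true_surface: pd.Series | None = None  # per-plot spatial effect
    true_variance_components: dict = field(default_factory=dict)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Independent biallelic SNP dosages for a fully inbred panel.

    Marker allele frequencies are drawn uniformly from ``cfg.maf_range``;
    each line carries dosage 2 with probability equal to the allele
    frequency, else 0 (no heterozygotes in an inbred panel).
    """
    rng = cfg.rng(1)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers)
    dosages = 2.0 * (rng.random((cfg.n_lines, cfg.n_markers)) < p)
    width = len(str(cfg.n_markers))
    marker_ids = np.array([f"M{str(j + 1).zfill(width)}" for j in range(cfg.n_markers)])
    return GenotypeMatrix(line_ids=cfg.line_ids, marker_ids=marker_ids, dosages=dosages)


_EC_PROFILES = [
    ("max_temp_C", 34.0, 1.1),
    ("min_temp_C", -2.5, 1.5),
    ("total_precip_mm", 700.0, 130.0),
]


def simulate_env_covariates(cfg: SimConfig, n_covs: int = 3) -> EnvCovariateTable:
    """Continuous environment covariates on weather-record scales.

    The first three covariates mimic seasonal maximum temperature (deg C),
    minimum temperature (deg C) and total precipitation (mm); any further
    covariates are standard normal.
    """
    if n_covs < 1:
        raise ValueError("n_covs must be >= 1")
    rng = cfg.rng(2)
    cols, names = [], []
    for q in range(n_covs):
        if q < len(_EC_PROFILES):
            name, mu, sd = _EC_PROFILES[q]
        else:
            name, mu, sd = f"ec_{q + 1}", 0.0, 1.0
        names.append(name)
        cols.append(rng.normal(mu, sd, size=cfg.n_envs))
    return EnvCovariateTable(
        env_ids=cfg.env_ids,
        covariate_names=np.array(names),
        values=np.column_stack(cols),
    )


def _psd_sqrt(A: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(np.asarray(A, dtype=float))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_breeding_values(
    K: GRM | np.ndarray,
    env_cov_matrix: np.ndarray,
    rng: np.random.Generator | int = 0,
    line_ids: np.ndarray | None = None,
    env_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Breeding values with vec(U) ~ N(0, E (x) K) (Kronecker covariance).

    Sampled as U = L_K Z L_E' with L_K L_K' = K and L_E L_E' = E, which has
    exactly the Kronecker covariance between environments and lines.
    """
    Kmat = K.K if isinstance(K, GRM) else np.asarray(K, dtype=float)
    if line_ids is None:
        line_ids = K.line_ids if isinstance(K, GRM) else np.arange(Kmat.shape[0])
    E = np.asarray(env_cov_matrix, dtype=float)
    if E.shape[0] != E.shape[1]:
        raise ValueError("env_cov_matrix must be square")
    if not np.allclose(E, E.T):
        raise ValueError("env_cov_matrix must be symmetric")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    Lk = _psd_sqrt(Kmat)
    Le = _psd_sqrt(E)
    Z = rng.standard_normal((Kmat.shape[0], E.shape[0]))
    U = Lk @ Z @ Le.T
    if env_ids is None:
        env_ids = [f"E{j + 1}" for j in range(E.shape[0])]
    return pd.DataFrame(U, index=line_ids, columns=env_ids)


def _smooth_surface(rows: np.ndarray, cols: np.ndarray, n_rows: int, n_cols: int,
                    amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth bivariate field trend: low-frequency sinusoids + a bilinear term.

    The surface lives inside the function space a PS-ANOVA decomposition can
    represent, so spatial adjustment is a fair recovery problem.
    """
    if amplitude == 0.0:
        return np.zeros(rows.shape[0])
    r = (rows - 1) / max(n_rows - 1, 1)
    c = (cols - 1) / max(n_cols - 1, 1)
    a = rng.normal(size=5)
    surf = (
        a[0] * np.sin(np.pi * r)
        + a[1] * np.cos(np.pi * c)
        + a[2] * np.sin(2 * np.pi * r) * np.sin(np.pi * c)
        + a[3] * (r - r.mean()) * (c - c.mean())
        + a[4] * np.cos(2 * np.pi * c)
    )
    sd = surf.std()
    if sd > 0:
        surf = surf * (amplitude / sd)
    return surf - surf.mean()


def simulate_field_trial(
    cfg: SimConfig,
    true_u: pd.DataFrame,
    trait: str = "trait",
    enforce_min_envs: bool = True,
) -> tuple[pd.DataFrame, TruthSet]:
    """Plot-level phenotypes on a replicated row-column layout.

    Phenotype = environment mean + breeding value + smooth spatial surface
    + replicate effect + Gaussian residual.  The residual variance is set
    from the per-environment heritability target so that, at the level of
    line means over replicates, var(g) / (var(g) + var(eps)/n_reps) equals
    the target (the spatial surface sits on top and is removable by
    adjustment).  A ``missing_cell_fraction`` of line x environment cells is
    then dropped; with ``enforce_min_envs`` no line ends up missing in two
    or more environments, mirroring the exclusion rule applied to real
    unbalanced panels.
    """
    n, J = true_u.shape
    if n != cfg.n_lines or J != cfg.n_envs:
        raise ValueError("true_u shape does not match configuration")
    rng = cfg.rng(3)
    n_plots_env = cfg.n_lines * cfg.n_reps
    if cfg.field_rows * cfg.field_cols < n_plots_env:
        raise ValueError("field layout too small for all plots")

    genetic_var = np.diag(cfg.env_cov_matrix).astype(float)
    resid_var = cfg.n_reps * genetic_var * (1.0 - cfg.h2_per_env) / cfg.h2_per_env

    # choose which cells are observed
    observed = np.ones((n, J), dtype=bool)
    n_target = int(round(cfg.missing_cell_fraction * n * J))
    if n_target > 0:
        if enforce_min_envs:
            if n_target > n:
                n_target = n  # at most one missing env per line
            lines = rng.choice(n, size=n_target, replace=False)
            envs = rng.integers(0, J, size=n_target)
            observed[lines, envs] = False
        else:
            flat = rng.choice(n * J, size=n_target, replace=False)
            observed[np.unravel_index(flat, (n, J))] = False

    records = []
    surfaces = []
    truth_var = {}
    grid_r, grid_c = np.meshgrid(
        np.arange(1, cfg.field_rows + 1), np.arange(1, cfg.field_cols + 1), indexing="ij"
    )
    positions = np.column_stack([grid_r.ravel(), grid_c.ravel()])

    for j, env in enumerate(true_u.columns):
        perm = rng.permutation(positions.shape[0])[:n_plots_env]
        pos = positions[perm]
        # replicate blocks: first n_lines plots = rep 1, next = rep 2, ...
        line_order = np.concatenate([rng.permutation(n) for _ in range(cfg.n_reps)])
        rep_ids = np.repeat(np.arange(1, cfg.n_reps + 1), n)
        rows, cols = pos[:, 0].astype(int), pos[:, 1].astype(int)
        surf = _smooth_surface(rows, cols, cfg.field_rows, cfg.field_cols,
                               cfg.spatial_amplitude, rng)
        rep_effects = rng.normal(0.0, cfg.rep_effect_sd, size=cfg.n_reps)
        eps = (rng.normal(0.0, math.sqrt(resid_var[j]), size=n_plots_env)
               if resid_var[j] > 0 else np.zeros(n_plots_env))
        u_env = true_u.iloc[:, j].to_numpy()
        y = (cfg.env_means[j] + u_env[line_order] + surf
             + rep_effects[rep_ids - 1] + eps)
        keep = observed[line_order, j]
        df = pd.DataFrame(
            {
                "env": env,
                "rep": rep_ids,
                "row": rows,
                "col": cols,
                "genotype": true_u.index.to_numpy()[line_order],
                trait: y,
            }
        )[keep]
        records.append(df)
        surfaces.append(pd.Series(surf[keep], index=df.index))
        truth_var[env] = {
            "genetic": genetic_var[j],
            "residual": resid_var[j],
            "rep_effect": cfg.rep_effect_sd ** 2,
            "spatial": cfg.spatial_amplitude ** 2,
        }

    plots = pd.concat(records, ignore_index=True)
    surface = pd.concat(surfaces, ignore_index=True)
    truth = TruthSet(true_u=true_u.copy(), true_surface=surface,
                     true_variance_components=truth_var)
    return plots, truth


def simulate_study(
    cfg: SimConfig, n_covs: int = 3, trait: str = "trait"
) -> dict:
    """Full synthetic study: genotypes, ECs, breeding values, field plots.

    Returns a dict with keys ``genotypes``, ``ec``, ``plots``, ``truth``.
    The GRM used to draw breeding values is computed from the simulated
    genotypes, so realized relationships and the generative covariance
    agree.
    """
    from menvgp.kernels import center_standardize, grm_vanraden

    geno = simulate_genotypes(cfg)
    ec = simulate_env_covariates(cfg, n_covs=n_covs)
    # markers can drift to fixation in a finite panel; the GRM needs spread
    poly = np.nanstd(geno.dosages, axis=0) > 0
    W = center_standardize(geno.dosages[:, poly])
    K = grm_vanraden(W, line_ids=geno.line_ids)
    true_u = simulate_breeding_values(
        K, cfg.env_cov_matrix, rng=cfg.rng(4), env_ids=cfg.env_ids
    )
    plots, truth = simulate_field_trial(cfg, true_u, trait=trait)
    return {"genotypes": geno, "ec": ec, "grm": K, "plots": plots, "truth": truth}
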