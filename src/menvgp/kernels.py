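"""Marker quality control, genomic and environmental kernels, kinship imputation.

The genomic relationship matrix follows VanRaden: K = WW'/p where W is the
column-centered, column-standardized dosage matrix and p the number of
markers.  The environment kernel Omega is built the same way from
environmental covariates (temperature, precipitation, ...), so that
environments with similar growing conditions are treated as similar in the
reaction-norm models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MISSING_TOL = 1e-12


@dataclass
class GenotypeMatrix:
    """Line x marker dosage matrix.

    Dosages are 0/1/2 copies of the alternate allele; missing calls are
    ``np.nan``.  Fully inbred panels only contain {0, 2}.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray  # float array, n_lines x n_markers, NaN = missing

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.line_ids) != n or len(self.marker_ids) != m:
            raise ValueError("ID lengths do not match dosage dimensions")
        if len(set(self.line_ids.tolist())) != n:
            raise ValueError("duplicate line IDs")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be in {0, 1, 2} or missing")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per marker, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def missing_rates(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)


@dataclass
class QCReport:
    n_removed_maf: int
    n_removed_missing: int
    n_removed_corr: int
    retained_marker_ids: np.ndarray

    @property
    def n_retained(self) -> int:
        return len(self.retained_marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["maf", "missing_rate", "correlation", "retained"],
                "count": [
                    self.n_removed_maf,
                    self.n_removed_missing,
                    self.n_removed_corr,
                    self.n_retained,
                ],
            }
        )


@dataclass
class GRM:
    """Genomic relationship matrix among lines (symmetric, PSD, centered)."""

    line_ids: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape != (len(self.line_ids),) * 2:
            raise ValueError("K shape does not match line IDs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.K, index=self.line_ids, columns=self.line_ids)


@dataclass
class EnvCovariateTable:
    """Environment x covariate table (e.g. seasonal temperature extremes, rainfall)."""

    env_ids: np.ndarray
    covariate_names: np.ndarray
    values: np.ndarray  # J x q

    def __post_init__(self) -> None:
        self.env_ids = np.asarray(self.env_ids)
        self.covariate_names = np.asarray(self.covariate_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.env_ids), len(self.covariate_names)):
            raise ValueError("value shape does not match IDs")
        if np.isnan(self.values).any():
            raise ValueError("environmental covariates may not be missing")
        if self.values.shape[1] < 1:
            raise ValueError("at least one covariate required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.env_ids, columns=self.covariate_names)


@dataclass
class EnvKernel:
    env_ids: np.ndarray
    Omega: np.ndarray

    def __post_init__(self) -> None:
        self.env_ids = np.asarray(self.env_ids)
        self.Omega = np.asarray(self.Omega, dtype=float)
        if self.Omega.shape != (len(self.env_ids),) * 2:
            raise ValueError("Omega shape does not match env IDs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Omega, index=self.env_ids, columns=self.env_ids)


@dataclass
class BLUETable:
    """Genotype x environment adjusted means with optional SEs and imputed flags."""

    values: pd.DataFrame  # index = genotype, columns = environment, NaN = unobserved
    se: pd.DataFrame | None = None
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )

    @property
    def genotypes(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def envs(self) -> np.ndarray:
        return self.values.columns.to_numpy()


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------

def qc_markers(
    G: GenotypeMatrix,
    maf_max_removed: float = 0.05,
    miss_max: float = 0.10,
    corr_max: float = 0.99,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers by minor allele frequency, missing rate and correlation.

    Rules are applied in sequence, with inclusive thresholds: markers with
    MAF <= ``maf_max_removed`` are removed, then markers with missing rate
    >= ``miss_max``, then a greedy left-to-right correlation prune drops
    the later marker of every remaining pair with |r| >= ``corr_max``
    (correlations computed on mean-imputed dosages).
    """
    maf = G.minor_allele_frequencies()
    keep_maf = maf > maf_max_removed
    n_removed_maf = int((~keep_maf).sum())

    miss = G.missing_rates()
    keep_miss = keep_maf & (miss < miss_max)
    n_removed_missing = int(keep_maf.sum() - keep_miss.sum())

    idx = np.flatnonzero(keep_miss)
    if idx.size == 0:
        raise ValueError("no markers retained after MAF/missing-rate filtering")

    X = G.dosages[:, idx].copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 0.0)
    corr = np.abs(np.nan_to_num(corr))

    kept: list[int] = []
    for j in range(idx.size):
        if kept and np.any(corr[j, kept] >= corr_max):
            continue
        kept.append(j)
    n_removed_corr = int(idx.size - len(kept))
    final = idx[np.array(kept, dtype=int)]
    if final.size == 0:
        raise ValueError("no markers retained after correlation pruning")

    out = GenotypeMatrix(
        line_ids=G.line_ids.copy(),
        marker_ids=G.marker_ids[final].copy(),
        dosages=G.dosages[:, final].copy(),
    )
    report = QCReport(
        n_removed_maf=n_removed_maf,
        n_removed_missing=n_removed_missing,
        n_removed_corr=n_removed_corr,
        retained_marker_ids=G.marker_ids[final].copy(),
    )
    logger.info(
        "marker QC: %d in, removed %d (MAF), %d (missing), %d (corr), %d retained",
        G.n_markers, n_removed_maf, n_removed_missing, n_removed_corr, final.size,
    )
    return out, report


def center_standardize(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Column-center and scale dosages to unit population SD.

    Residual missing values are mean-imputed per marker first.  Columns with
    zero variance raise — they should have been removed by QC.
    """
    X = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    X = X.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD (ddof=0)
    if np.any(sd <= _MISSING_TOL):
        bad = np.flatnonzero(sd <= _MISSING_TOL)
        raise ValueError(f"zero-variance marker columns at indices {bad[:10].tolist()}")
    return (X - mean) / sd


def grm_vanraden(W: np.ndarray, p: int | None = None,
                 line_ids: np.ndarray | None = None) -> GRM:
    """VanRaden genomic relationship matrix K = WW'/p from centered W."""
    W = np.asarray(W, dtype=float)
    if p is None:
        p = W.shape[1]
    if p == 0:
        raise ValueError("p must be positive")
    K = W @ W.T / p
    K = (K + K.T) / 2.0
    if line_ids is None:
        line_ids = np.arange(W.shape[0])
    return GRM(line_ids=line_ids, K=K)


def ec_kernel(ec: EnvCovariateTable) -> EnvKernel:
    """Environment similarity kernel Omega = CC'/q from standardized covariates."""
    if len(ec.env_ids) < 2:
        raise ValueError("need at least two environments")
    X = ec.values.astype(float)
    sd = X.std(axis=0)
    if np.any(sd <= _MISSING_TOL):
        bad = ec.covariate_names[sd <= _MISSING_TOL]
        raise ValueError(f"constant covariate columns: {bad.tolist()}")
    C = (X - X.mean(axis=0)) / sd
    Omega = C @ C.T / C.shape[1]
    Omega = (Omega + Omega.T) / 2.0
    return EnvKernel(env_ids=ec.env_ids.copy(), Omega=Omega)


# ---------------------------------------------------------------------------
# kinship-based phenotype imputation
# ---------------------------------------------------------------------------

def drop_sparse_lines(blues: BLUETable, max_missing_envs: int = 1) -> BLUETable:
    """Drop lines with missing records in more than ``max_missing_envs`` environments."""
    n_missing = blues.values.isna().sum(axis=1)
    keep = n_missing <= max_missing_envs
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d lines missing in >= %d environments",
                    n_drop, max_missing_envs + 1)
    return BLUETable(
        values=blues.values.loc[keep].copy(),
        se=None if blues.se is None else blues.se.loc[keep].copy(),
        imputed=blues.imputed.loc[keep].copy(),
    )


def impute_phenotypes_by_kin(blues: BLUETable, K: GRM, k: int = 20) -> BLUETable:
    """Fill missing adjusted means from the k most related observed lines.

    Lines missing in two or more environments are removed first.  A missing
    cell (line i, environment j) is replaced by the unweighted mean of the
    adjusted means, in environment j, of the ``k`` lines with the largest
    genomic relationship to line i among lines observed in j (the line
    itself excluded).  Ties in relationship are broken by line order in the
    table so the result is deterministic.
    """
    blues = drop_sparse_lines(blues, max_missing_envs=1)
    values = blues.values.copy()
    imputed = blues.imputed.copy()

    kin = K.to_frame()
    missing_from_K = values.index.difference(pd.Index(K.line_ids))
    if len(missing_from_K):
        raise ValueError(f"lines absent from GRM: {missing_from_K[:5].tolist()}")

    for env in values.columns:
        observed = values.index[values[env].notna()]
        for line in values.index[values[env].isna()]:
            candidates = observed.drop(line, errors="ignore")
            if len(candidates) == 0:
                raise ValueError(f"no observed neighbours for line {line} in {env}")
            sim = kin.loc[line, candidates].to_numpy(dtype=float)
            # stable sort on (-similarity, table order) breaks ties by line order
            order = np.argsort(-sim, kind="stable")
            chosen = candidates[order[:k]]
            if len(candidates) < k:
                warnings.warn(
                    f"only {len(candidates)} neighbours available for line {line} "
                    f"in {env} (requested {k})"
                )
            values.loc[line, env] = values.loc[chosen, env].mean()
            imputed.loc[line, env] = True

    return BLUETable(values=values, se=blues.se, imputed=imputed)
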