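"""PS-ANOVA P-spline spatial adjustment of row-column field trials.

Each environment is analysed with the mixed model

    y = 1*mu + Xs*bs + Zs*s + Zu*u + Zg*g + eps

where ``Xs*bs`` holds the unpenalized surface part (linear row, column and
row-by-column trends), ``Zs*s`` the penalized smooth surface split into
five blocks (row smooth, column smooth, two linear-by-smooth interactions
and a smooth-by-smooth tensor block), ``u`` random row and column effects
for discontinuous field variation, and ``g`` fixed genotype effects under
sum-to-zero contrasts.  Smooth blocks are cubic B-splines with second-order
difference penalties, reparameterized to i.i.d. random-effect form so each
block k carries one variance sigma2_sk with smoothing ratio
lambda_sk = sigma2_eps / sigma2_sk, estimated by REML with fixed-point
updates on effective dimensions.  The genotype BLUE for environment j is
the intercept plus the genotype effect; these adjusted means feed every
downstream prediction model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from menvgp.kernels import BLUETable, GRM, impute_phenotypes_by_kin

logger = logging.getLogger(__name__)

_VAR_FLOOR_REL = 1e-10


def _bspline_design(x: np.ndarray, n_seg: int, degree: int = 3) -> np.ndarray:
    """Equally spaced cubic B-spline design matrix (P-spline convention)."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("coordinate has no spread")
    dx = (hi - lo) / n_seg
    knots = lo + dx * np.arange(-degree, n_seg + degree + 1)
    B = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    return B


def _difference_reparam(B: np.ndarray, order: int = 2) -> np.ndarray:
    """Whiten a B-spline block against its difference penalty.

    With penalty P = D'D (D the ``order``-th differences), the columns of
    Z = B U+ diag(lam+^-1/2) carry i.i.d. random coefficients; the penalty
    null space (polynomials up to degree order-1) is dropped, being spanned
    by the fixed part of the PS-ANOVA decomposition.
    """
    K = B.shape[1]
    D = np.diff(np.eye(K), n=order, axis=0)
    P = D.T @ D
    lam, U = np.linalg.eigh(P)
    keep = lam > 1e-10 * lam.max()
    return B @ U[:, keep] / np.sqrt(lam[keep])


def _default_n_seg(coord: np.ndarray) -> int:
    """One knot per two plot positions, clipped to [5, 20] segments."""
    n_distinct = np.unique(coord).size
    return int(np.clip(n_distinct // 2, 5, 20))


def build_psanova_basis(
    rows: np.ndarray,
    cols: np.ndarray,
    n_knots_r: int | None = None,
    n_knots_c: int | None = None,
) -> dict:
    """Fixed part and the five penalized blocks of the PS-ANOVA surface.

    Returns a dict with ``fixed`` (columns 1, r, c, rc on centered
    unit-scaled coordinates) and ``blocks``, an ordered mapping of the five
    penalized design matrices: ``f_row``, ``f_col``, ``h_row_by_col``
    (row-smooth slope varying with column), ``h_col_by_row`` and the tensor
    block ``f_row_col``.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    for name, coord in (("rows", rows), ("cols", cols)):
        if np.unique(coord).size < 4:
            raise ValueError(f"need >= 4 distinct {name} coordinates")
    n_seg_r = _default_n_seg(rows) if n_knots_r is None else int(n_knots_r)
    n_seg_c = _default_n_seg(cols) if n_knots_c is None else int(n_knots_c)
    if n_seg_r > np.unique(rows).size or n_seg_c > np.unique(cols).size:
        raise ValueError("knot count exceeds number of distinct coordinates")

    def unit(x):
        return (x - x.min()) / (x.max() - x.min())

    r = unit(rows)
    c = unit(cols)
    rc_ = r - r.mean()
    cc_ = c - c.mean()
    fixed = np.column_stack([np.ones_like(r), rc_, cc_, rc_ * cc_])

    Zr = _difference_reparam(_bspline_design(r, n_seg_r))
    Zc = _difference_reparam(_bspline_design(c, n_seg_c))
    # row-wise Khatri-Rao product for the smooth-by-smooth tensor block
    Zrc = (Zr[:, :, None] * Zc[:, None, :]).reshape(len(r), -1)

    blocks = {
        "f_row": Zr,
        "f_col": Zc,
        "h_row_by_col": Zr * cc_[:, None],
        "h_col_by_row": Zc * rc_[:, None],
        "f_row_col": Zrc,
    }
    return {"fixed": fixed, "blocks": blocks, "n_seg": (n_seg_r, n_seg_c)}


@dataclass
class SpatialFit:
    """REML fit of the PS-ANOVA spatial model for one environment."""

    env: str
    genotypes: np.ndarray
    genotype_effects: pd.Series  # sum-to-zero effects, one per genotype
    intercept: float
    blues: pd.Series  # intercept + effect
    blue_se: pd.Series
    beta_surface: np.ndarray  # linear trend coefficients (r, c, rc)
    spline_coefs: dict
    row_effects: pd.Series
    col_effects: pd.Series
    varcomp: dict  # sigma2 per random block + "residual"
    lambdas: dict  # lambda_sk = sigma2_eps / sigma2_sk
    fitted: np.ndarray
    residuals: np.ndarray
    loglik_trace: list
    converged: bool
    n_iter: int

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else np.nan


def _genotype_design(genotype: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum-to-zero contrast design: G-1 columns, last level = -sum of others."""
    levels = np.unique(genotype)
    G = len(levels)
    idx = np.searchsorted(levels, genotype)
    X = np.zeros((len(genotype), G - 1))
    sel = idx < G - 1
    X[np.flatnonzero(sel), idx[sel]] = 1.0
    X[~sel, :] = -1.0
    return X, levels


def _factor_design(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, idx = np.unique(values, return_inverse=True)
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), idx] = 1.0
    return Z, levels


def _reml_loglik(y, X, Zs, sig2s, sig2e):
    n = len(y)
    V = sig2e * np.eye(n)
    for Z, s2 in zip(Zs, sig2s):
        if s2 > 0:
            V += s2 * (Z @ Z.T)
    cf = cho_factor(V, lower=True)
    logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
    Vi_y = cho_solve(cf, y)
    Vi_X = cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = y @ Vi_y - (X.T @ Vi_y) @ beta
    return -0.5 * (logdetV + logdetX + yPy)


def fit_spatial_model(
    plots: pd.DataFrame,
    trait: str = "trait",
    n_knots_r: int | None = None,
    n_knots_c: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    include_spatial: bool = True,
    include_rowcol: bool = True,
) -> SpatialFit:
    """REML fit of the spatial model for a single environment's plot table.

    Variance components are estimated with fixed-point updates on effective
    dimensions (solve the mixed-model equations at the current smoothing
    ratios, update each sigma2_sk from its coefficient norm and effective
    dimension, update sigma2_eps from the residual sum of squares), until
    successive REML log-likelihoods differ by less than ``tol``.  With
    ``include_spatial=False`` and ``include_rowcol=False`` the model reduces
    to a one-way fixed-effects analysis and genotype estimates are ordinary
    least-squares means.
    """
    required = {"env", "rep", "row", "col", "genotype", trait}
    missing = required - set(plots.columns)
    if missing:
        raise ValueError(f"plot table missing columns: {sorted(missing)}")
    envs = plots["env"].unique()
    if len(envs) != 1:
        raise ValueError("fit_spatial_model expects a single environment")
    env = str(envs[0])

    y = plots[trait].to_numpy(dtype=float)
    n = len(y)
    Xg, geno_levels = _genotype_design(plots["genotype"].to_numpy())
    block_names: list[str] = []
    Zs: list[np.ndarray] = []
    if include_spatial:
        basis = build_psanova_basis(
            plots["row"].to_numpy(), plots["col"].to_numpy(), n_knots_r, n_knots_c
        )
        X = np.column_stack([basis["fixed"], Xg])
        for name, Z in basis["blocks"].items():
            block_names.append(name)
            Zs.append(Z)
    else:
        X = np.column_stack([np.ones(n), Xg])
    if include_rowcol:
        Zrow, row_levels = _factor_design(plots["row"].to_numpy())
        Zcol, col_levels = _factor_design(plots["col"].to_numpy())
        block_names += ["row", "col"]
        Zs += [Zrow, Zcol]
    else:
        row_levels = col_levels = np.array([])

    p = X.shape[1]
    rank_X = np.linalg.matrix_rank(X)
    if rank_X < p:
        raise ValueError("singular genotype/fixed design (aliased genotypes?)")
    var_y = y.var() if y.var() > 0 else 1.0
    floor = _VAR_FLOOR_REL * var_y

    if not Zs:
        # pure fixed-effects model: ordinary least squares
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
        sig2e = resid @ resid / max(n - p, 1)
        C_inv = np.linalg.pinv(X.T @ X)
        return _assemble_fit(
            env, plots, trait, beta, {}, [], block_names, geno_levels,
            row_levels, col_levels, np.array([]), {}, sig2e, fitted, resid,
            [np.nan], True, 0, C_inv, include_spatial,
        )

    q_k = [Z.shape[1] for Z in Zs]
    Zall = np.hstack(Zs)
    q_tot = Zall.shape[1]
    offsets = np.cumsum([0] + q_k)

    XtX = X.T @ X
    XtZ = X.T @ Zall
    ZtZ = Zall.T @ Zall
    Xty = X.T @ y
    Zty = Zall.T @ y

    # equal-split initialization over blocks and residual
    n_blocks = len(Zs)
    sig2s = np.full(n_blocks, var_y / (2.0 * n_blocks))
    sig2e = var_y / 2.0

    loglik_trace: list[float] = []
    converged = False
    it = 0
    beta = np.zeros(p)
    u = np.zeros(q_tot)
    Cinv = None
    for it in range(1, max_iter + 1):
        lam = sig2e / np.maximum(sig2s, floor)
        C = np.block([[XtX, XtZ], [XtZ.T, ZtZ]])
        diag_pen = np.concatenate(
            [np.full(qk, lk) for qk, lk in zip(q_k, lam)]
        )
        C[p:, p:] += np.diag(diag_pen)
        rhs = np.concatenate([Xty, Zty])
        try:
            cf = cho_factor(C, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ValueError("mixed-model equations singular "
                             "(aliased genotypes or empty blocks)") from exc
        sol = cho_solve(cf, rhs)
        beta, u = sol[:p], sol[p:]
        Cinv = cho_solve(cf, np.eye(p + q_tot))

        eds = np.empty(n_blocks)
        for k in range(n_blocks):
            sl = slice(p + offsets[k], p + offsets[k + 1])
            tr = np.trace(Cinv[sl, sl])
            eds[k] = q_k[k] - lam[k] * tr
            uk = u[offsets[k]:offsets[k + 1]]
            if eds[k] > 1e-8:
                sig2s[k] = max(float(uk @ uk) / eds[k], floor)
            else:
                sig2s[k] = floor
        fitted = X @ beta + Zall @ u
        resid = y - fitted
        rss = float(resid @ resid)
        denom = n - rank_X - eds.sum()
        sig2e = max(rss / max(denom, 1.0), floor)

        ll = _reml_loglik(y, X, Zs, sig2s, sig2e)
        loglik_trace.append(ll)
        if sig2e <= floor * 10:
            converged = True  # noise-free data: nothing left to estimate
            break
        if it > 1 and abs(loglik_trace[-1] - loglik_trace[-2]) < tol:
            converged = True
            break
    if not converged:
        logger.warning("REML did not converge in %d iterations for env %s "
                       "(last delta %.3g)", max_iter, env,
                       abs(loglik_trace[-1] - loglik_trace[-2]))

    varcomp = {nm: float(s2) for nm, s2 in zip(block_names, sig2s)}
    lambdas = {nm: float(sig2e / max(s2, floor)) for nm, s2 in varcomp.items()
               if nm.startswith(("f_", "h_"))}
    return _assemble_fit(
        env, plots, trait, beta, varcomp, [u[offsets[k]:offsets[k + 1]] for k in range(n_blocks)],
        block_names, geno_levels, row_levels, col_levels, u, lambdas,
        sig2e, fitted, resid, loglik_trace, converged, it, Cinv, include_spatial,
    )


def _assemble_fit(env, plots, trait, beta, varcomp, u_blocks, block_names,
                  geno_levels, row_levels, col_levels, u, lambdas, sig2e,
                  fitted, resid, loglik_trace, converged, n_iter, Cinv,
                  include_spatial) -> SpatialFit:
    G = len(geno_levels)
    n_fixed_surface = 4 if include_spatial else 1
    intercept = float(beta[0])
    contrasts = beta[n_fixed_surface:n_fixed_surface + G - 1]
    effects = np.append(contrasts, -contrasts.sum())
    blues = intercept + effects

    # SEs of intercept + effect from the prediction-error covariance
    se = np.full(G, np.nan)
    if Cinv is not None:
        A = np.zeros((G, Cinv.shape[0]))
        A[:, 0] = 1.0
        for i in range(G - 1):
            A[i, n_fixed_surface + i] = 1.0
        A[G - 1, n_fixed_surface:n_fixed_surface + G - 1] = -1.0
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", A, Cinv * sig2e, A), 0.0))

    spline_coefs = {}
    row_eff = pd.Series(dtype=float)
    col_eff = pd.Series(dtype=float)
    for nm, ub in zip(block_names, u_blocks):
        if nm == "row":
            row_eff = pd.Series(ub, index=row_levels)
        elif nm == "col":
            col_eff = pd.Series(ub, index=col_levels)
        else:
            spline_coefs[nm] = ub
    varcomp = dict(varcomp)
    varcomp["residual"] = float(sig2e)

    return SpatialFit(
        env=env,
        genotypes=geno_levels,
        genotype_effects=pd.Series(effects, index=geno_levels),
        intercept=intercept,
        blues=pd.Series(blues, index=geno_levels, name=env),
        blue_se=pd.Series(se, index=geno_levels, name=env),
        beta_surface=beta[1:n_fixed_surface],
        spline_coefs=spline_coefs,
        row_effects=row_eff,
        col_effects=col_eff,
        varcomp=varcomp,
        lambdas=lambdas,
        fitted=fitted,
        residuals=resid,
        loglik_trace=loglik_trace,
        converged=converged,
        n_iter=n_iter,
    )


def extract_blues(
    fits: dict[str, SpatialFit] | list[SpatialFit],
    K: GRM | None = None,
    k_neighbours: int = 20,
    apply_exclusion: bool = True,
) -> BLUETable:
    """Assemble per-environment spatial fits into a genotype x environment table.

    If a genomic relationship matrix is supplied, lines missing in two or
    more environments are excluded and remaining missing cells are imputed
    from the ``k_neighbours`` most related observed lines
    (:func:`menvgp.kernels.impute_phenotypes_by_kin`).
    """
    if isinstance(fits, dict):
        fit_list = list(fits.values())
    else:
        fit_list = list(fits)
    values = pd.concat([f.blues for f in fit_list], axis=1)
    se = pd.concat([f.blue_se for f in fit_list], axis=1)
    table = BLUETable(values=values, se=se)
    if K is not None and apply_exclusion:
        table = impute_phenotypes_by_kin(table, K, k=k_neighbours)
    return table
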