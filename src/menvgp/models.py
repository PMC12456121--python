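"""Bayesian genomic-prediction models on a shared multi-kernel Gibbs engine.

Five models are provided, all fitted by Markov chain Monte Carlo with
scaled-inverse-chi-square priors on scalar variances and inverse-Wishart
priors on unstructured covariances:

* single-environment GBLUP: y = 1*mu + g + eps with g ~ N(0, K sigma2_g);
* the reaction-norm genotype-by-covariate (G x C) model, whose interaction
  covariances are Hadamard products of the genomic kernel with the
  same-environment indicator and with the environmental-covariate kernel
  Omega;
* the marker-by-environment (M x E) model in its GBLUP parameterization,
  decomposing genetic effects into an across-environment main component
  and environment-specific deviations (the equivalent ridge-regression
  parameterization is available in closed form for cross-checking);
* two multi-trait models treating each environment as a trait, with
  genetic covariance E (x) K (MTM1) and an extra line-level component
  F (x) I (MTM2).

Record vectors for multi-environment models are stacked environment-major
(all lines of environment 1, then environment 2, ...), so every covariance
used here is a Kronecker product of a small environment-side matrix and a
line-side matrix, which the engine exploits for fast effect updates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.stats import invwishart

logger = logging.getLogger(__name__)

_EIG_DROP = 1e-10
_MIN_EIG = -1e-6


@dataclass
class MCMCConfig:
    """Chain settings and priors for the Gibbs samplers.

    Defaults follow common practice for this model family: 20,000
    iterations, 8000 burn-in, thinning of five; scalar variances get
    scaled-inverse-chi-square priors with ``nu0`` degrees of freedom and
    scales chosen so the prior mode splits the sample phenotypic variance
    equally across model terms; unstructured J x J covariances get
    inverse-Wishart priors with J + 2 degrees of freedom and a diagonal
    scale, unless overridden.
    """

    n_iter: int = 20000
    burn_in: int = 8000
    thin: int = 5
    seed: int = 0
    nu0: float = 5.0
    scale0: dict | None = None  # per-term prior scale overrides
    iw_df: float | None = None  # default J + 2
    iw_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def replace(self, **kw) -> "MCMCConfig":
        return _dc_replace(self, **kw)


class KernelTerm:
    """One random term of a multi-kernel model.

    The covariance among the N records is either an explicit N x N matrix
    or a Kronecker product ``env_side (x) line_side`` (environment-major
    record order).  Eigendecompositions are computed once in
    :meth:`prepare` and may be shared between terms via the ``line_eig``
    argument, which is what makes repeated cross-validation fits cheap.
    """

    def __init__(self, label, kernel=None, env_side=None, line_side=None,
                 line_eig=None, env_eig=None):
        self.label = label
        self.kernel = None if kernel is None else np.asarray(kernel, dtype=float)
        self.env_side = None if env_side is None else np.asarray(env_side, dtype=float)
        self.line_side = None if line_side is None else np.asarray(line_side, dtype=float)
        if (self.kernel is None) == (self.line_side is None):
            raise ValueError("provide either kernel or env_side/line_side factors")
        self._line_eig = line_eig
        self._env_eig = env_eig
        self._prepared = False

    # -- eigen preparation -------------------------------------------------
    @staticmethod
    def _checked_eig(M, eig=None):
        if eig is None:
            d, V = np.linalg.eigh(M)
        else:
            V, d = eig
            d = np.asarray(d, float)
            V = np.asarray(V, float)
        top = max(d.max(), 1.0)
        if d.min() < _MIN_EIG * top:
            raise ValueError(f"kernel not PSD (min eigenvalue {d.min():.3g})")
        keep = d > _EIG_DROP * top
        return V[:, keep], np.clip(d[keep], 0.0, None)

    def prepare(self) -> "KernelTerm":
        if self._prepared:
            return self
        if self.kernel is not None:
            self._V, self._d = self._checked_eig(self.kernel)
            self.n_records = self.kernel.shape[0]
        else:
            self._VK, self._dK = self._checked_eig(self.line_side, self._line_eig)
            self._VA, self._dA = self._checked_eig(self.env_side, self._env_eig)
            self.n_records = self.line_side.shape[0] * self.env_side.shape[0]
            self._d = (self._dA[None, :] * self._dK[:, None]).ravel(order="F")
        self._prepared = True
        return self

    @property
    def coef_len(self) -> int:
        return len(self._d)

    @property
    def prior_d(self) -> np.ndarray:
        return self._d

    def diag_mean(self) -> float:
        if self.kernel is not None:
            return float(np.diag(self.kernel).mean())
        return float(np.diag(self.line_side).mean() * np.diag(self.env_side).mean())

    def full_kernel(self) -> np.ndarray:
        if self.kernel is not None:
            return self.kernel
        return np.kron(self.env_side, self.line_side)

    # -- fast products with the eigenbasis --------------------------------
    def project(self, e: np.ndarray) -> np.ndarray:
        """V' e for the record vector e."""
        if self.kernel is not None:
            return self._V.T @ e
        n = self.line_side.shape[0]
        J = self.env_side.shape[0]
        Emat = e.reshape(n, J, order="F")
        return (self._VK.T @ Emat @ self._VA).ravel(order="F")

    def expand(self, b: np.ndarray) -> np.ndarray:
        """V b back to the record scale."""
        if self.kernel is not None:
            return self._V @ b
        qK = self._VK.shape[1]
        qA = self._VA.shape[1]
        B = b.reshape(qK, qA, order="F")
        return (self._VK @ B @ self._VA.T).ravel(order="F")


@dataclass
class ModelFit:
    """Posterior summaries of one fitted model."""

    model: str
    varcomp_samples: dict  # label -> (S,) array, includes "residual"
    beta_samples: np.ndarray  # (S, p)
    effect_means: dict  # label -> (N,) posterior-mean effect on record scale
    fitted_mean: np.ndarray  # posterior mean of X beta + sum of effects
    record_frame: pd.DataFrame | None = None  # columns line, env per record
    missing_mask: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.varcomp_samples.values())))

    @property
    def varcomp_means(self) -> dict:
        return {k: float(np.mean(v)) for k, v in self.varcomp_samples.items()}

    @property
    def predicted(self) -> pd.Series | np.ndarray:
        """Posterior-mean predictions for records whose phenotype was masked."""
        if self.missing_mask is None or not self.missing_mask.any():
            return pd.Series(dtype=float)
        vals = self.fitted_mean[self.missing_mask]
        if self.record_frame is not None:
            idx = pd.MultiIndex.from_frame(self.record_frame[self.missing_mask]
                                           .reset_index(drop=True))
            return pd.Series(vals, index=idx)
        return vals


def _ess(x: np.ndarray) -> float:
    """Crude effective sample size from the lag-1 autocorrelation."""
    x = np.asarray(x, float)
    if len(x) < 3 or x.std() == 0:
        return float(len(x))
    r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
    r1 = min(max(r1, 0.0), 0.999)
    return float(len(x) * (1 - r1) / (1 + r1))


def gibbs_multikernel(
    y: np.ndarray,
    terms: list[KernelTerm],
    mcmc: MCMCConfig,
    X: np.ndarray | None = None,
    fixed_variances: dict | None = None,
    record_frame: pd.DataFrame | None = None,
    model_name: str = "multikernel",
) -> ModelFit:
    """Gibbs sampler for y = X beta + sum_k u_k + eps with u_k ~ N(0, sigma2_k K_k).

    Each effect vector is updated jointly from its multivariate-normal full
    conditional using the eigendecomposition of its kernel; scalar
    variances get scaled-inverse-chi-square updates; fixed effects have a
    flat prior; records with missing phenotype are treated by data
    augmentation, which leaves them without influence on the posterior and
    yields their predictive mean as a by-product.  Variances named in
    ``fixed_variances`` (term labels or ``"residual"``) are held fixed.
    """
    y = np.asarray(y, dtype=float)
    N = len(y)
    if not terms and X is None:
        X = np.ones((N, 1))
    if X is None:
        X = np.ones((N, 1))
    X = np.asarray(X, dtype=float)
    if X.shape[0] != N:
        raise ValueError("X rows must match y length")
    for t in terms:
        t.prepare()
        if t.n_records != N:
            raise ValueError(f"term {t.label}: {t.n_records} records, y has {N}")

    obs = ~np.isnan(y)
    if obs.sum() == 0:
        raise ValueError("no observed phenotypes")
    y_obs = y[obs]
    var_y = float(y_obs.var())
    if var_y <= 0:
        if terms:
            raise ValueError("degenerate phenotype vector (zero variance)")
        var_y = 1.0  # intercept-only model on constant data is still fine

    fixed_variances = fixed_variances or {}
    rng = np.random.default_rng(mcmc.seed)
    nu0 = mcmc.nu0
    n_terms = len(terms)
    share = var_y / (n_terms + 1)
    scale0 = dict(mcmc.scale0 or {})
    S_term = {}
    for t in terms:
        S_term[t.label] = scale0.get(
            t.label, share * (nu0 + 2) / nu0 / max(t.diag_mean(), 1e-12)
        )
    S_eps = scale0.get("residual", share * (nu0 + 2) / nu0)

    # state
    p = X.shape[1]
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    L_beta = np.linalg.cholesky(XtX_inv)
    beta = XtX_inv @ (X.T @ np.where(obs, y, np.nanmean(y_obs)))
    b = {t.label: np.zeros(t.coef_len) for t in terms}
    u = {t.label: np.zeros(N) for t in terms}
    sig2 = {t.label: fixed_variances.get(t.label, share / max(t.diag_mean(), 1e-12))
            for t in terms}
    sig2e = fixed_variances.get("residual", share)
    y_cur = y.copy()
    y_cur[~obs] = float(np.mean(y_obs))
    total = X @ beta + sum(u.values()) if terms else X @ beta

    S = mcmc.n_kept
    var_samps = {t.label: np.empty(S) for t in terms}
    var_samps["residual"] = np.empty(S)
    beta_samps = np.empty((S, p))
    eff_sum = {t.label: np.zeros(N) for t in terms}
    fitted_sum = np.zeros(N)
    s_idx = 0

    for it in range(1, mcmc.n_iter + 1):
        for t in terms:
            lbl = t.label
            e = y_cur - (total - u[lbl])
            r = t.project(e)
            d = t.prior_d
            prec = 1.0 / sig2e + 1.0 / (sig2[lbl] * d)
            mean = (r / sig2e) / prec
            b_new = mean + rng.standard_normal(len(d)) / np.sqrt(prec)
            b[lbl] = b_new
            u_new = t.expand(b_new)
            total += u_new - u[lbl]
            u[lbl] = u_new
            if lbl not in fixed_variances:
                ss = float(np.sum(b_new ** 2 / d))
                sig2[lbl] = (S_term[lbl] * nu0 + ss) / rng.chisquare(nu0 + len(d))
        # fixed effects (flat prior)
        e = y_cur - (total - X @ beta)
        beta_hat = XtX_inv @ (X.T @ e)
        beta_new = beta_hat + np.sqrt(sig2e) * (L_beta @ rng.standard_normal(p))
        total += X @ (beta_new - beta)
        beta = beta_new
        # residual variance
        resid = y_cur - total
        if "residual" not in fixed_variances:
            sig2e = (S_eps * nu0 + float(resid @ resid)) / rng.chisquare(nu0 + N)
        # data augmentation for masked records
        if (~obs).any():
            y_cur[~obs] = total[~obs] + np.sqrt(sig2e) * rng.standard_normal((~obs).sum())

        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            for t in terms:
                var_samps[t.label][s_idx] = sig2[t.label]
                eff_sum[t.label] += u[t.label]
            var_samps["residual"][s_idx] = sig2e
            beta_samps[s_idx] = beta
            fitted_sum += total
            s_idx += 1

    effect_means = {lbl: s / S for lbl, s in eff_sum.items()}
    fitted_mean = fitted_sum / S
    logger.debug("%s: ESS(residual) = %.0f of %d kept samples",
                 model_name, _ess(var_samps["residual"]), S)
    return ModelFit(
        model=model_name,
        varcomp_samples=var_samps,
        beta_samples=beta_samps,
        effect_means=effect_means,
        fitted_mean=fitted_mean,
        record_frame=record_frame,
        missing_mask=~obs,
    )


def blup_closed_form(
    y: np.ndarray,
    terms: list[KernelTerm],
    variances: dict,
    sigma2_e: float,
    X: np.ndarray | None = None,
) -> dict:
    """Exact mixed-model (Henderson) solution at known variance components.

    Serves as the independent oracle for the Gibbs engine: with the same
    variances held fixed, posterior-mean effects from the sampler converge
    to these BLUPs.  Records with missing ``y`` are excluded from the
    equations and predicted from the kernel cross-covariances.
    """
    y = np.asarray(y, dtype=float)
    N = len(y)
    obs = ~np.isnan(y)
    if X is None:
        X = np.ones((N, 1))
    X = np.asarray(X, dtype=float)
    kernels = {t.label: t.full_kernel() for t in terms}
    for lbl, s2 in variances.items():
        if lbl != "residual" and s2 <= 0:
            raise ValueError("variances must be positive")

    V = sigma2_e * np.eye(int(obs.sum()))
    for t in terms:
        V += variances[t.label] * kernels[t.label][np.ix_(obs, obs)]
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance system") from exc
    Xo = X[obs]
    XtViX = Xo.T @ Vi @ Xo
    beta = np.linalg.solve(XtViX, Xo.T @ Vi @ y[obs])
    r = Vi @ (y[obs] - Xo @ beta)
    effects = {}
    fitted = X @ beta
    for t in terms:
        u = variances[t.label] * kernels[t.label][:, obs] @ r
        effects[t.label] = u
        fitted = fitted + u
    return {"beta": beta, "effects": effects, "fitted": fitted}


# ---------------------------------------------------------------------------
# record stacking and model constructors
# ---------------------------------------------------------------------------

def _as_values(blues) -> pd.DataFrame:
    from menvgp.kernels import BLUETable

    if isinstance(blues, BLUETable):
        return blues.values
    return pd.DataFrame(blues)


def stack_records(values: pd.DataFrame, mask: pd.DataFrame | None = None):
    """Stack a genotype x environment table environment-major.

    Returns (y, record_frame); cells flagged in ``mask`` are set to NaN so
    the samplers treat them as prediction targets.
    """
    vals = values.copy()
    if mask is not None:
        vals = vals.mask(mask.reindex_like(vals).fillna(False).astype(bool))
    y = vals.to_numpy(dtype=float).ravel(order="F")
    lines = np.tile(values.index.to_numpy(), len(values.columns))
    envs = np.repeat(values.columns.to_numpy(), len(values.index))
    frame = pd.DataFrame({"line": lines, "env": envs})
    return y, frame


def _aligned_K(K, line_index: pd.Index) -> np.ndarray:
    from menvgp.kernels import GRM

    if isinstance(K, GRM):
        kf = K.to_frame()
        missing = line_index.difference(kf.index)
        if len(missing):
            raise ValueError(f"lines absent from GRM: {missing[:5].tolist()}")
        return kf.loc[line_index, line_index].to_numpy()
    return np.asarray(K, dtype=float)


def _aligned_Omega(Omega, env_index: pd.Index) -> np.ndarray:
    from menvgp.kernels import EnvKernel

    if isinstance(Omega, EnvKernel):
        of = Omega.to_frame()
        missing = env_index.difference(of.index)
        if len(missing):
            raise ValueError(f"environments absent from Omega: {missing.tolist()}")
        return of.loc[env_index, env_index].to_numpy()
    return np.asarray(Omega, dtype=float)


def build_gxc_terms(values: pd.DataFrame, K, Omega) -> list[KernelTerm]:
    """The five random terms of the reaction-norm G x C model.

    Genetic main effect (K in every environment pair), environment main
    effect, environmental-covariate effect (Omega between environments),
    and the two Hadamard interactions: genomic-by-same-environment
    (block-diagonal K) and genomic-by-covariate-similarity (Omega (x) K).
    """
    n, J = values.shape
    Kmat = _aligned_K(K, values.index)
    Om = _aligned_Omega(Omega, values.columns)
    ones_J = np.ones((J, J))
    ones_n = np.ones((n, n))
    dK, VK = np.linalg.eigh(Kmat)
    line_eig = (VK, dK)
    return [
        KernelTerm("g", env_side=ones_J, line_side=Kmat, line_eig=line_eig),
        KernelTerm("E", env_side=np.eye(J), line_side=ones_n),
        KernelTerm("w", env_side=Om, line_side=ones_n),
        KernelTerm("gE", env_side=np.eye(J), line_side=Kmat, line_eig=line_eig),
        KernelTerm("gw", env_side=Om, line_side=Kmat, line_eig=line_eig),
    ]


def build_mxe_terms(values: pd.DataFrame, K) -> list[KernelTerm]:
    """Main + environment-specific genetic terms of the M x E GBLUP model."""
    n, J = values.shape
    Kmat = _aligned_K(K, values.index)
    dK, VK = np.linalg.eigh(Kmat)
    line_eig = (VK, dK)
    terms = [KernelTerm("main", env_side=np.ones((J, J)), line_side=Kmat,
                        line_eig=line_eig)]
    for j, env in enumerate(values.columns):
        A = np.zeros((J, J))
        A[j, j] = 1.0
        terms.append(KernelTerm(f"specific_{env}", env_side=A, line_side=Kmat,
                                line_eig=line_eig))
    return terms


def fit_gblup_single_env(y: pd.Series, K, mcmc: MCMCConfig) -> ModelFit:
    """Single-environment GBLUP: y = 1 mu + g + eps, g ~ N(0, K sigma2_g).

    ``y`` is a line-indexed vector of adjusted means; NaN entries are
    prediction targets.  Genomic heritability samples
    sigma2_g / (sigma2_g + sigma2_eps) are stored in ``extras``.
    """
    y = pd.Series(y).astype(float)
    Kmat = _aligned_K(K, y.index)
    term = KernelTerm("g", kernel=Kmat)
    frame = pd.DataFrame({"line": y.index.to_numpy(),
                          "env": np.repeat("single", len(y))})
    fit = gibbs_multikernel(y.to_numpy(), [term], mcmc, record_frame=frame,
                            model_name="gblup")
    g = fit.varcomp_samples["g"]
    e = fit.varcomp_samples["residual"]
    fit.extras["h2_samples"] = g / (g + e)
    fit.extras["line_index"] = y.index
    return fit


def fit_gxc(blues, K, Omega, mcmc: MCMCConfig, mask: pd.DataFrame | None = None,
            terms: list[KernelTerm] | None = None) -> ModelFit:
    """Reaction-norm G x C model with Hadamard-product interaction kernels."""
    values = _as_values(blues)
    if terms is None:
        terms = build_gxc_terms(values, K, Omega)
    y, frame = stack_records(values, mask)
    return gibbs_multikernel(y, terms, mcmc, record_frame=frame, model_name="gxc")


def fit_mxe(blues, K, mcmc: MCMCConfig, parameterization: str = "gblup",
            mask: pd.DataFrame | None = None,
            terms: list[KernelTerm] | None = None) -> ModelFit:
    """Marker-by-environment model (GBLUP parameterization).

    Decomposes genetic effects into a main component shared by all
    environments and per-environment deviations, with per-environment
    intercepts.  The equivalent ridge-regression parameterization on
    marker effects is available in closed form via
    :func:`mxe_ridge_blup` and is used for cross-checking only.
    """
    if parameterization != "gblup":
        raise ValueError(
            "only the 'gblup' parameterization is fitted by MCMC; the ridge "
            "parameterization is available via mxe_ridge_blup for "
            "equivalence checks"
        )
    values = _as_values(blues)
    n, J = values.shape
    if J < 2:
        raise ValueError("the M x E model needs at least two environments")
    if terms is None:
        terms = build_mxe_terms(values, K)
    y, frame = stack_records(values, mask)
    X = np.kron(np.eye(J), np.ones((n, 1)))  # per-environment intercepts
    return gibbs_multikernel(y, terms, mcmc, X=X, record_frame=frame,
                             model_name="mxe")


def mxe_ridge_blup(
    y: np.ndarray,
    W: np.ndarray,
    env_idx: np.ndarray,
    sigma2_b0: float,
    sigma2_bj: np.ndarray | float,
    sigma2_e: float,
) -> dict:
    """Closed-form M x E ridge-regression BLUP on marker effects.

    Model: y_ij = mu_j + sum_k w_ijk (b0k + bjk) + eps with
    b0 ~ N(0, I sigma2_b0) common across environments and bj ~
    N(0, I sigma2_bj) environment-specific.  With K = WW'/p this is
    equivalent to the GBLUP parameterization at sigma2_u0 = p * sigma2_b0
    and sigma2_uj = p * sigma2_bj.  Records with missing y are excluded
    from the equations and predicted.
    """
    y = np.asarray(y, dtype=float)
    W = np.asarray(W, dtype=float)
    env_idx = np.asarray(env_idx)
    envs = np.unique(env_idx)
    J = len(envs)
    p = W.shape[1]
    sigma2_bj = np.broadcast_to(np.asarray(sigma2_bj, dtype=float), (J,))
    N = len(y)
    X = np.zeros((N, J))
    for j, env in enumerate(envs):
        X[env_idx == env, j] = 1.0
    Z_parts = [W]
    lam = [np.full(p, sigma2_e / sigma2_b0)]
    for j, env in enumerate(envs):
        Zj = np.zeros((N, p))
        sel = env_idx == env
        Zj[sel] = W[sel]
        Z_parts.append(Zj)
        lam.append(np.full(p, sigma2_e / sigma2_bj[j]))
    Z = np.hstack(Z_parts)
    lam = np.concatenate(lam)

    obs = ~np.isnan(y)
    Xo, Zo, yo = X[obs], Z[obs], y[obs]
    q = Z.shape[1]
    pj = X.shape[1]
    C = np.block([[Xo.T @ Xo, Xo.T @ Zo], [Zo.T @ Xo, Zo.T @ Zo + np.diag(lam)]])
    rhs = np.concatenate([Xo.T @ yo, Zo.T @ yo])
    sol = np.linalg.solve(C, rhs)
    mu, coef = sol[:pj], sol[pj:]
    fitted = X @ mu + Z @ coef
    return {"mu": mu, "b0": coef[:p],
            "b_specific": coef[p:].reshape(J, p),
            "fitted": fitted}


def fit_mtm(blues, K, mcmc: MCMCConfig, extra_component: bool = False,
            mask: pd.DataFrame | None = None, ridge: float = 1e-6) -> ModelFit:
    """Multi-trait model with Kronecker genetic covariance E (x) K.

    Each environment is a trait; the n x J genetic effect matrix U has
    vec covariance E (x) K with E unstructured (inverse-Wishart prior).
    With ``extra_component`` an additional line-level matrix F (x) I
    captures genetic variability not explained by markers (MTM2).  The
    sampler works in the eigenbasis of the ridge-stabilized K, so the
    per-line conditionals are independent J x J problems; masked cells are
    handled by data augmentation.
    """
    values = _as_values(blues)
    n, J = values.shape
    Kmat = _aligned_K(K, values.index) + ridge * np.eye(n)
    dK, VK = np.linalg.eigh(Kmat)
    if dK.min() <= 0:
        raise ValueError("K numerically singular even after ridge stabilization")

    vals = values.copy()
    if mask is not None:
        vals = vals.mask(mask.reindex_like(vals).fillna(False).astype(bool))
    Y = vals.to_numpy(dtype=float)
    obs = ~np.isnan(Y)
    if not obs.any():
        raise ValueError("no observed phenotypes")
    col_means = np.array([Y[obs[:, j], j].mean() if obs[:, j].any() else 0.0
                          for j in range(J)])
    var_obs = np.array([Y[obs[:, j], j].var() if obs[:, j].sum() > 1 else 1.0
                        for j in range(J)])
    var_obs = np.maximum(var_obs, 1e-12)

    rng = np.random.default_rng(mcmc.seed)
    nuE = mcmc.iw_df if mcmc.iw_df is not None else J + 2
    n_gen_terms = 2 if extra_component else 1
    share = var_obs / (n_gen_terms + 1)
    # scale chosen so the prior mean of the covariance is an equal share of
    # the per-environment phenotypic variance
    iw_mean_factor = max(nuE - J - 1, 0.5)
    S0E = (mcmc.iw_scale if mcmc.iw_scale is not None
           else np.diag(share) * iw_mean_factor)
    S0F = np.diag(share) * iw_mean_factor
    nu0 = mcmc.nu0
    S_eps = float(share.mean()) * (nu0 + 2) / nu0

    # state
    mu = col_means.copy()
    E = np.diag(share.copy())
    F = np.diag(share.copy())
    U = np.zeros((n, J))
    Phi = np.zeros((n, J))
    sig2e = float(share.mean())
    Ycur = np.where(obs, Y, col_means[None, :])

    S = mcmc.n_kept
    E_samps = np.empty((S, J, J))
    F_samps = np.empty((S, J, J)) if extra_component else None
    sig2e_samps = np.empty(S)
    mu_samps = np.empty((S, J))
    U_sum = np.zeros((n, J))
    Phi_sum = np.zeros((n, J))
    fitted_sum = np.zeros((n, J))
    s_idx = 0

    eyeJ = np.eye(J)
    for it in range(1, mcmc.n_iter + 1):
        # genetic matrix U | E, sig2e  (rows independent in K's eigenbasis)
        R = Ycur - mu[None, :] - Phi
        Rt = VK.T @ R
        Einv = np.linalg.inv(E)
        P = Einv[None, :, :] / dK[:, None, None] + eyeJ[None, :, :] / sig2e
        Sig = np.linalg.inv(P)
        mean = np.einsum("njk,nk->nj", Sig, Rt / sig2e)
        L = np.linalg.cholesky(Sig)
        Ut = mean + np.einsum("njk,nk->nj", L, rng.standard_normal((n, J)))
        U = VK @ Ut
        # E | U
        scaleE = S0E + Ut.T @ (Ut / dK[:, None])
        scaleE = (scaleE + scaleE.T) / 2.0
        E = invwishart.rvs(df=nuE + n, scale=scaleE, random_state=rng)
        E = np.atleast_2d(E)
        if extra_component:
            R2 = Ycur - mu[None, :] - U
            Finv = np.linalg.inv(F)
            SigF = np.linalg.inv(Finv + eyeJ / sig2e)
            meanF = (R2 / sig2e) @ SigF.T
            LF = np.linalg.cholesky(SigF)
            Phi = meanF + rng.standard_normal((n, J)) @ LF.T
            scaleF = S0F + Phi.T @ Phi
            scaleF = (scaleF + scaleF.T) / 2.0
            F = np.atleast_2d(invwishart.rvs(df=nuE + n, scale=scaleF,
                                             random_state=rng))
        # per-environment means (flat prior)
        resid_mu = Ycur - U - Phi
        mu = resid_mu.mean(axis=0) + np.sqrt(sig2e / n) * rng.standard_normal(J)
        # residual variance
        fitted = mu[None, :] + U + Phi
        resid = Ycur - fitted
        sig2e = (S_eps * nu0 + float((resid ** 2).sum())) / rng.chisquare(nu0 + n * J)
        # data augmentation for masked cells
        if (~obs).any():
            Ycur[~obs] = fitted[~obs] + np.sqrt(sig2e) * rng.standard_normal((~obs).sum())

        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            E_samps[s_idx] = E
            if extra_component:
                F_samps[s_idx] = F
            sig2e_samps[s_idx] = sig2e
            mu_samps[s_idx] = mu
            U_sum += U
            Phi_sum += Phi
            fitted_sum += fitted
            s_idx += 1

    U_mean = U_sum / S
    fitted_mean = fitted_sum / S
    y_flat = Y.ravel(order="F")
    frame = pd.DataFrame({
        "line": np.tile(values.index.to_numpy(), J),
        "env": np.repeat(values.columns.to_numpy(), n),
    })
    varcomp = {"residual": sig2e_samps}
    for j, env in enumerate(values.columns):
        varcomp[f"genetic_{env}"] = E_samps[:, j, j]
        if extra_component:
            varcomp[f"extra_{env}"] = F_samps[:, j, j]
    fit = ModelFit(
        model="mtm2" if extra_component else "mtm1",
        varcomp_samples=varcomp,
        beta_samples=mu_samps,
        effect_means={"u": U_mean.ravel(order="F"),
                      "f": (Phi_sum / S).ravel(order="F")},
        fitted_mean=fitted_mean.ravel(order="F"),
        record_frame=frame,
        missing_mask=np.isnan(y_flat),
    )
    fit.extras["E_samples"] = E_samps
    if extra_component:
        fit.extras["F_samples"] = F_samps
    fit.extras["env_index"] = values.columns
    fit.extras["line_index"] = values.index
    fit.extras["U_mean"] = pd.DataFrame(U_mean, index=values.index,
                                        columns=values.columns)
    h2 = E_samps[:, np.arange(J), np.arange(J)] / (
        E_samps[:, np.arange(J), np.arange(J)] + sig2e_samps[:, None])
    fit.extras["h2_samples"] = pd.DataFrame(h2, columns=values.columns)
    logger.debug("%s: ESS(residual) = %.0f of %d kept samples",
                 fit.model, _ess(sig2e_samps), S)
    return fit


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def heritability(fit: ModelFit):
    """Per-environment genomic heritability sigma2_g / (sigma2_g + sigma2_eps).

    Computed per posterior sample, then averaged.  Returns a float for a
    single-environment fit, a Series per environment for multi-trait fits.
    """
    h2 = fit.extras.get("h2_samples")
    if h2 is not None:
        if isinstance(h2, pd.DataFrame):
            return h2.mean(axis=0)
        return float(np.mean(h2))
    if "g" in fit.varcomp_samples:
        g = fit.varcomp_samples["g"]
        e = fit.varcomp_samples["residual"]
        return float(np.mean(g / (g + e)))
    raise ValueError("fit does not expose genetic and residual variances")


def genetic_correlations(fit: ModelFit) -> pd.DataFrame:
    """Posterior-mean between-environment genetic correlation matrix.

    r_jk = E_jk / sqrt(E_jj E_kk) per posterior sample, averaged; draws
    with non-positive diagonal are excluded (with a logged count); the
    diagonal is exactly 1.
    """
    E_samps = fit.extras.get("E_samples")
    if E_samps is None:
        raise ValueError("genetic correlations require a multi-trait fit")
    diag = np.einsum("sjj->sj", E_samps)
    ok = (diag > 0).all(axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("excluding %d posterior draws with non-positive "
                       "genetic variance", n_bad)
    Es = E_samps[ok]
    sd = np.sqrt(np.einsum("sjj->sj", Es))
    corr = Es / (sd[:, :, None] * sd[:, None, :])
    mean_corr = corr.mean(axis=0)
    np.fill_diagonal(mean_corr, 1.0)
    envs = fit.extras.get("env_index")
    return pd.DataFrame(mean_corr, index=envs, columns=envs)


def variance_proportions(fit: ModelFit) -> pd.Series:
    """Share of the total modelled variance attributed to each component.

    Posterior-mean variances divided by their sum (residual included).
    For the M x E model the per-environment specific variances are
    averaged into a single "specific" share; for multi-trait fits the
    per-environment genetic variances are likewise averaged.
    """
    means = fit.varcomp_means
    out: dict[str, float] = {}
    if fit.model == "mxe":
        spec = [v for k, v in means.items() if k.startswith("specific_")]
        out["main"] = means["main"]
        out["specific"] = float(np.mean(spec))
        out["residual"] = means["residual"]
    elif fit.model in ("mtm1", "mtm2"):
        gen = [v for k, v in means.items() if k.startswith("genetic_")]
        out["genetic"] = float(np.mean(gen))
        if fit.model == "mtm2":
            extra = [v for k, v in means.items() if k.startswith("extra_")]
            out["extra_genetic"] = float(np.mean(extra))
        out["residual"] = means["residual"]
    else:
        out.update(means)
    s = pd.Series(out, dtype=float)
    return s / s.sum()
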