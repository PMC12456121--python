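"""Cross-validation designs and predictive-ability evaluation.

Three schemes mirror how breeders deploy genomic prediction:

* ``single_env`` — repeated random 80/20 subsampling of lines within each
  environment, evaluated with single-environment GBLUP;
* ``cv1`` — test lines are hidden in *every* environment (newly developed
  lines with no phenotypes anywhere);
* ``cv2`` — the same test lines keep at least one observed environment and
  are hidden in a random nonempty proper subset of the rest (sparse
  testing).

Predictive ability is the Pearson correlation between predicted and
held-out adjusted means, computed per environment and aggregated over
replicates.  Paired one-sided Wilcoxon signed-rank and t tests compare a
candidate model against a baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from menvgp.models import (
    MCMCConfig,
    build_gxc_terms,
    build_mxe_terms,
    fit_gblup_single_env,
    fit_gxc,
    fit_mtm,
    fit_mxe,
)

logger = logging.getLogger(__name__)

SCHEMES = ("single_env", "cv1", "cv2")
MULTI_ENV_MODELS = ("gxc", "mxe", "mtm1", "mtm2")


@dataclass
class CVPlan:
    """One replicate of a cross-validation masking pattern."""

    scheme: str
    replicate: int
    masked_lines: np.ndarray  # the 20% test lines
    masked_cells: list  # list of (line, env) tuples actually hidden
    seed: int

    def mask_frame(self, values: pd.DataFrame) -> pd.DataFrame:
        mask = pd.DataFrame(False, index=values.index, columns=values.columns)
        for line, env in self.masked_cells:
            mask.loc[line, env] = True
        return mask


@dataclass
class CVResult:
    """Per-environment predictive abilities across replicates."""

    records: pd.DataFrame  # columns: scheme, model, env, replicate, r

    def summary(self) -> pd.DataFrame:
        return (self.records.groupby(["scheme", "model", "env"])["r"]
                .agg(["mean", "std", "count"]).reset_index())

    def mean_by_model(self) -> pd.Series:
        return self.records.groupby(["scheme", "model"])["r"].mean()


def make_cv_plans(
    lines,
    envs,
    scheme: str,
    n_reps: int = 100,
    frac_test: float = 0.2,
    seed: int = 0,
    observed: pd.DataFrame | None = None,
) -> list[CVPlan]:
    """Reproducible masking plans for one scheme.

    ``single_env`` and ``cv1`` mask floor(frac_test * n) lines per
    replicate in every environment; ``cv2`` masks the same line set but
    hides each test line only in a uniformly chosen nonempty proper subset
    of its observed environments.  ``observed`` (line x env boolean) limits
    maskable cells; by default every cell is observed.
    """
    if not 0.0 < frac_test < 1.0:
        raise ValueError("frac_test must lie in (0, 1)")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    lines = np.asarray(lines)
    envs = np.asarray(envs)
    n_test = int(np.floor(frac_test * len(lines)))
    if n_test < 1:
        raise ValueError("test set is empty; increase n lines or frac_test")
    if observed is None:
        observed = pd.DataFrame(True, index=lines, columns=envs)

    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(1, n_reps + 1):
        test_lines = rng.choice(lines, size=n_test, replace=False)
        cells = []
        if scheme in ("single_env", "cv1"):
            for line in test_lines:
                for env in envs:
                    if observed.loc[line, env]:
                        cells.append((line, env))
        else:  # cv2: nonempty proper subset of the line's observed envs
            for line in test_lines:
                obs_envs = [e for e in envs if observed.loc[line, e]]
                if len(obs_envs) < 2:
                    continue  # cannot hide anything while keeping one observed
                size = int(rng.integers(1, len(obs_envs)))
                hidden = rng.choice(obs_envs, size=size, replace=False)
                cells.extend((line, env) for env in hidden)
        plans.append(CVPlan(scheme=scheme, replicate=rep,
                            masked_lines=test_lines, masked_cells=cells,
                            seed=seed))
    return plans


def predictive_ability(observed: pd.Series, predicted: pd.Series,
                       min_pairs: int = 3) -> float:
    """Pearson correlation between held-out observations and predictions."""
    common = observed.index.intersection(predicted.index)
    if len(common) < min_pairs:
        warnings.warn(f"fewer than {min_pairs} test observations; "
                      "predictive ability recorded as missing")
        return np.nan
    o = observed.loc[common].to_numpy(dtype=float)
    p = predicted.loc[common].to_numpy(dtype=float)
    if o.std() == 0 or p.std() == 0:
        return np.nan
    return float(np.corrcoef(o, p)[0, 1])


def _fit_multi_env(model: str, values, K, Omega, mcmc, mask, term_cache):
    if model == "gxc":
        if Omega is None:
            raise ValueError("the G x C model needs an environment kernel")
        terms = term_cache.setdefault("gxc", build_gxc_terms(values, K, Omega))
        return fit_gxc(values, K, Omega, mcmc, mask=mask, terms=terms)
    if model == "mxe":
        terms = term_cache.setdefault("mxe", build_mxe_terms(values, K))
        return fit_mxe(values, K, mcmc, mask=mask, terms=terms)
    if model == "mtm1":
        return fit_mtm(values, K, mcmc, extra_component=False, mask=mask)
    if model == "mtm2":
        return fit_mtm(values, K, mcmc, extra_component=True, mask=mask)
    raise ValueError(f"unknown model {model!r}")


def run_cv(
    blues,
    K,
    models,
    plans: list[CVPlan],
    mcmc: MCMCConfig,
    Omega=None,
) -> CVResult:
    """Fit models under each plan's masking and score held-out predictions.

    For the ``single_env`` scheme each environment is analysed separately
    with single-environment GBLUP (``models`` is ignored); for ``cv1`` and
    ``cv2`` every requested multi-environment model is fitted to the
    masked record stack and masked cells are predicted.  Pearson r is
    computed per environment over that environment's masked cells;
    environments with fewer than three test observations are recorded as
    missing.  Kernel eigendecompositions are shared across replicates.
    """
    from menvgp.kernels import BLUETable

    values = blues.values if isinstance(blues, BLUETable) else pd.DataFrame(blues)
    rows = []
    term_cache: dict = {}
    for plan in plans:
        chain_seed = (mcmc.seed + 7919 * plan.replicate) % (2 ** 31)
        mcmc_rep = mcmc.replace(seed=chain_seed)
        if plan.scheme == "single_env":
            for env in values.columns:
                y = values[env].copy()
                test = [l for (l, e) in plan.masked_cells if e == env]
                y_masked = y.copy()
                y_masked.loc[test] = np.nan
                fit = fit_gblup_single_env(y_masked, K, mcmc_rep)
                pred = pd.Series(fit.fitted_mean, index=y.index).loc[test]
                r = predictive_ability(y.loc[test].dropna(), pred)
                rows.append((plan.scheme, "gblup", env, plan.replicate, r))
        else:
            mask = plan.mask_frame(values)
            mask &= values.notna()  # can only hold out observed cells
            for model in models:
                fit = _fit_multi_env(model, values, K, Omega, mcmc_rep, mask,
                                     term_cache)
                pred = fit.predicted
                for env in values.columns:
                    test_lines = mask.index[mask[env]]
                    obs_held = values.loc[test_lines, env].dropna()
                    try:
                        pred_env = pred.xs(env, level="env")
                    except KeyError:
                        pred_env = pd.Series(dtype=float)
                    r = predictive_ability(obs_held, pred_env)
                    rows.append((plan.scheme, model, env, plan.replicate, r))
    records = pd.DataFrame(rows, columns=["scheme", "model", "env",
                                          "replicate", "r"])
    return CVResult(records=records)


def compare_models(
    pa_baseline: np.ndarray | pd.Series,
    pa_candidate: np.ndarray | pd.Series,
) -> dict:
    """Paired one-sided tests of candidate improvement over a baseline.

    Vectors are paired by environment x replicate.  Returns one-sided
    p-values (alternative: candidate > baseline) from the Wilcoxon
    signed-rank test (exact null for <= 25 pairs, normal approximation
    with continuity correction otherwise; zero differences dropped) and
    the paired t test, plus the mean and percent improvement.
    """
    b = np.asarray(pa_baseline, dtype=float)
    c = np.asarray(pa_candidate, dtype=float)
    if b.shape != c.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(b) | np.isnan(c))
    b, c = b[keep], c[keep]
    d = c - b
    out = {
        "n_pairs": int(len(d)),
        "mean_improvement": float(d.mean()),
        "percent_improvement": (float((c.mean() - b.mean()) / abs(b.mean()) * 100)
                                if b.mean() != 0 else np.nan),
        "degenerate": False,
    }
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        out.update({"wilcoxon_p": 1.0, "ttest_p": 1.0, "degenerate": True})
        return out
    method = "exact" if len(nonzero) <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wstat, wp = stats.wilcoxon(d, alternative="greater",
                                   zero_method="wilcox", correction=True,
                                   method=method)
    out["wilcoxon_stat"] = float(wstat)
    out["wilcoxon_p"] = float(wp)
    if np.std(d) == 0:
        out["ttest_p"] = 0.0 if d.mean() > 0 else 1.0
        out["degenerate"] = True
    else:
        t = stats.ttest_rel(c, b, alternative="greater")
        out["ttest_stat"] = float(t.statistic)
        out["ttest_p"] = float(t.pvalue)
    return out
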