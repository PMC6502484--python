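"""CV1/CV2 cross-validation, predictive ability and the Fisher-Z ANOVA.

CV1 validates accessions with no phenotype anywhere; CV2 additionally gives
the model the validation accessions' records in helper environments, so
information can flow to the target environment through the genetic
correlations.  Predictive ability is the Pearson correlation between GEBVs
and observed adjusted phenotypes in the validation fold of the target
environment.  Replicate-level comparisons are made on the Fisher
Z = arctanh(r) scale with a fixed-effects ANOVA (sequential Type-I sums of
squares).

Marker sets are either a fixed LD-pruned subset or re-selected inside every
replicate from a GWAS on the training fold only, which keeps the selection
free of validation-set leakage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ConfigError, DataError
from .genio import GenotypeMatrix, LocusStats
from .gwaselect import grm, mlm_gwas, select_top_k, structure_covariates
from .kernelmodels import (
    KernelSpec,
    build_kernel,
    fit_gblup,
    fit_gxe_rkhs,
    fit_kron_multitrait,
    fit_mxe_gblup,
    fit_rkhs,
    predict,
)
from .ldprune import prune_by_ld

logger = logging.getLogger(__name__)

SINGLE_ENV_MODELS = ("gblup", "rkhs")
MULTI_ENV_MODELS = ("mxe_gblup", "gxe_rkhs", "kron_multitrait")


@dataclass
class CvPlan:
    """Reusable train/validation partitions (the same plan can be applied to
    every trait and model so comparisons share their partitions)."""

    partitions: list  # list of (train_ids, validation_ids)
    train_frac: float
    n_reps: int
    seed: int


@dataclass
class CvScenario:
    """One cross-validation experiment.

    ``scheme`` CV1 or CV2; under CV2 the helper-environment records of the
    validation accessions are appended to the training data.  ``marker_mode``
    is ``ld_derived`` (fixed LD-pruned subset, thresholds ``ld_r2_max`` /
    ``ld_min_maf``) or ``gwas_derived`` (top-``top_k`` markers re-selected per
    replicate from a training-fold GWAS).
    """

    scheme: str = "CV1"
    target_env: str = "E1"
    helper_envs: list = field(default_factory=list)
    marker_mode: str = "ld_derived"
    top_k: int = 28091
    model: str = "gblup"
    ld_r2_max: float = 0.5
    ld_min_maf: float = 0.05
    k_subpops: int = 5
    iters: int = 25000
    burnin: int = 5000

    def validate(self):
        if self.scheme not in ("CV1", "CV2"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.marker_mode not in ("ld_derived", "gwas_derived"):
            raise ConfigError(f"unknown marker_mode {self.marker_mode!r}")
        if self.model not in SINGLE_ENV_MODELS + MULTI_ENV_MODELS:
            raise ConfigError(f"unknown model {self.model!r}")
        if self.target_env in self.helper_envs:
            raise ConfigError("target_env cannot be one of helper_envs")


@dataclass
class PaResult:
    """Per-replicate predictive abilities and their summary."""

    table: pd.DataFrame  # replicate, env, r
    summary: pd.DataFrame  # env, n_reps, mean_r, se_r, mean_r_ztransformed


def make_partitions(ids, train_frac: float = 0.8, n_reps: int = 100, seed: int = 0) -> CvPlan:
    """Random 80/20-style partitions, reproducible under ``seed``.

    Replicate-level randomness derives from (seed, replicate index), so a plan
    regenerated with the same arguments is identical.
    """
    ids = list(ids)
    n = len(ids)
    if n < 5:
        raise DataError("need at least 5 accessions to partition")
    if not 0.0 < train_frac < 1.0:
        raise ConfigError("train_frac must be in (0, 1)")
    if n_reps <= 0:
        raise ConfigError("n_reps must be positive")
    n_train = int(round(train_frac * n))
    partitions = []
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        perm = rng.permutation(n)
        train = [ids[i] for i in perm[:n_train]]
        valid = [ids[i] for i in perm[n_train:]]
        partitions.append((train, valid))
    return CvPlan(partitions=partitions, train_frac=train_frac, n_reps=n_reps, seed=seed)


def predictive_ability(pred, obs) -> float:
    """Sample Pearson correlation between predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise DataError("pred and obs must have equal length")
    if len(pred) < 3:
        raise DataError("predictive ability needs >= 3 pairs")
    if np.std(pred) == 0 or np.std(obs) == 0:
        warnings.warn("zero variance in predictions or observations", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


def fisher_z(r: float) -> float:
    """Z = 0.5 ln[(1 + r) / (1 - r)] = arctanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse of the Fisher transform: tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def _select_markers_gwas(g, premiss, y_train, scenario):
    K = grm(g, centering="vanraden")
    Q = structure_covariates(g, k_subpops=scenario.k_subpops)
    res = mlm_gwas(y_train, g, K, Q)
    k = min(scenario.top_k, g.n_loci)
    return select_top_k(res, k)


def _fit_and_predict(scenario, g_sel, train_records, valid_ids, seed):
    """Fit the scenario's model on assembled training records and predict the
    validation accessions in the target environment."""
    target = scenario.target_env
    targets = [(a, target) for a in valid_ids]
    if scenario.model in SINGLE_ENV_MODELS:
        y = train_records.loc[train_records["env"] == target]
        y = pd.Series(y["value"].to_numpy(), index=y["accession"].to_numpy())
        if scenario.model == "gblup":
            K = build_kernel(g_sel, KernelSpec(kind="linear_grm"))
            fit = fit_gblup(y, K, env=target)
        else:
            Kg = build_kernel(g_sel, KernelSpec(kind="gaussian"))
            fit = fit_rkhs(y, Kg, env=target)
        return predict(fit, targets)
    if scenario.model == "mxe_gblup":
        K = build_kernel(g_sel, KernelSpec(kind="linear_grm"))
        fit = fit_mxe_gblup(train_records, K, iters=scenario.iters,
                            burnin=scenario.burnin, seed=seed)
    elif scenario.model == "gxe_rkhs":
        Kg = build_kernel(g_sel, KernelSpec(kind="gaussian"))
        fit = fit_gxe_rkhs(train_records, Kg, iters=scenario.iters,
                           burnin=scenario.burnin, seed=seed)
    else:  # kron_multitrait
        K = build_kernel(g_sel, KernelSpec(kind="linear_grm"))
        envs = [target] + list(scenario.helper_envs)
        Y = train_records.pivot(index="accession", columns="env", values="value")
        Y = Y.reindex(columns=envs)
        extra = [a for a in valid_ids if a not in Y.index]
        if extra:
            Y = pd.concat([Y, pd.DataFrame(index=extra, columns=envs, dtype=float)])
        fit = fit_kron_multitrait(Y, K, iters=scenario.iters,
                                  burnin=scenario.burnin, seed=seed)
    return predict(fit, targets)


def run_cv(
    scenario: CvScenario,
    plan: CvPlan,
    y_adj: dict,
    g: GenotypeMatrix,
    premiss: LocusStats | None = None,
) -> PaResult:
    """Run a cross-validation scenario over every replicate of the plan.

    ``y_adj`` maps environment label → Series of adjusted means indexed by
    accession.  Training data per replicate are the training accessions'
    records in the target and helper environments, plus — under CV2 — the
    helper-environment records of the validation accessions.  Predictive
    ability is computed per replicate over the validation accessions observed
    in the target environment.
    """
    scenario.validate()
    target = scenario.target_env
    if target not in y_adj:
        raise DataError(f"no adjusted phenotypes for target env {target!r}")
    for h in scenario.helper_envs:
        if h not in y_adj:
            raise DataError(f"no adjusted phenotypes for helper env {h!r}")
    envs_used = [target] + list(scenario.helper_envs)

    if scenario.marker_mode == "ld_derived":
        if premiss is None:
            from .genio import locus_stats
            premiss = locus_stats(g)
        pr = prune_by_ld(g, r2_max=scenario.ld_r2_max, min_maf=scenario.ld_min_maf,
                         premiss=premiss, seed=plan.seed)
        g_fixed = g.subset_loci_by_id(pr.kept_locus_ids)
    else:
        g_fixed = None
        if premiss is None:
            from .genio import locus_stats
            premiss = locus_stats(g)

    rows = []
    for rep, (train_ids, valid_ids) in enumerate(plan.partitions):
        obs_valid = [a for a in valid_ids if a in y_adj[target].index]
        if len(obs_valid) < 3:
            warnings.warn(f"replicate {rep}: fewer than 3 phenotyped validation "
                          "accessions; skipped", stacklevel=2)
            continue

        # assemble training records (no validation phenotype from any env in CV1)
        recs = []
        for env in envs_used:
            s = y_adj[env]
            tr = [a for a in train_ids if a in s.index]
            recs.append(pd.DataFrame({"accession": tr, "env": env,
                                      "value": s.loc[tr].to_numpy()}))
        if scenario.scheme == "CV2":
            for env in scenario.helper_envs:
                s = y_adj[env]
                va = [a for a in valid_ids if a in s.index]
                recs.append(pd.DataFrame({"accession": va, "env": env,
                                          "value": s.loc[va].to_numpy()}))
        train_records = pd.concat(recs, ignore_index=True)

        if scenario.marker_mode == "gwas_derived":
            s = y_adj[target]
            tr = [a for a in train_ids if a in s.index]
            kept = _select_markers_gwas(g, premiss, s.loc[tr], scenario)
            g_sel = g.subset_loci_by_id(kept)
        else:
            g_sel = g_fixed

        rep_seed = int(np.random.default_rng(
            np.random.SeedSequence([plan.seed, 10_000 + rep])).integers(2**31 - 1))
        pres = _fit_and_predict(scenario, g_sel, train_records, obs_valid, rep_seed)
        pred = pres.table.set_index("accession")["gebv"].loc[obs_valid].to_numpy()
        obs = y_adj[target].loc[obs_valid].to_numpy()
        rows.append((rep, target, predictive_ability(pred, obs)))

    table = pd.DataFrame(rows, columns=["replicate", "env", "r"])
    if len(table) == 0:
        raise DataError("every replicate was skipped")
    summary = _summarize_pa(table)
    return PaResult(table=table, summary=summary)


def _summarize_pa(table: pd.DataFrame) -> pd.DataFrame:
    out = []
    for env, sub in table.groupby("env"):
        r = sub["r"].dropna().to_numpy()
        z = np.arctanh(np.clip(r, -0.999999, 0.999999))
        out.append(
            {
                "env": env,
                "n_reps": len(r),
                "mean_r": float(np.mean(r)),
                "se_r": float(np.std(r, ddof=1) / np.sqrt(len(r))) if len(r) > 1 else np.nan,
                "mean_r_ztransformed": float(np.tanh(np.mean(z))),
            }
        )
    return pd.DataFrame(out)


@dataclass
class ZAnovaResult:
    """Fixed-effects ANOVA of Fisher-transformed predictive abilities."""

    table: pd.DataFrame  # Source, DF, SS, MS, F, ProbF
    factors: list
    interactions: str


def anova_z(
    pa: pd.DataFrame,
    factors: list,
    interactions: str = "none",
    response: str = "r",
) -> ZAnovaResult:
    """Fixed-effects ANOVA of Z = arctanh(r) with sequential (Type I) SS.

    ``pa`` is a tidy table with one row per replicate and columns for each
    factor; ``factors`` gives the fitting order.  With
    ``interactions="first_order"`` all pairwise interactions are added after
    the main effects.
    """
    if interactions not in ("none", "first_order"):
        raise ConfigError(f"unknown interactions option {interactions!r}")
    for f in factors:
        if f not in pa.columns:
            raise DataError(f"factor {f!r} not in the table")
        if pa[f].nunique() < 2:
            raise DataError(f"factor {f!r} has fewer than 2 levels")
    df = pa.copy()
    r = df[response].to_numpy(dtype=float)
    df["_z"] = np.arctanh(np.clip(r, -0.999999, 0.999999))
    terms = [f"C({f})" for f in factors]
    if interactions == "first_order":
        terms += [f"C({a}):C({b})" for i, a in enumerate(factors) for b in factors[i + 1:]]
    formula = "_z ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    tab = tab.rename(
        columns={"df": "DF", "sum_sq": "SS", "mean_sq": "MS", "F": "F", "PR(>F)": "ProbF"}
    )
    tab.insert(0, "Source", tab.index)
    tab = tab.reset_index(drop=True)
    return ZAnovaResult(table=tab, factors=list(factors), interactions=interactions)
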