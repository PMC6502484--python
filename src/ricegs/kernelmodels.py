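"""Kernel-based genomic prediction: single- and multi-environment models.

Single-environment models are GBLUP (linear genomic relationship kernel) and
RKHS (Gaussian kernel), both fitted by EM-REML for ``y = mu + u + e`` with
``u ~ N(0, sigma2_u K)``; genetic values of unphenotyped accessions are the
conditional-expectation extension ``K_target,train V^-1 (y - mu)``.

Multi-environment models are Gibbs samplers:

* marker-by-environment (M×E) decomposition — a genetic main effect shared by
  all environments plus an environment-specific deviation, each with the same
  kernel (``u0 ~ N(0, s2_0 K)``, ``u_j ~ N(0, s2_j K)``); with a linear GRM
  this is the M×E GBLUP, with a Gaussian kernel the G×E RKHS;
* a Kronecker multi-trait model — genetic covariance ``Sigma_G ⊗ K`` with an
  unstructured environment covariance sampled under an inverse-Wishart prior,
  diagonal per-environment residuals, and missing cells handled by data
  augmentation.

Scale variances carry scaled-inverse-chi-squared priors (df 5, scales derived
from the sample variance with an R² split of 0.5, the convention of the
standard Bayesian genomic-regression packages).  Chains default to 25,000
iterations after 5,000 burn-in and are reproducible under a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .errors import ConfigError, ConvergenceError, DataError
from .genio import GenotypeMatrix
from .gwaselect import GRM, grm

_EIG_FLOOR_REL = 1e-10
_PRIOR_DF = 5.0
_PRIOR_R2 = 0.5


@dataclass
class KernelSpec:
    """Kernel choice for a prediction model.

    ``linear_grm`` is the VanRaden cross-product kernel; ``gaussian`` is
    ``K_ij = exp(-h d²_ij)`` with ``d²`` the squared Euclidean distance between
    dosage rows divided by the locus count.  ``bandwidth_rule`` is either
    ``fixed`` (use ``h``) or ``reciprocal_median_d2`` (``h = 1 / median`` of
    the off-diagonal ``d²``).
    """

    kind: str = "linear_grm"
    bandwidth_rule: str = "reciprocal_median_d2"
    h: float | None = None

    def __post_init__(self):
        if self.kind not in ("linear_grm", "gaussian"):
            raise ConfigError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian":
            if self.bandwidth_rule not in ("fixed", "reciprocal_median_d2"):
                raise ConfigError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
            if self.bandwidth_rule == "fixed":
                if self.h is None or self.h <= 0:
                    raise ConfigError("fixed bandwidth requires h > 0")


def gaussian_kernel(g: GenotypeMatrix, spec: KernelSpec | None = None) -> GRM:
    """Gaussian kernel over accessions; unit diagonal, symmetric."""
    if spec is None:
        spec = KernelSpec(kind="gaussian")
    if spec.kind != "gaussian":
        raise ConfigError("gaussian_kernel requires a gaussian KernelSpec")
    M = g.dosage
    if np.isnan(M).any():
        raise DataError("gaussian_kernel requires imputed dosages")
    sq = (M**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (M @ M.T), 0.0) / g.n_loci
    if spec.bandwidth_rule == "fixed":
        h = float(spec.h)
    else:
        off = d2[np.triu_indices_from(d2, k=1)]
        med = float(np.median(off))
        if med <= 0:
            raise DataError("median off-diagonal distance is zero; cannot set bandwidth")
        h = 1.0 / med
    if h <= 0:
        raise ConfigError("bandwidth h must be positive")
    K = np.exp(-h * d2)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return GRM(accession_ids=list(g.accession_ids), matrix=K, centering="gaussian", scale=h)


def build_kernel(g: GenotypeMatrix, spec: KernelSpec) -> GRM:
    """Dispatch on KernelSpec.kind."""
    if spec.kind == "linear_grm":
        return grm(g, centering="vanraden")
    return gaussian_kernel(g, spec)


# ---------------------------------------------------------------------------
# Single-environment EM-REML


@dataclass
class SingleEnvFit:
    """Converged single-environment kernel regression."""

    mu: float
    u_hat: pd.Series  # genetic values for every kernel accession
    sigma2_u: float
    sigma2_e: float
    kernel: KernelSpec
    loglik_trace: list = field(repr=False, default_factory=list)
    converged: bool = True
    solver: str = "em_reml"
    env: str | None = None


def fit_gblup(
    y: pd.Series,
    K: GRM,
    tol: float = 1e-8,
    max_iter: int = 1000,
    fix_sigma2_e: float | None = None,
    kernel_spec: KernelSpec | None = None,
    env: str | None = None,
) -> SingleEnvFit:
    """EM-REML fit of ``y = mu + u + e`` with ``u ~ N(0, sigma2_u K)``.

    ``K`` must cover the training accessions (``y.index``) and any prediction
    targets; genetic values for non-training accessions are filled in by the
    conditional-expectation extension.  The restricted log-likelihood is
    non-decreasing across EM iterations.
    """
    train_ids = list(y.index)
    kpos = {a: i for i, a in enumerate(K.accession_ids)}
    missing = [a for a in train_ids if a not in kpos]
    if missing:
        raise DataError(f"accessions absent from kernel: {missing[:5]}")
    ti = np.array([kpos[a] for a in train_ids])
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    Ktt = K.matrix[np.ix_(ti, ti)]

    w, U = np.linalg.eigh(Ktt)
    if w.min() < -1e-6 * max(w.max(), 1.0):
        raise DataError("kernel is not positive semi-definite over the training set")
    w = np.maximum(w, 0.0)
    yr = U.T @ yv
    xr = U.T @ np.ones(n)

    vy = max(float(np.var(yv)), 1e-12)
    mw = max(float(w.mean()), 1e-12)
    s2u = 0.5 * vy / mw
    s2e = fix_sigma2_e if fix_sigma2_e is not None else 0.5 * vy
    s2e = max(s2e, 1e-12)

    def pieces(s2u, s2e):
        d = s2u * w + s2e
        xd = xr / d
        xx = float(xr @ xd)
        b = float(xd @ yr) / xx
        Py = yr / d - xd * b  # P y in the rotated basis
        ll = -0.5 * (np.log(d).sum() + np.log(xx) + float(yr @ Py))
        return d, xd, xx, b, Py, ll

    trace = []
    converged = False
    for it in range(max_iter):
        d, xd, xx, b, Py, ll = pieces(s2u, s2e)
        trace.append(ll)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        # EM updates in the eigenbasis; tr(KP) and tr(P) have closed forms
        trKP = float((w / d).sum() - (xd * w * xd).sum() / xx)
        trP = float((1.0 / d).sum() - (xd * xd).sum() / xx)
        quad_u = float(Py @ (w * Py))
        quad_e = float(Py @ Py)
        s2u = max(s2u + (s2u**2 / n) * (quad_u - trKP), 1e-12)
        if fix_sigma2_e is None:
            s2e = max(s2e + (s2e**2 / n) * (quad_e - trP), 1e-12)

    if not converged:
        warnings.warn("fit_gblup: EM-REML did not converge", stacklevel=2)

    d, xd, xx, b, Py, ll = pieces(s2u, s2e)
    trace.append(ll)
    # u_hat over all kernel accessions: sigma2_u * K[:, train] V^-1 (y - mu)
    Vinv_r = U @ Py  # P y equals V^-1 (y - X b) at the solution
    u_all = s2u * (K.matrix[:, ti] @ Vinv_r)
    return SingleEnvFit(
        mu=float(b),
        u_hat=pd.Series(u_all, index=K.accession_ids),
        sigma2_u=float(s2u),
        sigma2_e=float(s2e),
        kernel=kernel_spec or KernelSpec(kind="linear_grm"),
        loglik_trace=trace,
        converged=converged,
        env=env,
    )


def fit_rkhs(
    y: pd.Series,
    Kg: GRM,
    tol: float = 1e-8,
    max_iter: int = 1000,
    env: str | None = None,
) -> SingleEnvFit:
    """RKHS regression: identical mixed-model machinery with a Gaussian kernel."""
    return fit_gblup(
        y, Kg, tol=tol, max_iter=max_iter,
        kernel_spec=KernelSpec(kind="gaussian"), env=env,
    )


# ---------------------------------------------------------------------------
# Multi-environment Gibbs samplers


@dataclass
class MultiEnvFit:
    """Posterior summaries of a multi-environment model."""

    model: str
    env_labels: list[str]
    intercepts: pd.Series  # per environment
    genetic_values: pd.DataFrame  # accession × env posterior means
    sigma2_0: float | None = None
    sigma2_env: dict | None = None
    sigma_g: np.ndarray | None = None  # env × env genetic covariance (kron)
    sigma2_e: dict | None = None
    diagnostics: dict = field(default_factory=dict)


def _check_multienv(data: pd.DataFrame) -> pd.DataFrame:
    for col in ("accession", "env", "value"):
        if col not in data.columns:
            raise DataError(f"multi-environment data lacks column {col!r}")
    if data.duplicated(subset=["accession", "env"]).any():
        raise DataError("more than one record per (accession, env)")
    return data.dropna(subset=["value"]).reset_index(drop=True)


def _kernel_basis(K: GRM):
    w, U = np.linalg.eigh(K.matrix)
    keep = w > _EIG_FLOOR_REL * max(w.max(), 1.0)
    return U[:, keep] * np.sqrt(w[keep])  # L with K = L L^T


def _sample_scaled_inv_chi2(rng, df, scale_sum):
    return scale_sum / rng.chisquare(df)


def _gibbs_env_decomposition(
    data: pd.DataFrame,
    K: GRM,
    iters: int,
    burnin: int,
    seed: int,
    model_name: str,
) -> MultiEnvFit:
    data = _check_multienv(data)
    envs = list(pd.unique(data["env"]))
    counts = data["env"].value_counts()
    for env in envs:
        if counts[env] < 2:
            raise DataError(f"environment {env!r} has fewer than 2 records")
    if iters <= burnin:
        raise ConfigError("iters must exceed burnin")

    ids = list(K.accession_ids)
    kpos = {a: i for i, a in enumerate(ids)}
    missing = [a for a in data["accession"] if a not in kpos]
    if missing:
        raise DataError(f"accessions absent from kernel: {sorted(set(missing))[:5]}")

    rng = np.random.default_rng(seed)
    L = _kernel_basis(K)
    r = L.shape[1]
    J = len(envs)
    acc_idx = data["accession"].map(kpos).to_numpy()
    env_idx = data["env"].map({e: j for j, e in enumerate(envs)}).to_numpy()
    yv = data["value"].to_numpy(dtype=float)
    N = len(yv)

    M0 = L[acc_idx]
    G0 = M0.T @ M0
    rows_j = [np.flatnonzero(env_idx == j) for j in range(J)]
    Mj = [M0[rows] for rows in rows_j]
    Gj = [m.T @ m for m in Mj]

    vy = max(float(np.var(yv)), 1e-12)
    mdk = max(float(np.mean(np.einsum("ij,ij->i", M0, M0))), 1e-12)
    df = _PRIOR_DF
    n_gen_terms = 1 + J
    S_e = vy * (1 - _PRIOR_R2) * (df + 2) / df
    S_u = vy * _PRIOR_R2 / n_gen_terms / mdk * (df + 2) / df

    mu = np.array([yv[rows].mean() for rows in rows_j])
    a0 = np.zeros(r)
    aj = np.zeros((J, r))
    s2_0 = S_u
    s2_j = np.full(J, S_u)
    s2_e = S_e * df / (df + 2)

    f0 = M0 @ a0
    fj_rec = np.zeros(N)  # env-specific genetic value aligned to records

    keep = iters - burnin
    sum_gv = np.zeros((len(ids), J))
    sum_mu = np.zeros(J)
    sum_s2 = np.zeros(3 + J)  # s2_0, s2_e, (spare), s2_j...
    for it in range(iters):
        # intercepts (flat prior)
        for j, rows in enumerate(rows_j):
            resid = yv[rows] - f0[rows] - fj_rec[rows]
            mu[j] = rng.normal(resid.mean(), np.sqrt(s2_e / len(rows)))
        mu_rec = mu[env_idx]

        # main genetic effect
        rvec = yv - mu_rec - fj_rec
        prec = G0 / s2_e + np.eye(r) / s2_0
        cl = np.linalg.cholesky(prec)
        mean = sla.cho_solve((cl, True), M0.T @ rvec / s2_e)
        a0 = mean + sla.solve_triangular(cl.T, rng.standard_normal(r), lower=False)
        f0 = M0 @ a0

        # environment-specific deviations
        for j, rows in enumerate(rows_j):
            rv = yv[rows] - mu[j] - f0[rows]
            prec = Gj[j] / s2_e + np.eye(r) / s2_j[j]
            cl = np.linalg.cholesky(prec)
            mean = sla.cho_solve((cl, True), Mj[j].T @ rv / s2_e)
            aj[j] = mean + sla.solve_triangular(cl.T, rng.standard_normal(r), lower=False)
            fj_rec[rows] = Mj[j] @ aj[j]

        # scale variances
        s2_0 = _sample_scaled_inv_chi2(rng, df + r, float(a0 @ a0) + df * S_u)
        for j in range(J):
            s2_j[j] = _sample_scaled_inv_chi2(rng, df + r, float(aj[j] @ aj[j]) + df * S_u)
        e = yv - mu_rec - f0 - fj_rec
        s2_e = _sample_scaled_inv_chi2(rng, df + N, float(e @ e) + df * S_e)

        if it >= burnin:
            gv0 = L @ a0
            for j in range(J):
                sum_gv[:, j] += gv0 + L @ aj[j]
            sum_mu += mu
            sum_s2[0] += s2_0
            sum_s2[1] += s2_e
            sum_s2[3:] += s2_j

    genval = pd.DataFrame(sum_gv / keep, index=ids, columns=envs)
    return MultiEnvFit(
        model=model_name,
        env_labels=envs,
        intercepts=pd.Series(sum_mu / keep, index=envs),
        genetic_values=genval,
        sigma2_0=float(sum_s2[0] / keep),
        sigma2_env={e: float(v) for e, v in zip(envs, sum_s2[3:] / keep)},
        sigma2_e={"all": float(sum_s2[1] / keep)},
        diagnostics={"iters": iters, "burnin": burnin, "seed": seed},
    )


def fit_mxe_gblup(
    data: pd.DataFrame,
    K: GRM,
    iters: int = 25000,
    burnin: int = 5000,
    seed: int = 0,
) -> MultiEnvFit:
    """Marker-by-environment GBLUP: shared main genetic effect plus
    environment-specific deviations, linear GRM kernel, Gibbs sampling."""
    return _gibbs_env_decomposition(data, K, iters, burnin, seed, "mxe_gblup")


def fit_gxe_rkhs(
    data: pd.DataFrame,
    Kg: GRM,
    iters: int = 25000,
    burnin: int = 5000,
    seed: int = 0,
) -> MultiEnvFit:
    """G×E RKHS: the same main-plus-deviation decomposition with a Gaussian
    kernel in place of the linear GRM."""
    return _gibbs_env_decomposition(data, Kg, iters, burnin, seed, "gxe_rkhs")


def fit_kron_multitrait(
    Y: pd.DataFrame,
    K: GRM,
    iters: int = 25000,
    burnin: int = 5000,
    seed: int = 0,
) -> MultiEnvFit:
    """Kronecker multi-trait model: genetic covariance Sigma_G ⊗ K.

    ``Y`` is an accession × environment matrix; missing cells are allowed and
    are handled by conditional sampling.  Sigma_G is unstructured with an
    inverse-Wishart prior (df J+2, identity-proportional scale); residual
    covariance is diagonal per environment.
    """
    if Y.shape[1] < 2:
        raise DataError("Kronecker multi-trait model requires >= 2 environments")
    if iters <= burnin:
        raise ConfigError("iters must exceed burnin")
    envs = list(Y.columns)
    obs = Y.notna().to_numpy()
    if (~obs).all(axis=0).any():
        bad = [e for e, m in zip(envs, (~obs).all(axis=0)) if m]
        raise DataError(f"environment(s) entirely missing: {bad}")

    ids = list(Y.index)
    kpos = {a: i for i, a in enumerate(K.accession_ids)}
    missing = [a for a in ids if a not in kpos]
    if missing:
        raise DataError(f"accessions absent from kernel: {missing[:5]}")
    idx = np.array([kpos[a] for a in ids])
    Ksub = K.matrix[np.ix_(idx, idx)]
    n, J = Y.shape

    rng = np.random.default_rng(seed)
    w, U = np.linalg.eigh(Ksub)
    w = np.maximum(w, _EIG_FLOOR_REL * max(w.max(), 1.0))

    Yv = Y.to_numpy(dtype=float)
    col_mean = np.nanmean(Yv, axis=0)
    col_var = np.nanvar(Yv, axis=0)
    col_var = np.maximum(col_var, 1e-12)
    Yc = np.where(obs, Yv, col_mean)

    df_e = _PRIOR_DF
    S_e = col_var * (1 - _PRIOR_R2) * (df_e + 2) / df_e
    df0 = J + 2.0
    S0 = np.diag(_PRIOR_R2 * col_var)  # prior mean of Sigma_G at df0 = J+2

    mu = col_mean.copy()
    Sigma = np.diag(_PRIOR_R2 * col_var)
    s2e = col_var * (1 - _PRIOR_R2)
    G = np.zeros((n, J))

    keep = iters - burnin
    sum_G = np.zeros((n, J))
    sum_mu = np.zeros(J)
    sum_Sigma = np.zeros((J, J))
    sum_s2e = np.zeros(J)
    eye_cache = np.eye(J)
    for it in range(iters):
        # impute missing cells
        if (~obs).any():
            noise = rng.standard_normal(Yc.shape) * np.sqrt(s2e)
            Yc = np.where(obs, Yv, mu + G + noise)

        # sample G in the eigenbasis of K (rows decouple)
        Sinv = np.linalg.inv(Sigma + 1e-10 * eye_cache)
        Rinv = np.diag(1.0 / s2e)
        Yt = U.T @ (Yc - mu)
        prec = Sinv[None, :, :] / w[:, None, None] + Rinv[None, :, :]
        cl = np.linalg.cholesky(prec)
        rhs = Yt / s2e
        mean = np.linalg.solve(prec, rhs[:, :, None])[:, :, 0]
        z = rng.standard_normal((n, J))
        # solve L^T x = z per row for a draw with covariance prec^-1
        draw = np.linalg.solve(np.transpose(cl, (0, 2, 1)), z[:, :, None])[:, :, 0]
        Gt = mean + draw
        G = U @ Gt

        # intercepts
        resid = Yc - G
        mu = rng.normal(resid.mean(axis=0), np.sqrt(s2e / n))

        # residual variances (diagonal per environment)
        E = Yc - mu - G
        for j in range(J):
            s2e[j] = _sample_scaled_inv_chi2(
                rng, df_e + n, float(E[:, j] @ E[:, j]) + df_e * S_e[j]
            )

        # genetic covariance: G^T K^-1 G computed in the eigenbasis
        Sq = Gt.T @ (Gt / w[:, None])
        Sigma = stats.invwishart.rvs(df=df0 + n, scale=S0 + Sq, random_state=rng)
        Sigma = np.atleast_2d(Sigma)

        if it >= burnin:
            sum_G += G
            sum_mu += mu
            sum_Sigma += Sigma
            sum_s2e += s2e

    genval = pd.DataFrame(sum_G / keep, index=ids, columns=envs)
    return MultiEnvFit(
        model="kron_multitrait",
        env_labels=envs,
        intercepts=pd.Series(sum_mu / keep, index=envs),
        genetic_values=genval,
        sigma_g=sum_Sigma / keep,
        sigma2_e={e: float(v) for e, v in zip(envs, sum_s2e / keep)},
        diagnostics={"iters": iters, "burnin": burnin, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Prediction


@dataclass
class PredictionResult:
    """GEBV per requested (accession, environment) cell."""

    table: pd.DataFrame  # accession, env, gebv


def predict(fit, targets: list[tuple[str, str | None]]) -> PredictionResult:
    """Genomic estimated breeding values for the requested cells.

    For single-environment fits the GEBV is ``mu + u_hat``; for
    multi-environment fits it is the environment intercept plus the posterior
    mean genetic value, conditional on any records seen at fit time.
    """
    rows = []
    if isinstance(fit, SingleEnvFit):
        unknown = [a for a, _ in targets if a not in fit.u_hat.index]
        if unknown:
            raise DataError(f"unknown accession(s): {sorted(set(unknown))[:10]}")
        for acc, env in targets:
            rows.append((acc, env if env is not None else fit.env,
                         fit.mu + float(fit.u_hat[acc])))
    elif isinstance(fit, MultiEnvFit):
        unknown = [a for a, _ in targets if a not in fit.genetic_values.index]
        if unknown:
            raise DataError(f"unknown accession(s): {sorted(set(unknown))[:10]}")
        for acc, env in targets:
            if env not in fit.env_labels:
                raise DataError(f"environment {env!r} not in fitted model")
            rows.append((acc, env,
                         float(fit.intercepts[env]) + float(fit.genetic_values.loc[acc, env])))
    else:
        raise TypeError(f"cannot predict from {type(fit).__name__}")
    return PredictionResult(table=pd.DataFrame(rows, columns=["accession", "env", "gebv"]))
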