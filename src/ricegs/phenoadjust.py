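"""Plot-level mixed-model adjustment of field-trial phenotypes.

For each environment and trait the plot value is modeled as

    Y_ijk = mu + C_j + beta_k + N_i * alpha_i + eps_ijk

with the overall mean ``mu`` and the check effects ``C_j`` fixed, the block
effects ``beta_k`` and the accession effects ``alpha_i`` random, and ``N_i`` a
covariate equal to 1 for test accessions and 0 for check plots (so checks
inform the mean, check and block effects but carry no accession effect; block
effects are effectively estimated from the replicated checks).  Variance
components are estimated by EM-REML, whose restricted log-likelihood is
non-decreasing at every iteration.  The adjusted phenotype of accession i is
``mu_hat + BLUP(alpha_i)`` (a block-corrected raw mean is available as an
alternative), and broad-sense heritability on a plot basis is
``H² = sigma2_g / (sigma2_g + sigma2_e)``.

The accession effect is fitted as a main effect: with a single plot per
accession within each block, an accession-within-block effect would be
confounded with the residual.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-10


@dataclass
class VarianceComponents:
    """REML variance components and fixed effects of the adjustment model."""

    sigma2_g: float
    sigma2_e: float
    sigma2_block: float
    fixed_effects: dict
    loglik_restricted: float
    loglik_trace: list = field(repr=False)
    converged: bool = True
    # solution detail used by adjusted_means
    accession_blup: pd.Series | None = field(default=None, repr=False)
    block_blup: pd.Series | None = field(default=None, repr=False)


@dataclass
class AdjustedPhenotypes:
    """Adjusted accession means for one (environment, trait)."""

    env: str
    trait: str
    y_adj: pd.Series  # indexed by accession id


def _design(fb: pd.DataFrame, env, trait):
    sub = fb[(fb["env"] == env) & (fb["trait"] == trait)].dropna(subset=["value"])
    if len(sub) == 0:
        raise DataError(f"no records for env={env!r}, trait={trait!r}")
    blocks = sub["block"].unique()
    if len(blocks) < 2:
        raise DataError("adjustment model requires >= 2 blocks")
    for b in blocks:
        if not sub.loc[sub["block"] == b, "is_check"].any():
            raise DataError(f"block {b!r} contains no check record")
    y = sub["value"].to_numpy(dtype=float)
    n = len(y)

    checks = sorted(sub.loc[sub["is_check"], "entry_id"].unique())
    X = np.ones((n, 1 + len(checks)))
    for j, cid in enumerate(checks):
        X[:, 1 + j] = (sub["entry_id"] == cid).to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("singular fixed-effects design (aliased check levels)")

    block_ids = list(blocks)
    Zb = np.zeros((n, len(block_ids)))
    for k, b in enumerate(block_ids):
        Zb[:, k] = (sub["block"] == b).to_numpy(dtype=float)

    acc_ids = sorted(sub.loc[~sub["is_check"], "entry_id"].unique())
    Za = np.zeros((n, len(acc_ids)))
    acc_pos = {a: i for i, a in enumerate(acc_ids)}
    for row, (eid, chk) in enumerate(zip(sub["entry_id"], sub["is_check"])):
        if not chk:
            Za[row, acc_pos[eid]] = 1.0
    return y, X, Zb, Za, checks, block_ids, acc_ids


def _reml_loglik(y, X, V):
    """Restricted log-likelihood (up to an additive constant)."""
    L = np.linalg.cholesky(V)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    logdet_V = 2.0 * np.log(np.diag(L)).sum()
    sign, logdet_X = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    quad = float(y @ Py)
    return -0.5 * (logdet_V + logdet_X + quad), Py, beta


def fit_adjustment_model(
    fb: pd.DataFrame,
    env,
    trait,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> VarianceComponents:
    """EM-REML fit of the plot adjustment model for one environment and trait.

    Iterates until the restricted log-likelihood changes by less than ``tol``
    or ``max_iter`` is reached (a warning flags non-convergence).  Negative
    variance iterates are floored at a small positive value.
    """
    y, X, Zb, Za, checks, block_ids, acc_ids = _design(fb, env, trait)
    n = len(y)
    vtot = max(float(np.var(y)), _VAR_FLOOR)
    s2 = {"block": vtot / 4, "acc": vtot / 2, "e": vtot / 2}
    Zs = {"block": Zb, "acc": Za}
    ZZt = {r: Z @ Z.T for r, Z in Zs.items()}

    trace: list[float] = []
    Py = beta = None
    converged = False
    for it in range(max_iter):
        V = s2["e"] * np.eye(n) + s2["block"] * ZZt["block"] + s2["acc"] * ZZt["acc"]
        ll, Py, beta = _reml_loglik(y, X, V)
        trace.append(ll)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        # EM updates
        Vi = np.linalg.inv(V)
        XtViX_inv = np.linalg.inv(X.T @ Vi @ X)
        P = Vi - Vi @ X @ XtViX_inv @ X.T @ Vi
        for r, Z in Zs.items():
            q = Z.shape[1]
            PZ = P @ Z
            upd = s2[r] + (s2[r] ** 2 / q) * (
                float((Py @ Z) @ (Z.T @ Py)) - float(np.trace(Z.T @ PZ))
            )
            s2[r] = max(upd, _VAR_FLOOR)
        upd_e = s2["e"] + (s2["e"] ** 2 / n) * (float(Py @ Py) - float(np.trace(P)))
        s2["e"] = max(upd_e, _VAR_FLOOR)

    if not converged:
        warnings.warn(
            f"EM-REML did not converge in {max_iter} iterations for "
            f"env={env!r} trait={trait!r}",
            stacklevel=2,
        )

    # BLUPs at the final iterate
    V = s2["e"] * np.eye(n) + s2["block"] * ZZt["block"] + s2["acc"] * ZZt["acc"]
    ll, Py, beta = _reml_loglik(y, X, V)
    trace.append(ll)
    u_acc = s2["acc"] * (Za.T @ Py)
    u_block = s2["block"] * (Zb.T @ Py)

    fixed = {"mu": float(beta[0])}
    fixed.update({f"check:{c}": float(b) for c, b in zip(checks, beta[1:])})
    return VarianceComponents(
        sigma2_g=s2["acc"],
        sigma2_e=s2["e"],
        sigma2_block=s2["block"],
        fixed_effects=fixed,
        loglik_restricted=ll,
        loglik_trace=trace,
        converged=converged,
        accession_blup=pd.Series(u_acc, index=acc_ids),
        block_blup=pd.Series(u_block, index=block_ids),
    )


def adjusted_means(
    fit: VarianceComponents,
    fb: pd.DataFrame,
    env,
    trait,
    method: str = "blup",
) -> AdjustedPhenotypes:
    """Adjusted accession means for genomic prediction.

    ``blup`` (default): ``mu_hat + BLUP(alpha_i)``, the shrunken accession
    effect from the mixed model.  ``block_corrected``: the raw accession mean
    after subtracting the BLUP of its block effect(s).
    """
    if method == "blup":
        y_adj = fit.fixed_effects["mu"] + fit.accession_blup
    elif method == "block_corrected":
        sub = fb[(fb["env"] == env) & (fb["trait"] == trait) & (~fb["is_check"])]
        sub = sub.dropna(subset=["value"]).copy()
        sub["corr"] = sub["value"].to_numpy() - fit.block_blup.reindex(sub["block"]).to_numpy()
        y_adj = sub.groupby("entry_id")["corr"].mean()
        y_adj.index.name = None
    else:
        raise ValueError(f"unknown adjusted-means method {method!r}")
    return AdjustedPhenotypes(env=str(env), trait=str(trait), y_adj=y_adj.sort_index())


def broad_sense_h2(sigma2_g: float, sigma2_e: float) -> float:
    """Broad-sense heritability H² = sigma2_g / (sigma2_g + sigma2_e)."""
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma2_g + sigma2_e
    if tot == 0:
        raise ValueError("H² undefined when both variance components are zero")
    return sigma2_g / tot
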