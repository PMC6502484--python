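"""Kinship, structure covariates, mixed-linear-model GWAS and top-k selection.

The association scan is the standard MLM ``y = Xb + m*beta + g + e`` with
``g ~ N(0, sigma2_g K)``: variance components are estimated once under the
marker-free null by REML on the eigendecomposition of K (the P3D/EMMAX
approximation) and each marker is then tested by generalized least squares
with covariates ``[1, Q, marker]``, the two-sided p-value coming from the t
statistic of the marker coefficient.  Population structure Q is represented
by principal components of the centered dosage matrix (K subpopulations map
to K-1 components).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, DataError
from .genio import GenotypeMatrix

_JITTER = 1e-8


@dataclass
class GRM:
    """Genomic relationship (or cross-product) matrix over accessions."""

    accession_ids: list[str]
    matrix: np.ndarray
    centering: str  # {"raw", "vanraden"}
    scale: float

    def align(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            idx = [pos[a] for a in ids]
        except KeyError as exc:
            raise DataError(f"accession {exc.args[0]!r} absent from GRM") from exc
        return self.matrix[np.ix_(idx, idx)]


@dataclass
class StructureCovariates:
    """Mean-centered structure covariates (principal components)."""

    accession_ids: list[str]
    q: np.ndarray  # n × (K-1)
    method: str = "pca"


@dataclass
class GwasResult:
    """Per-locus effect estimates and p-values plus model metadata."""

    table: pd.DataFrame  # locus_id, chrom, pos_bp, beta, se, p
    n: int
    sigma2_g: float
    sigma2_e: float
    n_covariates: int


def grm(g: GenotypeMatrix, centering: str = "vanraden") -> GRM:
    """Genomic relationship matrix.

    ``raw``: G = M Mᵀ on dosages as-is.  ``vanraden`` (default): columns
    centered by 2p̂ and G scaled by Σ 2p̂(1-p̂).  The result is symmetrized and
    jittered on the diagonal to be numerically PSD.
    """
    if g.n_loci == 0:
        raise DataError("cannot build a GRM from zero loci")
    M = g.dosage
    if np.isnan(M).any():
        raise DataError("GRM requires imputed dosages (found NaN)")
    if centering == "raw":
        G = M @ M.T
        scale = 1.0
    elif centering == "vanraden":
        p = M.mean(axis=0) / 2.0
        Mc = M - 2.0 * p
        scale = float(np.sum(2.0 * p * (1.0 - p)))
        if scale <= 0:
            raise DataError("all loci monomorphic; VanRaden scale is zero")
        G = (Mc @ Mc.T) / scale
    else:
        raise ConfigError(f"unknown GRM centering {centering!r}")
    G = 0.5 * (G + G.T) + _JITTER * np.eye(g.n_accessions)
    return GRM(accession_ids=list(g.accession_ids), matrix=G, centering=centering, scale=scale)


def structure_covariates(g: GenotypeMatrix, k_subpops: int) -> StructureCovariates:
    """First ``k_subpops - 1`` principal components of the centered dosages."""
    if k_subpops < 2:
        raise ConfigError("k_subpops must be >= 2")
    if k_subpops > g.n_accessions:
        raise ConfigError("k_subpops exceeds the number of accessions")
    M = g.dosage
    if np.isnan(M).any():
        raise DataError("structure_covariates requires imputed dosages")
    Mc = M - M.mean(axis=0)
    U, S, _ = np.linalg.svd(Mc, full_matrices=False)
    q = U[:, : k_subpops - 1] * S[: k_subpops - 1]
    q = q - q.mean(axis=0)
    return StructureCovariates(accession_ids=list(g.accession_ids), q=q)


def _null_reml(y, X, K):
    """REML variance components of y = Xb + g + e, g ~ N(0, s2g K).

    Profiled on the ratio via the eigendecomposition of K; returns
    (sigma2_g, sigma2_e, eigvals, eigvecs).
    """
    n, p = X.shape
    w, U = np.linalg.eigh(K)
    w = np.maximum(w, 0.0)
    yr = U.T @ y
    Xr = U.T @ X

    def neg_restricted_ll(log_delta):
        # delta = s2e / s2g
        delta = np.exp(log_delta)
        d = w + delta
        Xw = Xr / d[:, None]
        XtVX = Xr.T @ Xw
        b = np.linalg.solve(XtVX, Xw.T @ yr)
        r = yr - Xr @ b
        quad = float(r @ (r / d))
        s2g = quad / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(s2g)
            + np.log(d).sum()
            + np.linalg.slogdet(XtVX)[1]
            + (n - p)
        )
        return -ll

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-10.0, 10.0), method="bounded")
    delta = float(np.exp(res.x))
    d = w + delta
    Xw = Xr / d[:, None]
    XtVX = Xr.T @ Xw
    b = np.linalg.solve(XtVX, Xw.T @ yr)
    r = yr - Xr @ b
    s2g = float(r @ (r / d)) / (n - p)
    return s2g, s2g * delta, w, U


def mlm_gwas(
    y_adj: pd.Series,
    g: GenotypeMatrix,
    K: GRM,
    Q: StructureCovariates | None = None,
) -> GwasResult:
    """P3D/EMMAX mixed-linear-model association scan over all loci.

    ``y_adj`` is indexed by accession id; K (and Q, if given) are aligned to
    it.  Markers collinear with the covariates are flagged with p = 1.
    """
    ids = [a for a in g.accession_ids if a in y_adj.index]
    if len(ids) < 3:
        raise DataError("fewer than 3 accessions shared between phenotypes and genotypes")
    pos = {a: i for i, a in enumerate(g.accession_ids)}
    rows = np.array([pos[a] for a in ids])
    y = y_adj.loc[ids].to_numpy(dtype=float)
    M = g.dosage[rows, :]
    if np.isnan(M).any():
        raise DataError("mlm_gwas requires imputed dosages")

    Xcols = [np.ones(len(ids))]
    if Q is not None and Q.q.shape[1] > 0:
        qpos = {a: i for i, a in enumerate(Q.accession_ids)}
        Xcols.append(Q.q[[qpos[a] for a in ids], :])
    X = np.column_stack(Xcols)
    Km = K.align(ids)

    s2g, s2e, w, U = _null_reml(y, X, Km)
    d = s2g * w + s2e  # rotated marginal variances
    sw = 1.0 / np.sqrt(d)
    # whitened data: OLS in this space == GLS with V fixed at the null fit
    yw = (U.T @ y) * sw
    Xw = (U.T @ X) * sw[:, None]
    Mw = (U.T @ M) * sw[:, None]

    # residualize marker columns and y against the covariates
    Qx, _ = np.linalg.qr(Xw)
    yr = yw - Qx @ (Qx.T @ yw)
    Mr = Mw - Qx @ (Qx.T @ Mw)

    mm = np.einsum("ij,ij->j", Mr, Mr)
    my = Mr.T @ yr
    yy = float(yr @ yr)
    ok = mm > 1e-10
    beta = np.zeros(g.n_loci)
    se = np.full(g.n_loci, np.nan)
    pvals = np.ones(g.n_loci)
    df = len(ids) - X.shape[1] - 1
    beta[ok] = my[ok] / mm[ok]
    # residual scale re-estimated per marker (the V ratio stays fixed at the
    # null fit), so with K = I the test reduces exactly to per-marker OLS
    rss = np.maximum(yy - my[ok] ** 2 / mm[ok], 0.0)
    s2 = rss / df
    se[ok] = np.sqrt(s2 / mm[ok])
    tstat = np.divide(beta[ok], se[ok], out=np.zeros(ok.sum()), where=se[ok] > 0)
    pvals[ok] = np.clip(2.0 * stats.t.sf(np.abs(tstat), df), np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "locus_id": g.loci["locus_id"].to_numpy(),
            "chrom": g.loci["chrom"].to_numpy(),
            "pos_bp": g.loci["pos_bp"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": pvals,
            "collinear": ~ok,
        }
    )
    return GwasResult(table=table, n=len(ids), sigma2_g=s2g, sigma2_e=s2e,
                      n_covariates=X.shape[1])


def select_top_k(res: GwasResult, k: int) -> list[str]:
    """Locus ids of the k smallest p-values; ties broken by genomic order."""
    if k <= 0:
        raise ConfigError("k must be positive")
    t = res.table
    if k > len(t):
        raise ConfigError(f"k={k} exceeds the {len(t)} tested loci")
    order = np.lexsort((np.arange(len(t)), t["p"].to_numpy()))
    chosen = set(order[:k])
    # return in genomic order
    return [lid for i, lid in enumerate(t["locus_id"]) if i in chosen]
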