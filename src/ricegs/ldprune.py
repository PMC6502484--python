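"""Pairwise linkage disequilibrium, LD-based marker pruning and LD-decay curves.

LD between unphased dosage columns is measured by the composite (Rogers–Huff
style) r²: the squared Pearson correlation of the two dosage vectors.  Pruning
treats loci on a chromosome as nodes of a graph with an edge wherever
r² > r2_max; each connected component ("cluster") is represented by a single
locus — the one with the fewest missing calls before imputation, ties broken by
the highest MAF, remaining ties uniformly at random.  By construction every
retained pair on a chromosome then satisfies r² <= r2_max.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConfigError
from .genio import GenotypeMatrix, LocusStats

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Symmetric matrix of pairwise r² for the loci of one chromosome."""

    chrom: str
    locus_ids: list[str]
    r2: np.ndarray


@dataclass
class PruneResult:
    """Outcome of LD pruning: one representative locus per LD cluster."""

    kept_locus_ids: list[str]
    cluster_of: dict[str, int]
    thresholds: tuple[float, float]  # (r2_max, min_maf)


def _r2_from_columns(x: np.ndarray) -> np.ndarray:
    """Squared correlation between columns; monomorphic columns get r²=0."""
    n, m = x.shape
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    poly = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(poly, 1.0, np.nan) * xc / np.where(sd > 0, sd, 1.0)
    z = np.nan_to_num(z)
    r = z.T @ z / n
    r2 = r**2
    r2[~poly, :] = 0.0
    r2[:, ~poly] = 0.0
    np.fill_diagonal(r2, 1.0)
    return np.clip(r2, 0.0, 1.0)


def pairwise_r2(g: GenotypeMatrix, chrom) -> LDMatrix:
    """Composite r² between all locus pairs of one chromosome.

    Dosages must be imputed first (no NaN).  A single-locus chromosome yields
    a 1×1 matrix with a warning.
    """
    mask = (g.loci["chrom"] == chrom).to_numpy()
    ids = list(g.loci.loc[mask, "locus_id"])
    x = g.dosage[:, mask]
    if np.isnan(x).any():
        raise ValueError("pairwise_r2 requires imputed dosages (found NaN)")
    if len(ids) < 2:
        warnings.warn(f"chromosome {chrom!r} has fewer than 2 loci", stacklevel=2)
        return LDMatrix(chrom=str(chrom), locus_ids=ids, r2=np.ones((len(ids), len(ids))))
    return LDMatrix(chrom=str(chrom), locus_ids=ids, r2=_r2_from_columns(x))


def prune_by_ld(
    g: GenotypeMatrix,
    r2_max: float,
    min_maf: float,
    premiss: LocusStats,
    seed: int = 0,
) -> PruneResult:
    """Select one representative locus per LD cluster, chromosome by chromosome.

    ``premiss`` supplies the *pre-imputation* missing rates and MAFs used for
    representative choice.  After pruning, kept loci with MAF < min_maf are
    dropped.  Deterministic given ``seed``.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ConfigError(f"r2_max={r2_max} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    st = premiss.table.set_index("locus_id")
    kept: list[str] = []
    cluster_of: dict[str, int] = {}
    offset = 0
    for chrom in g.loci["chrom"].unique():
        ld = pairwise_r2(g, chrom)
        m = len(ld.locus_ids)
        adj = ld.r2 > r2_max
        np.fill_diagonal(adj, False)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        ids = np.asarray(ld.locus_ids)
        miss = st.loc[ids, "missing_rate"].to_numpy()
        maf = st.loc[ids, "maf"].to_numpy()
        for lid, lab in zip(ids, labels):
            cluster_of[lid] = offset + int(lab)
        for comp in range(n_comp):
            members = np.flatnonzero(labels == comp)
            if len(members) == 1:
                kept.append(ids[members[0]])
                continue
            key_miss = miss[members]
            best = members[key_miss == key_miss.min()]
            key_maf = maf[best]
            best = best[key_maf == key_maf.max()]
            pick = best[rng.integers(len(best))] if len(best) > 1 else best[0]
            kept.append(ids[pick])
        offset += n_comp
    # final MAF screen on the representatives
    kept = [lid for lid in kept if st.loc[lid, "maf"] >= min_maf]
    # restore genomic order
    order = {lid: i for i, lid in enumerate(g.loci["locus_id"])}
    kept.sort(key=order.__getitem__)
    logger.info(
        "prune_by_ld(r2_max=%.2f, min_maf=%.2f): kept %d / %d loci",
        r2_max, min_maf, len(kept), g.n_loci,
    )
    return PruneResult(kept_locus_ids=kept, cluster_of=cluster_of, thresholds=(r2_max, min_maf))


def threshold_grid(
    g: GenotypeMatrix,
    r2_levels: list[float],
    maf_levels: list[float],
    premiss: LocusStats,
    seed: int = 0,
):
    """Prune at every (r², MAF) threshold combination.

    Returns ``(sizes, results)``: a DataFrame of retained-set sizes indexed by
    r² level (columns: MAF levels) and a dict mapping (r2, maf) → PruneResult.
    """
    if not r2_levels or not maf_levels:
        raise ConfigError("r2_levels and maf_levels must be non-empty")
    results: dict[tuple[float, float], PruneResult] = {}
    sizes = pd.DataFrame(index=r2_levels, columns=maf_levels, dtype=float)
    for r2 in r2_levels:
        base = prune_by_ld(g, r2_max=r2, min_maf=0.0, premiss=premiss, seed=seed)
        st = premiss.table.set_index("locus_id")
        for maf in maf_levels:
            kept = [lid for lid in base.kept_locus_ids if st.loc[lid, "maf"] >= maf]
            results[(r2, maf)] = PruneResult(
                kept_locus_ids=kept, cluster_of=base.cluster_of, thresholds=(r2, maf)
            )
            sizes.loc[r2, maf] = len(kept)
    sizes.index.name = "r2_max"
    sizes.columns.name = "min_maf"
    return sizes.astype(int), results


def ld_decay_curve(
    g: GenotypeMatrix,
    bin_width_kb: float = 25.0,
    max_dist_kb: float = 1000.0,
):
    """Mean and SD of r² binned by physical distance, pooled over chromosomes.

    Returns ``(curve, half_decay_kb)``.  ``curve`` has one row per distance bin
    (bin_start_kb, bin_end_kb, mean_r2, sd_r2, n_pairs); ``half_decay_kb`` is
    the start of the first bin whose mean r² falls below half the first bin's
    mean (NaN if the curve never halves).
    """
    n_bins = int(np.ceil(max_dist_kb / bin_width_kb))
    sums = np.zeros(n_bins)
    sq = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for chrom in g.loci["chrom"].unique():
        mask = (g.loci["chrom"] == chrom).to_numpy()
        if mask.sum() < 2:
            continue
        ld = pairwise_r2(g, chrom)
        pos = g.loci.loc[mask, "pos_bp"].to_numpy() / 1000.0  # kb
        iu = np.triu_indices(len(pos), k=1)
        dist = np.abs(pos[iu[0]] - pos[iu[1]])
        r2 = ld.r2[iu]
        sel = dist < max_dist_kb
        b = (dist[sel] / bin_width_kb).astype(int)
        np.add.at(sums, b, r2[sel])
        np.add.at(sq, b, r2[sel] ** 2)
        np.add.at(counts, b, 1)
    if counts.sum() == 0:
        warnings.warn("no locus pairs within max_dist_kb", stacklevel=2)
        return pd.DataFrame(
            columns=["bin_start_kb", "bin_end_kb", "mean_r2", "sd_r2", "n_pairs"]
        ), float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
        var = sq / counts - mean**2
    curve = pd.DataFrame(
        {
            "bin_start_kb": np.arange(n_bins) * bin_width_kb,
            "bin_end_kb": (np.arange(n_bins) + 1) * bin_width_kb,
            "mean_r2": mean,
            "sd_r2": np.sqrt(np.maximum(var, 0.0)),
            "n_pairs": counts,
        }
    )
    curve = curve[curve["n_pairs"] > 0].reset_index(drop=True)
    half = 0.5 * curve["mean_r2"].iloc[0]
    below = curve[curve["mean_r2"] < half]
    half_decay_kb = float(below["bin_start_kb"].iloc[0]) if len(below) else float("nan")
    return curve, half_decay_kb
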