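"""Genotype matrix container, file I/O, QC filters and imputation.

The central object is :class:`GenotypeMatrix`: an accession × locus matrix of
alternate-allele dosages (0, 1, 2, with ``NaN`` for missing calls) plus per-locus
chromosome/position/allele metadata.  Quality control follows the standard
diversity-panel thresholds: per-locus missing rate <= 20%, minor allele
frequency >= 2% and heterozygosity <= 5%; haplotype-based imputation is
deliberately replaced by per-locus mean (default) or mode imputation, which is
sufficient for kernel-based prediction at these marker densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

logger = logging.getLogger(__name__)

LOCUS_COLUMNS = ["locus_id", "chrom", "pos_bp", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Accession × locus dosage matrix with locus metadata.

    Parameters
    ----------
    accession_ids
        Unique accession identifiers, one per matrix row.
    loci
        DataFrame with columns ``locus_id, chrom, pos_bp, ref, alt``; loci are
        sorted by (chrom, pos_bp), strictly increasing within each chromosome.
    dosage
        Float array of shape (n_accessions, n_loci); alternate-allele counts
        in {0, 1, 2} (fractional after mean imputation) with NaN for missing.
    """

    accession_ids: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise DataError("accession_ids are not unique")
        self.loci = self.loci.reset_index(drop=True)
        if list(self.loci.columns[: len(LOCUS_COLUMNS)]) != LOCUS_COLUMNS:
            missing = set(LOCUS_COLUMNS) - set(self.loci.columns)
            if missing:
                raise DataError(f"loci table lacks columns: {sorted(missing)}")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.accession_ids), len(self.loci)):
            raise DataError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accession_ids)} accessions × {len(self.loci)} loci"
            )
        for _, sub in self.loci.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise DataError("pos_bp not strictly increasing within a chromosome")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, mask_or_index) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given loci (order preserved)."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            loci=self.loci.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
        )

    def subset_loci_by_id(self, locus_ids) -> "GenotypeMatrix":
        order = {lid: i for i, lid in enumerate(self.loci["locus_id"])}
        try:
            idx = sorted(order[lid] for lid in locus_ids)
        except KeyError as exc:
            raise DataError(f"unknown locus id {exc.args[0]!r}") from exc
        return self.subset_loci(np.asarray(idx, dtype=int))


@dataclass
class LocusStats:
    """Per-locus allele-frequency and call-quality summaries.

    ``maf``/``het_rate`` are computed over non-missing calls; ``missing_rate``
    over all accessions.  Loci with zero non-missing calls are flagged in
    ``all_missing`` and carry NaN maf/het.
    """

    table: pd.DataFrame = field(repr=False)

    @property
    def maf(self) -> np.ndarray:
        return self.table["maf"].to_numpy()

    @property
    def missing_rate(self) -> np.ndarray:
        return self.table["missing_rate"].to_numpy()

    @property
    def het_rate(self) -> np.ndarray:
        return self.table["het_rate"].to_numpy()


def locus_stats(g: GenotypeMatrix) -> LocusStats:
    """Compute per-locus MAF, heterozygosity and missing rate."""
    d = g.dosage
    obs = ~np.isnan(d)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.nansum(d, axis=0) / (2.0 * n_obs)
        het = np.nansum(d == 1, axis=0) / n_obs
    maf = np.minimum(p_alt, 1.0 - p_alt)
    missing = 1.0 - n_obs / g.n_accessions
    table = pd.DataFrame(
        {
            "locus_id": g.loci["locus_id"].to_numpy(),
            "maf": maf,
            "missing_rate": missing,
            "het_rate": het,
            "all_missing": n_obs == 0,
        }
    )
    return LocusStats(table=table)


def filter_loci(
    g: GenotypeMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.02,
    max_het: float = 0.05,
) -> GenotypeMatrix:
    """Retain loci with missing_rate <= max_missing, maf >= min_maf and
    het_rate <= max_het (all boundaries inclusive); order preserved."""
    for name, val in [("max_missing", max_missing), ("min_maf", min_maf), ("max_het", max_het)]:
        if not 0.0 <= val <= 1.0:
            raise ConfigError(f"{name}={val} outside [0, 1]")
    st = locus_stats(g)
    keep = (
        (st.missing_rate <= max_missing)
        & (st.maf >= min_maf)
        & (st.het_rate <= max_het)
        & ~st.table["all_missing"].to_numpy()
    )
    n_keep = int(keep.sum())
    logger.info("filter_loci: retained %d / %d loci", n_keep, g.n_loci)
    if n_keep == 0:
        raise DataError("filter_loci removed every locus")
    return g.subset_loci(keep)


def impute_missing(g: GenotypeMatrix, method: str = "mean") -> GenotypeMatrix:
    """Replace missing dosages per locus by the observed mean or mode.

    Mean imputation yields fractional dosages in [0, 2]; mode yields integers
    (ties broken toward the smaller dosage).  Observed calls are never altered.
    """
    if method not in ("mean", "mode"):
        raise ConfigError(f"unknown imputation method {method!r}")
    d = g.dosage.copy()
    miss = np.isnan(d)
    if not miss.any():
        return replace(g, dosage=d)
    n_obs = (~miss).sum(axis=0)
    if np.any(n_obs == 0):
        raise DataError("impute_missing: locus with zero non-missing calls")
    if method == "mean":
        fill = np.nansum(d, axis=0) / n_obs
    else:
        counts = np.stack([np.nansum(d == v, axis=0) for v in (0.0, 1.0, 2.0)])
        fill = np.argmax(counts, axis=0).astype(float)  # argmax takes first max
    d[miss] = np.broadcast_to(fill, d.shape)[miss]
    return replace(g, dosage=d)


# ---------------------------------------------------------------------------
# I/O


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from VCF (GT field) or a tab-delimited dosage table.

    Only biallelic SNPs are loaded; other records are skipped and counted.
    Dosage is the alternate-allele count; missing genotypes are preserved as NaN.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_table":
        return _read_dosage_table(path)
    raise ConfigError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files") from exc
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows = []
    dosages = []
    skipped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        dose = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append((lid, str(var.CHROM), int(var.POS), var.REF, alts[0]))
        dosages.append(dose)
    vcf.close()
    if skipped:
        logger.info("read_genotypes: skipped %d non-biallelic-SNP records", skipped)
    if not rows:
        raise DataError(f"no biallelic SNP records in {path}")
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    g = GenotypeMatrix(accession_ids=samples, loci=loci, dosage=np.column_stack(dosages))
    g.n_skipped_records = skipped
    return g


def _read_dosage_table(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse dosage table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise DataError(f"no loci in dosage table {path}")
    rows = []
    for lid in df.columns:
        chrom, _, pos = lid.rpartition("_")
        if not chrom or not pos.isdigit():
            raise FormatError(
                f"dosage table {path}: locus id {lid!r} is not of the form 'chrom_pos'"
            )
        rows.append((lid, chrom, int(pos), "A", "T"))
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    dosage = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return GenotypeMatrix(accession_ids=list(df.index), loci=loci, dosage=dosage)


def write_dosage_table(g: GenotypeMatrix, path) -> None:
    """Write a tab-delimited dosage table (header 'chrom_pos', first col accession)."""
    ids = [f"{c}_{p}" for c, p in zip(g.loci["chrom"], g.loci["pos_bp"])]
    df = pd.DataFrame(g.dosage, index=g.accession_ids, columns=ids)
    df.index.name = "accession"
    df.to_csv(path, sep="\t", na_rep="NA")


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write an (unphased, GT-only) VCF 4.2 file; fractional dosages are rounded."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.accession_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in g.loci.iterrows():
            calls = []
            for v in g.dosage[:, j]:
                if np.isnan(v):
                    calls.append("./.")
                else:
                    calls.append(gt_map[int(round(v))])
            fh.write(
                f"{row.chrom}\t{row.pos_bp}\t{row.locus_id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )
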