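"""Synthetic rice-like genotypes and multi-environment phenotypes.

The generator emulates the statistical structure of a rainfed-lowland rice
diversity panel: ~280 inbred accessions drawn from 5 admixed subpopulations,
12 chromosomes of SNPs with a low-LD mosaic structure that decays over
hundreds of kb, a minor-allele-frequency spectrum skewed toward rare alleles,
and three trial environments whose genetic correlations can range from high
(flowering time, plant height) to near zero (yield under contrasting water
regimes).  Phenotypes are laid out either as an augmented design (test entries
unreplicated, replicated checks in every block) or an alpha-lattice with two
replications.

Genotypes use a haplotype-mosaic model: each subpopulation owns a small pool
of ancestral haplotypes whose allele frequencies drift from shared ancestral
frequencies (Balding–Nichols, Fst = 0.1); an accession's haplotype walks along
each chromosome copying from one ancestral haplotype and switching to a fresh
one with probability ``1 - ld_copy_prob`` per locus, which makes adjacent-locus
r² decay geometrically with distance.  Accessions are fully inbred (dosage
0/2); residual heterozygosity and missingness are injected completely at
random at the configured rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genio import GenotypeMatrix, LOCUS_COLUMNS

# internal Balding–Nichols differentiation between subpopulations
_FST = 0.1

FIELDBOOK_COLUMNS = ["env", "entry_id", "is_check", "block", "rep", "trait", "value"]

#: default between-environment genetic correlations: high E1-E2 / E1-E3 /
#: moderate E2-E3, the pattern of a flowering-time trait across a non-stress
#: and two drought trials (0.71 / 0.68 / 0.58).
DEFAULT_GENETIC_CORR = np.array(
    [
        [1.00, 0.71, 0.68],
        [0.71, 1.00, 0.58],
        [0.68, 0.58, 1.00],
    ]
)


@dataclass
class FieldDesign:
    """Field layout for one environment.

    kind
        ``augmented`` — unreplicated test entries, checks replicated in every
        block (1 rep); ``alpha_lattice`` — 2 complete replications, each split
        into incomplete blocks, checks in every block.
    block_var_ratio
        Block variance as a fraction of the environment's genetic variance.
    """

    kind: str = "augmented"
    n_blocks: int = 14
    n_checks: int = 16
    block_var_ratio: float = 0.2

    @property
    def n_reps(self) -> int:
        return 2 if self.kind == "alpha_lattice" else 1


@dataclass
class SimConfig:
    """Parameters of the synthetic panel; defaults mirror the rice study setup."""

    n_accessions: int = 280
    n_subpops: int = 5
    admixture_conc: float = 0.3
    n_chrom: int = 12
    loci_per_chrom: int = 250
    locus_spacing_kb: float = 20.0
    ld_copy_prob: float = 0.95
    maf_floor: float = 0.02
    missing_rate: float = 0.04
    het_rate: float = 0.01
    pool_size: int = 6
    n_qtl: int = 100
    env_labels: list = field(default_factory=lambda: ["E1", "E2", "E3"])
    h2_target: dict = field(default_factory=lambda: {"E1": 0.75, "E2": 0.76, "E3": 0.84})
    genetic_corr: np.ndarray = field(default_factory=lambda: DEFAULT_GENETIC_CORR.copy())
    design: dict = field(
        default_factory=lambda: {
            "E1": FieldDesign("augmented", n_blocks=14),
            "E2": FieldDesign("alpha_lattice", n_blocks=10),
            "E3": FieldDesign("alpha_lattice", n_blocks=10),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 2:
            raise ConfigError("n_accessions must be >= 2")
        if self.n_subpops < 1:
            raise ConfigError("n_subpops must be >= 1")
        if self.admixture_conc <= 0:
            raise ConfigError("admixture_conc must be > 0")
        if not 0.0 <= self.ld_copy_prob < 1.0:
            raise ConfigError("ld_copy_prob must be in [0, 1)")
        if self.pool_size < 1:
            raise ConfigError("pool_size must be >= 1")
        if not 0.0 <= self.maf_floor <= 0.5:
            raise ConfigError("maf_floor must be in [0, 0.5]")
        for name in ("missing_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.n_qtl > self.n_chrom * self.loci_per_chrom:
            raise ConfigError("n_qtl exceeds the total number of loci")
        J = len(self.env_labels)
        C = np.asarray(self.genetic_corr, dtype=float)
        if C.shape != (J, J):
            raise ConfigError("genetic_corr shape does not match env_labels")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ConfigError("genetic_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ConfigError("genetic_corr must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ConfigError("genetic_corr must be positive semi-definite")
        for env in self.env_labels:
            h2 = self.h2_target.get(env)
            if h2 is None or not 0.0 < h2 <= 1.0:
                raise ConfigError(f"h2_target[{env!r}] must be in (0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated panel (filled in two stages)."""

    subpop_of: pd.Series  # accession -> subpopulation id
    ancestry: pd.DataFrame  # accession × subpop proportions (rows sum to 1)
    qtl_indices: np.ndarray | None = None  # column indices into the genotype matrix
    qtl_effects: np.ndarray | None = None  # env × QTL additive effects
    true_bv: pd.DataFrame | None = None  # accession × env genetic values
    qtl_dosage: np.ndarray | None = None  # clean (pre-missing) QTL dosages
    check_values: pd.DataFrame | None = None  # check × env genetic values


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate the dosage matrix and population structure.

    Reproducible bit-for-bit under a fixed ``config.seed``.  The returned
    matrix contains the injected missing calls; the clean dosages are kept on
    the truth object for downstream phenotype simulation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, K = config.n_accessions, config.n_subpops
    L = config.loci_per_chrom
    c = config.ld_copy_prob

    ancestry = rng.dirichlet(np.full(K, config.admixture_conc), size=n)
    subpop_of = ancestry.argmax(axis=1)

    # ancestral minor-allele frequencies: skewed-low Beta rescaled above the
    # floor (a margin keeps >=95% of realized MAFs above maf_floor after drift)
    p_min = min(0.45, config.maf_floor + 0.10)
    p_anc_all = p_min + (0.5 - p_min) * rng.beta(0.8, 1.6, size=config.n_chrom * L)
    flip_all = rng.random(config.n_chrom * L) < 0.5  # random ref/alt orientation

    hap = np.empty((n, config.n_chrom * L), dtype=np.int8)
    loci_rows = []
    col = 0
    for chrom in range(1, config.n_chrom + 1):
        p_anc = p_anc_all[col : col + L]
        # Balding–Nichols subpopulation frequencies
        a = p_anc * (1 - _FST) / _FST
        b = (1 - p_anc) * (1 - _FST) / _FST
        f_sub = rng.beta(a, b, size=(K, L))
        # pool of ancestral haplotypes per subpopulation
        pool = (rng.random((K, config.pool_size, L)) < f_sub[:, None, :]).astype(np.int8)
        pool_flat = pool.reshape(K * config.pool_size, L)

        # mosaic copying: switch ancestor with prob 1-c at each step
        sub_draw = np.array([rng.choice(K, size=L, p=q) for q in ancestry])
        member = rng.integers(config.pool_size, size=(n, L))
        switch = rng.random((n, L)) < (1 - c)
        switch[:, 0] = True
        seg = np.maximum.accumulate(np.where(switch, np.arange(L), -1), axis=1)
        anc_idx = sub_draw * config.pool_size + member
        anc_idx = np.take_along_axis(anc_idx, seg, axis=1)
        hap[:, col : col + L] = pool_flat[anc_idx, np.arange(L)]

        pos = (np.arange(1, L + 1) * config.locus_spacing_kb * 1000).astype(int)
        for j in range(L):
            loci_rows.append((f"{chrom}_{pos[j]}", str(chrom), int(pos[j]), "A", "T"))
        col += L

    # fully inbred accessions: dosage = 2 x haplotype allele, minor/major
    # orientation randomized per locus
    dose = 2.0 * np.where(flip_all[None, :], 1 - hap, hap)
    clean = dose.copy()
    het_mask = rng.random(dose.shape) < config.het_rate
    dose[het_mask] = 1.0
    miss_mask = rng.random(dose.shape) < config.missing_rate
    dose[miss_mask] = np.nan

    loci = pd.DataFrame(loci_rows, columns=LOCUS_COLUMNS)
    acc_ids = [f"ACC{i+1:04d}" for i in range(n)]
    g = GenotypeMatrix(accession_ids=acc_ids, loci=loci, dosage=dose)
    truth = SimTruth(
        subpop_of=pd.Series(subpop_of, index=acc_ids, name="subpop"),
        ancestry=pd.DataFrame(ancestry, index=acc_ids, columns=[f"P{k+1}" for k in range(K)]),
    )
    truth._clean_dosage = clean
    return g, truth


def simulate_phenotypes(
    g: GenotypeMatrix,
    truth: SimTruth,
    config: SimConfig,
    trait_name: str = "trait",
) -> tuple[dict, SimTruth]:
    """Draw QTL effects, genetic values and plot-level field books.

    QTL effects per environment are multivariate normal across environments
    with correlation ``config.genetic_corr``, so the realized correlation of
    true genetic values matches it up to sampling error.  Residual variance is
    scaled so the plot-level broad-sense heritability matches ``h2_target``;
    block variance is ``block_var_ratio`` times the genetic variance.  Checks
    are fixed genotypes with their own true values, replicated in every block,
    and are not part of the prediction set.

    Returns ``(fieldbooks, truth)`` with one plot-record DataFrame per
    environment (columns: env, entry_id, is_check, block, rep, trait, value).
    """
    config.validate()
    for env in config.env_labels:
        if env not in config.design:
            raise ConfigError(f"no field design descriptor for environment {env!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    J = len(config.env_labels)
    n_loci = g.n_loci

    qtl = np.sort(rng.choice(n_loci, size=config.n_qtl, replace=False))
    C = np.asarray(config.genetic_corr, dtype=float)
    # MVN effects across environments: chol of corr (jitter for PSD-only input)
    Lc = np.linalg.cholesky(C + 1e-10 * np.eye(J))
    effects = (Lc @ rng.standard_normal((J, config.n_qtl)))  # env × QTL

    clean = getattr(truth, "_clean_dosage", None)
    X = clean[:, qtl] if clean is not None else np.nan_to_num(g.dosage[:, qtl])
    bv = X @ effects.T  # accession × env
    bv_df = pd.DataFrame(bv, index=g.accession_ids, columns=config.env_labels)

    truth.qtl_indices = qtl
    truth.qtl_effects = effects
    truth.true_bv = bv_df
    truth.qtl_dosage = X

    check_rows = {}
    fieldbooks: dict[str, pd.DataFrame] = {}
    for j, env in enumerate(config.env_labels):
        design = config.design[env]
        if design.kind not in ("augmented", "alpha_lattice"):
            raise ConfigError(f"unknown design kind {design.kind!r} for {env!r}")
        y_g = bv[:, j]
        sigma2_g = float(np.var(y_g))
        h2 = config.h2_target[env]
        sigma2_e = sigma2_g * (1.0 / h2 - 1.0)
        sigma2_b = design.block_var_ratio * sigma2_g

        check_ids = [f"CHK{k+1:02d}" for k in range(design.n_checks)]
        check_vals = rng.normal(np.mean(y_g), np.std(y_g) if sigma2_g > 0 else 1.0,
                                size=design.n_checks)
        check_rows[env] = pd.Series(check_vals, index=check_ids)

        records = []
        for rep in range(1, design.n_reps + 1):
            order = rng.permutation(g.n_accessions)
            splits = np.array_split(order, design.n_blocks)
            for kb, accs in enumerate(splits, start=1):
                block = f"r{rep}b{kb}"
                b_eff = rng.normal(0.0, np.sqrt(sigma2_b)) if sigma2_b > 0 else 0.0
                for ci, cid in enumerate(check_ids):
                    e = rng.normal(0.0, np.sqrt(sigma2_e)) if sigma2_e > 0 else 0.0
                    records.append((env, cid, True, block, str(rep), trait_name,
                                    check_vals[ci] + b_eff + e))
                for ai in accs:
                    e = rng.normal(0.0, np.sqrt(sigma2_e)) if sigma2_e > 0 else 0.0
                    records.append((env, g.accession_ids[ai], False, block, str(rep),
                                    trait_name, y_g[ai] + b_eff + e))
        fieldbooks[env] = pd.DataFrame(records, columns=FIELDBOOK_COLUMNS)

    truth.check_values = pd.DataFrame(check_rows)
    return fieldbooks, truth


def write_fieldbook(fb: pd.DataFrame, path) -> None:
    fb.to_csv(path, index=False)


def read_fieldbook(path) -> pd.DataFrame:
    fb = pd.read_csv(path, dtype={"block": str, "rep": str, "entry_id": str})
    missing = set(FIELDBOOK_COLUMNS) - set(fb.columns)
    if missing:
        raise ConfigError(f"fieldbook {path} lacks columns: {sorted(missing)}")
    return fb
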