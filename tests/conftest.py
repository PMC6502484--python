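import numpy as np
import pandas as pd
import pytest

from ricegs.genio import GenotypeMatrix
from ricegs import simdata as sd


def make_gm(dosage, chrom=None, start_pos=1000, spacing=1000, ids=None):
    """Build a GenotypeMatrix from a raw dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if chrom is None:
        chrom = ["1"] * m
    pos, counters = [], {}
    for c in chrom:
        counters[c] = counters.get(c, 0) + 1
        pos.append(start_pos + (counters[c] - 1) * spacing)
    loci = pd.DataFrame(
        {
            "locus_id": [f"{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom,
            "pos_bp": pos,
            "ref": "A",
            "alt": "T",
        }
    )
    if ids is None:
        ids = [f"A{i+1}" for i in range(n)]
    return GenotypeMatrix(accession_ids=ids, loci=loci, dosage=dosage)


@pytest.fixture
def tiny_gm():
    """4 accessions × 4 loci with one missing call."""
    return make_gm(
        [
            [0, 1, 2, 0],
            [0, 0, 1, 1],
            [1, 0, 0, np.nan],
            [2, 0, 1, 1],
        ]
    )


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated two-environment panel shared across test modules."""
    cfg = sd.SimConfig(
        n_accessions=150,
        n_chrom=2,
        loci_per_chrom=120,
        seed=17,
        env_labels=["E1", "E2"],
        h2_target={"E1": 0.7, "E2": 0.7},
        genetic_corr=np.array([[1.0, 0.8], [0.8, 1.0]]),
        design={
            "E1": sd.FieldDesign("augmented", n_blocks=8),
            "E2": sd.FieldDesign("alpha_lattice", n_blocks=6),
        },
    )
    g, truth = sd.simulate_genotypes(cfg)
    fieldbooks, truth = sd.simulate_phenotypes(g, truth, cfg)
    return cfg, g, truth, fieldbooks
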