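import numpy as np
import pandas as pd
import pytest

from crisprscan import genotypes, simulate


@pytest.fixture(scope="session")
def small_screen():
    """A small simulated screen with one planted hotspot window."""
    spec = simulate.ScreenSimSpec(
        protein_length=300,
        n_sgrnas=120,
        n_controls=24,
        hotspots=[(100, 130, 3.0)],
    )
    return simulate.simulate_screen(spec, seed=11)


@pytest.fixture(scope="session")
def toy_gene():
    """Two-exon toy gene model: 60 nt exon / 30 nt intron / 60 nt exon."""
    return simulate.make_toy_gene(np.random.default_rng(42))


@pytest.fixture(scope="session")
def flat_gene():
    """Single-exon gene whose amplicon is exactly the (stop-free) CDS."""
    rng = np.random.default_rng(3)
    from Bio.Seq import Seq

    while True:
        cds = "".join(rng.choice(list("ACGT"), size=60))
        if "*" not in str(Seq(cds).translate()):
            break
    return genotypes.GeneModel(amplicon=cds, exons=[(1, 60)], cds_offset=0)


@pytest.fixture(scope="session")
def gof_alleles(toy_gene):
    sim = simulate.simulate_allele_tables(
        simulate.AlleleSimSpec(regime="GOF"), seed=21, gene=toy_gene
    )
    merged = genotypes.merge_conditions(sim.vehicle, sim.drug, sim.gene)
    return genotypes.filter_and_normalize(merged)


def make_class_table(rows):
    """Hand-built filtered allele table for arithmetic tests.

    ``rows``: list of (allele, classification, freq_vehicle, freq_drug).
    """
    df = pd.DataFrame(
        rows, columns=["allele", "classification", "freq_vehicle", "freq_drug"]
    )
    df["lof"] = df["classification"].isin(genotypes.LOF_CLASSES)
    df["reads_vehicle"] = (df["freq_vehicle"] * 100).astype(int)
    df["reads_drug"] = (df["freq_drug"] * 100).astype(int)
    df.attrs["total_reads"] = {"vehicle": 10_000, "drug": 10_000}
    return df
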