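import numpy as np
import pandas as pd
import pytest

from curdpred import simulate
from curdpred.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def structured_panel():
    """Mid-size structured panel with LD and one oligogenic trait (cached)."""
    cfg = simulate.SimConfig(
        n_individuals=120,
        n_chromosomes=3,
        markers_per_chromosome=150,
        n_clusters=3,
        F=0.25,
        ld_correlation=0.7,
        traits=(simulate.TraitSpec(name="t", n_qtl=8, h2=0.7),),
    )
    G, truth = simulate.simulate_population(cfg, seed=11)
    return cfg, G, truth


@pytest.fixture(scope="session")
def trait_vector(structured_panel):
    """Entry-mean phenotype at the trait's target heritability."""
    cfg, G, truth = structured_panel
    rng = np.random.default_rng(77)
    g = truth.genetic_values["t"]
    y = g + rng.normal(0.0, np.sqrt(1 / 0.7 - 1.0), G.n_individuals)
    return y


def toy_matrix(dosages, chrom=None, pos=None):
    """Small GenotypeMatrix from a literal dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = chrom if chrom is not None else ["C1"] * m
    pos = pos if pos is not None else list(range(100, 100 + m * 10, 10))
    markers = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "C"})
    return GenotypeMatrix(
        ids=[f"i{k}" for k in range(n)], markers=markers, dosages=dosages
    )
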