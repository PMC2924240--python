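import numpy as np
import pytest

from codonga import (
    CodonAlignment,
    GeneticCode,
    ModelParameters,
    ModelStructure,
    Phylogeny,
    SimulationDesign,
    simulate_alignment,
)


@pytest.fixture(scope="session")
def code():
    return GeneticCode.universal()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_parameters(code, rng, K=2, freq_mode="MG"):
    """Random valid model parameters for property checks."""
    nuc = rng.uniform(0.3, 3.0, size=6)
    rates = rng.uniform(0.05, 3.0, size=K)
    if freq_mode == "MG":
        pf = rng.dirichlet(np.full(4, 5.0), size=3)
        return ModelParameters(nuc, rates, "MG", position_freqs=pf)
    cf = rng.dirichlet(np.full(code.n_sense, 5.0))
    return ModelParameters(nuc, rates, "F61", codon_freqs=cf)


@pytest.fixture(scope="session")
def small_alignment(code):
    """A deterministic 4-taxon alignment of 40 codons with some missing data."""
    design = SimulationDesign(n_taxa=4, divergence=0.3, n_codon_sites=40,
                              class_rates=(0.2, 1.0), seed=99)
    aln, structure, tree, params = simulate_alignment(design, 0, code)
    codes = aln.codes.copy()
    codes[0, 3] = -1
    codes[2, 7] = -1
    return CodonAlignment(aln.names, codes, code), tree


@pytest.fixture(scope="session")
def two_taxon_sim(code):
    design = SimulationDesign(n_taxa=2, divergence=0.2, n_codon_sites=2000,
                              class_rates=(0.25, 1.0), seed=7)
    return simulate_alignment(design, 0, code)
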