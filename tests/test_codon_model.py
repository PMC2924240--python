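"""Rate-matrix construction: frequencies, reversibility, structural zeros."""

import numpy as np
import pytest

from codonga import (
    CodonAlignment,
    ModelParameters,
    ModelStructure,
    PhyloEvaluator,
    Phylogeny,
    build_rate_matrix,
    expected_substitution_rate,
    f61_frequencies,
    mg_codon_frequencies,
    solve_unit_time,
)
from codonga.codon_model import RateMatrix, RateMatrixBuilder
from codonga.genetic_code import NUC_PAIR_INDEX

from conftest import random_parameters


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def test_structure_extremes():
    sr = ModelStructure.single_rate()
    rev = ModelStructure.rev()
    assert sr.K == 1 and len(set(sr.assignment)) == 1
    assert rev.K == 75 and len(set(rev.assignment)) == 75


def test_structure_requires_all_labels():
    with pytest.raises(ValueError):
        ModelStructure((0,) * 74 + (2,), 3)


def test_canonicalize_by_rates_orders_increasing():
    s = ModelStructure((1, 0) * 37 + (1,), 2)
    canon, rates = s.canonicalize_by_rates([2.0, 0.5])
    assert list(rates) == [0.5, 2.0]
    # old class 1 (rate 0.5) becomes class 0
    assert canon.assignment[0] == 0 and canon.assignment[1] == 1


def test_canonical_key_is_relabeling_invariant():
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 3, size=75)
    labels[:3] = [0, 1, 2]
    a = ModelStructure.from_labels(labels)
    b = ModelStructure.from_labels([(x + 1) % 3 for x in labels])
    assert a.canonical_key() == b.canonical_key()


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def test_mg_uniform_frequencies(code):
    pi = mg_codon_frequencies(np.full((3, 4), 0.25), code)
    assert pi.shape == (61,)
    np.testing.assert_allclose(pi, 1.0 / 61, rtol=1e-12)


def test_mg_frequencies_normalized(code, rng):
    pf = rng.dirichlet(np.full(4, 2.0), size=3)
    pi = mg_codon_frequencies(pf, code)
    assert pytest.approx(pi.sum(), rel=1e-12) == 1.0
    assert np.all(pi >= 0)


def test_mg_rejects_bad_input(code):
    with pytest.raises(ValueError):
        mg_codon_frequencies(np.full((3, 4), 0.3), code)  # rows don't sum to 1


def test_f61_single_codon_and_smoothing(code):
    counts = np.zeros(61)
    counts[code.codon_index["ATG"]] = 50
    pi = f61_frequencies(counts, code)
    assert pi[code.codon_index["ATG"]] == pytest.approx(50 / (50 + 60))
    assert np.all(pi > 0)  # pseudo-counts remove structural zeros
    assert pi.sum() == pytest.approx(1.0)


def test_f61_uniform(code):
    pi = f61_frequencies(np.full(61, 7.0), code)
    np.testing.assert_allclose(pi, 1.0 / 61)


def test_f61_empty_rejected(code):
    with pytest.raises(ValueError):
        f61_frequencies(np.zeros(61), code)


# ---------------------------------------------------------------------------
# rate matrix properties
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("freq_mode", ["MG", "F61"])
@pytest.mark.parametrize("trial", range(3))
def test_rate_matrix_properties_randomized(code, freq_mode, trial):
    """Row sums zero, detailed balance, structural multi-step zeros."""
    rng = np.random.default_rng(100 + trial)
    params = random_parameters(code, rng, K=3, freq_mode=freq_mode)
    structure = ModelStructure.from_labels(
        np.r_[0, 1, 2, rng.integers(0, 3, size=72)])
    rm = build_rate_matrix(structure, params, code)
    np.testing.assert_allclose(rm.Q.sum(axis=1), 0.0, atol=1e-12)
    assert np.all(rm.Q - np.diag(np.diag(rm.Q)) >= 0)
    flux = rm.pi[:, None] * rm.Q
    np.testing.assert_allclose(flux, flux.T, atol=1e-14)
    # multi-step entries are exactly zero without the extension
    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            nd = sum(a != b for a, b in zip(ci, cj))
            if nd > 1:
                assert rm.Q[i, j] == 0.0


def test_k1_collapse_to_single_rate(code, rng):
    """With one class, every non-synonymous entry is omega times the
    matched synonymous-form entry."""
    omega = 0.37
    params = random_parameters(code, rng, K=1, freq_mode="F61").with_class_rates([omega])
    rm = build_rate_matrix(ModelStructure.single_rate(), params, code,
                          normalize=False)
    nt_idx = NUC_PAIR_INDEX
    for i, j, pos, pc in code.one_step_codon_pairs():
        ci, cj = code.sense_codons[i], code.sense_codons[j]
        key = "".join(sorted((ci[pos], cj[pos])))
        base = params.nuc_rates[nt_idx[key]] * params.codon_freqs[j] / params.codon_freqs.sum()
        expected = base * (omega if pc.kind == "nonsynonymous_1step" else 1.0)
        assert rm.Q[i, j] == pytest.approx(expected, rel=1e-9)


def test_relabeling_invariance(code, rng):
    params = random_parameters(code, rng, K=2)
    labels = np.r_[0, 1, rng.integers(0, 2, size=73)]
    s1 = ModelStructure.from_labels(labels)
    s2 = ModelStructure(tuple(int(x) for x in 1 - labels), 2)  # swapped labels
    rm1 = build_rate_matrix(s1, params, code)
    rm2 = build_rate_matrix(
        s2, params.with_class_rates(params.class_rates[::-1]), code)
    np.testing.assert_allclose(rm1.Q, rm2.Q, atol=1e-13)


def test_multistep_extension_entries(code):
    """Two-difference entries equal the product of the nucleotide rates,
    target frequency and the matching multi-step parameter; zero without."""
    rng = np.random.default_rng(5)
    nuc = rng.uniform(0.5, 2.0, size=6)
    cf = rng.dirichlet(np.full(61, 5.0))
    ms = np.array([0.07, 0.02, 0.05, 0.01])  # syn2, syn3, nonsyn2, nonsyn3
    params = ModelParameters(nuc, np.array([0.5]), "F61", codon_freqs=cf,
                             multistep=ms)
    rm = build_rate_matrix(ModelStructure.single_rate(), params, code,
                          normalize=False)
    i = code.codon_index["AGT"]
    j = code.codon_index["TCT"]
    # AGT -> TCT (Ser -> Ser): A/T at pos 0, G/C at pos 1
    expected = nuc[NUC_PAIR_INDEX["AT"]] * nuc[NUC_PAIR_INDEX["CG"]] * \
        (cf[j] / cf.sum()) * ms[0]
    assert rm.Q[i, j] == pytest.approx(expected, rel=1e-9)
    # Lys -> Pro, AAA -> CCC, three transversions, non-synonymous
    i3, j3 = code.codon_index["AAA"], code.codon_index["CCC"]
    expected3 = nuc[NUC_PAIR_INDEX["AC"]] ** 3 * (cf[j3] / cf.sum()) * ms[3]
    assert rm.Q[i3, j3] == pytest.approx(expected3, rel=1e-9)
    # without the extension the same entry is exactly zero
    rm0 = build_rate_matrix(ModelStructure.single_rate(),
                            ModelParameters(nuc, np.array([0.5]), "F61",
                                            codon_freqs=cf), code)
    assert rm0.Q[i, j] == 0.0


def test_expected_rate_and_unit_time(code, rng):
    params = random_parameters(code, rng, K=2)
    structure = ModelStructure.from_labels(np.r_[0, 1, rng.integers(0, 2, 73)])
    rm = build_rate_matrix(structure, params, code, normalize=False)
    mu = expected_substitution_rate(rm)
    # row-sum identity: mu equals total off-diagonal flux
    off = rm.Q - np.diag(np.diag(rm.Q))
    assert mu == pytest.approx(float(rm.pi @ off.sum(axis=1)), rel=1e-12)
    assert solve_unit_time(rm) == pytest.approx(1.0 / mu)
    # scaling linearity
    rm2 = RateMatrix(Q=2 * rm.Q, pi=rm.pi, mu=2 * mu)
    assert expected_substitution_rate(rm2) == pytest.approx(2 * mu)
    assert solve_unit_time(rm2) == pytest.approx(0.5 / mu)


def test_normalized_matrix_unit_nucleotide_rate(code, rng):
    params = random_parameters(code, rng, K=1)
    rm = build_rate_matrix(ModelStructure.single_rate(), params, code)
    assert expected_substitution_rate(rm) == pytest.approx(3.0)  # per codon site


def test_mg_gy_equivalence_on_matched_frequencies(code):
    """The MG and GY parameterizations share the stationary distribution
    whenever the codon frequencies equal the MG product distribution, and
    at uniform positional frequencies the matrices (hence likelihoods)
    coincide exactly.  With non-uniform products the frequency factors
    differ entrywise (positional vs whole-codon), so only the uniform case
    is an identity."""
    rng = np.random.default_rng(11)
    structure = ModelStructure.from_labels(np.r_[0, 1, rng.integers(0, 2, 73)])
    rates = np.array([0.3, 1.2])
    nuc = rng.uniform(0.5, 2.0, 6)
    # general product frequencies: stationary distributions agree
    pf = rng.dirichlet(np.full(4, 8.0), size=3)
    pi = mg_codon_frequencies(pf, code)
    rm_mg = build_rate_matrix(structure,
                              ModelParameters(nuc, rates, "MG",
                                              position_freqs=pf), code)
    rm_gy = build_rate_matrix(structure,
                              ModelParameters(nuc, rates, "F61",
                                              codon_freqs=pi), code)
    np.testing.assert_allclose(rm_mg.pi, rm_gy.pi, atol=1e-12)
    # uniform positional frequencies: full matrix identity and equal lnL
    pf_u = np.full((3, 4), 0.25)
    pi_u = mg_codon_frequencies(pf_u, code)
    rm_mg = build_rate_matrix(structure,
                              ModelParameters(nuc, rates, "MG",
                                              position_freqs=pf_u), code)
    rm_gy = build_rate_matrix(structure,
                              ModelParameters(nuc, rates, "F61",
                                              codon_freqs=pi_u), code)
    np.testing.assert_allclose(rm_mg.Q, rm_gy.Q, atol=1e-12)
    from codonga import SimulationDesign, simulate_alignment
    aln, _, tree, _ = simulate_alignment(
        SimulationDesign(n_taxa=4, divergence=0.3, n_codon_sites=30,
                         class_rates=(0.5,), seed=3), 0, code)
    ev = PhyloEvaluator(aln, tree)
    assert ev.log_likelihood(rm_mg) == pytest.approx(ev.log_likelihood(rm_gy),
                                                     abs=1e-6)


def test_builder_rejects_inconsistent_rates(code, rng):
    params = random_parameters(code, rng, K=2)
    with pytest.raises(ValueError):
        build_rate_matrix(ModelStructure.single_rate(),
                          params, code)  # K mismatch: 2 rates, 1 class
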