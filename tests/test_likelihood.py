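"""Pruning likelihood against exhaustive oracles; ML fitting behavior."""

import itertools

import numpy as np
import pytest

from codonga import (
    CodonAlignment,
    ModelParameters,
    ModelStructure,
    PhyloEvaluator,
    Phylogeny,
    SimulationDesign,
    SpectralMatrix,
    build_rate_matrix,
    count_parameters,
    fit_branch_lengths,
    fit_model,
    sample_size,
    simulate_alignment,
)
from codonga.likelihood import fit_class_rates
from codonga.codon_model import RateMatrixBuilder

from conftest import random_parameters


def brute_force_lnl_3taxon(aln, tree, rm):
    """Exhaustive oracle: sum over all internal-node state combinations.

    Assumes the shape ((A,B),C) with two internal nodes (root and the AB
    ancestor); complexity 61^2 per site, practical for <= 5 sites.
    """
    sm = SpectralMatrix(rm)
    P = {v: sm.transition(tree.lengths[v]) for v in range(tree.n_nodes)
         if tree.parent[v] >= 0}
    root = tree.root
    (inner,) = [v for v in tree.children[root] if not tree.is_leaf(v)]
    (leaf_c,) = [v for v in tree.children[root] if tree.is_leaf(v)]
    leaf_a, leaf_b = tree.children[inner]
    row = {tree.leaf_names[v]: aln.names.index(tree.leaf_names[v])
           for v in (leaf_a, leaf_b, leaf_c)}
    n = len(rm.pi)
    total = 0.0
    for s in range(aln.n_codon_sites):
        a = aln.codes[row[tree.leaf_names[leaf_a]], s]
        b = aln.codes[row[tree.leaf_names[leaf_b]], s]
        c = aln.codes[row[tree.leaf_names[leaf_c]], s]
        lik = 0.0
        for r_state in range(n):
            pc = P[leaf_c][r_state, c] if c >= 0 else 1.0
            for m_state in range(n):
                pa = P[leaf_a][m_state, a] if a >= 0 else 1.0
                pb = P[leaf_b][m_state, b] if b >= 0 else 1.0
                lik += (rm.pi[r_state] * P[inner][r_state, m_state]
                        * pa * pb * pc)
        total += np.log(lik)
    return total


@pytest.fixture(scope="module")
def tiny_3taxon(code):
    design = SimulationDesign(n_taxa=4, divergence=0.4, n_codon_sites=5,
                              class_rates=(0.3, 1.2), seed=42)
    aln4, _, _, _ = simulate_alignment(design, 0, code)
    aln = CodonAlignment(aln4.names[:3], aln4.codes[:3].copy(), code)
    aln.codes[1, 2] = -1  # one missing codon
    names = aln4.names
    tree = Phylogeny.from_newick(
        f"(({names[0]}:0.07,{names[1]}:0.12):0.05,{names[2]}:0.21);")
    return aln, tree


def test_pruning_matches_exhaustive_summation(code, tiny_3taxon, rng):
    aln, tree = tiny_3taxon
    params = random_parameters(code, rng, K=2)
    structure = ModelStructure.from_labels(np.r_[0, 1, rng.integers(0, 2, 73)])
    rm = build_rate_matrix(structure, params, code)
    ev = PhyloEvaluator(aln, tree)
    assert ev.log_likelihood(rm) == pytest.approx(
        brute_force_lnl_3taxon(aln, tree, rm), abs=1e-8)


def test_root_placement_invariance(code, rng):
    """The pulley principle: rerooting along the central edge of a 4-taxon
    tree leaves the likelihood of a reversible model unchanged."""
    design = SimulationDesign(n_taxa=4, divergence=0.4, n_codon_sites=30,
                              class_rates=(0.5,), seed=8)
    aln, _, _, _ = simulate_alignment(design, 0, code)
    a, b, c, d = aln.names
    t1 = Phylogeny.from_newick(f"(({a}:0.1,{b}:0.2):0.05,({c}:0.15,{d}:0.25):0.07);")
    t2 = Phylogeny.from_newick(f"(({a}:0.1,{b}:0.2):0.12,({c}:0.15,{d}:0.25):0.0);")
    t3 = Phylogeny.from_newick(f"(({a}:0.1,{b}:0.2):0.0,({c}:0.15,{d}:0.25):0.12);")
    params = random_parameters(code, rng, K=1)
    rm = build_rate_matrix(ModelStructure.single_rate(), params, code)
    vals = [PhyloEvaluator(aln, t).log_likelihood(rm) for t in (t1, t2, t3)]
    assert vals[0] == pytest.approx(vals[1], abs=1e-8)
    assert vals[0] == pytest.approx(vals[2], abs=1e-8)


def test_identical_sequences_zero_branches(code):
    """Zero-time transitions are the identity, so lnL is just the
    stationary log-probabilities of the observed states."""
    seq = "ATGTTTGGCACC"
    aln = CodonAlignment.from_sequences({"x": seq, "y": seq}, code)
    tree = Phylogeny.from_newick("(x:0.0,y:0.0);")
    params = ModelParameters.default(1)
    rm = build_rate_matrix(ModelStructure.single_rate(), params, code)
    expected = sum(np.log(rm.pi[aln.codes[0, s]]) for s in range(4))
    assert PhyloEvaluator(aln, tree).log_likelihood(rm) == pytest.approx(expected)


def test_likelihood_invariant_to_column_and_taxon_order(code, small_alignment):
    aln, tree = small_alignment
    params = ModelParameters.default(1)
    rm = build_rate_matrix(ModelStructure.single_rate(), params, code)
    base = PhyloEvaluator(aln, tree).log_likelihood(rm)
    rng = np.random.default_rng(3)
    perm = rng.permutation(aln.n_codon_sites)
    shuffled = CodonAlignment(aln.names, aln.codes[:, perm], code)
    assert PhyloEvaluator(shuffled, tree).log_likelihood(rm) == pytest.approx(base)
    order = rng.permutation(aln.n_taxa)
    retaxed = CodonAlignment([aln.names[i] for i in order],
                             aln.codes[order], code)
    assert PhyloEvaluator(retaxed, tree).log_likelihood(rm) == pytest.approx(base)


def test_per_site_log_likelihoods_negative(code, small_alignment):
    aln, tree = small_alignment
    rm = build_rate_matrix(ModelStructure.single_rate(),
                           ModelParameters.default(1), code)
    lnl = PhyloEvaluator(aln, tree).log_likelihood(rm)
    assert lnl / aln.n_codon_sites < 0


def test_taxon_mismatch_rejected(code, small_alignment):
    aln, _ = small_alignment
    tree = Phylogeny.from_newick("(whoever:0.1,elsewho:0.1);")
    with pytest.raises(ValueError, match="mismatch"):
        PhyloEvaluator(aln, tree)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_single_rate_recovery(code):
    """Simulation-recovery: the fitted class rate approaches the generating
    omega on a long two-sequence alignment."""
    design = SimulationDesign(n_taxa=2, divergence=0.3, n_codon_sites=4000,
                              class_rates=(0.2,), seed=13)
    aln, structure, tree, _ = simulate_alignment(design, 0, code)
    fr = fit_model(structure, aln, tree, rounds=2)
    assert fr.params.class_rates[0] == pytest.approx(0.2, abs=0.03)
    assert fr.branch_lengths.sum() == pytest.approx(0.3, abs=0.04)


def test_refit_is_fixed_point(code, two_taxon_sim):
    aln, structure, tree, _ = two_taxon_sim
    fr = fit_model(structure, aln, tree, rounds=2)
    fr2 = fit_model(structure, aln, tree, start=fr.params,
                    start_lengths=fr.branch_lengths, rounds=1)
    assert abs(fr2.lnL - fr.lnL) < 0.05


def test_nested_models_order_likelihood(code, two_taxon_sim):
    """A K=2 fit started from the merged K=1 solution can only improve."""
    aln, structure, tree, _ = two_taxon_sim
    ev = PhyloEvaluator(aln, tree)
    sr = fit_model(ModelStructure.single_rate(), aln, tree, rounds=1,
                   evaluator=ev)
    builder = RateMatrixBuilder(code, sr.params.nuc_rates, "MG",
                                position_freqs=sr.params.position_freqs)
    lnl1, _ = fit_class_rates(ev, builder, ModelStructure.single_rate(),
                              sr.params.class_rates, sr.branch_lengths)
    lnl2, _ = fit_class_rates(ev, builder, structure.canonical_key(),
                              np.repeat(sr.params.class_rates, 2),
                              sr.branch_lengths)
    assert lnl2 >= lnl1 - 1e-6


def test_branch_lengths_zero_for_identical_children(code):
    seq = "ATGTTTGGCACCGAGCTG" * 10
    aln = CodonAlignment.from_sequences({"x": seq, "y": seq}, code)
    tree = Phylogeny.from_newick("(x:0.05,y:0.05);")
    rm = build_rate_matrix(ModelStructure.single_rate(),
                           ModelParameters.default(1), code)
    lengths, _ = fit_branch_lengths(PhyloEvaluator(aln, tree), rm)
    assert lengths.sum() < 1e-3


@pytest.mark.parametrize("K,freq_mode,expected", [
    (1, "MG", 1 + 5 + 9),      # single-rate: 1 non-synonymous parameter
    (75, "MG", 75 + 5 + 9),    # fully general: 75
    (4, "MG", 4 + 5 + 9),      # structured: K
    (1, "F61", 1 + 5 + 60),    # F61 frequencies: 60 free parameters
])
def test_parameter_counts(K, freq_mode, expected):
    assert count_parameters(K, freq_mode) == expected


def test_parameter_count_extensions():
    assert count_parameters(2, "F61", multistep=True) == 2 + 5 + 60 + 4
    assert count_parameters(0, "MG", omega_s=True) == 0 + 5 + 9 + 1
    assert count_parameters(1, "MG", n_branches=5,
                            include_branch_lengths=True) == 15 + 5


def test_sample_size_conventions(code, small_alignment):
    aln, _ = small_alignment
    assert sample_size(aln) == aln.n_taxa * aln.n_codon_sites
    assert sample_size(aln, "sites") == aln.n_codon_sites
    assert sample_size(aln, "nucleotides") == 3 * aln.n_taxa * aln.n_codon_sites
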