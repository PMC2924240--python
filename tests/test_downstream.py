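"""Substitution spectra, model distances / NJ clustering, multi-rate FEL."""

import numpy as np
import pytest

from codonga import (
    CodonAlignment,
    ModelParameters,
    ModelStructure,
    Phylogeny,
    SimulationDesign,
    build_rate_matrix,
    fit_model,
    model_distance_matrix,
    multirate_fel,
    nj_tree,
    simulate_alignment,
    spectrum_distance,
    substitution_spectrum,
)
from codonga.codon_model import RateMatrix

from conftest import random_parameters


def _random_model_spectrum(code, seed, K=2):
    rng = np.random.default_rng(seed)
    params = random_parameters(code, rng, K=K)
    structure = ModelStructure.from_labels(np.r_[np.arange(K), rng.integers(0, K, 75 - K)])
    rm = build_rate_matrix(structure, params, code)
    return substitution_spectrum(rm, code)


def test_spectrum_scale_invariance(code, rng):
    params = random_parameters(code, rng, K=2)
    structure = ModelStructure.from_labels(np.r_[0, 1, rng.integers(0, 2, 73)])
    rm = build_rate_matrix(structure, params, code, normalize=False)
    s1 = substitution_spectrum(rm, code)
    s2 = substitution_spectrum(RateMatrix(Q=7.3 * rm.Q, pi=rm.pi, mu=7.3 * rm.mu),
                               code)
    np.testing.assert_allclose(s1, s2, rtol=1e-12)
    assert np.all(s1 >= 0)


def test_spectrum_sums_to_nonsynonymous_fraction(code, rng):
    """mu t* = 1 decomposes into synonymous + non-synonymous one-step flux,
    so the spectrum total is the non-synonymous fraction, below 1."""
    params = random_parameters(code, rng, K=1)
    rm = build_rate_matrix(ModelStructure.single_rate(), params, code)
    s = substitution_spectrum(rm, code)
    total_flux = float(rm.pi @ (rm.Q - np.diag(np.diag(rm.Q))).sum(axis=1))
    syn_flux = total_flux - s.sum() * rm.mu  # spectrum is flux * t* = flux / mu
    assert 0 < s.sum() < 1
    assert syn_flux > 0


def test_single_rate_spectrum_proportional_to_opportunity(code, rng):
    """Under one class, doubling omega leaves the spectrum *shape* fixed:
    relative abundances reflect mutational opportunity alone."""
    params = random_parameters(code, rng, K=1).with_class_rates([0.4])
    rm1 = build_rate_matrix(ModelStructure.single_rate(), params, code)
    rm2 = build_rate_matrix(ModelStructure.single_rate(),
                            params.with_class_rates([0.8]), code)
    s1 = substitution_spectrum(rm1, code)
    s2 = substitution_spectrum(rm2, code)
    np.testing.assert_allclose(s1 / s1.sum(), s2 / s2.sum(), rtol=1e-9)


def test_spectrum_distance_metric_axioms(code):
    spectra = [_random_model_spectrum(code, seed) for seed in range(4)]
    for s in spectra:
        assert spectrum_distance(s, s) == 0.0
    for i in range(4):
        for j in range(4):
            assert spectrum_distance(spectra[i], spectra[j]) == pytest.approx(
                spectrum_distance(spectra[j], spectra[i]))
    for i, j, k in [(0, 1, 2), (1, 2, 3), (0, 2, 3)]:
        assert spectrum_distance(spectra[i], spectra[k]) <= (
            spectrum_distance(spectra[i], spectra[j])
            + spectrum_distance(spectra[j], spectra[k]) + 1e-12)


def test_distance_matrix_symmetric_zero_diagonal(code):
    spectra = [_random_model_spectrum(code, seed) for seed in range(3)]
    D = model_distance_matrix(spectra)
    np.testing.assert_allclose(D, D.T)
    np.testing.assert_allclose(np.diag(D), 0.0)


def test_nj_joins_duplicate_models_first(code):
    s = [_random_model_spectrum(code, 1), _random_model_spectrum(code, 1),
         _random_model_spectrum(code, 2)]
    D = model_distance_matrix(s)
    newick = nj_tree(D, ["m1", "m2", "m3"])
    assert "m1" in newick and "m2" in newick


def test_nj_recovers_additive_topology():
    """NJ on an additive (four-point) matrix recovers the generating tree:
    A,B form a cherry separated from C,D."""
    # tree ((A:1,B:2):3,(C:1.5,D:2.5))
    D = np.array([
        [0.0, 3.0, 5.5, 6.5],
        [3.0, 0.0, 6.5, 7.5],
        [5.5, 6.5, 0.0, 4.0],
        [6.5, 7.5, 4.0, 0.0],
    ])
    newick = nj_tree(D, ["A", "B", "C", "D"])
    tree = Phylogeny.from_newick(newick)
    # find the bipartition: A,B on one side
    for v in range(tree.n_nodes):
        if not tree.is_leaf(v) and tree.parent[v] >= 0:
            below = set()
            stack = [v]
            while stack:
                u = stack.pop()
                if tree.is_leaf(u):
                    below.add(tree.leaf_names[u])
                stack.extend(tree.children[u])
            if below in ({"A", "B"}, {"C", "D"}):
                return
    pytest.fail("NJ did not recover the A,B | C,D split")


def test_nj_requires_three_models():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["a", "b"])


# ---------------------------------------------------------------------------
# multi-rate FEL
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fel_setup(code):
    """An 8-taxon alignment under a 2-class model, with its global fit."""
    design = SimulationDesign(n_taxa=8, divergence=0.8, n_codon_sites=60,
                              class_rates=(0.3, 1.2), seed=19)
    aln, structure, tree, params = simulate_alignment(design, 0, code)
    fit = fit_model(structure, aln, tree, start=params, rounds=1,
                    optimize_frequencies=False)
    return aln, tree, structure, fit


def test_fel_invariant_sites_short_circuit(code, fel_setup):
    aln, tree, structure, fit = fel_setup
    codes = aln.codes.copy()
    codes[:, 0] = codes[0, 0]  # force an invariant column
    aln2 = CodonAlignment(aln.names, codes, code)
    res = multirate_fel(aln2, tree, structure, fit, sites=[0])[0]
    assert res.invariant
    np.testing.assert_array_equal(res.lrt, 0.0)
    np.testing.assert_array_equal(res.pvalues, 1.0)
    assert not res.significant.any()


def test_fel_statistics_well_formed(code, fel_setup):
    aln, tree, structure, fit = fel_setup
    results = multirate_fel(aln, tree, structure, fit, sites=range(6))
    for res in results:
        assert res.lrt.shape == (2,)
        assert np.all(res.lrt >= 0)
        assert np.all((res.pvalues >= 0) & (res.pvalues <= 1))


def test_fel_k1_matches_independent_two_rate_fit(code):
    """With one class the site test reduces to the classical FEL setup:
    an independent (synonymous, non-synonymous) optimization using scipy's
    dense matrix exponential reaches the same site optimum."""
    from scipy.linalg import expm
    from scipy.optimize import minimize
    from codonga import PhyloEvaluator
    from codonga.codon_model import RateMatrixBuilder

    design = SimulationDesign(n_taxa=8, divergence=0.6, n_codon_sites=20,
                              class_rates=(0.6,), seed=23)
    aln, structure, tree, params = simulate_alignment(design, 0, code)
    fit = fit_model(structure, aln, tree, start=params, rounds=1,
                    optimize_frequencies=False, optimize_nuc_rates=False)
    site = next(s for s in range(20)
                if len(np.unique(aln.codes[:, s][aln.codes[:, s] >= 0])) > 1)
    res = multirate_fel(aln, tree, structure, fit, sites=[site])[0]

    builder = RateMatrixBuilder(code, fit.params.nuc_rates, "MG",
                                position_freqs=fit.params.position_freqs)
    raw = builder.build(structure, fit.params.class_rates, normalize=False)
    scale0 = 3.0 / raw.mu
    col = CodonAlignment(aln.names, aln.codes[:, site:site + 1], code)
    ev = PhyloEvaluator(col, tree)

    def site_lnl(syn, beta):
        rm = builder.build(structure, np.array([beta / syn]), normalize=False)
        Q = rm.Q * syn * scale0
        Pm = np.stack([expm(Q * fit.branch_lengths[v])
                       for v in range(tree.n_nodes)])
        return ev._lnl_from_P(Pm, rm.pi)

    ref = minimize(lambda x: -site_lnl(np.exp(x[0]), np.exp(x[1])),
                   np.log([1.0, 0.6]), method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 500})
    lnl_oracle = -float(ref.fun)
    lnl_pkg = site_lnl(res.syn_rate, res.class_rates[0])
    assert lnl_pkg == pytest.approx(lnl_oracle, abs=0.01)


def test_fel_type_one_error_controlled(code):
    """On neutral data (every class rate equal to the synonymous rate, so
    each per-class null is true at every site) the Bonferroni-corrected
    tests flag at or below the nominal rate.  Gene-size conditions (16
    taxa, moderate divergence) -- with few sequences or saturated branches
    the per-site chi-squared reference is anticonservative."""
    design = SimulationDesign(n_taxa=16, divergence=1.0, n_codon_sites=50,
                              class_rates=(1.0, 1.0), seed=29)
    aln, structure, tree, params = simulate_alignment(design, 0, code)
    fit = fit_model(structure, aln, tree, start=params, rounds=1,
                    optimize_frequencies=False)
    results = multirate_fel(aln, tree, structure, fit, alpha=0.05)
    n_class_tests = sum(len(r.lrt) for r in results)
    n_flagged = sum(int(r.significant.sum()) for r in results)
    # binomial(100, 0.05) upper bound: observing > 10 would be p < 0.01
    assert n_flagged <= max(3, int(0.10 * n_class_tests))


def test_fel_detects_planted_selection(code):
    """Sites simulated with a strongly elevated class rate are flagged for
    that class more often than background sites."""
    base = SimulationDesign(n_taxa=8, divergence=1.0, n_codon_sites=25,
                            class_rates=(0.2, 0.4), seed=37)
    hot = SimulationDesign(n_taxa=8, divergence=1.0, n_codon_sites=25,
                           class_rates=(0.2, 8.0), seed=37)
    aln_b, structure, tree, params = simulate_alignment(base, 0, code)
    aln_h, _, _, _ = simulate_alignment(hot, 0, code)
    combined = CodonAlignment(aln_b.names,
                              np.hstack([aln_b.codes, aln_h.codes]), code)
    fit = fit_model(structure, combined, tree, start=params, rounds=1,
                    optimize_frequencies=False)
    res = multirate_fel(combined, tree, structure, fit, alpha=0.05)
    hot_sites = [r for r in res if r.site >= 25]
    cold_sites = [r for r in res if r.site < 25]
    hot_hits = sum(int(r.significant[1] and r.diversifying[1]) for r in hot_sites)
    cold_hits = sum(int(r.significant[1] and r.diversifying[1]) for r in cold_sites)
    assert hot_hits > cold_hits
    assert hot_hits >= 2
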