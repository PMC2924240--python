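"""Codon-alignment simulation and the calibration / power experiments.

Alignments are simulated under structured multi-rate models on two-taxon or
balanced n-taxon trees: root states are drawn from the stationary
distribution and evolved down each branch with exp(Q t).  The default
study conditions follow the published simulation design: uniform positional
nucleotide frequencies, an HKY85 nucleotide bias, pairwise divergence
expressed in expected substitutions per nucleotide site, and generating
partitions drawn by assigning each of the 75 one-step pairs to one of
K_true bins with equal probability.

Evaluation reruns the full GA selection on each replicate and reports the
proportions of correctly-sized / under-fitted / over-fitted models and the
Rand statistic between generating and inferred partitions (over the
correct-K replicates only).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codon_model import (
    ModelParameters,
    ModelStructure,
    RateMatrixBuilder,
    SpectralMatrix,
)
from .ga import GAConfig, ModelArchive, StructureScorer, mbic, run_for_K, select_model
from .genetic_code import GeneticCode
from .likelihood import (
    CodonAlignment,
    PhyloEvaluator,
    Phylogeny,
    count_parameters,
    fit_model,
    profile_pair_rates,
    sample_size,
)

__all__ = [
    "SimulationDesign",
    "two_taxon_tree",
    "balanced_tree",
    "hky_nuc_rates",
    "random_assignment",
    "simulate_alignment",
    "rand_statistic",
    "evaluate_designs",
    "calibration_experiment",
    "two_taxon_design",
    "multi_taxon_design",
]


def hky_nuc_rates(kappa: float) -> np.ndarray:
    """HKY85 exchangeabilities in (AC, AG, AT, CG, CT, GT) order:
    transitions (AG, CT) at kappa, transversions at 1."""
    return np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])


def two_taxon_tree(divergence: float, names: Sequence[str] = ("t1", "t2")) -> Phylogeny:
    """Two leaves separated by the given pairwise divergence
    (substitutions per nucleotide site), root placed midway."""
    half = divergence / 2.0
    return Phylogeny.from_newick(f"({names[0]}:{half:.10g},{names[1]}:{half:.10g});")


def balanced_tree(n_taxa: int, divergence: float) -> Phylogeny:
    """Symmetric balanced binary tree with equal branch lengths chosen so
    the mean pairwise leaf distance equals ``divergence``."""
    if n_taxa < 2 or (n_taxa & (n_taxa - 1)) != 0:
        raise ValueError("n_taxa must be a power of 2")
    depth = int(np.log2(n_taxa))

    def rec(d: int, prefix: str) -> str:
        if d == 0:
            return f"t{prefix}:{{b}}"
        return f"({rec(d - 1, prefix + '0')},{rec(d - 1, prefix + '1')}):{{b}}"

    left = rec(depth - 1, "0")
    right = rec(depth - 1, "1")
    template = f"({left},{right});"
    # mean pairwise path length in edge units: leaves i, j diverge at the
    # depth of their first differing bit
    labels = ["".join(bits) for bits in itertools.product("01", repeat=depth)]
    total, npairs = 0, 0
    for a, b in itertools.combinations(labels, 2):
        first_diff = next(k for k in range(depth) if a[k] != b[k])
        total += 2 * (depth - first_diff)
        npairs += 1
    b_len = divergence / (total / npairs)
    newick = template.replace("{b}", f"{b_len:.10g}")
    return Phylogeny.from_newick(newick)


def random_assignment(K: int, rng: np.random.Generator, n_pairs: int = 75) -> ModelStructure:
    """Equal-probability binning of the one-step pairs into K classes, with
    every class guaranteed occupied."""
    while True:
        labels = rng.integers(0, K, size=n_pairs)
        if len(np.unique(labels)) == K:
            return ModelStructure(tuple(int(x) for x in labels), K)


@dataclass
class SimulationDesign:
    """One row of the simulation study: tree shape, divergence, generating
    rate classes and nucleotide model."""

    n_taxa: int = 2
    divergence: float = 0.2           # mean pairwise, substitutions/nt site
    n_codon_sites: int = 500
    class_rates: tuple[float, ...] = (0.5,)
    kappa: float = 2.0
    freq_mode: str = "MG"
    replicates: int = 100
    seed: int = 0
    tree: Optional[Phylogeny] = None

    def __post_init__(self):
        if any(r <= 0 for r in self.class_rates):
            raise ValueError("class rates must be positive")
        if self.divergence < 0:
            raise ValueError("divergence must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def K_true(self) -> int:
        return len(self.class_rates)

    def make_tree(self) -> Phylogeny:
        if self.tree is not None:
            return self.tree
        if self.n_taxa == 2:
            return two_taxon_tree(self.divergence)
        return balanced_tree(self.n_taxa, self.divergence)

    def params(self, code: GeneticCode) -> ModelParameters:
        if self.freq_mode == "MG":
            return ModelParameters(hky_nuc_rates(self.kappa),
                                   np.asarray(self.class_rates), "MG",
                                   position_freqs=np.full((3, 4), 0.25))
        return ModelParameters(hky_nuc_rates(self.kappa),
                               np.asarray(self.class_rates), "F61",
                               codon_freqs=np.full(code.n_sense, 1.0 / code.n_sense))


def two_taxon_design(class_rates, divergence: float = 0.2,
                     n_codon_sites: int = 40000, seed: int = 0,
                     replicates: int = 100) -> SimulationDesign:
    """Two-sequence study conditions: long alignments remove the effect of
    phylogeny, and their length matches the precision of the published
    rate-estimate dispersions for these designs."""
    return SimulationDesign(n_taxa=2, divergence=divergence,
                            n_codon_sites=n_codon_sites,
                            class_rates=tuple(class_rates), seed=seed,
                            replicates=replicates)


def multi_taxon_design(class_rates, n_taxa: int = 16, divergence: float = 0.2,
                       n_codon_sites: int = 500, seed: int = 0,
                       replicates: int = 100) -> SimulationDesign:
    """Gene-size multi-taxon study conditions on balanced trees."""
    return SimulationDesign(n_taxa=n_taxa, divergence=divergence,
                            n_codon_sites=n_codon_sites,
                            class_rates=tuple(class_rates), seed=seed,
                            replicates=replicates)


def simulate_alignment(design: SimulationDesign, rep_index: int,
                       code: GeneticCode):
    """Simulate one replicate; fully reproducible from (seed, rep_index).

    Returns (alignment, generating structure, tree, generating parameters).
    """
    rng = np.random.default_rng([design.seed, rep_index])
    tree = design.make_tree()
    if design.K_true > 1:
        structure = random_assignment(design.K_true, rng, code.n_pairs)
    else:
        structure = ModelStructure.single_rate(code.n_pairs)
    params = design.params(code)
    builder = RateMatrixBuilder(
        code, params.nuc_rates, params.freq_mode,
        position_freqs=params.position_freqs, codon_freqs=params.codon_freqs,
    )
    rm = builder.build(structure, params.class_rates)
    sm = SpectralMatrix(rm)
    n_sites = design.n_codon_sites
    states = {tree.root: rng.choice(code.n_sense, size=n_sites, p=rm.pi / rm.pi.sum())}
    for v in reversed(tree.postorder):  # preorder
        if v == tree.root:
            continue
        P = sm.transition(tree.lengths[v])
        P = P / P.sum(axis=1, keepdims=True)
        parent_states = states[tree.parent[v]]
        child = np.empty(n_sites, dtype=np.int16)
        for s in np.unique(parent_states):
            idx = np.where(parent_states == s)[0]
            child[idx] = rng.choice(code.n_sense, size=len(idx), p=P[s])
        states[v] = child
    names, rows = [], []
    for v, name in sorted(tree.leaf_names.items()):
        names.append(name)
        rows.append(states[v])
    aln = CodonAlignment(names, np.array(rows, dtype=np.int16), code)
    return aln, structure, tree, params


def rand_statistic(a: Sequence[int], b: Sequence[int]) -> float:
    """Rand's pair-counting agreement between two partitions of the same
    objects: (together-in-both + apart-in-both) / C(n, 2)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must label the same 1-D index set")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two objects")
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    agree = (same_a == same_b)
    iu = np.triu_indices(n, k=1)
    return float(agree[iu].mean())


# ---------------------------------------------------------------------------
# Table-2-style evaluation
# ---------------------------------------------------------------------------

def _rate_deviations(true_rates: np.ndarray, est_rates: np.ndarray) -> np.ndarray:
    """Deviations of estimated from generating class rates, both sorted."""
    return np.sort(est_rates) - np.sort(np.asarray(true_rates))


def evaluate_designs(designs: Sequence[SimulationDesign], config: GAConfig,
                     code: GeneticCode, replicates: Optional[int] = None,
                     return_details: bool = False):
    """Run the full GA selection on each replicate of each design.

    Returns a tidy table with P_K, P_under, P_over, mean Rand statistic
    (over correct-K replicates, as in the published evaluation) and the
    SD of rate estimates around the generating values.
    """
    rows = []
    details = []
    for design in designs:
        reps = replicates if replicates is not None else design.replicates
        n_correct = n_under = n_over = 0
        rands, devs = [], []
        for rep in range(reps):
            aln, true_structure, tree, _ = simulate_alignment(design, rep, code)
            cfg = replace(config, seed=int(np.random.default_rng(
                [config.seed, design.seed, rep]).integers(2 ** 31)))
            sel = select_model(aln, tree, cfg)
            K_hat = sel.best.K
            detail = {"design_seed": design.seed, "rep": rep, "K_true": design.K_true,
                      "K_hat": K_hat, "mbic": sel.best.mbic}
            if K_hat == design.K_true:
                n_correct += 1
                if design.K_true > 1:
                    r = rand_statistic(true_structure.assignment,
                                       sel.best.structure.assignment)
                    rands.append(r)
                    detail["rand"] = r
                devs.append(_rate_deviations(np.asarray(design.class_rates),
                                             sel.best.class_rates))
            elif K_hat < design.K_true:
                n_under += 1
            else:
                n_over += 1
            details.append(detail)
        row = {
            "K_true": design.K_true,
            "n_taxa": design.n_taxa,
            "divergence": design.divergence,
            "rates": design.class_rates,
            "replicates": reps,
            "P_K": n_correct / reps,
            "P_under": n_under / reps,
            "P_over": n_over / reps,
            "mean_rand": float(np.mean(rands)) if rands else np.nan,
            "rate_sd": tuple(np.std(np.vstack(devs), axis=0)) if devs else None,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    if return_details:
        return table, pd.DataFrame(details)
    return table


# ---------------------------------------------------------------------------
# penalty-factor calibration
# ---------------------------------------------------------------------------

def _best_for_K(aln: CodonAlignment, tree: Phylogeny, K: int, config: GAConfig,
                rng: np.random.Generator):
    """Best fixed-K model (GA-restricted search) for calibration runs."""
    code = aln.code
    evaluator = PhyloEvaluator(aln, tree)
    sr = fit_model(ModelStructure.single_rate(code.n_pairs), aln, tree,
                   freq_mode=config.freq_mode, rounds=1, evaluator=evaluator)
    if K == 1:
        return sr.lnL, count_parameters(1, config.freq_mode)
    builder = RateMatrixBuilder(
        code, sr.params.nuc_rates, sr.params.freq_mode,
        position_freqs=sr.params.position_freqs, codon_freqs=sr.params.codon_freqs,
    )
    profile = profile_pair_rates(evaluator, builder,
                                 float(sr.params.class_rates[0]),
                                 sr.branch_lengths) if config.profile_seed else None
    n = sample_size(aln, config.sample_size_mode)
    scorer = StructureScorer(evaluator, builder, sr.branch_lengths, n,
                             config.penalty_factor, config.freq_mode,
                             profile_rates=profile, ftol=config.score_ftol)
    archive = run_for_K(scorer, K, config, rng)
    best = min((r for r in archive if r.K == K), key=lambda r: r.mbic)
    return best.lnL, count_parameters(K, config.freq_mode)


def calibration_experiment(designs: Sequence[SimulationDesign],
                           c_grid: Sequence[float], config: GAConfig,
                           code: GeneticCode,
                           replicates: Optional[int] = None) -> pd.DataFrame:
    """Reproduce the penalty-calibration experiment.

    For each replicate, the best models with K_true-1, K_true and K_true+1
    classes are fitted; the scaled log-likelihood differences determine,
    per candidate penalty factor c, whether the correct model beats the
    under-fitted one (power) and whether the over-fitted one beats the
    correct one (false positive).
    """
    rows = []
    for design in designs:
        reps = replicates if replicates is not None else design.replicates
        for rep in range(reps):
            aln, _, tree, _ = simulate_alignment(design, rep, code)
            rng = np.random.default_rng([config.seed, design.seed, rep])
            n = sample_size(aln, config.sample_size_mode)
            logn = np.log(n)
            K = design.K_true
            lnls = {}
            for k in [k for k in (K - 1, K, K + 1) if k >= 1]:
                lnls[k], _ = _best_for_K(aln, tree, k, config, rng)
            for c in c_grid:
                row = {"K_true": K, "n_sites": design.n_codon_sites,
                       "rep": rep, "c": c, "n": n}
                if K - 1 >= 1:
                    d = (lnls[K] - lnls[K - 1]) / logn
                    row["scaled_gain_correct"] = d
                    row["correct_beats_underfit"] = 2 * d > c
                d_over = (lnls[K + 1] - lnls[K]) / logn
                row["scaled_gain_overfit"] = d_over
                row["overfit_beats_correct"] = 2 * d_over > c
                rows.append(row)
    return pd.DataFrame(rows)
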