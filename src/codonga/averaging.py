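"""Credible sets, Akaike weights and model-averaged rate matrices.

A GA run archives every structure it evaluates.  Models whose evidence
ratio against the best model, exp(-(mBIC_i - mBIC_best)/2), exceeds a
cutoff form the credible set; normalized weights over that set produce a
model-averaged 75-vector of non-synonymous rates (an empirical-style
matrix with no free rate parameters) and a pairwise matrix of
probabilities that two amino-acid pairs share a rate class.  The averaged
matrix can be applied to validation alignments as-is or with one extra
fitted global non-synonymous scaler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .codon_model import ModelParameters, ModelStructure, RateMatrixBuilder
from .ga import FitRecord, ModelArchive, mbic
from .likelihood import (
    CodonAlignment,
    PhyloEvaluator,
    Phylogeny,
    fit_branch_lengths,
)

__all__ = [
    "CredibleSet",
    "AveragedModel",
    "evidence_ratio",
    "akaike_weights",
    "credible_set",
    "model_average",
    "fit_omega_s",
    "cluster_affinity",
]


def evidence_ratio(mbic_i: float, mbic_best: float) -> float:
    """exp(-(mBIC_i - mBIC_best)/2), in (0, 1] for mbic_i >= mbic_best."""
    if mbic_i < mbic_best - 1e-9:
        raise ValueError("mbic_i must be >= mbic_best")
    return math.exp(-(mbic_i - mbic_best) / 2.0)


def akaike_weights(mbics: Sequence[float]) -> np.ndarray:
    """w_i = exp(-d_i/2) / sum_j exp(-d_j/2), d relative to the minimum."""
    m = np.asarray(mbics, dtype=float)
    if m.size == 0:
        raise ValueError("empty model set")
    d = m - m.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


@dataclass
class CredibleSet:
    """Models with evidence ratio above threshold, with normalized weights."""

    records: list[FitRecord]
    weights: np.ndarray
    threshold: float

    def __len__(self) -> int:
        return len(self.records)


def credible_set(archive: ModelArchive, threshold: float = 0.01) -> CredibleSet:
    records = sorted(archive, key=lambda r: r.mbic)
    best = records[0].mbic
    kept = [r for r in records if evidence_ratio(r.mbic, best) >= threshold]
    return CredibleSet(kept, akaike_weights([r.mbic for r in kept]), threshold)


@dataclass
class AveragedModel:
    """Model-averaged per-pair non-synonymous rates and co-clustering
    probabilities, computed over a credible set."""

    rates: np.ndarray              # 75-vector of averaged rates
    same_class_prob: np.ndarray    # 75x75, symmetric, unit diagonal
    weights: np.ndarray
    threshold: float
    omega_s: Optional[float] = None

    @property
    def n_pairs(self) -> int:
        return len(self.rates)

    def as_rev_structure(self) -> tuple[ModelStructure, np.ndarray]:
        """Represent the averaged model as a fixed fully-general structure."""
        return ModelStructure.rev(self.n_pairs), self.rates.copy()


def model_average(archive: ModelArchive, threshold: float = 0.01) -> AveragedModel:
    """Average per-pair rates and co-clustering indicators over the credible
    set with Akaike weights; averaging is on the rate scale."""
    cs = credible_set(archive, threshold)
    n_pairs = len(cs.records[0].structure.assignment)
    rates = np.zeros(n_pairs)
    prob = np.zeros((n_pairs, n_pairs))
    for w, rec in zip(cs.weights, cs.records):
        assign = np.asarray(rec.structure.assignment)
        rates += w * np.asarray(rec.class_rates)[assign]
        prob += w * (assign[:, None] == assign[None, :])
    np.fill_diagonal(prob, 1.0)
    return AveragedModel(rates=rates, same_class_prob=prob,
                         weights=cs.weights, threshold=threshold)


def cluster_affinity(edge: int, cluster: Sequence[int],
                     same_class_prob: np.ndarray) -> float:
    """Mean model-averaged probability that ``edge`` co-clusters with the
    other members of its assigned class; 1 for singleton clusters.

    Affinity below 0.5 flags ambiguous membership under majority rule.
    """
    if edge not in cluster:
        raise ValueError("edge must be a member of the cluster")
    others = [f for f in cluster if f != edge]
    if not others:
        return 1.0
    return float(np.mean([same_class_prob[edge, f] for f in others]))


def fit_omega_s(averaged: AveragedModel, aln: CodonAlignment, tree: Phylogeny,
                params: ModelParameters, *, n: Optional[int] = None,
                c: float = 2.0, optimize_branch_lengths: bool = True,
                evaluator: Optional[PhyloEvaluator] = None):
    """Fit the single global non-synonymous scaler of the averaged model.

    The averaged per-pair rates are held fixed (an empirical matrix); only
    omega_s -- and optionally branch lengths -- are estimated on the given
    (typically independent) alignment.  Returns an
    (omega_s, lnL, p, mbic, branch_lengths) tuple.
    """
    code = aln.code
    ev = evaluator if evaluator is not None else PhyloEvaluator(aln, tree)
    structure, rates = averaged.as_rev_structure()
    builder = RateMatrixBuilder(
        code, params.nuc_rates, params.freq_mode,
        position_freqs=params.position_freqs, codon_freqs=params.codon_freqs,
    )
    lengths = tree.lengths.copy()

    def nll(log_w):
        rm = builder.build(structure, rates, omega_s=float(np.exp(log_w)))
        return -ev.log_likelihood(rm, lengths)

    for _ in range(2 if optimize_branch_lengths else 1):
        res = optimize.minimize_scalar(nll, bounds=(np.log(1e-4), np.log(100.0)),
                                       method="bounded", options={"xatol": 1e-6})
        w = float(np.exp(res.x))
        lnl = -float(res.fun)
        if optimize_branch_lengths:
            rm = builder.build(structure, rates, omega_s=w)
            lengths, lnl = fit_branch_lengths(ev, rm, lengths)
        else:
            break
    # the averaged rates and the mutational component are fixed; the single
    # scaler is the only estimated rate parameter (the ECM+omega analog)
    p = 1
    score = mbic(lnl, p, n, c) if n is not None else None
    return w, lnl, p, score, lengths
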