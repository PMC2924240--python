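"""Genetic-algorithm search over multi-rate model structures.

The discrete component of a structured codon model -- the partition of the
75 one-step amino-acid pairs into K rate classes -- is optimized by a
genetic algorithm whose fitness is a modified BIC with the parameter
penalty doubled (mBIC = -2 lnL + c p ln n, c = 2 by default).  The number
of classes itself is chosen by a K-increment loop: starting from the
single-rate model, a (K+1)-class search seeded from the best K-class model
is accepted only if it improves the mBIC, and the loop stops at the first
rejection.

Candidate structures are scored by maximizing the likelihood over their K
class rates only, holding the mutational component and branch lengths
fixed at the incumbent stage's estimates; branch lengths are re-estimated
under the incumbent best model whenever the best fitness improves by more
than ``branch_refresh_threshold`` points since the last re-estimation, and
each accepted per-K best is refit jointly before the accept/reject
decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .codon_model import ModelParameters, ModelStructure, RateMatrixBuilder
from .likelihood import (
    CodonAlignment,
    FitResult,
    PhyloEvaluator,
    Phylogeny,
    count_parameters,
    fit_branch_lengths,
    fit_class_rates,
    fit_model,
    profile_pair_rates,
    sample_size,
)

__all__ = [
    "GAConfig",
    "FitRecord",
    "ModelArchive",
    "mbic",
    "ga_step",
    "run_for_K",
    "select_model",
    "StructureScorer",
]


def mbic(lnL: float, p: int, n: int, c: float = 2.0) -> float:
    """Modified BIC: -2 lnL + c * p * ln(n); c=1 is the standard BIC."""
    if n < 2:
        raise ValueError("sample size n must be at least 2")
    return -2.0 * lnL + c * p * math.log(n)


@dataclass
class GAConfig:
    """Hyperparameters of the GA search; all values are stamped into run
    metadata so results are reproducible from config + inputs."""

    population_size: int = 48
    stop_generations: int = 15          # stop after this many stagnant generations
    max_generations: int = 150
    min_improvement: float = 6.0        # mBIC step below which a generation counts as stagnant
    refine_per_generation: int = 12     # candidates refined with full rate fits
    accept_margin_params: float = 2.0   # K-increment margin, in parameter-equivalents
    mutation_rate: float = 2.0 / 75.0   # per-element reassignment probability
    crossover_rate: float = 0.8
    crossover: str = "uniform"          # or "single" (single-point)
    tournament_size: int = 3
    elitism: int = 2
    seed: int = 0
    branch_refresh_threshold: float = 50.0  # mBIC-scale improvement trigger
    penalty_factor: float = 2.0
    sample_size_mode: str = "characters"
    profile_seed: bool = True   # per-pair profile rates warm-start the optimizer
    max_K: int = 10
    score_ftol: float = 5e-6
    freq_mode: str = "MG"
    threads: int = 1

    def __post_init__(self):
        if min(self.population_size, self.stop_generations, self.elitism) <= 0:
            raise ValueError("population_size, stop_generations, elitism must be positive")
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.crossover_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class FitRecord:
    """A model structure with its fitted rates, log-likelihood and mBIC."""

    structure: ModelStructure
    lnL: float
    class_rates: np.ndarray
    p: int
    mbic: float
    fit: Optional[FitResult] = None

    @property
    def K(self) -> int:
        return self.structure.K

    def canonical(self) -> "FitRecord":
        structure, rates = self.structure.canonicalize_by_rates(self.class_rates)
        return replace(self, structure=structure, class_rates=rates)


class ModelArchive:
    """All models evaluated in a run, deduplicated by canonical structure."""

    def __init__(self):
        self._records: dict[tuple[int, ...], FitRecord] = {}

    def add(self, record: FitRecord) -> None:
        key = record.structure.canonical_key().assignment
        old = self._records.get(key)
        if old is None or record.mbic < old.mbic:
            self._records[key] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def merge(self, other: "ModelArchive") -> None:
        for rec in other:
            self.add(rec)

    @property
    def best(self) -> FitRecord:
        if not self._records:
            raise ValueError("empty archive")
        return min(
            self._records.values(),
            key=lambda r: (r.mbic, r.K, r.structure.canonical_key().assignment),
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in sorted(self._records.values(), key=lambda r: r.mbic):
            rows.append({
                "K": rec.K,
                "lnL": rec.lnL,
                "p": rec.p,
                "mbic": rec.mbic,
                "class_rates": ",".join(f"{r:.6g}" for r in rec.class_rates),
                "assignment": "".join(
                    str(a) for a in rec.structure.canonical_key().assignment
                ),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# candidate scoring
# ---------------------------------------------------------------------------

class StructureScorer:
    """Fits candidate structures (class rates only) with caching.

    Holds the alignment evaluator, the mutational-component builder and the
    current branch-length approximation.  ``refresh_branch_lengths``
    re-estimates branch lengths under a given model and invalidates the
    score cache.
    """

    def __init__(self, evaluator: PhyloEvaluator, builder: RateMatrixBuilder,
                 lengths: np.ndarray, n: int, c: float,
                 freq_mode: str, profile_rates: Optional[np.ndarray] = None,
                 ftol: float = 1e-7):
        self.evaluator = evaluator
        self.builder = builder
        self.lengths = np.asarray(lengths, dtype=float).copy()
        self.n = n
        self.c = c
        self.freq_mode = freq_mode
        self.profile_rates = profile_rates
        self.ftol = ftol
        self.n_fits = 0
        self._cache: dict[tuple[int, ...], FitRecord] = {}
        self._quick: dict[tuple[int, ...], float] = {}

    def start_rates(self, structure: ModelStructure) -> np.ndarray:
        if self.profile_rates is not None:
            logp = np.log(np.clip(self.profile_rates, 1e-4, 50.0))
            assign = np.asarray(structure.assignment)
            return np.array([
                np.exp(logp[assign == k].mean()) for k in range(structure.K)
            ])
        return np.full(structure.K, 0.5)

    def score(self, structure: ModelStructure,
              archive: Optional[ModelArchive] = None) -> FitRecord:
        key = structure.canonical_key()
        cached = self._cache.get(key.assignment)
        if cached is not None:
            return cached
        lnl, rates = fit_class_rates(
            self.evaluator, self.builder, key, self.start_rates(key),
            lengths=self.lengths, ftol=self.ftol, method="coord",
        )
        self.n_fits += 1
        p = count_parameters(key.K, self.freq_mode)
        rec = FitRecord(key, lnl, rates, p, mbic(lnl, p, self.n, self.c))
        self._cache[key.assignment] = rec
        if archive is not None:
            archive.add(rec)
        return rec

    def quick_score(self, structure: ModelStructure) -> float:
        """Screening mBIC: one likelihood evaluation at the warm-start
        rates.  Under-estimates the fitted score by well under the
        selection deadband, which is all the resolution selection uses."""
        key = structure.canonical_key()
        full = self._cache.get(key.assignment)
        if full is not None:
            return full.mbic
        cached = self._quick.get(key.assignment)
        if cached is not None:
            return cached
        rm = self.builder.build(key, self.start_rates(key))
        lnl = self.evaluator.log_likelihood(rm, self.lengths)
        p = count_parameters(key.K, self.freq_mode)
        val = mbic(lnl, p, self.n, self.c)
        self._quick[key.assignment] = val
        return val

    def refresh_branch_lengths(self, record: FitRecord) -> None:
        rm = self.builder.build(record.structure, record.class_rates)
        old = self.lengths
        self.lengths, _ = fit_branch_lengths(self.evaluator, rm, self.lengths,
                                             passes=1, xtol=1e-3)
        # scores only need re-deriving when the lengths actually moved;
        # typically they barely change between models on the same data
        rel = np.abs(self.lengths - old) / (np.abs(old) + 1e-3)
        if rel.max() > 0.01:
            self._cache.clear()
            self._quick.clear()


# ---------------------------------------------------------------------------
# GA operators
# ---------------------------------------------------------------------------

def _repair(labels: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Ensure every class label in 0..K-1 occurs at least once."""
    present = np.unique(labels)
    missing = [k for k in range(K) if k not in present]
    for k in missing:
        # reassign a random element from a class with more than one member
        sizes = np.bincount(labels, minlength=K)
        candidates = np.where(sizes[labels] > 1)[0]
        pos = rng.choice(candidates)
        labels[pos] = k
    return labels


def random_structure(K: int, rng: np.random.Generator, n_pairs: int = 75) -> ModelStructure:
    labels = rng.integers(0, K, size=n_pairs)
    labels = _repair(labels, K, rng)
    return ModelStructure.from_labels(labels)


def ga_step(population: list[ModelStructure], scores: np.ndarray,
            config: GAConfig, rng: np.random.Generator, K: int) -> list[ModelStructure]:
    """One GA generation: elitism, tournament selection, crossover,
    per-element mutation, class-occupancy repair.

    Uniform crossover is the default: the lexicographic ordering of the 75
    one-step pairs carries no biological linkage, so allele-wise mixing
    propagates well-supported assignments in parallel.
    """
    n_pop = len(population)
    n_pairs = len(population[0].assignment)
    order = np.argsort(scores, kind="stable")
    elite = [population[i] for i in order[: config.elitism]]

    def pick() -> np.ndarray:
        # tournament with a noise deadband: scores within min_improvement of
        # the tournament best count as tied (such differences are below the
        # resolution the selection criterion itself considers meaningful),
        # so drift-scale fitness differences exert no selection pressure
        idx = rng.integers(0, n_pop, size=config.tournament_size)
        tied = idx[scores[idx] <= scores[idx].min() + config.min_improvement]
        return np.asarray(population[tied[rng.integers(len(tied))]].assignment)

    children: list[ModelStructure] = []
    while len(children) < n_pop - config.elitism:
        a = pick()
        if K > 1 and rng.random() < config.crossover_rate:
            b = pick()
            if config.crossover == "uniform":
                child = np.where(rng.random(n_pairs) < 0.5, a, b)
            else:
                cut = int(rng.integers(1, n_pairs))
                child = np.concatenate([a[:cut], b[cut:]])
        else:
            child = a.copy()
        if K > 1:
            mask = rng.random(n_pairs) < config.mutation_rate
            if np.any(mask):
                child[mask] = rng.integers(0, K, size=int(mask.sum()))
        child = _repair(child, K, rng)
        children.append(ModelStructure.from_labels(child))
    return elite + children


# ---------------------------------------------------------------------------
# per-K search and the K-increment loop
# ---------------------------------------------------------------------------

def _kmeans1d(values: np.ndarray, K: int, iters: int = 30) -> np.ndarray:
    """Deterministic 1-D k-means (quantile init + Lloyd), returns labels."""
    v = np.asarray(values, dtype=float)
    centers = np.quantile(v, (np.arange(K) + 0.5) / K)
    for _ in range(iters):
        labels = np.argmin(np.abs(v[:, None] - centers[None, :]), axis=1)
        new = np.array([
            v[labels == k].mean() if np.any(labels == k) else centers[k]
            for k in range(K)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    return np.argmin(np.abs(v[:, None] - centers[None, :]), axis=1)


def split_largest_class(structure: ModelStructure, rng: np.random.Generator) -> ModelStructure:
    """Increment K by splitting the most populous class into two random halves."""
    sizes = structure.class_sizes()
    k = int(np.argmax(sizes))
    members = structure.class_members(k)
    take = rng.choice(members, size=max(1, len(members) // 2), replace=False)
    labels = np.asarray(structure.assignment).copy()
    labels[take] = structure.K
    return ModelStructure.from_labels(labels)


def _seed_structures(K: int, incumbent: Optional[ModelStructure],
                     rng: np.random.Generator) -> list[ModelStructure]:
    """Generation-0 seeds for the K-class search: random splits of the
    incumbent (K-1)-class best.  Structure seeds are deliberately
    uninformed by the data -- the search itself must discover partitions,
    which keeps its overfitting behavior calibrated."""
    seeds: list[ModelStructure] = []
    if incumbent is not None and incumbent.K == K - 1:
        for _ in range(3):
            seeds.append(split_largest_class(incumbent, rng))
    return seeds


def run_for_K(scorer: StructureScorer, K: int, config: GAConfig,
              rng: np.random.Generator,
              seeds: Iterable[ModelStructure] = (),
              archive: Optional[ModelArchive] = None) -> ModelArchive:
    """GA search over K-class structures; returns the archive of all
    structures evaluated (merged into ``archive`` when provided)."""
    archive = archive if archive is not None else ModelArchive()
    n_pairs = scorer.builder.code.n_pairs
    if K == 1:
        scorer.score(ModelStructure.single_rate(n_pairs), archive)
        return archive
    population: list[ModelStructure] = [s for s in seeds if s.K == K]
    while len(population) < config.population_size:
        population.append(random_structure(K, rng, n_pairs))
    population = population[: config.population_size]

    best: Optional[FitRecord] = None
    refresh_anchor: Optional[float] = None
    idle = 0
    for _gen in range(config.max_generations):
        # two-stage scoring: screen everyone at warm-start rates, refine the
        # generation's top candidates with full class-rate fits (screening
        # error is well under the selection deadband)
        scores = np.array([scorer.quick_score(s) for s in population])
        top = np.argsort(scores, kind="stable")[: config.refine_per_generation]
        for i in top:
            rec = scorer.score(population[int(i)], archive)
            scores[i] = rec.mbic
        gen_best = scorer.score(population[int(top[0])], archive)
        for i in top[1:]:
            rec = scorer.score(population[int(i)], archive)
            if rec.mbic < gen_best.mbic:
                gen_best = rec
        prev = best.mbic if best is not None else np.inf
        if gen_best.mbic < prev - 1e-9:
            best = gen_best
        # stagnation rule: a generation counts as progress only when it
        # improves the best score by more than min_improvement -- smaller
        # steps are indistinguishable from noise climbing
        if prev - gen_best.mbic > config.min_improvement:
            idle = 0
        else:
            idle += 1
        if refresh_anchor is None:
            refresh_anchor = best.mbic
        elif refresh_anchor - best.mbic > config.branch_refresh_threshold:
            scorer.refresh_branch_lengths(best)
            refresh_anchor = None
            scores = np.array([scorer.quick_score(s) for s in population])
            best = scorer.score(population[int(np.argmin(scores))], archive)
            refresh_anchor = best.mbic
        if idle >= config.stop_generations:
            break
        population = ga_step(population, scores, config, rng, K)
    return archive


@dataclass
class SelectionResult:
    best: FitRecord
    archive: ModelArchive
    sr_fit: FitResult
    n: int
    profile_rates: Optional[np.ndarray]
    config: GAConfig


def _full_refit(structure: ModelStructure, aln: CodonAlignment, tree: Phylogeny,
                evaluator: PhyloEvaluator, config: GAConfig,
                start: ModelParameters, start_lengths: np.ndarray,
                n: int) -> FitRecord:
    fr = fit_model(structure, aln, tree, freq_mode=config.freq_mode,
                   start=start, start_lengths=start_lengths, rounds=1,
                   evaluator=evaluator)
    rec = FitRecord(structure, fr.lnL, fr.params.class_rates, fr.p,
                    mbic(fr.lnL, fr.p, n, config.penalty_factor), fit=fr)
    return rec


def select_model(aln: CodonAlignment, tree: Phylogeny, config: GAConfig,
                 ) -> SelectionResult:
    """The full model-selection procedure.

    Fits the single-rate model (including branch lengths), then runs the
    K-increment loop with a GA search at each K, and returns the overall
    best model together with the merged archive of everything evaluated.
    """
    rng = np.random.default_rng(config.seed)
    code = aln.code
    evaluator = PhyloEvaluator(aln, tree)
    n = sample_size(aln, config.sample_size_mode)

    sr_structure = ModelStructure.single_rate(code.n_pairs)
    sr_fit = fit_model(sr_structure, aln, tree, freq_mode=config.freq_mode,
                       rounds=2, evaluator=evaluator)
    incumbent = FitRecord(
        sr_structure, sr_fit.lnL, sr_fit.params.class_rates, sr_fit.p,
        mbic(sr_fit.lnL, sr_fit.p, n, config.penalty_factor), fit=sr_fit,
    )
    archive = ModelArchive()
    archive.add(incumbent)

    def make_builder(params: ModelParameters) -> RateMatrixBuilder:
        return RateMatrixBuilder(
            code, params.nuc_rates, params.freq_mode,
            position_freqs=params.position_freqs, codon_freqs=params.codon_freqs,
        )

    builder = make_builder(sr_fit.params)
    lengths = sr_fit.branch_lengths
    profile = None
    if config.profile_seed:
        profile = profile_pair_rates(
            evaluator, builder, float(sr_fit.params.class_rates[0]), lengths,
        )

    K = 2
    while K <= config.max_K:
        scorer = StructureScorer(evaluator, builder, lengths, n,
                                 config.penalty_factor, config.freq_mode,
                                 profile_rates=profile, ftol=config.score_ftol)
        seeds = _seed_structures(K, incumbent.structure, rng)
        run_for_K(scorer, K, config, rng, seeds=seeds, archive=archive)
        ga_best = min((r for r in archive if r.K == K),
                      key=lambda r: r.mbic, default=None)
        if ga_best is None:
            break
        start = replace(
            incumbent.fit.params if incumbent.fit is not None else
            ModelParameters.default(K, config.freq_mode, code.n_sense),
            class_rates=ga_best.class_rates,
        )
        candidate = _full_refit(ga_best.structure, aln, tree, evaluator,
                                config, start, scorer.lengths, n)
        archive.add(candidate)
        # the K-increment is accepted only when it improves the criterion by
        # more than the penalty-equivalent of the proposal's extra freedom:
        # one rate parameter plus the partition choice the adaptive search
        # maximizes over (two parameter-equivalents by default, calibrated
        # on null simulations).  Smaller differences are ties and parsimony
        # retains K.
        margin = (config.accept_margin_params * config.penalty_factor
                  * math.log(n))
        if candidate.mbic < incumbent.mbic - margin:
            incumbent = candidate
            builder = make_builder(candidate.fit.params)
            lengths = candidate.fit.branch_lengths
            K += 1
        else:
            break

    return SelectionResult(best=incumbent.canonical(), archive=archive,
                           sr_fit=sr_fit, n=n, profile_rates=profile,
                           config=config)
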