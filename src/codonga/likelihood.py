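"""Phylogenetic likelihood of codon alignments under structured models.

The likelihood is the standard pruning (sum-product) recursion over a fixed
rooted tree, with per-branch transition matrices exp(Q t) obtained from the
symmetrized eigendecomposition of the reversible rate matrix.  Site columns
are compressed to unique patterns, partial likelihoods are rescaled per
node to avoid underflow, and codons containing gaps or ambiguity characters
are treated as fully missing (all-ones partial vectors).

Continuous parameters (nucleotide exchangeabilities, MG position
frequencies, class rates, branch lengths) are estimated by bounded
quasi-Newton optimization on log-transformed rates, alternating with
coordinate-wise branch-length polishing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy import optimize

from .codon_model import (
    ModelParameters,
    ModelStructure,
    RateMatrix,
    RateMatrixBuilder,
    SpectralMatrix,
    f61_frequencies,
)
from .genetic_code import GeneticCode

MISSING = -1

__all__ = [
    "CodonAlignment",
    "Phylogeny",
    "PhyloEvaluator",
    "FitResult",
    "fit_model",
    "fit_branch_lengths",
    "fit_class_rates",
    "profile_pair_rates",
    "count_parameters",
    "sample_size",
]


# ---------------------------------------------------------------------------
# alignment container
# ---------------------------------------------------------------------------

class CodonAlignment:
    """A codon-aware alignment encoded as sense-codon indices.

    ``codes`` has shape (n_taxa, n_codon_sites); entries are indices into
    the genetic code's sense-codon order or ``MISSING`` (-1).
    """

    def __init__(self, names: Sequence[str], codes: np.ndarray, code: GeneticCode):
        self.names = list(names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon names")
        self.codes = np.asarray(codes, dtype=np.int16)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.names):
            raise ValueError("codes must be (n_taxa, n_sites)")
        self.code = code

    @classmethod
    def from_sequences(cls, seqs: dict[str, str], code: GeneticCode) -> "CodonAlignment":
        names = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal length")
        (L,) = lengths
        if L % 3 != 0:
            raise ValueError(f"alignment length {L} is not divisible by 3")
        n_sites = L // 3
        codes = np.full((len(names), n_sites), MISSING, dtype=np.int16)
        for r, name in enumerate(names):
            seq = seqs[name].upper().replace("U", "T")
            for s in range(n_sites):
                codon = seq[3 * s: 3 * s + 3]
                if any(b not in "ACGT" for b in codon):
                    continue  # gap or ambiguity -> missing
                aa = code.codon_to_aa[codon]
                if aa == "*":
                    raise ValueError(
                        f"internal stop codon {codon} in sequence {name!r} "
                        f"at codon position {s + 1}"
                    )
                codes[r, s] = code.codon_index[codon]
        return cls(names, codes, code)

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_codon_sites(self) -> int:
        return self.codes.shape[1]

    def codon_counts(self) -> np.ndarray:
        obs = self.codes[self.codes >= 0]
        return np.bincount(obs, minlength=self.code.n_sense).astype(float)

    def position_nucleotide_counts(self) -> np.ndarray:
        """3x4 counts of nucleotides by codon position over observed codons."""
        counts = np.zeros((3, 4))
        nt_index = {b: i for i, b in enumerate("ACGT")}
        codon_counts = self.codon_counts()
        for idx, codon in enumerate(self.code.sense_codons):
            for pos in range(3):
                counts[pos, nt_index[codon[pos]]] += codon_counts[idx]
        return counts

    def patterns(self):
        """Unique site patterns and their multiplicities."""
        cols = self.codes.T
        uniq, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        return uniq.T.copy(), counts.astype(float)

    def site_column(self, s: int) -> np.ndarray:
        return self.codes[:, s]

    def sequence_string(self, r: int) -> str:
        out = []
        for v in self.codes[r]:
            out.append("---" if v < 0 else self.code.sense_codons[v])
        return "".join(out)


def sample_size(aln: CodonAlignment, mode: str = "characters") -> int:
    """The alignment 'sample size' n used in the information criterion.

    ``characters`` (default): sequences x codon columns; ``sites``: codon
    columns only; ``nucleotides``: sequences x nucleotide columns.
    """
    if mode == "characters":
        return aln.n_taxa * aln.n_codon_sites
    if mode == "sites":
        return aln.n_codon_sites
    if mode == "nucleotides":
        return aln.n_taxa * aln.n_codon_sites * 3
    raise ValueError(f"unknown sample-size mode {mode!r}")


# ---------------------------------------------------------------------------
# tree container
# ---------------------------------------------------------------------------

class Phylogeny:
    """A rooted tree stored as flat arrays in postorder.

    Node ids are 0..n_nodes-1 with the root last in ``postorder``.
    ``lengths[v]`` is the branch length of the edge above node v (0 for the
    root), in expected substitutions per nucleotide site.
    """

    def __init__(self, children: list[list[int]], parent: np.ndarray,
                 lengths: np.ndarray, leaf_names: dict[int, str]):
        self.children = children
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be non-negative")
        self.leaf_names = dict(leaf_names)
        self.name_to_leaf = {v: k for k, v in self.leaf_names.items()}
        self.n_nodes = len(children)
        order = []
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                order.append(v)
            else:
                stack.append((v, True))
                for c in children[v]:
                    stack.append((c, False))
        self.postorder = order

    @property
    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @property
    def taxa(self) -> list[str]:
        return sorted(self.leaf_names.values())

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        t = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
        nodes = list(t.preorder_node_iter())
        ids = {id(nd): i for i, nd in enumerate(nodes)}
        children = [[] for _ in nodes]
        parent = np.full(len(nodes), -1, dtype=int)
        lengths = np.zeros(len(nodes))
        leaf_names = {}
        for nd in nodes:
            i = ids[id(nd)]
            if nd.parent_node is not None:
                parent[i] = ids[id(nd.parent_node)]
                children[parent[i]].append(i)
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                leaf_names[i] = nd.taxon.label if nd.taxon else ""
        return cls(children, parent, lengths, leaf_names)

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if self.is_leaf(v):
                body = self.leaf_names[v]
            else:
                body = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if self.parent[v] < 0:
                return body
            return f"{body}:{self.lengths[v]:.10g}"
        return rec(self.root) + ";"

    def with_lengths(self, lengths: np.ndarray) -> "Phylogeny":
        return Phylogeny(self.children, self.parent, lengths, self.leaf_names)

    def copy(self) -> "Phylogeny":
        return self.with_lengths(self.lengths.copy())

    def total_length(self) -> float:
        return float(self.lengths.sum())


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

class PhyloEvaluator:
    """Caches alignment patterns and tree traversal for repeated likelihood
    evaluations under different rate matrices / branch lengths."""

    def __init__(self, aln: CodonAlignment, tree: Phylogeny):
        if set(tree.taxa) != set(aln.names):
            missing = set(tree.taxa) ^ set(aln.names)
            raise ValueError(f"taxon mismatch between alignment and tree: {sorted(missing)}")
        self.aln = aln
        self.tree = tree
        self.code = aln.code
        pats, w = aln.patterns()
        self.pattern_weights = w
        self.n_patterns = pats.shape[1]
        # leaf node id -> pattern states row, plus precomputed gather
        # indices and missing-data masks for the pruning hot path
        self.leaf_states = {
            tree.name_to_leaf[name]: pats[r] for r, name in enumerate(aln.names)
        }
        self._leaf_take = {}
        self._leaf_missing = {}
        for v, states in self.leaf_states.items():
            self._leaf_take[v] = np.where(states < 0, 0, states).astype(np.intp)
            miss = states < 0
            self._leaf_missing[v] = miss if miss.any() else None
        # float32 partials once the problem is large enough that rounding
        # (~1e-3 lnL) is negligible against any decision threshold
        self._dtype = (np.float32 if self.n_patterns * tree.n_nodes > 4000
                       else np.float64)
        # two-taxon sufficient statistics: for a reversible model the pair
        # likelihood is pi_i P_ij(t1 + t2), so a 61x61 count matrix plus
        # single-observed marginals make evaluation cost length-independent
        self._pair_counts = None
        if aln.n_taxa == 2:
            a, b = aln.codes[0], aln.codes[1]
            both = (a >= 0) & (b >= 0)
            n = aln.code.n_sense
            N = np.zeros((n, n))
            np.add.at(N, (a[both], b[both]), 1.0)
            only_a = np.bincount(a[(a >= 0) & (b < 0)], minlength=n).astype(float)
            only_b = np.bincount(b[(b >= 0) & (a < 0)], minlength=n).astype(float)
            ri, ci = np.nonzero(N)
            self._pair_counts = (N[ri, ci], ri, ci, only_a + only_b)
            # order of the leaf branch lengths does not matter, only the sum
            r = tree.root
            self._pair_nodes = [v for v in tree.postorder if v != r]

    def _transition_set(self, sm: SpectralMatrix, lengths: np.ndarray) -> np.ndarray:
        return sm.transitions(lengths)

    def log_likelihood(self, rm: RateMatrix, lengths: Optional[np.ndarray] = None,
                       spectral: Optional[SpectralMatrix] = None) -> float:
        sm = spectral if spectral is not None else SpectralMatrix(rm)
        t = self.tree.lengths if lengths is None else np.asarray(lengths, dtype=float)
        if self._pair_counts is not None:
            counts, ri, ci, singles = self._pair_counts
            t_total = float(sum(t[v] for v in self._pair_nodes))
            P = sm.transition(t_total)
            joint = rm.pi[ri] * P[ri, ci]
            with np.errstate(divide="ignore"):
                lnl = float(counts @ np.log(joint))
            if singles.any():
                lnl += float(singles @ np.log(rm.pi))
            return lnl
        PT = sm.transitions_T(t, self._dtype)
        return self._lnl_from_PT(PT, rm.pi)

    def _lnl_from_P(self, P: np.ndarray, pi: np.ndarray) -> float:
        """Likelihood from a stack of standard-orientation P(t) matrices."""
        PT = np.ascontiguousarray(
            np.asarray(P, dtype=self._dtype).transpose(0, 2, 1))
        return self._lnl_from_PT(PT, pi)

    def _lnl_from_PT(self, PT: np.ndarray, pi: np.ndarray) -> float:
        # partial likelihoods are pattern-major (patterns x states) so tip
        # messages are contiguous row gathers and per-pattern rescaling is a
        # row reduction; PT[v] holds P(t_v) transposed
        tree = self.tree
        dtype = PT.dtype
        messages: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_patterns)
        for v in tree.postorder:
            if tree.is_leaf(v):
                msg = PT[v].take(self._leaf_take[v], axis=0)
                miss = self._leaf_missing[v]
                if miss is not None:
                    msg[miss] = 1.0
                messages[v] = msg
                continue
            children = tree.children[v]
            L = messages.pop(children[0])
            for c in children[1:]:
                L *= messages.pop(c)
            m = L.max(axis=1)
            if not m.all():
                return -np.inf
            L /= m[:, None]
            logscale += np.log(m, dtype=np.float64)
            if tree.parent[v] >= 0:
                messages[v] = L @ PT[v]
            else:
                site_lik = L @ pi.astype(dtype)
                return float(self.pattern_weights
                             @ (np.log(site_lik, dtype=np.float64) + logscale))
        raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted structured model: MLEs, log-likelihood and parameter count."""

    structure: ModelStructure
    params: ModelParameters
    branch_lengths: np.ndarray
    lnL: float
    p: int
    converged: bool = True

    def refit_delta(self, other: "FitResult") -> float:
        return abs(self.lnL - other.lnL)


def count_parameters(K: int, freq_mode: str = "MG", n_branches: int = 0,
                     include_branch_lengths: bool = False,
                     multistep: bool = False, omega_s: bool = False) -> int:
    """Number of independently estimated parameters.

    K class rates + 5 free nucleotide exchangeabilities + 9 (MG) or 60
    (F61) frequency parameters, plus optional extension parameters and,
    if requested, branch lengths.
    """
    p = K + 5 + (9 if freq_mode == "MG" else 60)
    if multistep:
        p += 4
    if omega_s:
        p += 1
    if include_branch_lengths:
        p += n_branches
    return p


_RATE_BOUNDS = (np.log(1e-5), np.log(100.0))


def _builder_for(params: ModelParameters, code: GeneticCode) -> RateMatrixBuilder:
    return RateMatrixBuilder(
        code, params.nuc_rates, params.freq_mode,
        position_freqs=params.position_freqs, codon_freqs=params.codon_freqs,
        multistep=params.multistep is not None,
    )


def _coordinate_newton(nll, x0, bounds, passes: int = 2, h: float = 0.25,
                       min_gain: float = 0.05):
    """Cheap coordinate-wise quadratic maximization for warm-started fits.

    For each coordinate a parabola through (x-h, x, x+h) supplies a Newton
    step (clipped to the bounds and to 4h); the step is kept only if it
    improves the objective.  Converges to scoring accuracy in ~3K-4K
    function evaluations for a warm start, a fraction of quasi-Newton cost.
    """
    lo, hi = bounds
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    f0 = nll(x)
    for _ in range(passes):
        gained = 0.0
        for i in range(len(x)):
            xm, xp = x.copy(), x.copy()
            xm[i] = max(lo, x[i] - h)
            xp[i] = min(hi, x[i] + h)
            fm, fp = nll(xm), nll(xp)
            # parabola vertex; fall back to the better neighbor if concave
            denom = fp - 2 * f0 + fm
            if denom > 1e-12:
                step = -0.5 * (fp - fm) / denom * h
            else:
                step = h if fp < fm else -h
            step = float(np.clip(step, -4 * h, 4 * h))
            if abs(step) < 0.02 and min(fm, fp) >= f0:
                continue  # already at a flat optimum in this coordinate
            xn = x.copy()
            xn[i] = float(np.clip(x[i] + step, lo, hi))
            fn = nll(xn)
            best = min((f0, 0), (fm, 1), (fp, 2), (fn, 3), key=lambda t: t[0])
            if best[1] == 1:
                x, gained, f0 = xm, gained + f0 - fm, fm
            elif best[1] == 2:
                x, gained, f0 = xp, gained + f0 - fp, fp
            elif best[1] == 3:
                x, gained, f0 = xn, gained + f0 - fn, fn
        if gained < min_gain:
            break
    return f0, x


def fit_class_rates(evaluator: PhyloEvaluator, builder: RateMatrixBuilder,
                    structure: ModelStructure, start_rates: np.ndarray,
                    lengths: Optional[np.ndarray] = None,
                    omega_s: Optional[float] = None, ms_rates=None,
                    ftol: float = 1e-8,
                    method: str = "lbfgs") -> tuple[float, np.ndarray]:
    """Maximize the likelihood over the K class rates only.

    The mutational component and branch lengths stay fixed; this is the
    inner scorer used for every candidate structure during the GA search
    (``method="coord"``, cheap warm-started coordinate steps) and the
    polishing fit for reported models (``method="lbfgs"``).
    """
    start = np.log(np.clip(np.asarray(start_rates, dtype=float), 1.5e-5, 90.0))

    def nll(x):
        rm = builder.build(structure, np.exp(x), omega_s=omega_s, ms_rates=ms_rates)
        val = evaluator.log_likelihood(rm, lengths)
        return -val if np.isfinite(val) else 1e12

    if method == "coord":
        f, x = _coordinate_newton(nll, start, _RATE_BOUNDS)
        return -float(f), np.exp(x)
    res = optimize.minimize(
        nll, start, method="L-BFGS-B",
        bounds=[_RATE_BOUNDS] * structure.K,
        # finite-difference step must clear the float32 pruning noise floor
        options={"ftol": ftol, "maxiter": 40, "maxfun": 80, "eps": 1e-4},
    )
    return -float(res.fun), np.exp(res.x)


def profile_pair_rates(evaluator: PhyloEvaluator, builder: RateMatrixBuilder,
                       base_rate: float, lengths: Optional[np.ndarray] = None,
                       xtol: float = 0.02) -> np.ndarray:
    """Per-pair one-dimensional profile rate estimates.

    For each one-step amino-acid pair, its own rate is optimized while all
    other pairs stay at the single-rate MLE -- one sweep of backfitting
    toward the fully general (REV) model.  The resulting 75-vector seeds
    the GA's initial populations.
    """
    n_pairs = builder.code.n_pairs
    out = np.empty(n_pairs)
    for e in range(n_pairs):
        labels = [0] * n_pairs
        labels[e] = 1
        structure = ModelStructure(tuple(labels), 2) if n_pairs > 1 else ModelStructure((0,), 1)

        def nll(logr, _s=structure):
            rm = builder.build(_s, np.array([base_rate, np.exp(logr)]))
            return -evaluator.log_likelihood(rm, lengths)

        res = optimize.minimize_scalar(
            nll, bounds=_RATE_BOUNDS, method="bounded",
            options={"xatol": xtol},
        )
        out[e] = np.exp(res.x)
    return out


def fit_branch_lengths(evaluator: PhyloEvaluator, rm: RateMatrix,
                       lengths: Optional[np.ndarray] = None,
                       passes: int = 2, xtol: float = 1e-4,
                       max_length: float = 20.0) -> tuple[np.ndarray, float]:
    """Coordinate-wise branch-length optimization under a fixed Q.

    Returns (lengths, lnL).  Each pass optimizes every branch in turn with
    bounded scalar minimization, reusing the eigendecomposition of Q.
    """
    tree = evaluator.tree
    sm = SpectralMatrix(rm)
    t = (tree.lengths if lengths is None else np.asarray(lengths, dtype=float)).copy()
    if evaluator._pair_counts is not None:
        # two-taxon: only the total path length matters; optimize it once
        def nll2(tt):
            trial = t * 0.0
            trial[evaluator._pair_nodes[0]] = tt
            return -evaluator.log_likelihood(rm, trial, spectral=sm)

        res = optimize.minimize_scalar(nll2, bounds=(0.0, max_length),
                                       method="bounded", options={"xatol": xtol})
        total = float(res.x)
        t[:] = 0.0
        # split evenly across the path (root placement is arbitrary)
        for v in evaluator._pair_nodes:
            t[v] = total / len(evaluator._pair_nodes)
        return t, -float(res.fun)
    PT = sm.transitions_T(t, evaluator._dtype)
    lnl = evaluator._lnl_from_PT(PT, rm.pi)
    for _ in range(passes):
        improved = False
        for v in tree.postorder:
            if tree.parent[v] < 0:
                continue

            def nll(tb, _v=v):
                PT[_v] = sm.transition(tb).T
                return -evaluator._lnl_from_PT(PT, rm.pi)

            res = optimize.minimize_scalar(
                nll, bounds=(0.0, max_length), method="bounded",
                options={"xatol": xtol},
            )
            if -res.fun > lnl + 1e-9:
                t[v] = float(res.x)
                lnl = -float(res.fun)
                improved = True
            PT[v] = sm.transition(t[v]).T
        if not improved:
            break
    return t, lnl


def fit_model(structure: ModelStructure, aln: CodonAlignment, tree: Phylogeny,
              *, freq_mode: str = "MG", start: Optional[ModelParameters] = None,
              start_lengths: Optional[np.ndarray] = None,
              optimize_branch_lengths: bool = True,
              optimize_frequencies: Optional[bool] = None,
              optimize_nuc_rates: bool = True,
              rounds: int = 2, ftol: float = 1e-8,
              evaluator: Optional[PhyloEvaluator] = None,
              include_branch_lengths_in_p: bool = False) -> FitResult:
    """Maximum-likelihood fit of a structured model on a fixed tree.

    Alternates bounded quasi-Newton optimization of the rate/frequency
    parameters with coordinate-wise branch-length passes.  Deterministic
    given starting values and tolerances.
    """
    code = aln.code
    ev = evaluator if evaluator is not None else PhyloEvaluator(aln, tree)
    if optimize_frequencies is None:
        optimize_frequencies = freq_mode == "MG"

    if start is None:
        if freq_mode == "MG":
            counts = aln.position_nucleotide_counts() + 1.0
            pf = counts / counts.sum(axis=1, keepdims=True)
            start = ModelParameters(np.ones(6), np.full(structure.K, 0.5), "MG",
                                    position_freqs=pf)
        else:
            cf = f61_frequencies(aln.codon_counts(), code)
            start = ModelParameters(np.ones(6), np.full(structure.K, 0.5), "F61",
                                    codon_freqs=cf)
    params = start
    lengths = (tree.lengths if start_lengths is None else np.asarray(start_lengths)).copy()

    # free-vector layout: [5 log nuc rates (AG fixed)] [K log class rates]
    #                     [4 log multistep rates] [9 frequency logits]
    nuc_free = [0, 2, 3, 4, 5]
    use_ms = params.multistep is not None

    def unpack(x):
        i = 0
        nuc = np.ones(6)
        if optimize_nuc_rates:
            nuc[nuc_free] = np.exp(x[i:i + 5])
            i += 5
        else:
            nuc = params.nuc_rates
        rates = np.exp(x[i:i + structure.K]); i += structure.K
        ms = None
        if use_ms:
            ms = np.exp(x[i:i + 4]); i += 4
        if optimize_frequencies and freq_mode == "MG":
            logits = x[i:i + 9].reshape(3, 3); i += 9
            z = np.hstack([logits, np.zeros((3, 1))])
            pf = np.exp(z - z.max(axis=1, keepdims=True))
            pf = pf / pf.sum(axis=1, keepdims=True)
        else:
            pf = params.position_freqs
        return nuc, rates, ms, pf

    def pack():
        x = []
        if optimize_nuc_rates:
            x.extend(np.log(np.clip(params.nuc_rates[nuc_free], 1e-4, 1e4)))
        x.extend(np.log(np.clip(params.class_rates, 1.5e-5, 90.0)))
        if use_ms:
            x.extend(np.log(np.clip(params.multistep, 1e-4, 1e4)))
        if optimize_frequencies and freq_mode == "MG":
            pf = np.clip(params.position_freqs, 1e-6, 1.0)
            x.extend((np.log(pf[:, :3]) - np.log(pf[:, 3:4])).ravel())
        return np.array(x)

    def nll(x):
        nuc, rates, ms, pf = unpack(x)
        try:
            if freq_mode == "MG":
                builder = RateMatrixBuilder(code, nuc, "MG", position_freqs=pf)
            else:
                builder = RateMatrixBuilder(code, nuc, "F61",
                                            codon_freqs=params.codon_freqs,
                                            multistep=use_ms)
            rm = builder.build(structure, rates, omega_s=params.omega_s, ms_rates=ms)
        except (ValueError, FloatingPointError):
            return 1e10
        val = ev.log_likelihood(rm, lengths)
        return -val if np.isfinite(val) else 1e10

    converged = True
    lnl = -np.inf
    for rnd in range(max(rounds, 1)):
        x0 = pack()
        nb = len(x0)
        bounds = [(-12.0, 12.0)] * nb
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": ftol, "maxiter": 200,
                                         "eps": 1e-4})
        nuc, rates, ms, pf = unpack(res.x)
        if freq_mode == "MG":
            params = ModelParameters(nuc, rates, "MG", position_freqs=pf,
                                     omega_s=params.omega_s)
        else:
            params = ModelParameters(nuc, rates, "F61", codon_freqs=params.codon_freqs,
                                     multistep=ms, omega_s=params.omega_s)
        lnl = -float(res.fun)
        converged = converged and bool(res.success)
        if optimize_branch_lengths:
            builder = _builder_for(params, code)
            rm = builder.build(structure, params.class_rates,
                               omega_s=params.omega_s, ms_rates=params.multistep)
            lengths, lnl = fit_branch_lengths(ev, rm, lengths)
        else:
            break

    p = count_parameters(structure.K, freq_mode,
                         n_branches=tree.n_branches,
                         include_branch_lengths=include_branch_lengths_in_p,
                         multistep=use_ms, omega_s=params.omega_s is not None)
    return FitResult(structure=structure, params=params, branch_lengths=lengths,
                     lnL=lnl, p=p, converged=converged)
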