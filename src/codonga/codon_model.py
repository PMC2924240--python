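"""Multi-rate codon substitution models.

The instantaneous rate matrix acts on the sense codons of a genetic code.
A one-step entry (codons differing at a single nucleotide position) is the
product of a nucleotide exchangeability, a frequency factor and -- for
non-synonymous changes -- the rate of the amino-acid pair's class, measured
relative to the synonymous rate which is fixed at 1.  Two frequency
parameterizations are supported: MG, where the frequency factor is the
target nucleotide's frequency at the substituted position (9 free
parameters), and GY with F61 codon frequencies (60 free parameters).
An optional extension assigns non-zero rates to codon pairs separated by
two or three nucleotide changes (four extra parameters, GY only), and an
optional global scaler multiplies every non-synonymous entry.

Matrices are scaled so that one unit of branch length equals one expected
substitution per *nucleotide* site (one third of the per-codon-site rate),
which keeps Newick branch lengths in the conventional units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import eigh as _scipy_eigh

from .genetic_code import NUC_PAIR_INDEX, GeneticCode

__all__ = [
    "ModelStructure",
    "ModelParameters",
    "RateMatrix",
    "RateMatrixBuilder",
    "mg_codon_frequencies",
    "f61_frequencies",
    "build_rate_matrix",
    "expected_substitution_rate",
    "solve_unit_time",
    "SpectralMatrix",
]


# ---------------------------------------------------------------------------
# model structure: the partition of one-step pairs into rate classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelStructure:
    """Assignment of each one-step amino-acid pair to one of K rate classes.

    ``assignment`` follows the genetic code's ``aa_pairs_one_step`` order.
    Every label in 0..K-1 must occur at least once.
    """

    assignment: tuple[int, ...]
    K: int

    def __post_init__(self):
        labels = set(self.assignment)
        if labels != set(range(self.K)):
            raise ValueError(
                f"assignment must use every label in 0..{self.K - 1}; got {sorted(labels)}"
            )

    @classmethod
    def single_rate(cls, n_pairs: int = 75) -> "ModelStructure":
        return cls(assignment=(0,) * n_pairs, K=1)

    @classmethod
    def rev(cls, n_pairs: int = 75) -> "ModelStructure":
        return cls(assignment=tuple(range(n_pairs)), K=n_pairs)

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "ModelStructure":
        """Build from arbitrary integer labels, relabeling canonically."""
        labels = list(labels)
        seen: dict[int, int] = {}
        out = []
        for lab in labels:
            if lab not in seen:
                seen[lab] = len(seen)
            out.append(seen[lab])
        return cls(assignment=tuple(out), K=len(seen))

    def canonical_key(self) -> "ModelStructure":
        """Relabel classes in order of first occurrence (rate-free canonical
        form, used for archive deduplication and equality)."""
        return ModelStructure.from_labels(self.assignment)

    def canonicalize_by_rates(self, rates: Sequence[float]):
        """Relabel classes in increasing order of fitted rate (ties broken by
        smallest member index); returns (structure, reordered rates)."""
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (self.K,):
            raise ValueError("rates length must equal K")
        first = [self.assignment.index(k) for k in range(self.K)]
        order = sorted(range(self.K), key=lambda k: (rates[k], first[k]))
        relabel = {old: new for new, old in enumerate(order)}
        assignment = tuple(relabel[a] for a in self.assignment)
        return ModelStructure(assignment, self.K), rates[order]

    def class_members(self, k: int) -> list[int]:
        return [i for i, a in enumerate(self.assignment) if a == k]

    def class_sizes(self) -> np.ndarray:
        return np.bincount(np.asarray(self.assignment), minlength=self.K)


# ---------------------------------------------------------------------------
# continuous parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """Continuous parameters of a structured codon model.

    nuc_rates follows :data:`codonga.genetic_code.NUC_PAIRS` order
    (AC, AG, AT, CG, CT, GT); the AG rate is conventionally fixed at 1
    during estimation.  class_rates are relative to the synonymous rate
    (fixed at 1).  Exactly one of ``position_freqs`` (MG: 3x4, rows sum
    to 1) or ``codon_freqs`` (GY/F61: length 61) is used, according to
    ``freq_mode``.  ``multistep`` holds the optional four rates
    (syn_2nt, syn_3nt, nonsyn_2nt, nonsyn_3nt); ``omega_s`` the optional
    global non-synonymous scaler.
    """

    nuc_rates: np.ndarray
    class_rates: np.ndarray
    freq_mode: str = "MG"
    position_freqs: Optional[np.ndarray] = None
    codon_freqs: Optional[np.ndarray] = None
    multistep: Optional[np.ndarray] = None
    omega_s: Optional[float] = None

    def __post_init__(self):
        self.nuc_rates = np.asarray(self.nuc_rates, dtype=float)
        self.class_rates = np.asarray(self.class_rates, dtype=float)
        if self.nuc_rates.shape != (6,):
            raise ValueError("nuc_rates must have length 6 (AC,AG,AT,CG,CT,GT)")
        if np.any(self.nuc_rates <= 0) or np.any(self.class_rates <= 0):
            raise ValueError("all rates must be strictly positive")
        if self.freq_mode not in ("MG", "F61"):
            raise ValueError(f"unknown freq_mode {self.freq_mode!r}")
        if self.freq_mode == "MG":
            if self.position_freqs is None:
                raise ValueError("MG parameterization requires position_freqs")
            self.position_freqs = np.asarray(self.position_freqs, dtype=float)
            if self.position_freqs.shape != (3, 4):
                raise ValueError("position_freqs must be 3x4")
            if not np.allclose(self.position_freqs.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("each position's nucleotide frequencies must sum to 1")
        else:
            if self.codon_freqs is None:
                raise ValueError("F61 parameterization requires codon_freqs")
            self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.multistep is not None:
            self.multistep = np.asarray(self.multistep, dtype=float)
            if self.multistep.shape != (4,) or np.any(self.multistep <= 0):
                raise ValueError("multistep must be 4 positive rates")
            if self.freq_mode != "F61":
                raise ValueError("the multi-step extension is defined for the GY/F61 parameterization")

    @property
    def K(self) -> int:
        return len(self.class_rates)

    @classmethod
    def default(cls, K: int = 1, freq_mode: str = "MG", code_size: int = 61):
        if freq_mode == "MG":
            return cls(np.ones(6), np.full(K, 0.5), "MG",
                       position_freqs=np.full((3, 4), 0.25))
        return cls(np.ones(6), np.full(K, 0.5), "F61",
                   codon_freqs=np.full(code_size, 1.0 / code_size))

    def with_class_rates(self, rates) -> "ModelParameters":
        return replace(self, class_rates=np.asarray(rates, dtype=float))


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def mg_codon_frequencies(position_freqs: np.ndarray, code: GeneticCode) -> np.ndarray:
    """Codon equilibrium frequencies implied by position-specific nucleotide
    frequencies: product over the three positions, renormalized by the total
    sense-codon mass (1 minus the stop-codon mass)."""
    pf = np.asarray(position_freqs, dtype=float)
    if pf.shape != (3, 4):
        raise ValueError("position_freqs must be 3x4")
    if np.any(pf < 0) or not np.allclose(pf.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each row of position_freqs must be a probability vector")
    nt_index = {b: i for i, b in enumerate("ACGT")}
    pi = np.array([
        pf[0, nt_index[c[0]]] * pf[1, nt_index[c[1]]] * pf[2, nt_index[c[2]]]
        for c in code.sense_codons
    ])
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate position frequencies: zero sense-codon mass")
    return pi / total


def f61_frequencies(codon_counts: np.ndarray, code: GeneticCode,
                    pseudocount: float = 1.0) -> np.ndarray:
    """Observed sense-codon proportions (the F61 estimator).

    ``codon_counts`` is a length-61 count vector in sense-codon order.
    Unobserved codons receive ``pseudocount`` before normalization so the
    stationary distribution has no structural zeros.
    """
    counts = np.asarray(codon_counts, dtype=float).copy()
    if counts.shape != (code.n_sense,):
        raise ValueError(f"expected {code.n_sense} codon counts")
    if counts.sum() <= 0:
        raise ValueError("empty alignment: no unambiguous codons observed")
    counts[counts == 0] = pseudocount
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# rate matrix construction
# ---------------------------------------------------------------------------

@dataclass
class RateMatrix:
    """An instantaneous rate matrix with its stationary distribution.

    ``mu`` is the expected number of substitutions per codon site per unit
    time under (Q, pi).  After default normalization mu == 3, i.e. one
    substitution per nucleotide site per unit time.
    """

    Q: np.ndarray
    pi: np.ndarray
    mu: float


def _nuc_pair_key(a: str, b: str) -> int:
    return NUC_PAIR_INDEX["".join(sorted((a, b)))]


def _code_skeleton(code: GeneticCode) -> dict:
    """Structural arrays of the rate matrix for a genetic code: entry
    coordinates, nucleotide-exchange indices, substituted positions and
    amino-acid pair classes.  Parameter-independent, cached on the code."""
    cached = getattr(code, "_rate_skeleton", None)
    if cached is not None:
        return cached
    n = code.n_sense
    nt_index = {b: i for i, b in enumerate("ACGT")}
    one = {k: [] for k in ("rows", "cols", "nuc", "pos", "tgt", "cls")}
    ms = {k: [] for k in ("rows", "cols", "kind", "nuc3")}
    for i in range(n):
        ci = code.sense_codons[i]
        for j in range(n):
            if i == j:
                continue
            cj = code.sense_codons[j]
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) == 1:
                pos = diffs[0]
                pc = code.classify_codon_pair(ci, cj)
                one["rows"].append(i)
                one["cols"].append(j)
                one["nuc"].append(_nuc_pair_key(ci[pos], cj[pos]))
                one["pos"].append(pos)
                one["tgt"].append(nt_index[cj[pos]])
                one["cls"].append(-1 if pc.synonymous else code.pair_index[pc.aa_pair])
            else:
                syn = code.codon_to_aa[ci] == code.codon_to_aa[cj]
                # multistep order: (syn_2nt, syn_3nt, nonsyn_2nt, nonsyn_3nt)
                ms["rows"].append(i)
                ms["cols"].append(j)
                ms["kind"].append((0 if syn else 2) + (len(diffs) - 2))
                ms["nuc3"].append([_nuc_pair_key(ci[p], cj[p]) if p in diffs
                                   else -1 for p in range(3)])
    skel = {
        "rows": np.array(one["rows"]), "cols": np.array(one["cols"]),
        "nuc": np.array(one["nuc"]), "pos": np.array(one["pos"]),
        "tgt": np.array(one["tgt"]), "cls": np.array(one["cls"]),
        "ms_rows": np.array(ms["rows"], dtype=int),
        "ms_cols": np.array(ms["cols"], dtype=int),
        "ms_kind": np.array(ms["kind"], dtype=int),
        "ms_nuc3": np.array(ms["nuc3"], dtype=int),
    }
    code._rate_skeleton = skel
    return skel


class RateMatrixBuilder:
    """Holds the mutational component (nucleotide rates and frequencies) of
    the rate matrix over a cached structural skeleton, so that matrices for
    many candidate structures (differing only in class rates) -- and many
    mutational-parameter values -- can be assembled cheaply."""

    def __init__(self, code: GeneticCode, nuc_rates, freq_mode: str = "MG",
                 position_freqs=None, codon_freqs=None, multistep: bool = False):
        self.code = code
        self.freq_mode = freq_mode
        self.nuc_rates = np.asarray(nuc_rates, dtype=float)
        n = code.n_sense
        if freq_mode == "MG":
            self.position_freqs = np.asarray(position_freqs, dtype=float)
            self.pi = mg_codon_frequencies(self.position_freqs, code)
        elif freq_mode == "F61":
            cf = np.asarray(codon_freqs, dtype=float)
            if cf.shape != (n,) or np.any(cf <= 0):
                raise ValueError("codon_freqs must be 61 positive values")
            self.pi = cf / cf.sum()
        else:
            raise ValueError(f"unknown freq_mode {freq_mode!r}")
        if multistep and freq_mode != "F61":
            raise ValueError("multi-step entries require the GY/F61 parameterization")
        self.multistep = multistep

        skel = _code_skeleton(code)
        self._rows = skel["rows"]
        self._cols = skel["cols"]
        self._cls = skel["cls"]
        self._syn_mask = self._cls < 0
        theta = self.nuc_rates[skel["nuc"]]
        if freq_mode == "MG":
            f = self.position_freqs[skel["pos"], skel["tgt"]]
        else:
            f = self.pi[self._cols]
        self._base = theta * f
        self._ms_rows = skel["ms_rows"]
        self._ms_cols = skel["ms_cols"]
        self._ms_kind = skel["ms_kind"]
        if multistep:
            nuc3 = skel["ms_nuc3"]
            theta3 = np.where(nuc3 >= 0,
                              self.nuc_rates[np.clip(nuc3, 0, None)], 1.0)
            self._ms_base = theta3.prod(axis=1) * self.pi[self._ms_cols]
        else:
            self._ms_base = np.zeros(len(self._ms_rows))

    def pair_entry_map(self):
        """(rows, cols, base, class_index) for one-step entries; class -1
        marks synonymous events."""
        return self._rows, self._cols, self._base, self._cls

    def build(self, structure: ModelStructure, class_rates,
              omega_s: Optional[float] = None, ms_rates=None,
              normalize: bool = True) -> RateMatrix:
        class_rates = np.asarray(class_rates, dtype=float)
        if class_rates.shape != (structure.K,):
            raise ValueError("class_rates length must equal structure.K")
        pair_to_class = np.asarray(structure.assignment)
        n = self.code.n_sense
        vals = self._base.copy()
        nonsyn = ~self._syn_mask
        rate_of_entry = class_rates[pair_to_class[self._cls[nonsyn]]]
        if omega_s is not None:
            rate_of_entry = rate_of_entry * omega_s
        vals[nonsyn] *= rate_of_entry
        Q = np.zeros((n, n))
        Q[self._rows, self._cols] = vals
        if self.multistep:
            if ms_rates is None:
                raise ValueError("builder configured with multistep=True; ms_rates required")
            ms_rates = np.asarray(ms_rates, dtype=float)
            ms_vals = self._ms_base * ms_rates[self._ms_kind]
            if omega_s is not None:
                ms_vals = np.where(self._ms_kind >= 2, ms_vals * omega_s, ms_vals)
            Q[self._ms_rows, self._ms_cols] = ms_vals
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(self.pi @ np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate model: zero expected substitution rate")
        if normalize:
            Q = Q * (3.0 / mu)  # one expected substitution per nucleotide site
            mu = 3.0
        return RateMatrix(Q=Q, pi=self.pi, mu=mu)


def build_rate_matrix(structure: ModelStructure, params: ModelParameters,
                      code: GeneticCode, normalize: bool = True) -> RateMatrix:
    """Assemble the rate matrix for one structured model.

    Convenience wrapper over :class:`RateMatrixBuilder` for one-off use;
    repeated construction over many structures should reuse a builder.
    """
    builder = RateMatrixBuilder(
        code, params.nuc_rates, params.freq_mode,
        position_freqs=params.position_freqs, codon_freqs=params.codon_freqs,
        multistep=params.multistep is not None,
    )
    return builder.build(structure, params.class_rates, omega_s=params.omega_s,
                         ms_rates=params.multistep, normalize=normalize)


def expected_substitution_rate(rm: RateMatrix) -> float:
    """mu = -sum_i pi_i Q_ii, substitutions per codon site per unit time."""
    mu = -float(rm.pi @ np.diag(rm.Q))
    if mu <= 0:
        raise ValueError("degenerate model: zero expected substitution rate")
    return mu


def solve_unit_time(rm: RateMatrix) -> float:
    """The time t* at which mu * t* = 1 (one substitution per codon site)."""
    return 1.0 / expected_substitution_rate(rm)


# ---------------------------------------------------------------------------
# transition probabilities via the symmetrized eigendecomposition
# ---------------------------------------------------------------------------

class SpectralMatrix:
    """Eigendecomposition of a reversible Q for fast exp(Q t) at many t.

    Reversibility makes D^{1/2} Q D^{-1/2} symmetric (D = diag(pi)), so a
    single symmetric eigendecomposition yields P(t) for any t with two
    matrix products.
    """

    def __init__(self, rm: RateMatrix):
        pi = rm.pi
        sq = np.sqrt(pi)
        B = (sq[:, None] * rm.Q) / sq[None, :]
        B = 0.5 * (B + B.T)
        lam, U = _scipy_eigh(B, check_finite=False, overwrite_a=True,
                             driver="evd")
        self.lam = lam
        # fold the diagonal similarity into the eigenvector matrices
        self._left = U / sq[:, None]      # D^{-1/2} U
        self._right = (U * sq[:, None]).T  # U^T D^{1/2}
        self.pi = pi

    def transition(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self.lam * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P

    def transitions(self, ts: np.ndarray) -> np.ndarray:
        """Batched P(t) for an array of branch lengths: (len(ts), n, n)."""
        ts = np.asarray(ts, dtype=float)
        E = np.exp(ts[:, None] * self.lam[None, :])
        P = (self._left[None, :, :] * E[:, None, :]) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P

    def transitions_T(self, ts: np.ndarray, dtype=np.float64) -> np.ndarray:
        """Batched transposed matrices P(t).T, contiguous, optionally in
        float32 -- the layout the pattern-major pruning consumes."""
        ts = np.asarray(ts, dtype=float)
        if dtype == np.float32:
            if not hasattr(self, "_leftT32"):
                self._leftT32 = np.ascontiguousarray(self._left.T,
                                                     dtype=np.float32)
                self._rightT32 = np.ascontiguousarray(self._right.T,
                                                      dtype=np.float32)
            leftT, rightT = self._leftT32, self._rightT32
            E = np.exp(ts[:, None] * self.lam[None, :]).astype(np.float32)
        else:
            leftT, rightT = self._left.T, self._right.T
            E = np.exp(ts[:, None] * self.lam[None, :])
        # P.T = right.T @ (E * left.T-by-row)
        PT = rightT[None, :, :] @ (E[:, :, None] * leftT[None, :, :])
        np.clip(PT, 0.0, None, out=PT)
        return PT
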