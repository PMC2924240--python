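"""Genetic-code tables and the combinatorics of codon substitution classes.

Everything downstream is indexed against two ordered collections derived
from a genetic code: the sense codons (61 under the universal code,
lexicographic over A<C<G<T) and the one-step amino-acid pairs -- unordered
pairs of distinct residues that can be exchanged by a single nucleotide
substitution between sense codons (75 of 190 possible pairs under the
universal code).  Multi-rate codon models are vectors over the one-step
pairs, so the deterministic ordering established here is what makes model
structures comparable and serializable across runs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Optional

from Bio.Data import CodonTable as _BioCodonTable

NUCLEOTIDES = "ACGT"
STOP = "*"

#: canonical ordering of the six unordered nucleotide exchange classes
NUC_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")
NUC_PAIR_INDEX = {p: i for i, p in enumerate(NUC_PAIRS)}


def _norm_codon(codon: str) -> str:
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in NUCLEOTIDES for b in c):
        raise ValueError(f"invalid codon {codon!r}: expected 3 characters over ACGT/U")
    return c


@dataclass(frozen=True)
class PairClass:
    """Classification of an (i, j) codon pair into a rate-matrix branch.

    kind is one of ``identical``, ``synonymous_1step``,
    ``nonsynonymous_1step``, ``multi_step`` or ``involves_stop``.
    ``aa_pair`` is set for non-synonymous one-step events; ``synonymous``
    for multi-step events.
    """

    kind: str
    n_diffs: int
    aa_pair: Optional[tuple[str, str]] = None
    synonymous: Optional[bool] = None


class GeneticCode:
    """A codon->amino-acid table plus derived index structures."""

    def __init__(self, name: str, codon_to_aa: dict[str, str]):
        table = {_norm_codon(c): aa for c, aa in codon_to_aa.items()}
        if len(table) != 64:
            raise ValueError(f"code {name!r} defines {len(table)} codons, expected 64")
        self.name = name
        self.codon_to_aa = table
        self.sense_codons: tuple[str, ...] = tuple(
            sorted(c for c, aa in table.items() if aa != STOP)
        )
        self.stop_codons: tuple[str, ...] = tuple(
            sorted(c for c, aa in table.items() if aa == STOP)
        )
        self.codon_index = {c: i for i, c in enumerate(self.sense_codons)}
        self.aa_pairs_one_step: tuple[tuple[str, str], ...] = self._one_step_pairs()
        self.pair_index = {p: i for i, p in enumerate(self.aa_pairs_one_step)}

    @classmethod
    def universal(cls) -> "GeneticCode":
        return cls.from_ncbi_id(1)

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
        table = {c: STOP for c in bio.stop_codons}
        table.update(bio.forward_table)
        return cls(bio.names[0] if bio.names else f"ncbi-{table_id}", table)

    @classmethod
    def from_json(cls, path_or_dict) -> "GeneticCode":
        """Load a code from the JSON override format {codon: symbol}."""
        if isinstance(path_or_dict, dict):
            doc = path_or_dict
        else:
            with open(path_or_dict) as fh:
                doc = json.load(fh)
        name = doc.get("name", "custom")
        return cls(name, doc["codon_to_aa"] if "codon_to_aa" in doc else
                   {k: v for k, v in doc.items() if k != "name"})

    # -- basic operations ------------------------------------------------

    def translate(self, codon: str) -> str:
        """Translate one codon; returns ``*`` for stop codons."""
        return self.codon_to_aa[_norm_codon(codon)]

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    @property
    def n_pairs(self) -> int:
        return len(self.aa_pairs_one_step)

    def _one_step_pairs(self) -> tuple[tuple[str, str], ...]:
        pairs = set()
        for ci in self.sense_codons:
            for pos in range(3):
                for b in NUCLEOTIDES:
                    if b == ci[pos]:
                        continue
                    cj = ci[:pos] + b + ci[pos + 1:]
                    aj = self.codon_to_aa[cj]
                    ai = self.codon_to_aa[ci]
                    if aj != STOP and aj != ai:
                        pairs.add(tuple(sorted((ai, aj))))
        return tuple(sorted(pairs))

    def classify_codon_pair(self, ci: str, cj: str) -> PairClass:
        """Assign the (ci, cj) entry of the rate matrix to its branch.

        Symmetric in its arguments.  Stop codons short-circuit to
        ``involves_stop`` regardless of the number of differences.
        """
        ci, cj = _norm_codon(ci), _norm_codon(cj)
        ai, aj = self.codon_to_aa[ci], self.codon_to_aa[cj]
        if ai == STOP or aj == STOP:
            return PairClass("involves_stop", sum(a != b for a, b in zip(ci, cj)))
        nd = sum(a != b for a, b in zip(ci, cj))
        if nd == 0:
            return PairClass("identical", 0)
        if nd == 1:
            if ai == aj:
                return PairClass("synonymous_1step", 1, synonymous=True)
            return PairClass(
                "nonsynonymous_1step", 1, aa_pair=tuple(sorted((ai, aj))),
                synonymous=False,
            )
        return PairClass("multi_step", nd, synonymous=ai == aj,
                         aa_pair=None if ai == aj else tuple(sorted((ai, aj))))

    def total_aa_pairs(self) -> int:
        """Number of unordered pairs of distinct residues in the code."""
        aas = {aa for aa in self.codon_to_aa.values() if aa != STOP}
        n = len(aas)
        return n * (n - 1) // 2

    def one_step_codon_pairs(self):
        """Ordered (i, j) sense-codon index pairs differing at one position.

        Yields (i, j, pos, class) with i < j, where ``pos`` is the differing
        position and ``class`` the :class:`PairClass`.
        """
        for i, j in itertools.combinations(range(self.n_sense), 2):
            ci, cj = self.sense_codons[i], self.sense_codons[j]
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) == 1:
                yield i, j, diffs[0], self.classify_codon_pair(ci, cj)

    def __repr__(self):  # pragma: no cover
        return f"GeneticCode({self.name!r}, {self.n_sense} sense codons, {self.n_pairs} one-step pairs)"


def translate(codon: str, code: GeneticCode) -> str:
    return code.translate(codon)


def sense_codon_count(code: GeneticCode) -> int:
    return code.n_sense


def one_step_pairs(code: GeneticCode) -> tuple[tuple[str, str], ...]:
    return code.aa_pairs_one_step


def classify_codon_pair(ci: str, cj: str, code: GeneticCode) -> PairClass:
    return code.classify_codon_pair(ci, cj)
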