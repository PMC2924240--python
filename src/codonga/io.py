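"""File formats: alignments, trees, model JSON documents, reports.

Alignments must be in frame (length divisible by 3); codons containing
gaps or ambiguity codes become missing data, internal stop codons are
rejected with the offending taxon and 1-based codon position.  Models are
exchanged as versioned JSON documents carrying the structure vector, all
parameter values, the normalization convention and run provenance, so a
fitted or model-averaged matrix can be applied to validation alignments.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import numpy as np
from Bio import AlignIO, SeqIO

from .averaging import AveragedModel
from .codon_model import ModelParameters, ModelStructure
from .genetic_code import GeneticCode
from .likelihood import CodonAlignment, Phylogeny

MODEL_FORMAT = "codonga-model/1"
NORMALIZATION = "substitutions-per-nucleotide-site"

__all__ = [
    "read_codon_alignment",
    "write_fasta",
    "read_tree",
    "write_tree",
    "write_model_json",
    "read_model_json",
    "config_hash",
]


def read_codon_alignment(path, fmt: str = "fasta",
                         code: Optional[GeneticCode] = None) -> CodonAlignment:
    """Read a FASTA or (relaxed) PHYLIP codon alignment."""
    code = code if code is not None else GeneticCode.universal()
    if fmt == "fasta":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    elif fmt == "phylip":
        msa = AlignIO.read(str(path), "phylip-relaxed")
        seqs = {rec.id: str(rec.seq) for rec in msa}
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    lengths = {name: len(s) for name, s in seqs.items()}
    for name, L in lengths.items():
        if L % 3 != 0:
            raise ValueError(
                f"sequence {name!r} has length {L}, not divisible by 3")
    return CodonAlignment.from_sequences(seqs, code)


def write_fasta(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for r, name in enumerate(aln.names):
            fh.write(f">{name}\n{aln.sequence_string(r)}\n")


def read_tree(path) -> Phylogeny:
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


def write_tree(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _params_doc(params: ModelParameters) -> dict:
    doc = {
        "nuc_rates": params.nuc_rates.tolist(),
        "freq_mode": params.freq_mode,
        "omega_s": params.omega_s,
    }
    if params.position_freqs is not None:
        doc["position_freqs"] = params.position_freqs.tolist()
    if params.codon_freqs is not None:
        doc["codon_freqs"] = params.codon_freqs.tolist()
    if params.multistep is not None:
        doc["multistep"] = params.multistep.tolist()
    return doc


def write_model_json(path, *, structure: Optional[ModelStructure] = None,
                     params: Optional[ModelParameters] = None,
                     averaged: Optional[AveragedModel] = None,
                     code: Optional[GeneticCode] = None,
                     lnL: Optional[float] = None, p: Optional[int] = None,
                     mbic: Optional[float] = None,
                     provenance: Optional[dict] = None) -> None:
    """Serialize a structured or model-averaged (empirical) model."""
    code = code if code is not None else GeneticCode.universal()
    doc: dict = {
        "format": MODEL_FORMAT,
        "code": code.name,
        "normalization": NORMALIZATION,
        "provenance": provenance or {},
    }
    if lnL is not None:
        doc["lnL"] = lnL
    if p is not None:
        doc["p"] = p
    if mbic is not None:
        doc["mbic"] = mbic
    if averaged is not None:
        doc["kind"] = "empirical"
        doc["pair_rates"] = averaged.rates.tolist()
        doc["same_class_prob"] = averaged.same_class_prob.tolist()
        doc["credible_threshold"] = averaged.threshold
        if averaged.omega_s is not None:
            doc["omega_s"] = averaged.omega_s
        if params is not None:
            doc["params"] = _params_doc(params)
    else:
        if structure is None or params is None:
            raise ValueError("structured models need structure and params")
        doc["kind"] = "structured"
        doc["K"] = structure.K
        doc["assignment"] = list(structure.assignment)
        doc["class_rates"] = params.class_rates.tolist()
        doc["params"] = _params_doc(params)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_model_json(path) -> dict:
    """Read a model document; returns a dict with decoded objects under
    'structure', 'params', 'averaged' keys as applicable."""
    with open(path) as fh:
        doc = json.load(fh)
    fmt = doc.get("format")
    if fmt != MODEL_FORMAT:
        raise ValueError(f"unsupported model format {fmt!r}; expected {MODEL_FORMAT}")
    if "normalization" not in doc:
        raise ValueError("model document lacks the normalization field")
    out = dict(doc)
    if "params" in doc:
        pd = doc["params"]
        kind = doc["kind"]
        class_rates = (np.asarray(doc["class_rates"]) if kind == "structured"
                       else np.ones(1))
        out["params"] = ModelParameters(
            np.asarray(pd["nuc_rates"]), class_rates, pd["freq_mode"],
            position_freqs=np.asarray(pd["position_freqs"]) if "position_freqs" in pd else None,
            codon_freqs=np.asarray(pd["codon_freqs"]) if "codon_freqs" in pd else None,
            multistep=np.asarray(pd["multistep"]) if "multistep" in pd else None,
            omega_s=pd.get("omega_s"),
        )
    if doc["kind"] == "structured":
        out["structure"] = ModelStructure(tuple(doc["assignment"]), doc["K"])
    else:
        out["averaged"] = AveragedModel(
            rates=np.asarray(doc["pair_rates"]),
            same_class_prob=np.asarray(doc["same_class_prob"]),
            weights=np.asarray(doc.get("weights", [1.0])),
            threshold=doc.get("credible_threshold", 0.01),
            omega_s=doc.get("omega_s"),
        )
    return out
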