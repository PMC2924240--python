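"""Model comparison via substitution spectra, and site-level selection tests.

The substitution spectrum of a fitted model is the 75-vector of expected
per-site counts of each one-step amino-acid pair substitution over one
normalized unit of evolutionary time (t* chosen so that mu t* = 1); it is
invariant to rescaling of Q, and Euclidean distances between spectra give
a model-comparison metric from which neighbor-joining trees of models can
be built.

The multi-rate site test generalizes the fixed-effects likelihood (FEL)
test for selection: at each site, a site-specific synonymous rate and K
site-specific class rates are estimated with everything else held at the
gene-wide MLEs, and each class rate is in turn constrained to equal the
synonymous rate (neutral evolution in that class) for a 1-df likelihood
ratio test, Bonferroni-corrected over the K per-site tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .codon_model import (
    ModelStructure,
    RateMatrix,
    RateMatrixBuilder,
)
from .genetic_code import GeneticCode
from .likelihood import CodonAlignment, FitResult, PhyloEvaluator, Phylogeny

__all__ = [
    "substitution_spectrum",
    "spectrum_distance",
    "model_distance_matrix",
    "nj_tree",
    "SiteTestResult",
    "multirate_fel",
]


def substitution_spectrum(rm: RateMatrix, code: GeneticCode) -> np.ndarray:
    """Expected one-step non-synonymous substitution counts per amino-acid
    pair per site over normalized time t* = 1/mu.

    Uses the rate-based expectation pi_i Q_ij t* (the time-reversibility
    simplification); invariant under any rescaling of Q.
    """
    mu = -float(rm.pi @ np.diag(rm.Q))
    if mu <= 0:
        raise ValueError("degenerate model: zero expected substitution rate")
    t_star = 1.0 / mu
    spectrum = np.zeros(code.n_pairs)
    for i, j, _pos, pc in code.one_step_codon_pairs():
        if pc.aa_pair is None:
            continue
        e = code.pair_index[pc.aa_pair]
        spectrum[e] += (rm.pi[i] * rm.Q[i, j] + rm.pi[j] * rm.Q[j, i]) * t_star
    return spectrum


def spectrum_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Euclidean distance between two substitution spectra."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("spectra must have the same length")
    return float(np.linalg.norm(s1 - s2))


def model_distance_matrix(spectra: Sequence[np.ndarray]) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise spectrum distances."""
    m = len(spectra)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = spectrum_distance(spectra[i], spectra[j])
    return D


def nj_tree(distance_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Neighbor-joining tree (Newick) from a model distance matrix."""
    D = np.asarray(distance_matrix, dtype=float)
    if D.shape[0] < 3:
        raise ValueError("neighbor joining requires at least 3 models")
    tree = _skbio_nj(DistanceMatrix(D, ids=list(labels)))
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# multi-rate FEL
# ---------------------------------------------------------------------------

@dataclass
class SiteTestResult:
    """Per-site likelihood-ratio tests of neutrality, one per rate class."""

    site: int                      # 0-based codon column
    syn_rate: float
    class_rates: np.ndarray        # unconstrained site-specific MLEs
    lrt: np.ndarray                # K statistics, >= 0
    pvalues: np.ndarray            # chi-squared(1) upper tails
    significant: np.ndarray        # Bonferroni-corrected flags (two-sided)
    diversifying: np.ndarray = None  # class rate above the synonymous rate
    invariant: bool = False

    def __post_init__(self):
        if self.diversifying is None:
            self.diversifying = np.asarray(self.class_rates) > self.syn_rate


def _site_evaluator(aln: CodonAlignment, tree: Phylogeny, s: int) -> PhyloEvaluator:
    col = aln.codes[:, s: s + 1]
    sub = CodonAlignment(aln.names, col, aln.code)
    return PhyloEvaluator(sub, tree)


def multirate_fel(aln: CodonAlignment, tree: Phylogeny,
                  structure: ModelStructure, fit: FitResult,
                  alpha: float = 0.05, sites: Optional[Sequence[int]] = None,
                  bonferroni_sites: bool = False) -> list[SiteTestResult]:
    """Site-by-site selection tests under a fitted multi-rate model.

    Branch lengths and the mutational component stay at the gene-wide MLEs.
    For each site, the unconstrained model has one synonymous rate and K
    class-rate multipliers; each class rate is then pinned to the
    synonymous rate for a chi-squared(1) LRT.  Sites with no variation are
    reported with statistic 0 and p = 1 without optimization.
    """
    code = aln.code
    params = fit.params
    K = structure.K
    builder = RateMatrixBuilder(
        code, params.nuc_rates, params.freq_mode,
        position_freqs=params.position_freqs, codon_freqs=params.codon_freqs,
    )
    # global normalization constant: branch lengths were estimated under the
    # normalized gene-wide matrix, so per-site matrices share its time scale
    raw = builder.build(structure, params.class_rates, normalize=False)
    scale0 = 3.0 / raw.mu
    lengths = fit.branch_lengths
    site_list = list(sites) if sites is not None else list(range(aln.n_codon_sites))
    n_tests = K * (len(site_list) if bonferroni_sites else 1)
    threshold = alpha / n_tests

    results = []
    for s in site_list:
        col = aln.codes[:, s]
        observed = np.unique(col[col >= 0])
        if len(observed) <= 1:
            results.append(SiteTestResult(
                site=s, syn_rate=1.0,
                class_rates=params.class_rates.copy(),
                lrt=np.zeros(K), pvalues=np.ones(K),
                significant=np.zeros(K, dtype=bool),
                diversifying=np.zeros(K, dtype=bool), invariant=True,
            ))
            continue
        ev = _site_evaluator(aln, tree, s)

        def site_lnl(syn: float, rates: np.ndarray) -> float:
            rm = builder.build(structure, np.asarray(rates) / syn, normalize=False)
            rm = RateMatrix(Q=rm.Q * (syn * scale0), pi=rm.pi, mu=rm.mu * syn * scale0)
            return ev.log_likelihood(rm, lengths)

        lb, ub = np.log(1e-4), np.log(50.0)
        start = np.log(np.clip(
            np.concatenate([[1.0], params.class_rates]), 2e-4, 45.0))

        def nll_u(x):
            return -site_lnl(np.exp(x[0]), np.exp(x[1:]))

        res_u = optimize.minimize(nll_u, start, method="L-BFGS-B",
                                  bounds=[(lb, ub)] * (K + 1),
                                  options={"ftol": 1e-9, "maxiter": 100})
        lnl_u = -float(res_u.fun)
        syn_hat = float(np.exp(res_u.x[0]))
        rates_hat = np.exp(res_u.x[1:])

        lrt = np.zeros(K)
        pvals = np.ones(K)
        for k in range(K):
            free = [i for i in range(K + 1) if i != k + 1]

            def nll_c(x, _k=k, _free=free):
                full = np.empty(K + 1)
                full[_free] = x
                full[_k + 1] = x[0]  # class k rate tied to the synonymous rate
                return -site_lnl(np.exp(full[0]), np.exp(full[1:]))

            res_c = optimize.minimize(nll_c, res_u.x[free], method="L-BFGS-B",
                                      bounds=[(lb, ub)] * K,
                                      options={"ftol": 1e-9, "maxiter": 100})
            lnl_c = -float(res_c.fun)
            lrt[k] = max(0.0, 2.0 * (lnl_u - lnl_c))
            pvals[k] = float(stats.chi2.sf(lrt[k], df=1))

        results.append(SiteTestResult(
            site=s, syn_rate=syn_hat, class_rates=rates_hat,
            lrt=lrt, pvalues=pvals, significant=pvals < threshold,
        ))
    return results
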