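"""Multi-rate site-level selection tests (FEL generalized to K classes).

At each codon site, a site-specific synonymous rate and K class-rate
multipliers are estimated; each class rate is then constrained to the
synonymous rate (neutrality in that class) for a 1-df likelihood-ratio
test.  Sites simulated with an elevated fast class should be flagged for
that class, while background sites should not.
"""

import numpy as np

import codonga as cg

code = cg.GeneticCode.universal()
base = cg.SimulationDesign(n_taxa=8, divergence=1.0, n_codon_sites=20,
                           class_rates=(0.2, 0.4), seed=37)
hot = cg.SimulationDesign(n_taxa=8, divergence=1.0, n_codon_sites=20,
                          class_rates=(0.2, 8.0), seed=37)
aln_b, structure, tree, params = cg.simulate_alignment(base, 0, code)
aln_h, _, _, _ = cg.simulate_alignment(hot, 0, code)
combined = cg.CodonAlignment(aln_b.names,
                             np.hstack([aln_b.codes, aln_h.codes]), code)
print(f"{combined.n_codon_sites} sites: 1-20 background (rates 0.2/0.4), "
      "21-40 with the fast class at 8.0 (diversifying)")

fit = cg.fit_model(structure, combined, tree, start=params, rounds=1,
                   optimize_frequencies=False)
results = cg.multirate_fel(combined, tree, structure, fit, alpha=0.05)

print(f"\n{'site':>4} {'syn':>6} {'r1':>6} {'r2':>6} {'LRT2':>7} {'p2':>8} flag")
n_flagged_hot = n_flagged_bg = 0
for r in results:
    # the LRT rejects neutrality in either direction; positive selection is
    # a significant test where the class rate exceeds the synonymous rate
    positive = bool(r.significant[1] and r.diversifying[1])
    flag = "+" if positive else ("-" if r.significant[1] else "")
    if positive:
        if r.site >= 20:
            n_flagged_hot += 1
        else:
            n_flagged_bg += 1
    if flag or r.site in (0, 20):
        print(f"{r.site + 1:>4} {r.syn_rate:>6.2f} {r.class_rates[0]:>6.2f} "
              f"{r.class_rates[1]:>6.2f} {r.lrt[1]:>7.2f} {r.pvalues[1]:>8.4f} {flag}")
print(f"\nfast-class positive-selection flags: {n_flagged_hot}/20 elevated "
      f"sites, {n_flagged_bg}/20 background sites "
      "(Bonferroni-corrected over the K=2 tests per site; '-' marks "
      "significant purifying departures)")
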