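# Methods

## The model

Codon evolution is modeled as a continuous-time, homogeneous, stationary
and time-reversible Markov process on the 61 sense codons of the universal
genetic code (alternate codes are supported by table swap; the constants
61 and 75 below are universal-code values).  The instantaneous rate from
codon `i` to codon `j` is non-zero only when the codons differ at exactly
one nucleotide position (unless the multi-step extension is enabled) and
factors as

    q_ij = theta_xy * f_ij * r_ij

where `theta_xy` is the exchangeability of the two nucleotides involved
(six unordered pairs; the AG rate is fixed at 1 for identifiability and
the other five are estimated), `f_ij` is a frequency factor, and `r_ij`
is 1 for synonymous changes and the rate of the amino-acid pair's class
for non-synonymous changes.  Rates are therefore measured relative to the
synonymous rate.

Two frequency parameterizations are supported:

* **MG** — `f_ij` is the frequency of the target nucleotide at the
  substituted codon position; 3 positions x 3 free parameters = 9, fitted
  by maximum likelihood (initialized from observed counts).  Codon
  equilibrium frequencies are the product of positional frequencies
  renormalized by the sense-codon mass.
* **GY / F61** — `f_ij` is the equilibrium frequency of the target codon,
  estimated by observed codon proportions (60 free parameters).  Codons
  never observed receive a pseudo-count of 1 before normalization so the
  stationary distribution has no structural zeros.

A *structured* (multi-rate) model partitions the 75 one-step amino-acid
pairs into K classes, one estimated rate per class: K=1 is the standard
single-rate (SR) model, K=75 the fully general reversible (REV) model.
The partition is stored as a length-75 integer vector over the
lexicographically ordered pairs; structures are compared after canonical
relabeling (by first occurrence for deduplication, by increasing fitted
rate for reporting).

Optional extensions: a four-parameter multi-nucleotide component
(synonymous/non-synonymous x two/three simultaneous changes, defined for
the GY/F61 parameterization, each entry the product of the per-position
nucleotide rates, the target codon frequency and the matching parameter)
and a single global scaler multiplying every non-synonymous entry (used
when a fixed, externally estimated matrix is applied to new data).

Q is rescaled so one unit of time produces one expected substitution per
*nucleotide* site (one third of the per-codon-site rate); Newick branch
lengths are therefore in the conventional substitutions-per-nucleotide
units throughout.

## Likelihood

The likelihood on a fixed rooted tree is computed by the standard pruning
recursion over unique site patterns with per-node rescaling.  Transition
matrices come from the symmetrized eigendecomposition of Q (one symmetric
eigensolve per matrix, two dense products per branch length), batched over
branches.  Codons containing gaps or ambiguity codes are fully missing
(all-ones partial vectors); internal stop codons are rejected at parse
time.  For two-sequence alignments the likelihood reduces, by
reversibility, to a 61x61 codon-pair count matrix against
`pi_i P_ij(t1+t2)`, making evaluation cost independent of alignment
length.

Continuous parameters are estimated by bounded quasi-Newton (L-BFGS-B) on
log-transformed rates (frequencies through per-position softmax logits),
alternating with coordinate-wise branch-length passes (bounded scalar
minimization per branch, reusing the eigendecomposition).  Candidate
structures inside the GA are scored by optimizing only their K class
rates with a cheap warm-started coordinate-Newton refinement (start
values are class-wise geometric means of per-pair profile rates, obtained
once per run by a single backfitting sweep toward REV); models that reach
the accept/reject decision are refit jointly with tight tolerances.

The information-criterion sample size `n` is the number of characters,
by default sequences x codon columns (configurable to columns only or to
nucleotide characters).  The parameter count `p` is K + 5 nucleotide
rates + 9 (MG) or 60 (F61) frequency parameters (+4 multi-step, +1
scaler); branch lengths are shared by all compared models on a fixed tree
and are excluded by default.

## Model search

The fitness of a structure is a modified BIC,

    mBIC = -2 lnL + c * p * ln(n),   c = 2 by default,

i.e. a BIC with the parameter penalty doubled: the discrete freedom of
the partition adds degrees of freedom beyond the parameter count, and the
doubled penalty compensates.  The number of classes is chosen by a
K-increment loop: fit SR (including branch lengths), then repeatedly run
a GA over (K+1)-class partitions seeded by random splits of the largest
class of the incumbent best; the increment is accepted only when the
refit best improves mBIC, and the loop stops at the first rejection.
Branch lengths are approximated under SR, held fixed during candidate
scoring, re-estimated under the incumbent best whenever the best fitness
improves by more than 50 mBIC points since the last re-estimation, and
refit for every model reaching the accept/reject decision.

The GA is generational with elitism (2), tournament selection (size 3),
uniform crossover (probability 0.8; the lexicographic ordering of the 75
pairs carries no linkage, so allele-wise mixing propagates well-supported
assignments in parallel), per-element mutation (probability 2/75) and
occupancy repair (every class label must appear at least once).
Population size is 48.

### Search resolution and overfitting control

Two facts, established by simulation during development, shape the search
design.  First, with two sequences the maximum-likelihood gain of the
best spurious extra rate class over the true model is 15-25 log-likelihood
units *independent of alignment length* (it is a fixed fraction of the
~75-component between-pair noise deviance), which always exceeds the
mBIC acceptance threshold ln(n).  The criterion therefore controls
overfitting only in combination with a search of bounded resolution —
the penalty and the search are co-calibrated, and the published operating
characteristics (overfit proportion about 0.01 on single-rate data)
embody that joint calibration.  Second, genuine per-element signal grows
linearly with alignment length while per-element noise differentials do
not, so resolution can be made honest rather than ad hoc: differences
below a threshold are treated as statistically meaningless everywhere.

Concretely, three rules share one resolution scale:

* **selection deadband** — tournament comparisons treat mBIC differences
  within `min_improvement` (default 6 mBIC points, i.e. 3 lnL units) as
  ties, so drift-scale differences exert no selection pressure;
* **stagnation stop** — a generation counts as progress only when it
  improves the best score by more than `min_improvement`; the run stops
  after 15 stagnant generations (hard cap 150);
* **acceptance margin** — the K-increment is accepted only when it
  improves mBIC by more than the penalty-equivalent of the proposal's
  extra freedom: one rate parameter plus the partition choice the
  adaptive search maximizes over, i.e. `2 c ln(n)` by default
  (`accept_margin_params = 2`); smaller improvements are ties and
  parsimony retains the smaller K.

Scoring is two-stage at the same resolution: every candidate is screened
with a single likelihood evaluation at its warm-start rates (which
under-estimates the fitted score by well under the deadband), and only
the generation's top candidates (12 by default) receive full class-rate
fits; the archive, best-tracking and the stagnation rule use full fits
only.

On noise the search then drifts without compounding (typical spurious
gains stay well below the acceptance margin), while on well-separated
signal every correct reassignment is worth far more than the deadband and
the search converges to the generating partition.  These settings were
calibrated once on null (single-rate) simulations, mirroring how the
penalty factor itself was originally calibrated, and are recorded in
every run's configuration output.  Deliberately *uninformed* structure
seeding matters for the same reason: seeding generation 0 with partitions
derived from per-pair rate estimates hands the search near-optimal noise
partitions on null data and destroys the false-positive calibration (we
verified this), so profile rates are used only to warm-start the
continuous optimizer.

Candidate evaluations within a generation are independent; the archive
deduplicates by canonical structure and every result is reduced in
deterministic order, so runs are reproducible from config + seed.

## Model averaging

Every structure evaluated in a run is archived.  The evidence ratio of
model `i` against the best is `exp(-(mBIC_i - mBIC_best)/2)`; models with
evidence ratio >= 0.01 (configurable) form the credible set, with Akaike
weights `w_i = exp(-d_i/2) / sum exp(-d_j/2)`.  The model-averaged rates
are per-pair weighted sums of class-rate MLEs on the rate scale, and the
75x75 co-clustering matrix holds the weighted probability that two pairs
share a class.  The *cluster affinity* of a pair for the best model's
cluster containing it is the mean co-clustering probability with the
other members (1 for singletons); values below 0.5 flag ambiguous
membership under majority rule.  The averaged matrix can be applied to
other alignments as a fixed empirical model, optionally with one fitted
global non-synonymous scaler (p = 1).

## Simulation and evaluation

The simulator draws root states from the stationary distribution and
evolves them down each branch with exp(Qt), fully reproducible from
(seed, replicate).  Study conditions follow the published simulation
design: uniform positional nucleotide frequencies, HKY85 nucleotide bias,
generating partitions drawn by equal-probability binning of the 75 pairs
with all classes occupied, and divergence D measured as mean pairwise
expected substitutions per nucleotide site (two-sequence trees place the
root midway; multi-taxon designs use symmetric balanced trees with equal
branch lengths scaled to the target mean pairwise divergence).

Two design families are pre-configured.  Two-sequence designs default to
40 000 codons: the published dispersions of the rate estimates for these
designs (0.004-0.010 for rates 0.25/1.0) imply alignments of a few tens
of thousands of codons, at gene-size lengths the generating partition is
not even the maximum-likelihood partition (so membership recovery near 1
would be unattainable for any search), and at shorter long-alignment
scales occasional low-opportunity pairs masquerade as an intermediate
rate class and the information criterion itself prefers a spurious K+1.  Multi-taxon designs are gene-size (500
codons, 16 or 32 taxa).  Values not stated anywhere: the HKY85
transition/transversion ratio is 2.0 and the single-rate simulations use
omega = 0.5; both are ordinary vertebrate/viral-scale choices.

Evaluation reruns the full selection loop per replicate and reports P_K
(correct number of classes), P_under, P_over and the Rand statistic
between generating and inferred partitions, averaged over correct-K
replicates only.  The Rand statistic is the pair-counting agreement
(together-in-both + apart-in-both) / C(n,2) on the 75-pair index set.
The penalty-calibration experiment fits best models with K_true-1,
K_true and K_true+1 classes per replicate and reports, per candidate
penalty factor, the power and false-positive indicators from the scaled
log-likelihood differences.

What the simulator does *not* emulate: site-to-site rate variation,
indels and alignment error, recombination, non-stationarity and
non-reversibility, and selection heterogeneity along branches.  Passing
the simulation studies shows the selection machinery recovers the
generating regime under the model's own assumptions; it does not certify
behavior on real data violating them.

## Downstream comparisons

The substitution spectrum of a model is the 75-vector of expected
one-step non-synonymous substitution counts per site over the normalized
time t* = 1/mu, computed as `pi_i q_ij t*` summed over the generating
codon pairs in both directions (the rate-based form licensed by
reversibility; an integrated form over exp(Qt) agrees to first order at
t* and is not used).  Spectra are invariant to rescaling Q.  Models are
compared by Euclidean distance between spectra; neighbor joining on the
distance matrix (scikit-bio) yields model-clustering trees.

The multi-rate site test holds branch lengths and the mutational
component at their gene-wide MLEs, then per site estimates one synonymous
rate and K class multipliers (unconstrained) and, for each class in turn,
re-estimates with that class pinned to the synonymous rate.  Twice the
log-likelihood difference is referred to chi-squared(1); the constrained
fits re-estimate the site's other parameters.  Significance is
Bonferroni-corrected over the K tests per site (alpha/K, default alpha
0.05; genome-wide correction optional and off by default).  Invariant
sites are reported with statistic 0 and p = 1 without optimization.  With
K = 1 the procedure is exactly the classical FEL-style site test.

## Numerical choices

* Rates are optimized on the log scale with bounds [1e-5, 100]; frequency
  logits bounded at +/-12.
* Scoring tolerance: coordinate-Newton with step 0.22 on log rates, up to
  3 sweeps, early exit below 0.02 lnL gain; polishing fits use L-BFGS-B
  with ftol 1e-8.  Branch lengths: bounded Brent per branch, xatol 1e-4,
  2 passes per round.
* Transition probabilities are clipped at zero after reconstruction;
  partial likelihoods are rescaled per node by their column maxima.
* Ties for the best archived model break toward smaller K, then the
  lexicographically smallest canonical assignment.
* Degenerate inputs: alignments with no unambiguous codon, all-zero rate
  matrices, and mismatched taxon sets raise errors rather than warnings.

## Known limitations

* The search-resolution constants were calibrated on two-class,
  well-separated designs; very finely separated rate classes (e.g. 0.25
  vs 0.3) will often be merged — the procedure is deliberately
  conservative, trading power for overfitting control.
* The acceptance margin makes the effective threshold for adding a class
  three penalty units rather than one; on small alignments this further
  favors small K.
* Multi-step extension is defined for the GY/F61 parameterization only,
  and the GA searches single-step classes only (the four multi-step rates
  are global).
* The two-sequence fast path assumes reversibility (which holds for every
  matrix this package builds).
* Site tests assume the chi-squared(1) reference, which requires adequate
  per-site information: with few sequences (8 taxa) or saturated
  divergence, sites lacking synonymous variation drive the site-specific
  synonymous rate to its bound and the test becomes anticonservative
  (observed per-test rates up to 4x nominal); at 16-taxon gene-size
  conditions the observed rate matches the nominal level.  The tests are
  two-sided: a significant result with the class rate *above* the
  synonymous rate indicates diversifying selection (the ``diversifying``
  flag), below it purifying selection.
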