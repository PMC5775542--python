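# Methods

## Codon substitution model

Rates act on the 61 sense codons of the standard genetic code. The
instantaneous rate from codon *i* to codon *j* is zero unless the codons
differ at exactly one nucleotide position, and otherwise proportional to
the stationary frequency π_j of the target codon, multiplied by κ if the
nucleotide change is a transition and by ω(class) if the amino acid
changes. Each branch carries one of two classes, WILD or DOMESTIC; the
one-ratio model (ORM) ties ω across classes, the two-ratios model (TRM)
frees them. Every class matrix is rescaled so that the expected number
of substitutions per codon per unit time is 1 at stationarity, making
branch lengths expected substitutions per codon.

Codon frequencies default to F3X4 (position-specific nucleotide
frequencies estimated from the alignment with a unit pseudocount so no
sense codon gets probability zero); EQUAL and F1X4 are selectable. The
model is time-reversible, so the likelihood is invariant to root
placement.

**Unrooted fitting.** ML fitting first collapses a degree-2 root into a
trifurcation. With a rooted tree the two root-adjacent branch lengths
are not separately identifiable under the ORM (only their path product
matters), while the TRM — whose two class matrices differ — turns that
split into a weakly identified extra direction; empirically this
inflated the null likelihood-ratio statistic well beyond χ²(1) (mean
≈ 1.4–2.2, growing with alignment length). On the unrooted shape the
statistic's null distribution matches χ²(1) closely (see Calibration).
When the two collapsed root edges have different classes, the merged
branch is tagged DOMESTIC: the wild/domestic boundary lies on it, and
assigning the boundary branch to the domestic class mirrors common
branch-model practice of tagging the stem of the domestic clade.

## Likelihood and optimisation

Column likelihoods use Felsenstein pruning over compressed site
patterns; codons containing gaps or ambiguity codes are treated as fully
missing (partial likelihood 1 for every state), so no column is
discarded. The matrix exponential uses the eigendecomposition of the
frequency-symmetrised generator (exact for reversible models) with a
scaling-and-squaring fallback; decompositions are cached per (κ, ω)
so finite-difference steps that perturb only branch lengths reuse them.
Partial-likelihood rescaling engages only near underflow.

Parameters (log κ, log ω per class, log branch lengths) are maximised
with bounded L-BFGS-B. Defaults: ω ∈ [1e-4, 999], κ ∈ [1e-3, 100],
branch lengths ∈ [1e-7, 20]; convergence when a restart from the
current optimum gains less than 1e-6 log-likelihood units (each start
is polished this way so that nested fits are equally converged — an
under-polished null fit would inflate the LRT). The TRM starts at the
ORM optimum with ω_W = ω_D = ω̂, which guarantees lnL_TRM ≥ lnL_ORM up
to tolerance. Seeded random restarts are available
(`FitConfig(n_restarts=...)`) but default to none: on the study
conditions the surface behaved unimodally in all calibration and
recovery runs, and restarts triple the cost. Branch lengths may instead
be fixed to the input tree's values
(`optimize_branch_lengths=False`); study-scale analyses here use that
mode, since the generated trees carry the true (jittered) lengths.

**Extreme fits.** A gene is flagged NO_SYNONYMOUS (or NO_NONSYNONYMOUS)
when a class's expected synonymous (nonsynonymous) divergence — class
tree length × the class matrix's synonymous (nonsynonymous) flux
fraction — falls below 1e-6, or when ω̂ sits at a bound. Such genes are
retained in per-species means only when their LRT is significant.

**Testing.** The LRT statistic is max(0, 2·ΔlnL) with df = 1; p-values
are χ²(1) upper tails. The default significance threshold is 0.05 with
no multiple-testing correction, matching how such genome scans are
usually reported; Benjamini–Hochberg is available as an option.

## Parsimony substitution counting

Per codon column, substitutions are assigned to branches by unit-cost
parsimony: over amino acids for nonsynonymous events, and over codons —
only at columns whose observed amino acids are invariant — for
synonymous events. All minimum-change ancestral labelings are counted
exactly by dynamic programming (subtree costs/counts downward,
complement costs/counts upward, joined across each branch), and each
possible change receives the fraction of optimal labelings in which it
occurs; column weights therefore always sum to the parsimony score, and
the procedure is deterministic and order-independent. Internal states
range over the column's observed states (sufficient for unit cost);
missing leaves may take any observed state at no cost; all-missing
columns contribute nothing. Counting uses the tree as given (a rooted
tree's root-edge ambiguity is split fractionally like any other tie).

Radical vs conservative: a nonsynonymous change is radical when it
crosses categories in at least one enabled partition. Defaults —
charge {RHK | DE | rest}, polarity {RNDCQEHKSTWY | AGILMFPV}, volume
{AGSCDNPTV | REQHILKMFWY} — follow published convention; partitions are
configurable because several classification schemes exist in the
literature. Counts are weighted sums per branch class and are additive
over genes.

## Species summaries and taxonomy

Per species, mean ω_D and mean ω_W are unweighted arithmetic means over
significant genes (capped extreme estimates enter as capped — large
per-species means arise exactly this way); Dω/Wω is the ratio of those
means (ratio of means, not mean of ratios). Radical and conservative
D/W ratios are quotients of weighted count sums over significant genes.
The six-way taxonomy uses strict inequalities with a tie tolerance of
1e-9: values tied with each other or with 1, and all non-significant
genes, are UN. The G-test per species is 2·Σ O·ln(O/E) on the 2×2 of
(radical, conservative) × (domestic, wild) summed over significant
genes, df = 1, no continuity correction (Williams' correction is
available but off by default). Pearson correlations of Dω/Wω,
D_radical/W_radical and D_conservative/W_conservative against Ne use
raw Ne by default (a log10 option exists); species with undefined
metrics are dropped pairwise.

The nearly neutral map ω(S) = S/(1 − e^(−S)), S = 4·Ne·s, is provided
with a series expansion through S = 0 (ω(0) = 1) and a bracketed
Brent inverse accurate to 1e-10.

## Synthetic data

Gene simulation is event-driven (Gillespie) per site along each branch
under the branch's class matrix, with the root drawn from the stationary
distribution; every substitution event is logged (branch, site, codon
change, synonymous flag), so simulated histories serve as exact oracles
for counting and recovery tests. Study simulation draws, per species,
a fraction of genes (default 0.3) under the TRM with
log(ω_D/ω_W) = β·log10(Ne/Ne_min) + Normal(0, 0.15) and the rest under
the ORM; ω_W is lognormal around 0.2 (σ = 0.3), κ = 2, branch lengths
0.1 expected substitutions/codon with lognormal jitter (σ = 0.2) shared
per gene. Default β = 0.5 over an Ne range of 1e4–1e5. Trees are
emitted in unrooted (trifurcating) form with the whole domestic clade,
including its stem, tagged.

What the generator does *not* emulate: among-site rate variation,
selection heterogeneity along genes, alignment error, annotation error,
recombination/linkage, and any demographic process — Ne acts only
through the effect map. Passing tests therefore validate the
statistical machinery under the model's own assumptions, not robustness
to real-data pathologies.

## Calibration, recovery and power (what the test suite runs)

Problem sizes were chosen to keep the whole suite desk-scale:

* **LRT null calibration** — 200 ORM genes, 300 codons, 6 taxa, full
  joint fits: rejection at 0.05 within [0.02, 0.09] and
  Kolmogorov–Smirnov distance of the p-distribution from uniform
  < 0.12. (Measured during development: rejection ≈ 0.05–0.07,
  KS ≈ 0.07.)
* **Recovery** — 20 TRM genes at 2000 codons (truth ω_W = 0.2,
  ω_D = 0.8): medians within ±0.1; and median absolute error at 2000
  codons below half the 200-codon error.
* **Study-level null and power** — 8 species, Ne 1e4–1e5, 12 genes
  each, 4 taxa, 200 codons, branch lengths fixed to the input trees.
  The power arm uses effect slope β = 1.5 (steeper than the generator
  default 0.5: with 8× fewer genes than a full-scale study the
  species-level Dω/Wω estimate is correspondingly noisier, and the
  steeper slope restores the full-scale signal-to-noise; the
  configuration was fixed from pilot runs on separate seeds before the
  assertions were frozen). Requirements: r > 0 in ≥ 90% of 20 power
  replicates; ≤ 3 of 15 null replicates rejecting at 0.05 (the 99%
  binomial envelope of a calibrated 5% test). Pearson p-value
  calibration itself is checked separately with 2000 direct replicates.

## Known limitations

* The χ²(1) reference for the LRT is asymptotic; at very low divergence
  or very short genes the statistic is conservative near zero.
* Parsimony undercounts substitutions at high divergence (multiple hits
  on one branch collapse); the counting tests therefore run at moderate
  divergence (≤ 0.3 substitutions/codon/branch), where inferred and
  true per-class counts correlate at r > 0.9.
* No among-site rate heterogeneity or branch-site models; one ω per
  branch class per gene.
* Dω/Wω is a ratio of means over significant genes and inherits the
  winner's-curse noise of post-selection estimates when few genes are
  significant; correlations against Ne should be read accordingly.
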