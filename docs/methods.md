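# Methods

This note documents the models, defaults, and numerical choices behind
`selstruct`, and what the synthetic-data tests do and do not establish
about real data.

## Codon substitution model and site classes

The substitution process is the Goldman–Yang codon model: rates between
sense codons differing at one nucleotide are proportional to the target
codon's equilibrium frequency, multiplied by κ for transitions and ω for
nonsynonymous changes; multi-nucleotide changes have rate zero; the
chain is time-reversible. Stop codons are excluded from the state space
(61 states under the standard code; the code table is configurable per
alignment through NCBI table ids).

Site models are mixtures over ω:

* **M0** — one ω for all sites (the whole-gene average dN/dS);
* **M1a** — purifying class ω₀ ∈ (0, 1) estimated, plus a neutral class
  at ω = 1 (we use the modern variant in which ω₀ is free, under the
  family's conventional "M1/M2" names);
* **M2a** — M1a plus a positive class ω₂ ≥ 1;
* **M7** — beta(p, q) on [0, 1], discretized into K = 10
  equal-probability classes at the bin medians (deterministic, the
  conventional discretization);
* **M8** — p₀·beta(p, q) plus one class at ω_s, with ω_s bounded below
  at 1 + 10⁻⁶ for identifiability.

**Rate scaling.** A single-class rate matrix is normalized to one
expected substitution per codon per unit time. Within a mixture, all
class matrices share one scale factor equal to the mixture-average rate,
so a branch length is the expected number of substitutions per codon
averaged over the site-class distribution and sites in high-ω classes
substitute faster than average. This shared scaling is what codon
site models conventionally do, and it matters: normalizing each class
separately removes the rate component of the positive-selection signal
and cripples per-site detection. The simulator uses the identical
convention (weights = planted class proportions), so simulation and
inference agree by construction.

**Codon frequencies.** F3x4 by default (position-specific nucleotide
frequencies, stop codons removed, renormalized), with a pseudocount
floor of 10⁻⁶ so no observed codon has zero prior frequency. Fequal,
F1x4 and Fcodon are available. The frequency mode is recorded in every
fit.

**Likelihood.** Felsenstein pruning over a flattened tree, vectorized
across site classes and unique site patterns; per-class transition
matrices come from a symmetrized eigendecomposition of the reversible
generator (one eigendecomposition per class per likelihood evaluation).
Gap codons are marginalized as missing data rather than deleted; the
alignment validator rejects frame-breaking gaps outright. Trees are
consumed as Newick; likelihood is invariant to root placement under
reversibility.

**Optimization.** Bounded L-BFGS-B on transformed parameters (log for
κ, ω, beta shapes, branch lengths; raw bounded proportions). Bounds:
κ ∈ [0.01, 50], ω ∈ [10⁻⁴, 20], beta shapes ∈ [0.005, 99],
ω_s ∈ [1 + 10⁻⁶, 20]. Branch lengths are optimized jointly under M0 and
then held fixed for the site models (`branch_policy="M0-fixed"`,
default; `"joint"` is available), the standard practice that
dramatically reduces cost. Fits run from a deterministic list of
starting points: further starts are tried only when a start fails to
converge, except for the models with a positive class (M2, M8), which
always evaluate at least two starts because their likelihood surface
has flat boundary ridges (p₀ → 1 or ω_s → 1) that can trap a single
start. When fitting a nested pair, the alternative is warm-started
from the null's MLE (mass 1 − 10⁻⁴ off the boundary), which guarantees
ℓ(alt) ≥ ℓ(null) up to optimizer tolerance. Degenerate inputs
(identical sequences) drive branch lengths to ~0 and are returned
flagged rather than raised.

**LRTs.** 2Δℓ clamped at zero against χ², df = 2 for both M1-vs-M2 and
M7-vs-M8, with no mixture-boundary correction — conservative, as the
null-calibration test demonstrates (empirical rejection well below the
nominal level). Fixed-site partition models share κ and branch lengths
across partitions and contrast one-ω-per-partition against a shared ω,
df = partitions − 1; partitions under 10 codons trigger a warning.

**Posteriors.** Naive empirical Bayes (NEB) evaluates
P(class | site) ∝ w_k L_k(site) at the MLEs; the posterior mean ω and
P(ω > 1) follow directly, and sites with P(ω > 1) > 0.9 are flagged
significant (the conventional threshold). The optional grid empirical
Bayes ("grid-BEB") averages NEB summaries over a uniform hyperparameter
grid weighted by integrated likelihood — 8 points per axis over (p, q)
for M7 and over (p₀, ω_s) for M8 with (p, q) held at their MLEs. A full
4-D grid would cost ~4000 likelihood evaluations for little benefit at
this scale; restricting the grid to the positive-class hyperparameters
captures the uncertainty that matters for P(ω > 1). The method used is
recorded in every output row. Exact reproduction of the reference BEB
implementation is out of scope.

**Pairwise dN/dS** fits (t, κ, ω) on a two-taxon tree; dS and dN divide
the synonymous/nonsynonymous substitution flux by site proportions
computed from the same model at ω = 1, so dN/dS equals the fitted ω.
The ratio is flagged undefined when dS ≈ 0.

## Structural context

Structures are read from PDB or mmCIF (first model, highest-occupancy
altlocs) via biotite; for predicted models the B-factor column is
interpreted as per-residue pLDDT. **Disorder** is pLDDT < 50 strictly
(50.0 counts as structured).

**SASA** is Shrake–Rupley with a deterministic Fibonacci sphere lattice
(960 points by default, probe 1.4 Å) — identical inputs give
bit-identical outputs, and the point count is configurable for
accuracy tests (an isolated atom reproduces 4π(r + 1.4)² to well under
1%). Van der Waals radii are a fixed per-element table (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20, P 1.80 Å); hydrogens are used if present and
never added, since predicted models lack them; unknown elements fall
back to the carbon radius with a warning.

**Relative SESA** divides residue SASA by the theoretical maximum
accessibility of its residue type (Tien et al. 2013, theoretical
column, bundled as a table). It is deliberately not clamped at 1 —
values above 1 flag unusual conformations rather than being hidden.
Residues with rel. SESA < 0.3 are **buried**; ≥ 0.3 in the monomeric
form are **surface**. Given a complex split into two chain groups,
ΔSASA(residue) = SASA(own side alone) − SASA(complex); surface residues
with ΔSASA ≥ 15 Å² are **contact** residues (both conditions are
enforced: interface burial and monomeric exposure). Atom-level contacts
use van der Waals overlap r_i + r_j − d ≥ −0.4 Å.

## Residue join and summaries

Alignment columns map to reference-taxon residues by skipping reference
gap codons; structure numbering is reconciled by a single integer offset
plus an amino-acid cross-check (no alignment-based rescue — predicted
full-length models use consistent numbering, and failures should be
loud). Mismatching residues are flagged and excluded from summaries;
more than 20% mismatches aborts the join. Enrichment tables report
burial × disorder fractions among all residues, residues with posterior
mean ω > 1, and residues with P(ω > 1) > 0.9. Viewer attribute files
(defattr dialect) carry the posterior mean ω capped at 1.5 for a fixed
color scale; the TSV keeps uncapped values. Group contrasts
(structured/disordered, buried/surface, surface/contact) use Welch's
two-sided t test. These tests pool residues across genes and lineages
without modeling within-gene correlation — a caveat inherited from the
analysis design they reproduce.

## Paralog comparison

Rigid Kabsch superposition seeded from shared residue numbering (or an
explicit pair list; externally produced two-column pair files are
accepted verbatim), followed by iterative mutual-nearest-neighbour
Cα matching within 4 Å with re-superposition until the pair set
stabilizes. Ties break by smaller distance, then lower residue number.
Quality is a TM-score with d₀ from the shorter chain; alignments are
usable only when TM > 0.5 and coverage ≥ 50% of the shorter protein
(the coverage threshold is this package's explicit choice where
"sufficient coverage" is otherwise unquantified). A rigid matcher is
adequate for same-fold paralog pairs; flexible alignment is a
non-goal. Δω tables report per-pair differences in posterior mean ω,
higher-in-A/higher-in-B/tied counts, and a Welch t test between the
matched samples. Divergence-versus-time fits ordinary least squares of
(100 − %identity) on divergence time per gene group.

## McDonald–Kreitman and DoS

Per codon column: segregating positions count as polymorphism; a
position counts as divergence only when the ingroup is monomorphic
there and differs from the outgroup (a site where some ingroup alleles
equal the outgroup is polymorphism only). Multi-hit codons are resolved
by uniform averaging over all minimal mutational paths that avoid stop
codons; paths through stops are excluded, and codons with no stop-free
path, gaps, or ambiguity are skipped with counted reasons. Polymorphic
changes are classified against the ingroup-consensus codon background
(majority per position, ties alphabetical — deterministic). Fisher's
exact test runs on counts rounded to integers (ties to even) with the
fractional table reported alongside; NI and DoS carry undefined flags
on zero denominators. No frequency filter is applied by default; a
minor-allele-count filter is available. Per-region reports take 1-based
inclusive codon ranges.

## Synthetic data: what it shows and what it does not

The generators are first-class, tested code: codon alignments evolved
by exact matrix-exponential transitions (no event-level simulation)
under planted site-class plans with exact class counts
(largest-remainder rounding); toy structures made of 4-atom pseudo
residues with designed buried cores (an inner occluding shell at
~4.6 Å, overflow residues in a distant exposed shell), designed dimer
interfaces (partner pseudo-residues at 5.4 Å across the interface,
non-interface partners 40 Å away), and planted pLDDT tracks — each
verified against the package's own SASA/contact operations before
emission; populations with exactly the planted PN/PS/DN/DS events, one
per codon. All generators take a single seed and emit a JSON truth
ledger; identical seeds give byte-identical outputs.

Desk-scale study conditions used by the property tests: M0 recovery at
6 taxa × 500 codons (κ = 2, ω = 0.3, tree depth 0.5 substitutions per
codon root-to-leaf); M7-null LRT calibration at 5 taxa × 200 codons
(depth 1.0, 50 replicates); per-site detection at 6 taxa × 300 codons
with an M8-generating mixture (90% beta(0.5, 1.5), 10% ω = 4) — note
that a background containing a large point mass exactly at ω = 1 would
make M8's positive class legitimately absorb neutral sites and is not a
meaningful test of detection precision; fixed-site partitions at
ω 0.1 vs 0.9 over 2 × 150 codons. These establish internal correctness
and calibration, not performance on real alignments, which bring
alignment error, recombination, synonymous-rate variation, and
non-equilibrium composition that the generator deliberately omits.
Toy structures have no realistic stereochemistry; they exist to give
the SASA and contact geometry controlled ground truth.

## Known limitations

* No branch or branch-site models, no synonymous-rate variation.
* NEB posteriors at MLEs understate hyperparameter uncertainty; the
  grid-BEB option mitigates but does not reproduce full BEB.
* The χ² reference for the mixture LRTs is conservative at the
  boundary; no correction is applied.
* MK counting uses a single outgroup (no polarization by multiple
  outgroups) and no asymptotic-MK extension.
* The rigid paralog matcher will under-match genuinely flexible or
  multi-domain rearranged pairs; such pairs fail the quality gate
  rather than being force-aligned.
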