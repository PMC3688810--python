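# Methods

This note records the models and procedures `mhcdab` implements, the
defaults and why, the numerical choices, and what the synthetic-data tests
do and do not establish about real data.

## Tag design

A tag is a 7-nt barcode prepended to each locus-specific primer.  Three
constraints make tags robust to pyrosequencing error modes:

* *no homopolymer*: no two identical adjacent bases (read as the strictest
  interpretation; 454 chemistry is homopolymer-error-prone);
* *no motif repetition*: no tandem repeat of any motif of length ≥ 2
  anywhere in the tag (ACAC…, TGGTGG…); both predicates are configurable;
* *pairwise Hamming distance ≥ 3* within a set, so one sequencing error
  cannot convert a valid tag into another valid tag.

1848 of the 16 384 7-mers pass the per-tag predicates (2916 with the
homopolymer rule alone).  Selection is greedy accretion over the
lexicographic candidate list with seeded shuffled restarts; the sizes
needed here (tens of tags) are far below coding-theory limits for distance
3 over quaternary length-7 space, so the greedy construction always
succeeds (it returns ≥ 134 tags).  Optimal code construction and
GC balancing are out of scope.

Primer coordinates follow the convention that a primer's stated position is
the 5′-most base of its annealing site on the reference, so the product
length is `rev_pos + rev_len − fwd_pos`; the bundled DAB1/DAB3 primer pairs
give 342/350 bp products, 356/364 bp with both tags.

## Synthetic data (the study conditions)

The generator emulates the real experiment's geometry so the pipeline can
be validated with known truth:

* **allele pools**: two lineage founders differing at 25 % of sites;
  within-lineage alleles carry `Binomial(276, divergence)` substitutions
  (default divergence 0.03), rejected if they create an in-frame stop.
  Every allele pair is kept ≥ 3 nt apart: alleles 1 nt apart are
  *indistinguishable in principle* from PCR substitution artefacts by the
  MPAF method, so resolvable spacing is part of the simulated conditions
  (a real caveat of the method on real data, where 1-nt-apart alleles may
  exist).  Species assignment cycles A / B / shared.
* **genotypes**: a specimen draws an expression pattern (count of DAB1 and
  DAB3 alleles, ≤ 4 per lineage and ≤ 8 total — two hypothetically
  duplicated diploid loci per lineage).  Default pattern weights emulate
  the observed species difference: the native-like species A mostly
  expresses 1–3 DAB3 alleles only (mean ≈ 2), the invasive-like species B
  expresses both lineages (mean ≈ 3), hybrids are intermediate.
* **reads**: forward tag + primer + exon-2 template + reverse-complemented
  reverse primer + reverse-complemented tag, all in forward orientation
  (the amplicon convention).  Per-amplicon coverage is uniform on a
  configurable range (default 300–3000, "hundreds to thousands");
  within-amplicon allele frequencies are Dirichlet(8) — balanced but
  uneven.  Point errors are i.i.d. per base (default 0.01); chimeras join
  two distinct templates of the same amplicon at a uniform crossover
  (default fraction 0.05).  Errors hit tags and primers too; the truth
  table records every read's source, chimera parents/breakpoint and tag
  integrity.  Homopolymer-indel error spectra and quality-aware calling
  are deliberately not modelled: validation uses counts, and quality
  strings are constant.
* **microsatellites**: 25 diploid loci (the number retained after
  null-allele screening in the motivating design; 41 were typed), two
  populations diverged under the Balding–Nichols model at a target F,
  hybrids drawing each allele copy from population 1 with probability
  equal to their admixture fraction.

A single master seed is split into named substreams per stage, so stages
are independently reproducible.

## MPAF-based allele validation

Within each amplicon (one specimen × one marker, identified by its tag
pair) reads are trimmed by exact coordinate and tabulated by exact
sequence.  A variant's **MPAF** is its largest within-amplicon frequency
across all amplicons.  Classification, in order:

1. *frameshift*: length incongruent (mod 3) with the marker reference →
   excluded;
2. *artefact*: MPAF below the auto-accept threshold and the variant is a
   1-bp substitution from, or a single-crossover recombinant of, variants
   with strictly higher frequency in the amplicon where it attains its
   MPAF → `artefact_substitution` / `artefact_chimera`.  Parent candidates
   are limited to the 50 most frequent variants of that amplicon (the
   plausible parents are the validated alleles, which are always near the
   top); ties in frequency never qualify as parents;
3. *auto-accept*: MPAF ≥ 0.50 → true allele (a variant holding half an
   amplicon cannot be an artefact of anything in it);
4. *support*: an amplicon "supports" a variant only with ≥ 2 reads — a
   single read is never credible evidence.  Variants with no supporting
   amplicon ("present in one copy" everywhere) are excluded; supported
   singletons (exactly one supporting amplicon in all data) are excluded
   unless their MPAF reaches the singleton floor (default 0.20, motivated
   by replicate-PCR practice: true singletons in the motivating design had
   mean MPAF 24 % and were re-genotyped twice);
5. everything else → true allele.  The published rule list leaves
   "low-MPAF, unexplainable, replicated" variants unaddressed; accepting
   them is the only reading consistent with the procedure's intent
   (variants were *checked* for artefacts, and kept when no artefact
   explained them) and is what makes the method recover alleles whose
   exact-sequence frequency is depressed by per-base sequencing error.

Classification depends only on counts, so it is idempotent.  The 5 %
artefact threshold, 50 % auto-accept, singleton floor and parent cap are
all configurable.

Two deliberate behaviours to know about:

* With 1 %/base errors on a 276-bp template, only ≈ 6 % of an allele's
  reads match it exactly; the allele is still recovered (rule 5) when it
  recurs across amplicons, but a *singleton* allele below the MPAF floor is
  excluded — by design; the remedy, as in the lab, is replication.
* No read-denoising/error-correction step is applied before tabulation.
  Coincidental recurrence of a specific multi-error read across amplicons
  is what rule 4's two-read support requirement guards against.

Marker assignment replaces a BLAST E-value screen with edit-distance
identity (edlib, global alignment) to one reference per lineage, threshold
0.80 — the lineages are deeply split, so discrimination is equivalent.

Nomenclature: `Pato-` (species A only), `Chna-` (species B only), `Pctn-`
(shared, or found solely in hybrids); an allele seen in one species and in
hybrids counts as species-specific.  Numbering is sequential per lineage
over alleles ordered by (amplicon support, sequence), hence stable across
reruns.

## Phylogeny

p-distances or Jukes–Cantor corrected distances
(d = −(3/4)·ln(1 − (4/3)p); p ≥ 0.75 raises a saturation error naming the
pair).  Neighbour joining is the standard Saitou–Nei agglomeration,
implemented in-package so the tie rule is fixed (smallest taxon-index
pair) and negative branch estimates are clamped to zero; scikit-bio's NJ
serves as an independent cross-check in the tests.  Bootstrap support is
the percentage of column-resampled replicate NJ trees containing each
bipartition (1000 replicates by default; replicate p-distances are capped
just below saturation so single replicates cannot abort a run).  The NJ
topology also provides the fixed tree for the codon models — a deliberate
replacement of a heuristic ML tree search: at this scale site-model
inference is robust to minor topology differences, and the package's scope
is site models, not tree search.

## NG86 dN/dS

Per codon pair: site counts are averaged between the two sequences, with a
position's synonymous fraction being the share of its three possible
changes that preserve the amino acid (changes to stops count as
nonsynonymous, so N + S = 3 per codon).  Difference counts average over
all minimal mutational pathways, excluding pathways through stop codons
(pairs whose pathways are all blocked — not possible between sense codons
of the standard code, but guarded — fall back to unrestricted averaging).
Jukes–Cantor correction is applied to pN and pS.  Partition rates (`all`,
`abs`, `non-abs`) are means over all sequence pairs restricted to the
partition's codons; SEs come from resampling partition codons with
replacement (1000 replicates), and the one-tailed Z test uses the
bootstrap SE of (dN − dS).  Within the bootstrap, saturating proportions
are capped just below 3/4 rather than aborting a replicate.

The ABS mask is an explicit input (1-based codon indices).  The bundled
`BROWN_ABS_BETA1` list holds peptide-contacting β1-domain positions from
the human DRB1 crystal structure in mature-chain numbering; mapping onto a
particular exon-2 alignment (the offset) is the user's responsibility, as
the correct mapping depends on the alignment's start.

## Codon site models

The substitution process is the Goldman–Yang 61-state codon model:
rate(i→j) = π\_j · κ^[transition] · ω^[nonsynonymous] for single-nucleotide
changes, F3x4 codon frequencies by default (positional nucleotide
frequencies with a 0.1 pseudocount to keep π > 0).  The matrix is
reversible, so likelihoods are computed by pruning after a symmetrising
similarity transform and `eigh` (fast, numerically stable), with per-node
rescaling against underflow and site-pattern compression.  Branch lengths
are expected substitutions per codon under the *mixture* (PAML's
normalisation).

Site-class mixtures follow the standard definitions; M3 uses three
discrete classes; M7/M8 discretise the beta into 10 equal-probability
categories (quantile midpoints).  Free ω-structure parameter counts — M0:
1, M1a: 1, M2a: 3, M3: 5, M7: 2, M8: 4 — give the LRT degrees of freedom
(M0 vs M3: 4; M1a vs M2a: 2; M7 vs M8: 2).

**Branch lengths.**  Rather than re-optimising every branch under each
model, each fit optimises a single global scale on the fixed NJ branch
lengths (plus κ and the mixture parameters).  ω inference is insensitive
to the residual branch-length error at these scales, the M7→M8 nesting
limit is exactly preserved (the scale is free in both), and the cost drops
by an order of magnitude.  `branch_mode="fixed"` disables the scale.

**Optimisation.**  Bounded L-BFGS-B with numerical gradients, multi-start
(3 by default; jittered log-normally around the default init), ftol 1e-8.
Alternatives can be warm-started from their fitted null
(`warm_start_from`), which guarantees lnL(alt) ≥ lnL(null) up to optimiser
noise; the LRT treats a deficit below 0.02 lnL units as zero and raises a
convergence error beyond it.  Eigendecompositions are cached per (κ, ω),
which pays off because most gradient perturbations leave the rate matrix
unchanged.

**BEB.**  For M2a and M8 the posterior probability of the
positive-selection class is integrated per site over a parameter grid
(10 points per dimension): proportions uniform over the simplex
(triangle-cell midpoints), ω0 on (0,1), ω2 and ω\_s on (1,11), beta shapes
on (0,2); κ, codon frequencies, branch lengths *and the rate
normalisation* stay at their MLEs (the normalisation freeze is an
approximation; varying it with the grid weights would change effective
branch lengths across grid points).  Sites with positive-class posterior
\> 0.95 (and > 0.99) are reported as positively selected.

**What the simulations show.**  On data simulated under the model itself:
M0 recovers a single ω = 0.3 with mean relative error well under 15 % at
40 × 92-codon scale; the M2a-vs-M1a LRT is conservative under an M1a null
(rejection ≤ 7 % at α = 0.05 over 200 replicates of 8 × 40 codons); BEB
recovers ≥ 8 of 10 sites planted at ω = 8 with ≤ 1 false positive
(16 × 50 codons).  These are self-consistency checks — real sequences
violate the model (recombination, among-site rate variation in dS,
non-stationary composition), and the checks do not speak to that.

## Gene conversion

Fragments are runs over *polymorphic columns only*, mapped back to
alignment coordinates (1-based); by default no mismatches are tolerated
inside a fragment (the classic gscale = 0 convention).  Inner fragments
are runs of agreement between a pair; outer fragments are runs of sites at
which one sequence is private (its state occurs exactly once in the
column).  A run of l sites scores its log-probability surprise,
−l·ln(match proportion) for pairs and −l·ln(private density) for
sequences, making scores comparable across pairs of different divergence
so near-identical pairs cannot dominate the global test.  Significance:
the order of polymorphic columns is permuted (10 000 by default; this
null preserves each pair's divergence exactly); a hit's `sim_p` is the
rank of its score among permuted *global* maxima, and `bc_ka_p` is the
rank among the pair's own permuted maxima Bonferroni-scaled by the number
of pairs — a permutation stand-in for the original program's
Karlin–Altschul analytic p-values, which are explicitly not reproduced.
The minimum achievable p is 1/(n\_perm + 1).

## Population genetics

**Dominant-marker F\_st** treats each allele column of the
presence/absence matrix as a binary locus and computes AMOVA-style
variance components on band frequencies (among/within populations, with
the usual n\_c correction), ratio-of-sums over loci; monomorphic matrices
are an error.  The degenerate cases are exact: equal band frequencies
give ≈ 0, fixed complementary bands give exactly 1.  No recessive-allele
frequency back-calculation is applied (the binary coding *is* the datum);
a Zhivotovsky-style correction was considered and left out as it changes
the estimand, not the comparison.  CIs: percentile bootstrap over loci,
20 000 replicates by default.  **Haplotype F\_st** is Wright's
(H\_T − H\_S)/H\_T on allele-frequency vectors normalised from carrier
counts.  **Microsatellite F\_st** is Weir–Cockerham θ (full diploid a, b,
c components summed over alleles and loci).  Pairwise tables are
restricted to populations with n > 8.

**Admixture** is a Gibbs sampler over the STRUCTURE admixture model with
uninformative priors: cluster allele frequencies Beta/Dirichlet(1),
ancestry vectors Dirichlet(α = 1, fixed — inferring α adds little at these
sample sizes and costs mixing).  Dominant data are handled by imputing the
two latent diploid copies per (individual, locus) under the constraint
that a band is present iff at least one copy carries the band allele
(joint draw of origins and alleles over the K²·3 valid configurations).
The independent-frequency prior is the default; this is a deliberate
simplification of the correlated-frequency variant (the F-model), which
matters most for weakly diverged clusters — the regimes tested here are
diverged.  Default chain length 1500 sweeps / 500 burn-in at desk scale;
the classic 4×10⁶/4×10⁵ settings are reachable through config.  A run's
model log-probability is the trace mean minus half the trace variance
(the usual deviance correction), which is what Evanno's
ΔK = mean|L(K+1) − 2L(K) + L(K−1)| / SD[L(K)] consumes; ΔK is defined for
interior K only, and zero SD yields ∞ with a warning.  Replicate runs are
aligned by optimal cluster-label assignment (Hungarian algorithm on the
q-matrix cross-product — the optimal version of greedy label matching)
and averaged.

**Mantel tests** delegate to scikit-bio (Spearman, joint row/column
permutation; the global NumPy seed is set from the named substream for
reproducibility).  Spearman correlations use scipy with tie handling.
**Allelic richness** is rarefaction to twice the smallest eligible
population size (floor n ≥ 9 by default; smaller groups report NaN, "not
evaluated").

## Pipeline

`RunConfig` (YAML round-trip, unknown keys rejected) drives the stages
simulate → genotype → phylo → selection/geneconv → popgen; each stage
checks its upstream files and fails with a dependency error naming the
missing stage.  A manifest records the package version, master seed and
SHA-256 digests of every output.  `generate_report` renders markdown
tables *from the stage TSVs only* — it never recomputes, so every number
in the report traces to a file in the run directory.  Deterministic stages
are byte-identical across reruns of the same config.

## Problem sizes in the test suite

Chosen as the smallest sizes at which the statistical behaviour under test
is unambiguous: genotyping end-to-end at 60 specimens × 2 markers,
coverage 500–1500 (≈ 90 000 reads); M0 recovery at 40 sequences × 92
codons × 10 seeds; LRT null calibration at 200 replicates of 8 × 40
codons; BEB at 16 × 50 codons; gene-conversion null calibration at 200
replicates × 199 permutations; admixture at 100 individuals × 25 loci,
ΔK over K = 1..4 with 3 runs each at 800 sweeps.  Bootstrap and
permutation defaults in the library remain at their full values
(1000/10 000/20 000); tests pass reduced counts explicitly.

## Known limitations

* The MPAF procedure cannot distinguish a true allele 1 nt from a
  co-occurring higher-frequency allele from a PCR substitution artefact;
  the generator therefore keeps alleles ≥ 3 nt apart, and on real data
  such allele pairs would require replicate-PCR confirmation.
* Unreplicated singleton alleles below the MPAF floor are excluded even
  when real; with per-base error ε the exact-sequence frequency of a pure
  allele is ≈ e^(−276ε), so the floor is effectively stricter at high
  error rates.
* No indel/homopolymer error model; frameshift exclusion is exercised by
  construction, not by simulation.
* The codon-model machinery fixes the tree topology and optimises only a
  global branch scale; branch-specific and branch-site models are out of
  scope.
* BEB freezes the rate normalisation at the MLE mixture.
* The gene-conversion p-values are permutation-based throughout; the
  analytic Karlin–Altschul pairwise values of the original program are
  approximated by Bonferroni-scaled permutation ranks.
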