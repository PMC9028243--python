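# Methods

This note documents the models, the numerical choices, what the synthetic
data do and do not emulate, and the design decisions taken where several
defensible options existed. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study design and trees

The fixed topology is
`((ostrich,(kiwi,tinamou)),((chicken,mallard),(egret,ibis)))` with the
tactile foragers — kiwi, mallard, crested ibis — as the foreground (TG)
set, their sisters — tinamou, chicken, egret — as background (BG), and the
ostrich as outgroup. The three foreground branches are the pendant
branches of the TG tips; they are treated as independent foreground
lineages (convergence, not shared ancestry, is the hypothesis).

Two branch-length scales are used, both fixture defaults rather than
estimates:

* **time tree** — ultrametric, root depth 111 time units by default
  (configurable); relative node ages are fixed so all analyses see the same
  shape. Units only matter jointly with λ, which is per gene per unit time.
* **sequence trees** — uniform per-branch lengths: 0.05
  substitutions/site/branch for the amino-acid (JTT) scale and 0.2
  substitutions/codon/branch on the neutral codon scale. Amino-acid
  divergence accumulates much more slowly than synonymous-scale codon
  divergence, hence the two defaults; 0.2 per branch on the neutral scale
  is conservative for bird lineages separated by tens of millions of
  years. Both are single-parameter knobs of the generators.

## Substitution models

**JTT + discrete γ.** The published Jones–Taylor–Thornton exchangeability
table and stationary frequencies are embedded as packaged data
(`data/jtt.dat`, amino-acid order ARNDCQEGHILKMFPSTWYV). Rate matrices are
normalized to one expected substitution per unit branch length. Among-site
rate variation uses K equal-probability γ categories represented by their
category means (K = 4 by default; the shape α is fitted per alignment).
An optional +F mode replaces the frequencies with alignment-observed ones;
it is off by default. Transition matrices come from the eigendecomposition
of the π-symmetrized generator, exact for any reversible model.

**GY94 codon model.** The 61 sense codons of the standard code; rates are
zero for multi-nucleotide changes and π_j scaled by κ for transitions and
by ω for nonsynonymous changes otherwise. Codon frequencies are F3x4 from
the analyzed alignment (position-specific nucleotide frequencies, floored
at 1e-6 and renormalized, restricted to sense codons). **Normalization
convention:** all (κ, ω) matrices for a given κ are divided by the mean
rate of the *neutral* (ω = 1) generator, so one unit of branch length is
one expected substitution per codon under neutrality and classes with
ω > 1 genuinely evolve faster. This is the convention the branch-site
machinery of codeml relies on; normalizing every class matrix to its own
unit mean rate would cancel the rate elevation of positively selected
classes and leave the LRT with only compositional signal (verified to
collapse its power in pilot simulations). The simulators and the
likelihood share the convention, and ω estimates are unaffected by it
(branch lengths absorb the scale).

## Likelihood machinery

One pruning engine serves both alphabets. Alignment columns are compressed
to unique patterns with multiplicities; partial likelihoods are rescaled
per node (log accumulators) for numerical stability; mixture components
(γ categories, branch-site classes) are summed at the site level. Marginal
ancestral posteriors at node v are proportional to the partial likelihood
below v times the partial likelihood of the rest of the tree, mixed over
components by their per-site posterior weight; the MAP state breaks ties
toward the lower state index (deterministic outputs). Correctness is
pinned by dense-joint enumeration oracles on 2–4-taxon trees (|Δ| < 1e-8
for log-likelihoods, < 1e-10 for posteriors).

Because every model is time-reversible, only the sum of the two
root-flanking branch lengths is identifiable; the optimizer ties them to
equal halves. Branch lengths (bounded ≥ 1e-8) and α (bounded [0.05, 50])
are optimized as logs by L-BFGS-B from the pruning likelihood. With
identical sequences all branch lengths land on the lower bound.

## Selection tests

Per gene, a one-ratio (M0) fit first estimates branch lengths, κ and a
single ω jointly.

* **Branch-site LRT.** Model A: classes 0 (ω₀ ≤ 1 everywhere),
  1 (ω = 1 everywhere), 2a (ω₂ on the foreground, ω₀ on the background)
  and 2b (ω₂ / 1), proportions parameterized as in codeml (p0, p1 with
  p2 split in proportion p0:p1). Branch lengths and κ are held at their
  M0 estimates; the class parameters are optimized by bounded L-BFGS-B
  from several deterministic starts, and the alternative is additionally
  seeded from the null optimum with ω₂ just above 1, which enforces the
  nested-model inequality lnL_alt ≥ lnL_null by construction. The test
  statistic 2Δℓ (clamped at 0) is referred to χ²₁ — the conservative
  convention for a boundary null — and genes with p < 0.05 are flagged.
  Holding branch lengths fixed across the two nested fits keeps the test
  valid (both models see the same distortion) at a fraction of the cost of
  re-optimizing lengths twice per gene.
* **Two-ratio ω(TG) − ω(BG).** One ω for the three foreground branches,
  one for everything else, with branch lengths *re-optimized jointly*
  (κ from M0): under the shared neutral time scale a branch's length and
  its ω are separately identifiable (length from total divergence, ω from
  nonsynonymous/synonymous composition), and fixing lengths at M0 values
  demonstrably shrinks the ω contrast. The LRT against M0 uses χ²₁;
  genes with p < 0.01 are flagged and ranked by ω(TG) − ω(BG). This
  two-ratio ML realization of "average group ω" is a declared design
  choice: per-branch free-ratio averages are unstable on short branches.
* **NG86.** Pathway-averaged difference counting with Jukes–Cantor
  correction. Site counting keeps S + N = 3 per codon: at each position
  the synonymous fraction is taken among non-stop changes, so mutations to
  stop codons implicitly count as nonsynonymous sites. Under a 61-state
  generator (which never visits stops) this convention is exact at κ = 1
  and slightly conservative otherwise; ω is reported as NaN when dS is 0.

## Gene-family birth–death model

Family size evolves as a linear birth–death chain with equal per-gene
birth and death rate λ (state 0 absorbing), with the closed-form
transition probability over a branch (see README). Matrices are truncated
at a cap of twice the largest observed count (minimum 16) and rows
renormalized; at the λt values arising here the clipped mass is below
1e-6. One global λ is fitted by bounded 1-D likelihood maximization, the
root marginalized over a uniform prior on 1..2·max-count and conditioned
on the family surviving somewhere.

* **Family-wide p-value** — Monte Carlo conditioned on the family's
  most-likely root count: null families are simulated from that root under
  the fitted λ (exact event-driven Gillespie stepping — the same simulator
  the generator uses, so the analytic transition law is independently
  cross-checked against it), and the add-one fraction with conditional
  likelihood at or below the observed family's is reported. Conditioning
  on the root removes the family-size confound (large families are
  intrinsically more dispersed); an earlier root-marginalized variant lost
  roughly half its power against planted ±10 jumps for exactly that
  reason.
* **Viterbi p-values** — max-product reconstruction of ancestral counts
  (ties toward the smaller count), then per branch a one-directional tail
  sum of the transition law relative to the parent's reconstructed count.
  Calls (expansion/contraction at p < 0.05) are tallied per branch only
  for families that also clear the family-wide threshold. The per-branch
  test carries no multiplicity correction, so its false-call rate sits
  near the nominal 5% by design.

## MCL clustering

Edge weight is −log10(e-value), capped at 200 and averaged over the two
hit directions (bit score selectable); edges above the 1e-5 e-value cutoff
are dropped, and genes left with no edges are reported as unclustered.
Self-loops at the maximum incident weight regularize the walk. Iteration:
column normalization, expansion (M·M), inflation (element-wise power 1.5,
renormalize), pruning of entries below 1e-6, until the maximum entry
change drops below 1e-8 (at most 200 iterations; non-convergence raises
with diagnostics). Clusters are read off attractor rows; overlapping
attractor supports are merged. The "other" gene category is defined as
the complement of the four explicit categories.

## Convergence calling

Criterion (2)'s "ancestors" default to *every* internal node of the tree
(the strictest reading; a `parents` mode restricts to the foreground
branches' parent nodes). A reconstructed ancestral state is accepted only
when its MAP posterior reaches 0.8 (configurable); columns whose
reconstruction at the outgroup's attachment node disagrees with the
outgroup residue are excluded (audit mode, which only flags, is also
exposed). Calls are reported in the original column coordinates via the
gap-strip map. Tightening the posterior floor can only remove calls
(monotonicity is property-tested).

The random-trio control re-runs the caller with three non-outgroup species
as an ad-hoc foreground and the remaining non-outgroup species as
background; the preset trio is crested ibis + chicken + tinamou. The
comparison report keeps gene-level and site-level overlap separate, since
two runs can flag the same gene at disjoint columns.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* the pipeline assumes:
JTT+γ site evolution with true ancestral states retained; convergent sites
injected only at columns where every background tip, the outgroup and all
true ancestors already agree (so the three criteria hold by construction,
and ancestors are untouched); GY94 codon evolution with branch- and
site-class-specific ω; family counts from the exact birth–death process
with deterministic planted jumps (on a planted branch the child count is
parent + jump, clamped at 0, in place of stochastic evolution — so the
jump is recovered exactly in bookkeeping tests); and a BLAST-tabular edge
table with within-family e-values below 1e-5 and sparse noise edges above
it.

They deliberately do **not** emulate: indels or alignment error (no gap
columns are generated; gap stripping is exercised on constructed cases),
heterotachy, codon-usage bias beyond the frequency vector,
assembly/annotation artifacts, paralogy interleaving within the similarity
graph signal range, or any coupling between a gene's protein and codon
alignments (the two are simulated independently — the convergence scan
consumes proteins, the selection scan codons, so nothing downstream
requires them to encode the same history). Passing tests therefore
demonstrate correctness and calibration of the methods under their own
model assumptions, not robustness to real-data violations of them.

## Default study conditions and problem sizes

The default end-to-end run uses 8 single-copy genes (300-aa proteins,
150–300-codon cds), 3 genes with 4 injected convergent sites each, 2 genes
with ω₂ = 4 on 15% of sites, 2 genes with a TG/BG shift of 0.8 vs 0.2, 80
families (plus planted +8 mallard / −6 egret jumps) at λ = 0.002, and 200
Monte-Carlo draws per family p-value. Calibration and recovery studies in
the tests use 10,000-column alignments for convergent-site recovery, 500
families for λ recovery, 300-codon replicates for LRT calibration and
power, and 500-codon replicates for the ω-shift recovery — sizes chosen so
each study estimates its rate with useful precision while the whole suite
runs in minutes on a single CPU. Every simulator is a pure function of its
arguments and one integer seed, and the pipeline derives all stage seeds
from the run seed through a fixed spawn order, so reruns are
byte-identical (verified by hashing every output file).

## Known limitations

* The branch-site fit inherits κ and branch lengths from M0 rather than
  re-optimizing them per hypothesis; with very long branches or extreme κ
  this can cost a little power (never validity, as both nested fits share
  the approximation).
* The family-wide p-value conditions on a point estimate of the root count
  rather than integrating over it; for families whose root is genuinely
  ambiguous the p-value is mildly optimistic.
* Enrichment operates on user-supplied term maps with no ontology graph
  propagation; at the default toy scale (8-gene universe) no term can
  reach q < 0.05, which the worked example shows honestly.
* The MCL implementation is dense; it is meant for the tens-of-thousands
  of genes scale at most, not millions.
* ω estimates from the two-ratio model are averages over the branch
  group; they do not identify which foreground lineage drives a shift.
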