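# convphy

Comparative phylogenomics of convergent adaptation in tactile-foraging
birds, as a tested, reusable Python pipeline.

Three bird lineages forage by touch rather than sight — the northern brown
kiwi, the mallard, and the crested ibis — and each has a non-tactile sister
species (white-throated tinamou, chicken, little egret) plus the visually
guided common ostrich as outgroup. Given proteomes, alignments, a species
tree and gene-family counts for such a design, `convphy` asks the standard
comparative-genomics questions: which gene families expanded or contracted
on each branch, which genes were positively selected on the tactile
(foreground, "TG") branches, whether dN/dS differs systematically between
the tactile and background ("BG") groups, and which amino-acid sites changed
convergently in all three tactile lineages.

Because real genome-scale inputs are enormous and assembly-dependent, the
package ships a first-class synthetic-data layer that generates every input
on the fixed 7-species tree with known ground truth (planted convergent
sites, planted ω shifts, planted family-size jumps), so every stage can be
validated end to end.

## What it computes

* **Orthology** — proteome filtering (< 30 aa, internal stops, longest
  transcript per gene), Markov clustering (MCL, inflation 1.5) of an
  all-vs-all similarity table at e-value ≤ 1e-5, per-species gene categories
  (single-copy / multiple-copy / unique / other / unclustered), and 1:1
  single-copy family extraction.
* **Gene-family evolution** — equal-rate linear birth–death model of family
  size on the ultrametric time tree:
  P(s→c | t, λ) = Σⱼ C(s,j)·C(s+c−j−1, s−1)·α^(s+c−2j)·(1−2α)^j with
  α = λt/(1+λt); global λ by maximum likelihood, Monte-Carlo family-wide
  p-values conditioned on the family's most-likely root count, per-branch
  Viterbi p-values and expansion/contraction calls.
* **Selection** — GY94 codon model (F3x4 frequencies, κ, ω; matrices on a
  shared neutral time scale). Branch-site Model A likelihood-ratio test for
  positive selection on the three tactile branches (ω₂ ≥ 1 free vs ω₂ = 1,
  χ²₁, p < 0.05), and a two-ratio ω(TG) vs ω(BG) fit with an LRT against the
  one-ratio model (p < 0.01), reporting ω(TG) − ω(BG). NG86 pairwise dN/dS
  counting is included as an independent estimator.
* **Ancestral reconstruction** — Felsenstein pruning under JTT + discrete-γ
  (K = 4 equal-probability categories), bounded-quasi-Newton fitting of
  branch lengths and the γ shape α, and marginal (per-node, per-site)
  posterior reconstruction with MAP states.
* **Convergence (CCS)** — a column is a convergent site iff (1) all three
  foreground tips share one residue X, (2) all background tips and the MAP
  states of the inspected ancestral nodes share one residue Y, and
  (3) X ≠ Y; sites inconsistent with the outgroup are skipped. A random-trio
  control re-runs the caller with an arbitrary species trio as foreground
  and reports gene-level vs site-level overlap with the true run.
* **Enrichment** — one-sided hypergeometric tests of result gene sets
  against user-supplied term maps with Benjamini–Hochberg FDR.

## Worked example

Run the numbered analysis scripts in order (they share
`results/analysis/`):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_cluster_families.py
python analysis/03_family_evolution.py
python analysis/04_selection_scan.py
python analysis/05_convergence_scan.py
python analysis/06_enrichment.py
```

Script 01 plants, at seed 1: convergent sites in genes g00–g02 (4, 4 and 4
columns), branch-site positive selection (ω₂ = 4 on 15 % of sites) in
g03–g04, a TG/BG ω shift (0.8 vs 0.2) in g05–g06, one null gene g07, and
family-size jumps of +8 on the mallard branch and −6 on the egret branch.
The downstream scripts print, among other things:

```
lambda_hat = 0.00211961 per gene per unit time (cap 42)    # true 0.002
g03: LRT p=0.0001015  omega_diff=+0.727 (p=3.747e-07)
g04: LRT p=0.003109   omega_diff=+0.357 (p=0.005112)
g05: LRT p=1          omega_diff=+0.837 (p=4.928e-11)
positively selected: ['g03', 'g04']; omega-shift: ['g03', 'g04', 'g05', 'g06']
11 convergent site(s) in 3 gene(s) under the tactile foreground
control trio ['chicken', 'ibis', 'tinamou']: 0 gene(s), gene overlap 0
```

So the two positively selected genes are exactly the planted ones, the
ω-difference scan flags the two planted shift genes plus the two
positive-selection genes (whose foreground ω really is elevated), the 11
called convergent sites sit in exactly the three planted genes (11 of the
12 planted columns; no false columns), and the non-tactile control trio
finds nothing. The family scan calls the mallard expansion and egret
contraction on the correct branches.

The same run is available as one command (plus a `manifest.json` whose file
hashes make reruns verifiable):

```bash
convphy run-all --seed 1 --out-dir run
```

Individual stages are exposed as `convphy simulate | cluster | asr |
converge | select | famevol | enrich` — see `convphy --help`.

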