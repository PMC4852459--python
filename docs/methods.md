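# Methods

`nlrevo` analyses large, young multigene families — the motivating case is
the fish NLR-B30.2 family, several hundred innate-immune receptor genes in
which two domains of the *same* protein evolve under different regimes.  The
package couples a forward simulator that can generate such families with
known ground truth to the analysis operations used to characterise them:
codon-level divergence, tree building and reduction, chromosomal layout
statistics, and motif-based gene discovery.

## The evolutionary model behind the simulator (`famsim`)

A family of `n_groups x genes_per_group` genes descends from a single root
coding sequence.  Group identity is a label plus a conversion topology;
there is no separate "group ancestor" divergence phase.  Three processes
act per generation, all logged as replayable events:

* **Point substitution.** For each gene and domain, a Poisson number of
  accepted single-nucleotide substitutions with mean
  `point_sub_rate x domain_codons` is applied.  Proposals are uniform over
  positions and alternative bases; proposals creating stop codons are
  rejected; a synonymous proposal is accepted with probability
  min(1, 1/&omega;) and a nonsynonymous one with min(1, &omega;), where
  &omega; is the proposal codon's selection class.  This
  proposal/acceptance kernel is deliberately simpler than a GY94 rate
  matrix: only the &omega; asymmetry matters for the signals the simulator
  exists to produce.  Two consequences of the kernel are worth knowing:
  (i) because acceptance is capped at 1, "positive selection" can only be
  expressed as *suppression of synonymous* changes at a site, so the
  realised domain-wide dN/dS is a weighted harmonic blend of the site
  classes, not their arithmetic mean; (ii) events are drawn per *domain*,
  not per gene — fixing the accepted-event total across a gene would let
  purifying selection in one domain displace events into the other
  domain's synonymous sites and distort its dN/dS.

* **Gene conversion.** Per gene, domain and generation, a Poisson number
  (mean `conversion_rate`) of non-reciprocal tract copies from a donor
  chosen uniformly among eligible genes: same group under the
  `within_group` policy, any other gene under `across_groups`.  Tract
  length is geometric with mean `tract_mean` codons, truncated at the
  domain boundary; the tract start is uniform inside the domain.  Pairwise
  divergence inside a converting pool of *n* genes behaves like a
  coalescent: a pair "coalesces" at a site when one member converts
  directly from the other, so the expected within-pool dS plateaus around
  `2 x sub_rate_per_site x (n-1) / (2 x c_site)` where `c_site` is the
  per-site conversion coverage per generation.  This is why cross-group
  conversion (pool = whole family) equilibrates at a somewhat higher dS
  than within-group conversion (pool = one group) at the same rate.

* **Duplication.** A full-gene tandem copy with a fresh id in the source
  gene's group (off by default; the acceptance regime holds family size
  fixed).

A *saturation guard* refuses configurations with
`point_sub_rate x generations > 1.5` expected accepted substitutions per
codon site per lineage, where Jukes–Cantor-corrected dS becomes undefined
for many pairs.

**Chromosomal placement.** `round(cluster_fraction x n)` genes form one
tandem run near the end of the designated chromosome (the first in the
table); the remainder is placed as per-group tandem runs on the other
chromosomes, each run landing inside the terminal 15% of its chromosome
with probability `end_bias`.  Genes never overlap.  `build_genome` embeds
the coding sequences (reverse-complemented on the minus strand) in uniform
random background so the motif screen can be scored against true spans.

**Embedded motifs.** The root carries the Walker A P-loop consensus
(`G[IV]AG[IV]AGK[TS]`) plus two invented conserved anchors at fixed codon
offsets.  Their codons evolve under &omega; = 0 — the motif is treated as
functionally required, so it is invariant at the protein level while still
accumulating synonymous change.  A green screen-recall test therefore
certifies the scanner and chainer, not mutational luck.

### Default parameter values and why

| parameter | default | rationale |
|---|---|---|
| domains | nacht, b30.2; 120 codons each | desk-scale stand-ins for the ~300-codon NACHT-containing exon and ~170-codon B30.2 exon |
| generations | 300 | with the substitution rate, gives between-group dS ≈ 1.0, far from both zero and saturation |
| point_sub_rate | 0.002 /codon/generation | `r x G = 0.6` accepted substitutions per codon site per lineage |
| conversion_rate | 2.5 /gene/generation/domain | within-group dS equilibrates near 0.06, between-group B30.2 dS near 0.06 — an order of magnitude below between-group NACHT dS |
| tract_mean | 10 codons | tracts much shorter than the domain, so substitutions in different tract lineages can recombine; shorter tracts also reduce replicate-to-replicate variance of the realised dN/dS |
| omega (nacht) | background 0.2, no hypervariable sites | ordinary purifying selection on the nucleotide-binding module |
| omega (b30.2) | 20% hypervariable at 4.0 over background 2.0 | calibrated so the *realised* domain-wide median dN/dS is ≈ 1.5–1.7, matching what is observed for B30.2-type recognition domains; under the acceptance kernel a neutral background plus 20% hyper sites would realise only ≈ 1.06 |
| cluster_fraction / end_bias | 0.75 / 0.81 | three quarters of the family on one chromosome; the rest biased toward chromosome ends |

These defaults are a *stated world*: they were chosen (on a seed range
disjoint from any test's) to land in the qualitative regime the analysis is
supposed to detect, and the recovery tests then check that the pipeline
detects it from the sequences alone.

### What the simulator does not model

No polymorphism within a gene (each gene is a single haploid sequence), no
whole-genome duplication, no pseudogenisation, no indels (all sequences
stay aligned by construction, so the back-translation path is exercised
with real alignments, not simulated ones), no rate heterogeneity beyond
the two-class &omega; profile, and no within-domain variation in
conversion propensity.  A green recovery test establishes that the
estimators detect the simulated contrast; it cannot certify behaviour on
features the generator lacks (alignment error above all).

## Divergence estimation (`codondiv`)

`ng86_pair` implements Nei–Gojobori (1986) counting with Jukes–Cantor
correction.  Conventions, each of which moves third-decimal digits:

* Single-base changes *to* stop codons count as nonsynonymous in site
  counting, so S + N = 3 for every codon.
* Codons differing at 2–3 positions average observed differences over all
  orderings of single-base steps, excluding orderings that pass through a
  stop (with a uniform fallback if all are blocked — unreachable between
  sense codons under the standard code, kept as a guard).
* Codon columns with a gap, ambiguity or stop on either side of a pair are
  excluded (pairwise complete-codon deletion, maximising comparable pairs).
* dS = −(3/4)·ln(1 − 4pS/3); if the log argument is ≤ 0 the pair is
  flagged invalid (saturated) and excluded from medians, with the count
  reported.
* &omega; is reported as NaN — an invalid ratio, not infinity — when
  dS = 0, and such pairs are excluded from &omega; medians only.
* Medians use numpy's midpoint rule for even counts.

`myn_pair` implements the iterative Yang–Nielsen (2000)-style estimator:
kappa estimated from nondegenerate and fourfold-degenerate positions via
the F84 correction (converted to HKY form, site-count-weighted average of
the two degeneracy classes); synonymous/nonsynonymous sites counted with
mutation weights (observed-codon frequency of the target codon, times
kappa for transitions), normalised to 3L per sequence and averaged;
observed differences partitioned into transitions/transversions per site
class, with multi-step codon pathways weighted by their probability under
a GY94-style codon model at the current (t, kappa, omega); per-class F84
distance correction; iterate to a 1e-5 tolerance with a 50-iteration cap
(`valid=False` on failure).  On tiny inputs whose codons have no observed
single-step neighbours the frequency weighting degenerates; the estimator
then falls back to uniform codon weights.

`backtranslate` threads unaligned CDSs onto a protein alignment
(tranalign-style), tolerating one trailing stop codon and reporting the id
and residue index of any disagreement.  Domain analyses slice the codon
alignment by named 1-based codon-column partitions, which are
user-supplied, not inferred.

## Trees (`treeops`)

Distances are Poisson-corrected amino-acid distances, d = −ln(1−p) over
pairwise-complete sites (invalid at p ≥ 1).  Trees are dendropy objects;
`nj_tree` is a textbook Saitou–Nei agglomeration with two documented
choices: all ties (Q-matrix minima) break by lexicographic order of
cluster representative labels, and negative branch lengths are clamped to
zero with the deficit transferred to the sister edge so path-length sums
are preserved where possible.  On additive matrices the unrooted topology
and all branch lengths are recovered exactly.

"Monophyletic paralogues" are read in the unrooted sense: a maximal
bipartition side (≥ 2 leaves) whose leaves all carry one species tag.  The
whole leaf set counts as one clade if the tree is monospecific.  Note that
on a 3-leaf unrooted tree *every* leaf pair is a bipartition side, so a
same-species pair among three leaves is always a clade.

`recursive_reduce` repeats build-tree → find clades → collapse until no
single-species clade remains (rounds capped at the input size).  Within a
collapsed clade one representative is kept *per group label present* — the
lexicographically smallest id — which guarantees no (species, group)
combination ever loses its last representative (the anchor rule).  The
recursion is builder-agnostic: any `builder(seqs) -> tree` (e.g. parsed
newick from an external Bayesian/ML run) can replace the internal NJ; by
default each round re-uses the fixed input alignment rather than
re-aligning — a per-round realignment hook is exactly what the builder
callable provides.

Tree incongruence restricts both trees to their shared leaves and counts
the symmetric difference of nontrivial bipartitions (Robinson–Foulds),
plus a per-gene leaf-order pairing table for tanglegram rendering.

## Layout statistics (`genomelayout`)

Gene position is the interval midpoint (the plotting convention is not
otherwise determined); coordinates are 0-based half-open BED throughout.
A gene is "near an end" iff min(rel, 1−rel) ≤ threshold (default 0.15).
Genes on chromosomes of unknown length are reported separately and
excluded from denominators, mirroring how unplaced scaffolds are handled
in practice.  Counting "chromosome 4" stands in for "the long arm of
chromosome 4" — the arm boundary is not modelled; pass an explicit
`exclude` set or pre-filter records if an arm split is needed.

## Motif screening (`motifscan`)

Patterns are PROSITE strings (`C-x(2,4)-C-...`) or plain class strings
(`G[IV]AG[IV]AGK[TS]`), compiled to regexes.  DNA is scanned in all six
frames with residue coordinates mapped back to forward-strand bp.  C2H2
zinc fingers use the PS00028-equivalent class pattern with
non-overlapping, leftmost-first counting (material in tandem arrays).
Locus chaining is greedy per sequence and strand: walking hits in strand
order, a hit extends the open chain if its profile rank is not lower than
the previous hit's and the gap is within `max_gap` (default 2000 bp, a
gene-scale window); chains with at least `min_motifs` (default 2) distinct
motifs become candidate loci, and overlapping loci merge keeping the
higher-scoring chain.  A two-motif profile with an amplicon-length window
doubles as an electronic-PCR primer scan.

## Numerical and degenerate-input policy

Estimator validity is always an explicit flag, never an exception, once
preconditions (frame, length, ≥ 1 comparable unit) hold; exceptions are
reserved for contract violations.  All randomness in the simulator flows
from one `numpy` Generator seeded from `SimConfig.seed`; byte-identical
outputs for equal seeds are a tested contract.  The genome builder derives
its default seed from the config seed so a dataset and its genome are
jointly reproducible.

## Known limitations

* The recursion collapses clades using the *input* alignment's distances
  each round; with very gappy alignments a per-round realignment builder
  is advisable.
* The YN00-style estimator is a pairwise counting method; it inherits the
  known small-sample biases of that family and is not a substitute for ML
  codon models when branch lengths are long.
* Conversion-tract detection is out of scope: conversion is *assessed* at
  domain granularity (the dS contrast), not located along the sequence.
* The screen's recall guarantee holds for the simulator's stated world
  (motifs under strong constraint); degraded motifs degrade recall, which
  is the biologically expected behaviour, not a bug.
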