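# Methods

`cyp2bdiv` analyses the diversity of expressed variants of a recently
duplicated gene subfamily — the motivating system is hepatic CYP2B
detoxification enzymes cloned from desert woodrats (*Neotoma lepida*)
after a population x diet feeding trial — and ships a synthetic
gene-family generator so the whole chain is testable end to end.

## Data model

The unit of analysis is a complete open reading frame (ORF): start codon
through a single terminal stop, no internal stops, unambiguous
nucleotides. Records violating these invariants are excluded and reported,
the same filtering applied to cloned cDNA contigs. Each sequence carries
treatment metadata (population: Great Basin or Mojave; diet: juniper or
creosote), giving four treatment groups. Because all clones are
full-length ORFs amplified with common primers they are positionally
homologous, so the codon "alignment" is the stacked sequence set; no MSA
step exists. All analysis positions exclude the terminal stop codon and
codon coordinates are 1-based, so a 1476-nt ORF has 491 analysed codons
(initial Met included).

## Dereplication

Protein variants are grouped by greedy centroid clustering: sequences in
input order join the first group whose representative identity is
*strictly* greater than the threshold (default 0.95), otherwise they found
a group. Identity is global-alignment identity with gaps: match +1,
mismatch 0, linear gap −1, computed by a dynamic program whose tie-break
(fewest gap columns among co-optimal alignments) is folded into the
objective, and identity = matches / alignment columns (gap columns
included). The scoring and tie-breaks are pinned because published
dereplication tools do not document theirs; greedy centroid grouping is
input-order dependent by nature, and a `presort` option (decreasing
length, then id) gives an order-independent canonical run. Normalising by
alignment length rather than by the shorter sequence is a pinned choice;
for the equal-length ORFs this package targets the two coincide unless
the aligner opens compensating gaps.

## Tree construction and ancestral states

Trees are neighbor-joining on pairwise distances: amino-acid p-distance
with Poisson correction −ln(1−p) by default (raw p-distance optional). NJ
is deterministic: Q-criterion ties break toward the smallest pair of
cluster creation indices, and negative branch-length estimates are clamped
to zero with the deficit moved to the sister branch so downstream UniFrac
sees non-negative lengths. A distance tree stands in for a full
likelihood search deliberately: every downstream consumer (UniFrac,
edge-level substitution counts) needs a reasonable tree with branch
lengths, not one specific ML topology, and the tests assert clade-level
structure rather than exact topologies. Rooting is midpoint by default or
on a designated outgroup's bisected terminal branch.

Ancestral codons come from Fitch parsimony, column by column: bottom-up
set intersections/unions give the minimal change count; the top-down pass
keeps the parent's state when possible and otherwise takes the
lexicographically smallest member, so reconstructions are deterministic
and achieve the minimum on the binary rooted trees used here. This is a
declared parsimony surrogate for likelihood ancestral reconstruction, not
claimed equivalent.

## Treatment structure: unweighted UniFrac

For two groups of leaves, unweighted UniFrac = (branch length unique to
one group) / (total branch length spanned), after restricting the tree to
the two groups' leaves and discarding edges above their common ancestor —
equivalent to physical pruning, and implemented with per-edge descendant
bitsets so permutations are cheap. The omnibus statistic over the four
treatments is the mean of the pairwise distances (the original omnibus
statistic of the Fast UniFrac service is unspecified; this choice is
pinned and reported as such). Significance comes from permuting leaf
labels with group sizes preserved — "bootstrapped permutations" is read as
label permutation, the standard UniFrac significance test — with add-one
p-values, p = (1 + #{null ≥ observed}) / (1 + n_perm), so p is never 0 and
never below 1/(1+n_perm). Pairwise tests use the same nulls with
Bonferroni correction for the number of compared pairs; groups with fewer
than two leaves are skipped with a warning and excluded from the
correction count. An abundance-weighted variant is deliberately absent:
presence/absence matches the question of which variants a treatment
expresses at all.

## Selection analysis

Counting follows Nei–Gojobori (1986). Potential sites per sense codon:
s = (synonymous single-nucleotide changes)/3 summed over the three
positions, n = 3 − s; mutations to stop codons are never synonymous and
remain in n. Observed differences per codon pair are averaged with equal
weight over all minimal mutational pathways, excluding pathways that pass
through a stop codon (if every pathway does, the average falls back to
all pathways rather than dropping the codon). Proportions pN = Nd/N and
pS = Sd/S are Jukes–Cantor corrected, d = −(3/4)ln(1 − 4p/3), undefined at
saturation (p ≥ 3/4). The global ratio is mean pairwise dN over mean
pairwise dS across all pairs with defined rates; an alignment with no
synonymous signal reports the ratio as undefined rather than infinite.

The neutrality z-test bootstraps codon columns: Z = (mean dS − mean dN) /
SE, with SE the standard deviation of that difference over column
resamples (default 1000), and a one-tailed normal p for the
purifying-selection alternative (dS > dN).

The per-site scan is a parsimony flavour of SLAC: substitutions are
tallied on every tree edge from the Fitch ancestral codons
(pathway-averaged for multi-step codon changes), and each column's
nonsynonymous count is tested against the neutral expectation
n_c/(n_c+s_c) with a two-tailed binomial test (fractional
pathway-averaged counts are rounded to integers for the test). Columns
with no changes are invariant; otherwise p < 0.1 classifies positive
(dN > dS in per-site rates) or negative selection, mirroring the
conventional reporting threshold; the threshold is configurable.

## SRS fingerprints and enrichment

The 13 substrate-recognition-site residue positions (default 114, 206,
209, 290, 294, 297, 298, 302, 363, 367, 477, 478, 480; 1-based on the
ungapped 491-residue protein) define a fingerprint: the ordered residue
tuple at those positions. Sequences are grouped by exact fingerprint;
labels (A, B, ...) follow order of first appearance. Clade concordance is
the fraction of multi-member fingerprints that are strictly monophyletic
on the tree (no foreign leaf inside, singletons excluded from the mean).
Enrichment compares (nonsynonymous, synonymous) substitution counts inside
vs outside the SRS codons with a two-sided Fisher exact test (conditional
rule: sum of hypergeometric probabilities ≤ observed); the odds ratio is
the cross-product ratio with a flagged Haldane 0.5 correction only when a
cell is zero. Counts default to the tree-scan tallies, with a
consensus-comparison fallback; the worked-example route accepts an
explicit 2x2 table directly.

## qPCR relative copy number

Copy number of the multigene target relative to a single-copy reference is
efficiency^(mean Cq_ref − mean Cq_target), efficiency defaulting to ideal
doubling (2.0) and configurable per primer set; replicate scatter
propagates through the log-ratio into a reported SD, and replicate SD
above 0.5 cycles warns. Group comparisons use Welch's t with Satterthwaite
degrees of freedom — the fractional df reported in this design's published
analysis indicates the Welch form despite "Student's t" wording. Raw Cq
data for the motivating study are unpublished, so this module is validated
by simulation only (estimator bias ≪ noise at SD 0.2 cycles; Welch
rejection rates match a permutation test).

## Synthetic gene family

The generator emulates the cloning study's structure:

* an ancestral ORF of 491 codons (ATG + 490 uniform sense codons + stop);
* `n_loci` (default 4) loci evolved independently from the ancestor under
  a proposal–acceptance codon model: proposals are uniform
  single-nucleotide changes at rate `locus_divergence` (default 0.05
  proposals per mutable nt site; start and stop codons immutable),
  stop-creating draws are redrawn so the realised rate stays near nominal,
  synonymous proposals are always accepted, nonsynonymous ones with
  probability min(1, ω) — `omega_background` 0.5 away from the SRS codons,
  `omega_srs` 2.0 (i.e. acceptance 1.0) at them, so loci diverge
  preferentially in SRS residues;
* per treatment, `animals_per_treatment` (3) animals contribute
  `clones_per_animal` (7) clones each — 84 clones total, near the real
  87 — whose source locus is an independent multinomial draw from the
  treatment's expression weights;
* within-locus allelic variation (`allele_divergence` 5e-4/nt) and RT-PCR
  error (`error_rate` 5e-4/nt) add ~1.5 unfiltered sense-preserving
  substitutions per clone, so a sizeable minority of clones are exact
  duplicates (cf. 87 clones → 62 unique nucleotide sequences observed).

Default expression weights give one clade expressed by every treatment
and three clades each dominated by a single treatment with some
treatment × clade combinations absent, the qualitative pattern described
for the real tree. A truth table records each clone's locus, animal,
treatment and injected noise positions. All draws flow from the single
model seed; identical models give byte-identical FASTA output.

What the generator does **not** emulate: indels, recombination/gene
conversion, codon-usage bias, pseudogenes, per-animal genotype structure
(clones are drawn per clone, not from two alleles per locus per animal),
and selection on within-locus allelic noise. The last point matters when
interpreting tests: because allelic/RT-PCR substitutions bypass the ω
filter, terminal branches carry a nonsynonymous fraction near the raw
proposal mix (~0.72), inflating the dataset-wide background fraction
above what `omega_background` alone would give. Passing tests therefore
demonstrate that the estimators recover the generating parameters where
the model expresses them (ω between loci, locus count, treatment bias),
not that real data meet these assumptions.

Calibration choices: `locus_divergence` 0.05 puts between-locus
amino-acid identity near 0.87–0.92, comfortably below the 0.95
dereplication threshold (the observed dataset's 3–4 variants at 95%
indicate clades in this range), while keeping the dataset mean nucleotide
p-distance at 0.03–0.05, the observed order of magnitude.

## Problem sizes and numerics

Default analyses run on desk scale: 84 clones × 491 codons, 1000
permutations, 1000 bootstrap columns (seconds on one CPU). Tests use a
reduced family (24 clones × 120 codons) where full size adds nothing.
Numerical conventions: fingerprint/NJ/Fitch tie-breaks as above; UniFrac
denominators of zero (no spanned branch length) return distance 0;
Fisher on pathway-averaged counts rounds to nearest integer; JSON output
rounds floats to 10 digits for byte-stable reruns; identical config +
seed reproduces byte-identical summary and tables.

## Known limitations

* The distance tree is a surrogate for likelihood reconstruction; exact
  published tree-dependent quantities (a specific omnibus p-value, the
  exact list of negatively selected codons, Z = −4.24) are not
  reproduction targets, and recombination screening before the site scan
  is omitted (sub-alignments can be supplied instead).
* Parsimony ancestors undercount substitutions on long branches, biasing
  edge tallies (and hence SRS enrichment counts from the scan route)
  downward at deep divergence.
* The identity-with-gaps DP is exact but quadratic; dereplicating very
  large clone sets (≫10³) would warrant a banded or heuristic pre-filter.
* Welch's t on copy ratios treats per-sample ratios as independent
  observations; plate effects and shared-reference correlation are not
  modelled.
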