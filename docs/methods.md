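# Methods

## The screen

The unit of inference is one anchor gene: the best filtered homology bit
scores of that gene in every strain of three groups (ACiM, nonACiM,
nonACiR) are treated as three samples and compared by one-way
fixed-effects ANOVA, F = [SSB/(k−1)]/[SSW/(N−k)] with the upper tail of
F(k−1, N−k) as p-value (computed through the regularized incomplete beta
function, via scipy). Benjamini–Hochberg step-up adjustment is applied
over the *tested* genes only; anchor genes with bit score 0 in every
non-focal strain carry no information about group contrast and are
reported with p = q = NA. Selection requires q < 0.001 **and** the ACiM
mean to strictly exceed both other group means. The directional contrast
is part of the hypothesis (conservation specifically with ACiM), not an
afterthought: group differences in the other direction (e.g. higher
similarity to same-genus nonACiR strains, the usual case) are significant
by ANOVA but are not AC-conserved genes.

Degenerate rows are kept explicit: SSW = 0 with SSB > 0 (identical scores
within every group, different between groups) is perfect within-group
conservation — the strongest possible signal — and gets F = ∞, p = 0 with
a degeneracy flag; all-identical rows get F = 0, p = 1. Missing hits enter
the ANOVA as bit score 0 rather than being dropped: absence from a whole
group is exactly the divergence signal the screen is after.

Islands are maximal runs of selected genes along the focal strain's gene
order in which consecutive selected genes are separated by at most
`max_gap` unselected genes (default 1), keeping runs with at least
`min_size` selected genes (default 3). Gaps are allowed because real
symbiosis regions carry occasional non-conserved insertions; both
parameters are exposed on the CLI. Coordinates are 0-based half-open.

## Homology engines

Two engines implement the same search contract (best hit per query with
E ≤ `evalue_max`, default 10⁻⁵, and min(query, target) coverage ≥
`coverage_min`, default 0.5):

* **sw** — exact affine-gap Smith–Waterman (numba-compiled DP with origin
  tracking, so alignment spans and coverages come without a traceback).
  Scoring is BLOSUM62 with gap open 11 / extend 1 (a length-L gap costs
  11 + L); raw scores map to bits via the Karlin–Altschul parameters of
  the gapped BLOSUM62 system (λ = 0.267 nats, K = 0.041), and E-values are
  per-pair, E = m·n·2⁻ᵇⁱᵗˢ, independent of database size. `X` is accepted
  and scores 0 against everything; ties between equal-scoring targets go
  to the lexicographically smallest id. The DP is verified against an
  exhaustive enumeration of all local alignment paths on short sequences.
* **phmmer** — HMMER's single-sequence protein search through pyhmmer,
  with full-sequence bit scores, HMMER's E-values (search-space = the
  pooled target set) and coverage from the best domain alignment. Used
  for large runs: exact all-vs-all DP over 10³ anchors × 2×10⁴ targets is
  ≈3×10¹¹ DP cells, far beyond a single core, while phmmer's filter
  pipeline does the same search in under a minute. Deterministic for
  fixed inputs.

Bit scores are only compared within one engine; the screen's rank
structure, not the absolute scale, carries the inference.

## Ortholog families and pan/core partitioning

Families are connected components of a graph over all genes with two edge
types: inter-strain reciprocal best hits, and any filtered hit pair whose
bit score is at least half the smaller of the two genes' self-scores.
Intra-strain edges are allowed, so in-paralogs co-cluster; the
single-copy-core filter (exactly one member in every strain) then removes
those families, which is what the concatenated phylogeny needs. Genes with
no qualifying edge become singleton families. Pan/core accumulation counts
families seen in at least one, respectively all, of the genomes added so
far; final values are order-invariant. Core percentages divide the core
size by the largest and smallest CDS counts and round half-away-from-zero
to one decimal.

## Phylogenetics

Families whose members all have equal length (the default simulator emits
no indels) are aligned positionally; otherwise a center-star alignment is
built around the longest member using affine-gap global alignments
(Biopython's PairwiseAligner under the same scoring system), merging
pairwise alignments with the usual "once a gap, always a gap" rule.
Distances are p-distances with pairwise deletion (columns gapped in either
row are skipped for that pair). Trees come from neighbor joining
(scikit-bio) with negative branch-length estimates clamped to zero; NJ is
exact on additive matrices, which the tests exploit. Robinson–Foulds
distances count non-trivial unrooted bipartitions present in exactly one
tree. Similarity ranges report 100·(1 − p) over all cross-group pairs,
rounded half-away-from-zero to one decimal. Maximum-likelihood inference
and split networks are out of scope; topology recovery is the quantity of
interest, and NJ on p-distances achieves it at desk scale.

## Genome-table statistics

The default two-sample test is the pooled-variance Student t
(df = n₁+n₂−2, two-sided); on the bundled 23-strain table it reproduces
the published genome-size comparison (p = 0.0116), which Welch's variant
does not, so pooled is the default and Welch is available as a separate
function. The GC comparison uses the six ACiM strains against the fourteen
non-AC rhizobia; the focal strain's GC (59.0 mol%) is an outlier noted in
the original description and is excluded from that test. Outgroup rows
never enter the two-group tests. The CDS-count vs genome-size R² is
computed over the 21 rhizobia; the value printed in the original report
(0.979) could not be confirmed from the table by any obvious strain subset
(we obtain 0.66), so the report includes the computed value without
asserting the printed one.

## The synthetic-data generator

The generator emulates the statistical structure the screen assumes, not
rhizobial genome content. One focal strain plus three groups (defaults
6/8/6, matching the original 21-strain design) evolve along a fixed
two-genus guide tree: a *Mesorhizobium* clade (ACiM + nonACiM) and a
*Rhizobium* clade (focal + nonACiR), each clade an independently drawn
random ultrametric binary subtree. Root-to-tip within-clade length is
`d_background`/2 and the two clade stems add
(`d_between_genus` − `d_background`)/2 each, so within-genus strain pairs
accumulate ≈ `d_background` substitution events per site and between-genus
pairs ≈ `d_between_genus`. Sequences evolve by i.i.d. per-site replacement
on the 20-letter alphabet (each site replaced with the branch probability
by one of the other 19 residues, uniformly); observed p-distances are
slightly below the summed event loads because of multiple hits. There are
no indels by default (keeping family alignments positional and oracles
exact); an optional per-copy `indel_rate` deletes 1–3 residues to exercise
the center-star path.

The planted island is a contiguous block of `island_size` families
(default 20) in the focal gene order, confined to one scaffold: each ACiM
copy is re-derived from the focal copy at divergence `d_within_island`
(default 0.02, the ~96–99% similarity regime of shared symbiosis genes),
and the block is absent from nonACiM and nonACiR strains, as a
horizontally acquired region would be. Ordinary families are lost from
each non-focal strain independently with probability `accessory_fraction`
(default 0.05), giving an open pan-genome with a core of roughly
(1−0.05)²⁰ ≈ 36% of families. Defaults for the divergences
(`d_background` = 0.25, `d_between_genus` = 0.45) sit in the
within-genus/between-genus range suggested by the published similarity
ranges; the original study reports no magnitudes for the island versus the
background, so these are chosen once to make the planted signal realistic
and detectable. When `d_within_island` equals `d_background` the island
families are generated exactly like ordinary families — the no-signal
control under which the screen should select (almost) nothing.

Randomness is structured as one PRNG stream per strain plus one global
stream, all spawned from the master seed, making outputs bit-identical for
a fixed seed and independent of strain insertion order. Genome summaries
report coding length (3·(residues+1) bases per CDS) as "genome size" and
an assigned per-strain GC model value; the generator carries no nucleotide
sequences.

What passing tests show — and don't: recovery of the planted island
demonstrates that the ANOVA/FDR/contrast machinery detects a
group-restricted low-divergence block against a group-structured
background at realistic divergences, and that FDR control holds under the
null. It does not show robustness to real-genome complications the
generator omits: paralog expansions, domain shuffling, partial-length
homologs, compositional bias, or islands shared imperfectly across the
conserved group.

## Problem sizes and numerical choices

* Screen validation runs the full stated design — 21 strains, 1000
  families of ~120 residues (lengths uniform on [100, 140]), 20 planted
  families, seeds 1–10 plus 10 no-signal controls — with the phmmer
  engine (~45 s per replicate on one core).
* Tree-recovery validation runs the same default configuration over ten
  seeds but builds the single-copy-core supermatrix from the generator's
  true family partition, isolating alignment → p-distance → NJ from
  clustering (whose correctness, including truth-partition equality, is
  tested separately at small scale, and which the small end-to-end
  pipeline test exercises through the clustering route).
* Floating-point TSV output uses `%.6g`; all tabular artifacts are
  tab-separated UTF-8 with a header row; trees are Newick; stage outputs
  are written atomically (temp file + rename).
* Ties: equal-bit-score best hits resolve to the smallest target id;
  family ids are assigned by the smallest member gene id; the DP prefers
  diagonal moves over gaps on score ties.

## Known limitations

* Bit scores differ in scale between the two engines; matrices from
  different engines must not be mixed.
* The RBH-plus-threshold clustering is a deterministic stand-in for
  heavier pan-genome pipelines; on deeply diverged or highly paralogous
  inputs its families will differ from theirs.
* Per-pair E-values (sw engine) are database-size independent by design;
  phmmer E-values scale with the pooled target set. The shared 10⁻⁵
  threshold therefore selects slightly different hit sets per engine.
* p-distance NJ is a topology-recovery tool here; branch lengths are not
  corrected for multiple hits and underestimate deep divergences.
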