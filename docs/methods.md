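# Methods

`plastevo` re-implements, as a tested library, the comparative analyses
commonly applied to plastid genomes (plastomes): quadripartite structure
characterization, a codon-usage-bias battery, microsatellite mining,
pairwise Ka/Ks selection analysis, gene-order synteny, and a distance
phylogeny — all exercisable on synthetic plastomes with known ground
truth. This note records the models, conventions and numerical choices.

## Coordinates and genetic code

All internal coordinates are 0-based half-open; GenBank I/O converts
to/from the 1-based inclusive convention at the boundary. Translation
uses the bacterial/plastid code (NCBI table 11) throughout; its sense
codons are identical to the standard code, so the familiar synonymous
family structure (nine 2-fold, one 3-fold, five 4-fold, three 6-fold
families, plus single-codon Met and Trp) applies.

## Quadripartite structure detection

A plastome is a circle partitioned as LSC + IRb + SSC + IRa, with IRa the
exact reverse complement of IRb. The detector finds the maximal pair of
exact reverse-complement repeats directly from the sequence (k-mer
seeding, k = min(31, min_ir), followed by greedy exact extension on the
circle; seed pairs are grouped by the extension-invariant anti-diagonal
so each physical repeat is extended once). The two single-copy gaps are
labeled LSC (longer) and SSC (shorter), and regions are reported in the
orientation LSC→IRb→SSC→IRa. Exact matching makes the detector
deterministic and orientation-invariant (rotations and reverse
complements of the input yield identical region lengths); annotation-
based junction curation, as used for real accessions, is out of scope.
`min_ir` defaults to 1,000 bp — long enough to skip dispersed repeats,
far below any true plastid IR. Ties between non-equivalent maximal pairs
raise an explicit error listing candidates.

## CDS curation

CDSs are spliced in transcription order and strand-corrected. A gene is
retained only if its length is a multiple of three and it contains no
internal stop codon; failures are reported with a reason, never silently
fixed. IR-duplicated gene names keep the copy with the lower start
coordinate, so downstream comparisons are effectively single-copy.

## Codon-usage battery

Statistics use the 59-codon informative set (61 sense codons minus ATG
and TGG); stop codons are tallied apart and excluded everywhere.

* **RSCU** for codon *j* of a family with *n* synonymous codons and
  family total *X*: RSCU = x_j · n / X. Unobserved families are omitted;
  within any observed family the mean RSCU is 1 by construction.
* **ENC** is Wright's estimator. Within-family homozygosity uses the
  unbiased form F̂ = (nΣp̂² − 1)/(n − 1) (a raw Σp̂² switch exists);
  families with n < 2 or F̂ ≤ 0 are dropped from their family-size
  average; a missing 3-fold class (Ile unobserved) is imputed as the
  mean of the 2- and 4-fold averages; otherwise ENC is undefined and
  flagged rather than raised. ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,
  capped at 61. The expected value under a purely GC3-driven mutation
  model is ENC* = 2 + s + 29/(s² + (1−s)²) with s = GC3s.
* **Positional GC**: GC1/GC2/GC3 run over all non-stop codons (so a
  Met-only gene has GC3 = 1, its codons ending in G); GC3s is restricted
  to the informative set and is flagged undefined when that set is
  empty. GC12 = (GC1 + GC2)/2.
* **PR2**: A3/(A3+T3) vs G3/(G3+C3) over third positions of the
  informative codons by default; a fourfold-family restriction is
  available behind a switch because the original parity literature
  sometimes uses it. Zero denominators flag the coordinate.
* **Neutrality regression**: unweighted OLS of GC12 on GC3 across a
  species' genes (no gene-length weighting). Slope near 1 indicates
  mutation-dominated codon usage, near 0 selection-dominated; zero GC3
  variance flags the slope undefined.

Per-species statistics are unweighted means over retained genes.

## Correspondence analysis

Classical CA of the per-gene × 59-codon RSCU table (an optional switch
accepts raw counts): P = X/total, standardized residuals
S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD of S, principal coordinates =
mass-rescaled singular vectors × singular values. Total inertia equals
the table's chi-square statistic divided by its grand total (asserted to
1e-10). Axes are sign-fixed by making the largest-magnitude column
loading positive, so coordinates are deterministic. Genes with
unobserved families are completed with zeros (logged); all-zero rows and
columns are pruned. CA is run per species over that species' genes.

## SSR mining

Perfect tandem repeats of primitive units 1–10 bp, with minimum copy
numbers 10 (mono), 6 (di), 5 (tri/tetra) and 3 (penta–deca). For each
unit length u the boolean match array seq[x] == seq[x+u] is run-length
scanned; a maximal run is reported once, at its primitive unit and
leftmost phase, with whole copies only (the interval is exactly
unit × copies). Sequences are scanned linearly; a repeat spanning the
circular origin is not joined. Canonical motifs are minimal rotations
without reverse-complement collapsing, so A- and T-homopolymers remain
distinct categories, matching how plastome SSR tables are reported.
Genomic context is assigned by the locus start position with priority
CDS exon > intron > intergenic spacer; tRNA/rRNA bodies count as IGS
because the three-way scheme has no structural-RNA class. Loci falling
in both IR copies are counted once per copy (a dedupe switch exists).
Species are clustered on the motif presence/absence matrix with Jaccard
distance and average linkage, species processed in name order for
deterministic ties, and exported as an ultrametric Newick dendrogram.

## Ka/Ks (Nei–Gojobori counting)

Orthologs are paired by gene name across all unordered species pairs.
Each pair is aligned globally at the protein level (match +1, mismatch
−1, a gap of length g costs 5 + g; Gotoh three-state dynamic programming
with deterministic traceback preferring diagonal > up > left),
back-translated, and gap columns removed entirely. Counting follows the
NG86 conventions: per-codon synonymous site fraction = Σ over positions
of (synonymous one-step changes)/3, with changes into stop codons never
synonymous — hence S + N = 3L exactly — and sites averaged between the
two sequences; observed differences are averaged over all mutational
pathways that avoid stop-codon intermediates (pathways through stops are
excluded; if every pathway is illegal the codon pair's differences are
skipped and logged). Proportions are Jukes–Cantor corrected,
d = −(3/4)ln(1 − 4p/3), undefined at p ≥ 3/4. dS = 0 with dN > 0 is
reported as infinite/undefined and excluded from summaries. Pairs are
classed as strong purifying (ratio < 0.5), relaxed purifying (0.5–1) or
positive (> 1); ratios > 10 are removed as outliers before statistics.
Category statistics: one-sample t-tests of each functional category's
ratios against 1 (Bonferroni over categories), all pairwise Wilcoxon
rank-sum tests (Bonferroni over category pairs) with pooled-SD Cohen's
d signed first-minus-second in report order, and per-category Pearson
r(Ka, Ks). Categories with fewer than two pairs are flagged and skipped.

## Synteny

Collinearity is computed from shared annotated gene order (case-
insensitive names, IR duplicates collapsed to the lower-start copy), not
from BLAST alignments: b's order forms a signed permutation relative to
a's; maximal runs in which consecutive ranks are adjacent with
consistent orientation are the synteny blocks, and breakpoints are the
unpreserved adjacencies. An identity yields one block and zero
breakpoints; a single internal inversion yields three blocks and two
breakpoints.

## Phylogeny

Per-gene codon alignments are concatenated in lexicographic gene order
with gap padding for missing species and a per-gene column-occupancy
filter (default: drop columns under 50% occupancy). Distances are
Jukes–Cantor with pairwise deletion; p ≥ 3/4 flags the entry. Trees come
from Saitou–Nei neighbor joining with lowest-index tie-breaking and
negative branch lengths clamped to zero (deficit logged); on additive
matrices the generating tree is recovered exactly. This distance
pipeline is a deliberate self-contained stand-in for external
maximum-likelihood inference: ML branch-length figures from real studies
are treated as non-reproducible anchors, while topology-level behavior
is fully testable on synthetic data. Branch-rate summaries report
per-genus means and SDs of terminal branch lengths (terminal-branch
semantics chosen over root-to-tip sums and documented as such).

## Synthetic data

The generator emulates the statistical structure of epidendroid
plastomes; its defaults are the study conditions. Region lengths default
to 85,994 (LSC), 608 (SSC) and 37,024 bp (IR) — a strongly
SSC-contracted 160,650 bp genome; intergenic filler is drawn at 63% AT;
coding sequence targets GC3 ≈ 0.28 (within-family third-position
weighting, deflated to compensate for Met/Trp always ending in G). Gene
counts per region (20 LSC, 6 IR, 0 SSC by default; fewer at desk scale
in tests) are layout choices, not biological claims. Planted SSRs are
written with flanking bases that break the repeat on both sides, so the
detector must recover their coordinates exactly; IR-planted elements
appear reverse-complemented in the mirrored copy with recorded
coordinates. Two junction-adjacent bases per single-copy region are
fixed so the IR palindrome cannot extend across region boundaries.

Ortholog divergence uses codon-wise rejection sampling: proposals at a
Poisson rate proportional to branch length, stop-creating proposals
rejected, synonymous proposals always accepted, nonsynonymous accepted
with probability ω. This is an approximation to a full codon
substitution model (no rate matrix, no indels, terminal stop held
fixed); it is sufficient because only rank-order and approximate
recovery of ω are asserted (mean NG86 estimate within ±0.05 of ω = 0.2
at 200 pairs of 300-codon genes diverged 0.04 per branch — the slight
downward bias comes from stop-adjacent proposals being rejected while
NG86 still counts those sites as nonsynonymous). Clade simulation evolves
genes along a user tree, adds independent filler substitutions at the
root-to-leaf rate (planted SSRs, their flanks and junction bases held
fixed), and re-mirrors IRb from IRa per leaf, so every leaf keeps an
exact quadripartite structure.

What the generator does not emulate: indel evolution, IR boundary
shifts over time, compound/imperfect repeats, rate heterogeneity across
sites, annotation errors. Passing tests therefore demonstrate estimator
correctness under the stated generative conditions, not robustness to
real-data artifacts such as misannotation or alignment ambiguity.

## Problem sizes in the default suite

The test suite runs on desk-scale genomes (≈6–13 kb, 4–8 genes) for
speed, one full-size genome (160,650 bp) for the structural checks, 100
random 5 kb sequences for the SSR oracle equivalence, 100 random 5-leaf
additive matrices for NJ recovery, and 200 simulated ortholog pairs for
ω recovery. These sizes were chosen so each property is exercised well
past its degenerate regime while the whole suite stays interactive.

## Known limitations

* IR detection requires exact repeat identity; a single polymorphism
  between IR copies truncates the detected repeat at that position.
* The NJ/JC stage is not a substitute for ML inference on real data;
  branch lengths are JC distances, not model-based estimates.
* NG86 saturates near p = 3/4; deeply diverged pairs are flagged rather
  than estimated.
* The SSR scanner is linear; a repeat spanning the circular origin is
  reported as up to two loci.
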