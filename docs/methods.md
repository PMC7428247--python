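# Methods

This note records the models, parameter choices and numerical decisions
behind `beemir`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates, alphabets, formats

All genomic intervals are 0-based half-open (BED convention); GFF3's
1-based closed coordinates are converted at the boundary, so a GFF gene of
length L always satisfies `end − start = L` internally. Genomes are stored
as DNA (T), miRNA sequences as RNA (U); every cross-alphabet comparison
goes through an explicit normalization helper. Repeat annotations arrive
as BED6; a name whose prefix matches a configurable transposable-element
class list (LINE, SINE, LTR, DNA, …) is a `transposable_element`,
anything else `uncharacterized_repeat` — repeat libraries in the wild mix
heterogeneous labels, and the strand column is taken at face value.
Introns are not read from annotation but derived as gaps between
consecutive exons of one gene; an exon leaking outside its gene span is
clipped with a warning, an exon without a resolvable parent is a hard
error, and an unstranded gene is treated as "+" with a warning.

## Discovery filters

Reads shorter than 18 nt or containing non-ACGT/U characters are dropped;
counts are preserved. Mapping is exact-match on both strands — synthetic
reads are error-free, and exactness makes support counts deterministic; a
mismatch budget would belong in the mapper, not here. Arm support counts
a read for the mature (or star) arm when its mapped interval matches the
arm within a ±2-nt slop, the usual tolerance for read stacks around
Drosha/Dicer cut sites. The retention rule is: no contaminant similarity,
≥ 5 reads on *each* arm, and a structure-test p strictly below 0.05.

The contaminant screen declares a hit when a local alignment against any
rRNA/tRNA sequence reaches ≥ 80 % identity over ≥ 20 columns (either
orientation). No published threshold exists for this step; both numbers
are exposed as arguments. Alignments are seeded by shared exact 11-mers
before Smith–Waterman confirmation, a BLAST-style heuristic that is
essentially lossless at these identity levels.

### Folding engine and the permutation structure test

The folding engine is a weighted Nussinov maximum-pairing algorithm:
pair weights GC = 3, AU = 2, GU = 1, hairpin loops of at least 3 nt,
`energy_score = −(total pair weight)`. This is deliberately *not* a
thermodynamic nearest-neighbour model: the structure test only needs a
consistent stability ordering between a sequence and its shuffles, and a
transparent integer model is easy to verify against exhaustive
enumeration (which the tests do for every sequence up to 12 nt). The
traceback prefers closing the outer pair, then end-unpairing, then the
leftmost bifurcation, making reported pairings deterministic. For the
permutation test the energy recursion is batched: one slab per interval
span, vectorized over shuffles and interval starts, so a 999-shuffle test
on a 60-nt precursor costs milliseconds.

Shuffles preserve the exact dinucleotide count vector via the
Altschul–Erickson Eulerian-path construction (random last-edge tree
toward the final character, then permuted out-edge lists). The p-value is
the add-one permutation form, with ties between the native energy and
shuffle energies split uniformly at random:
`p = (1 + #{null < observed} + U)/(n + 1)`, `U ~ uniform{0..#ties}`.
With an integer-valued energy, ties are common; counting them all (the
naive `≤` rule) makes the p-value conservatively super-uniform, while the
randomized split keeps it exactly uniform under the null — which the
calibration tests verify by KS test — at the cost of making borderline
decisions depend on the supplied RNG. p is never 0 and never exceeds 1.

## Homology classification

The seed is mature positions 2–8 (a 7-mer), the common miRBase-style
convention; the span is configurable (2–7 for the hexamer reading). Seed
matching is exact string identity — the strictest reading of seed
homology; a 1-mismatch tolerance would only merge groups and can be
emulated upstream. Tier priority is seed_match > premir_homolog > unique,
and lineage specificity requires single-species expression *and* no seed
match: genomic similarity of a hairpin elsewhere is not evidence that a
mature miRNA is transcribed there.

The precursor genome search is Smith–Waterman (Gotoh affine gaps) with
blastn-like scores +2/−3, gap open −5, extend −2, seeded by exact 11-mers
at stride 2 located through a sorted hash index of both genome strands,
with a two-hit-per-diagonal rule to suppress the random single-word
background. Significance uses the ungapped Karlin–Altschul E-value
applied to the gapped score, the same approximation blastn makes with
fitted parameters. λ is solved by bisection on
`Σ pᵢpⱼ exp(λ sᵢⱼ) = 1` to 10⁻¹² (valid only when the expected pair score
is negative and the maximum positive). K has no closed form; it is
estimated once per scoring scheme from the excursion statistics of the
induced one-dimensional score random walk — the expected number of
maximal segments scoring ≥ x per unit length is `K·e^{−λx}`, so counting
excursion peaks in a long simulated walk (fixed internal seed; 2·10⁶
steps) and inverting at several x gives a deterministic estimate. For
+1/−1 uniform DNA this yields K ≈ 0.35 against the published ≈ 0.33;
E-value decisions at the 10⁻⁵ cutoff are insensitive to error at this
scale, as the random-genome calibration test confirms. Hit filters:
identity ≥ 50 % over the aligned columns AND E ≤ 10⁻⁵, search space
`m × 2·(genome length)`.

## Localization

Intersection is a sorted two-list sweep per chromosome, verified
identical to the all-pairs brute force on random fixtures. Any ≥ 1 bp
overlap counts. A precursor contributes one count to every distinct
(category, strand-relation) cell it touches; exon and intron of the same
gene both count (the categories are feature-wise, not exclusive), loci
overlapping genes on both strands are counted in both strand columns and
reported as double-counted, and `intergenic` means no gene overlap on
either strand (so it can have no opposite-strand column). "Intragenic"
for the χ² association with lineage specificity means any gene overlap on
either strand. The 2×2 χ² applies the Yates continuity correction by
default — matching R's `chisq.test` on 2×2 tables, the likely reference
behaviour for analyses of this kind — and falls back to Fisher's exact
test when an expected cell drops below 1.

## Target prediction

The 3′-UTR proxy is the 500 bp immediately downstream of the gene model
(about the average fly 3′ UTR), reverse-complemented for minus-strand
genes, clipped at chromosome ends but *not* at neighbouring genes —
flanking-region extraction conventionally ignores gene adjacency, and the
synthetic generator keeps planted features from colliding anyway.

A candidate site requires the exact Watson–Crick reverse complement of
the full 7-nt seed (no G:U in the seed — the "strict" criterion). From
the anchor, a banded DP extends the duplex outward (pairs, 1×1
mismatches, single-nt bulges, at most 3 bulges per side, no two
consecutive bulges), maximizing the alignment score with ties broken
toward lower energy; score and energy are then read off the same optimal
pairing:

* score: +5 per WC pair, ×3 inside the seed, +1 per G:U, −3 per mismatch,
  −9 per bulge; threshold ≥ 140.
* energy: −3 GC, −2 AU, −1 GU, +3 per interior-loop/bulge opening;
  threshold ≤ −20.

The seed-scale factor exists because an unscaled +5-per-pair model cannot
reach 140 with an 18–26-nt miRNA (26 × 5 = 130): the miRanda-style score
this emulates weights seed-region columns by a scale factor (4.0 in the
original). The value 3 keeps both thresholds meaningful — a seed-only
site scores 105 and fails, a perfect 22-mer duplex scores 180 and passes,
and the boundary sits at roughly seven well-paired columns beyond the
seed. All constants are module-level and overridable.

The site p-value replaces an extreme-value fit with a permutation null,
same α = 0.01: for each miRNA, the null energy distribution is built by
implanting the seed complement at a random position of a
dinucleotide-shuffled window drawn from the UTR pool (the window spans
the maximal duplex reach, so local composition is preserved) and scoring
the duplex there; the observed site's energy is ranked with the same
randomized-tie add-one rule as the fold test. The null is built once per
miRNA and reused across its sites. A site is retained iff it passes both
score models *and* p < 0.01 — the ambiguity of whether the p cutoff
applied to one or both upstream programs is resolved by applying it once
to the single consensus site. Gene-level pairs deduplicate multiple sites.

## Gene age and enrichment

Since every species maps to exactly one most-specific clade, the ladder
rule ("oldest clade with a member not in the next lower clade") reduces
to: the age of an orthogroup is the oldest most-specific clade among its
members, with Vertebrata outside the nested chain (any vertebrate member
⇒ Vertebrata). Genes without orthogroups are Unique; an orthogroup
containing only the focal species is labelled Apoidea by default
(a flag flips this to Unique).

Enrichment: `x = |list1 ∩ list2|`, `E = nD/N`, `RF = x/E`; over- and
under-tails from the hypergeometric distribution evaluated in log space,
both including the point mass at x (so `p_over + p_under ≥ 1`). BH
adjustment is the step-up `min_{j≥i} p_(j)·m/j`, applied within each
named battery. The expression comparison is a Welch t-test on
log2(RPM+1) — raw small-RNA abundances are heavy-tailed and group
variances differ strongly (lineage-specific miRNAs are few and
low-expressed); a raw-scale option remains. Two-sided by default, with a
one-sided "lower" alternative exposed. Reciprocal-best-hit matching uses
the in-package aligner with a sharper +3/−2 identity scoring in lieu of a
substitution matrix, both directions requiring E ≤ 10⁻⁵.

## Phylogenetic scan

Independent contrasts follow the standard recursion: post-order,
contrast `(x₁ − x₂)/√(v₁ + v₂)`, ancestral value the variance-weighted
mean, parent branch lengthened by `v₁v₂/(v₁+v₂)`. Children are ordered by
their lexicographically smallest descendant leaf label, so contrasts of
two traits computed on the same tree pair up with consistent signs and
the scan is invariant to how the newick happens to order children.
Sociality enters as a numeric ordinal 0–3 (solitary → facultative basic →
obligate basic → obligate complex eusocial); contrasting an ordinal as if
continuous is a recognized approximation, inherited knowingly. Spearman's
rho uses average ranks; its p-value is exact (all n! permutations) for
n ≤ 9 contrasts and the t-approximation above. Accessions with zero
copy-number variance are skipped with a reason — in real scans roughly
half of known miRNAs have identical copy number in every genome — and BH
runs across the tested accessions. Zero-length branches are replaced by
1e−8 on read so contrast variances stay positive; polytomies are rejected
unless explicitly resolved (zero-length splits).

## The synthetic world

Defaults: 6 species, 500 kb single-chromosome genomes, 400 genes
(exon–intron–exon, laid out on fixed slots so every gene keeps a full
500-bp downstream flank), 60 shared miRNA families, 30 lineage-specific
miRNAs per species, lineage-specific mean expression 0.25× shared,
planted target RF 1.8, gene-age distribution 40 % Vertebrata / 20 %
Unique / the rest spread along the ladder.

* Shared families carry one identical seed in every carrier (half of
  families in all species, the rest in random subsets of ≥ 2); a fifth of
  family seeds are drawn from the packaged known-miRNA list (itself a
  synthetic stand-in shipped with the package) so the known-seed path is
  exercised. Non-seed positions drift by up to two substitutions per
  species.
* Lineage-specific miRNAs get world-unique seeds (checked against shared,
  known and each other). Half are "unique"; the other half get a diverged
  (8 % per-site) unexpressed precursor copy planted in another genome.
* Precursors are mature + 16-nt loop + a 3-mutation reverse-complement
  star arm (60 nt total, a strong but imperfect hairpin), placed
  intergenic/intron/exon/repeat at 0.45/0.35/0.05/0.15. Intergenic
  placements avoid downstream-flank zones: the star arm is a near-perfect
  target site for its own miRNA, and letting hairpins fall inside UTR
  proxies would plant unintended targets.
* Counts are negative binomial (dispersion 0.3 — overdispersion is the
  norm for small-RNA libraries and stresses the t-test) around
  lognormal-jittered means (shared ≈ 300 reads); star counts are binomial
  thinnings (p = 0.2) of mature counts, so the ≥ 5-read star filter fails
  realistically for weakly expressed miRNAs (roughly 5–10 % of
  lineage-specific ones). Junk reads (short, N-containing, unmappable)
  exercise QC. Two contaminant-derived decoy hairpins per species
  exercise the screen.
* Target sites are full-length reverse complements of the mature
  sequence, written into downstream flanks of genes chosen so each
  planted target gene is Unique-aged with probability `RF·D/N` — the
  construction that makes the expected overlap satisfy `x/E = RF`. All
  planted genes are distinct; the realized RF (recomputed from the sites
  actually written) is recorded in the truth manifest, and recovery is
  judged against that realized value, not the nominal 1.8.
* The orthogroup table pairs each non-Unique gene with an external
  clade representative (a fixed eight-species roster), closing the loop
  so the age module reconstructs exactly the planted age labels. The
  copy-number matrix has one planted monotone family (copies =
  1 + sociality level), half constant rows, and random rest.

Everything is deterministic given `rng_seed`: the same seed produces
byte-identical bundles.

**What passing these tests does and does not show.** The generator omits
sequencing error, adapter remnants, paralogous read multi-mapping,
isochore-scale composition structure, overlapping/nested genes, annotated
3′ UTRs and arm-switching. Recovery near 1.0 therefore demonstrates the
*logic* of the pipeline — filters, tier assignment, interval conventions,
enrichment arithmetic — under clean conditions, not robustness to the
noise sources of real libraries. Conversely the planted difficulty is
real: support-filter failures, diverged precursor copies, decoys and
chance seed matches all occur.

## Recovery scoring

Classification sensitivity/specificity are computed over planted miRNAs
that survive the discovery filters: a miRNA rejected for insufficient
star reads never reaches the classifier, and counting it against
classification would conflate two stages (the thinning decision above
*guarantees* some such rejections). The overall filter pass rate is
reported alongside so nothing is hidden. Target-site recovery likewise
conditions on the owning miRNA having been retained. RF recovery compares
the species-mean estimated RF with the species-mean realized planted RF.

## Problem sizes and runtime choices

The pipeline defaults to 99 fold-test shuffles (resolution 0.01 against
the 0.05 cutoff) and 149 target-null permutations (resolution ~0.0067
against 0.01); the dedicated calibration experiments probe the
permutation machinery at their own sizes. The recovery experiments use
20 default worlds in the test suite and 8 in the acceptance script; a
world runs end to end in ~15 s on one CPU. The type-I calibration of the
enrichment test uses a 4000-gene universe: the exact hypergeometric tail
is discrete, and at a 400-gene universe with typical list sizes the
largest attainable level below 0.05 is ≈ 0.028 — any exact test is
conservative there — so nominal-level calibration is checked where the
lattice is fine enough to attain it, and the small-universe rate is
checked for validity (never anticonservative).

## Known limitations

* The folding and duplex energy models are ordinal stand-ins, not
  thermodynamics; absolute energies are unitless and comparable only
  within a model.
* The ungapped Karlin–Altschul formula applied to gapped scores slightly
  misstates E-values, in the same direction for all queries; thresholds
  are calibrated empirically by the random-genome tests.
* Randomized tie-breaking makes permutation p-values for borderline
  candidates RNG-dependent; at the retention thresholds used here this
  affects only candidates whose energy ties the null lattice exactly.
* The Eulerian-path shuffle samples paths approximately uniformly (random
  arborescence via walk last-exit edges); exchangeability of the
  calibration construction does not depend on exact uniformity.
* Exact Spearman p-values are enumerated only to n = 9; above that the
  t-approximation is inherited from the reference statistical stack.
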