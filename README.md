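# beemir

Comparative analysis of brain-expressed microRNAs across bee species.

Eusociality evolved repeatedly in bees, and lineage-specific gene
regulation is a candidate driver. This package implements the
computational core of a comparative brain-miRNA study across species with
contrasting social organization: which expressed miRNAs are shared between
species, which are lineage specific, where their precursors sit in the
genome, which mRNAs they are predicted to repress, how old those target
genes are, and whether miRNA copy number tracks sociality once phylogeny
is accounted for.

Because the raw inputs of such a study (genome assemblies, small-RNA
libraries, orthology databases) are large and external, the package ships
a first-class synthetic-data generator: multi-species "worlds" with
planted homology structure, expression effects, genomic context and
target-age enrichment, so every stage can be scored against known truth.

## What it computes

* **Discovery filters** — read QC (length ≥ 18, standard bases only),
  exact-match read mapping, mature/star arm support counting (≥ 5 reads
  each), an rRNA/tRNA contaminant screen, and a secondary-structure
  permutation test: the precursor's weighted-Nussinov folding energy is
  ranked against dinucleotide-preserving (Altschul–Erickson) shuffles,
  retaining candidates with p < 0.05.
* **Homology tiers** — miRNAs grouped by identical 7-nt seed (mature
  positions 2–8). A seed shared with another species or a known insect
  miRNA ⇒ *seed match*; otherwise a Smith–Waterman search of the other
  genomes for the precursor (identity ≥ 50 %, Karlin–Altschul E ≤ 10⁻⁵,
  `E = K·m·n·e^{−λS}`) ⇒ *pre-miR homolog*; else *unique*. A miRNA is
  **lineage specific** when expressed in one species with no seed match.
* **Localization** — strand-aware interval intersection of precursor loci
  with exons, introns, transposable elements and uncharacterized repeats,
  with deliberate double counting of loci overlapping genes on both
  strands, plus a Yates-corrected χ² of intragenic localization vs
  lineage specificity.
* **Target prediction** — on 500-bp downstream flanks (3′-UTR proxies),
  strict Watson–Crick seed sites extended by a banded duplex DP and scored
  under two linear models; retained iff alignment score ≥ 140 AND duplex
  energy ≤ −20 AND permutation p < 0.01 against shuffled-UTR nulls.
* **Gene age** — orthogroup taxonomic breadth over the clade ladder
  Vertebrata → Metazoa → Arthropoda → Insecta → Holometabola →
  Hymenoptera → Aculeata → Apoidea; genes without orthologues are
  *Unique*.
* **Enrichment statistics** — hypergeometric over/under-enrichment with
  representation factors `RF = x/E`, `E = nD/N`; Benjamini–Hochberg
  correction; Welch t-tests of log2(RPM+1) expression; reciprocal-best-hit
  orthologue matching.
* **Phylogenetic scan** — Felsenstein's independent contrasts of miRNA
  copy number and ordinal sociality, Spearman-correlated per accession
  with BH correction.

## Worked example

```python
import numpy as np
from beemir import WorldConfig, generate_world, run_pipeline, score_against_truth

world = generate_world(WorldConfig(rng_seed=1))      # six species, planted truth
result = run_pipeline(world, rng=np.random.default_rng(2))
report = score_against_truth(world, result)
```

`result.summary` for this seed prints:

```
 species  expressed_mirs  seed_match  premir_homolog  unique  lineage_specific     rf  rf_p_over  ttest_p
species1              71          45              11      15                26 1.8635     0.0001      0.0
species2              81          54              13      14                27 1.4555     0.0092      0.0
species3              73          46              14      13                27 1.6675     0.0013      0.0
species4              74          47              12      15                27 1.2995     0.0981      0.0
species5              76          49              13      14                27 1.4930     0.0144      0.0
species6              73          46              15      12                27 2.0793     0.0000      0.0
```

Each row is one species: how many miRNA candidates survived the discovery
filters, their homology-tier split, and the downstream statistics — `rf`
is the representation factor of *Unique*-aged genes among the predicted
targets of that species' lineage-specific miRNAs (the generator planted
RF ≈ 1.8), `rf_p_over` its hypergeometric over-enrichment p-value, and
`ttest_p` the Welch p-value showing lineage-specific miRNAs are expressed
significantly lower than shared ones. Scoring against the truth manifest
gives

```
sensitivity=1.000 specificity=0.997 rf_estimated=1.64 rf_planted=1.74
```

— essentially every planted lineage-specific miRNA that survives the
support/structure filters is called lineage specific, almost no shared
miRNA is mislabelled, and the estimated enrichment tracks the planted
(realized) value.

The same flow is available from a shell:

```bash
beemir simulate --out world/ --seed 1        # write the input bundle + truth.json
beemir filter --reads world/species1/reads.fa --genome world/species1/genome.fa \
      --hairpins world/species1/hairpins.tsv --contaminants world/contaminants.fa \
      --out candidates.tsv
beemir run --seed 1                          # full pipeline + recovery report
```

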