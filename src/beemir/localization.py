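"""Strand-aware assignment of hairpin loci to genomic context categories.

A precursor is *intergenic* when it overlaps no gene feature on either
strand; otherwise it contributes one count to every distinct
(category, strand-relation) it overlaps — exon, intron, transposable
element, uncharacterized repeat — so a locus straddling an exon on the
sense strand and a different gene's intron on the antisense strand is
counted in both cells (double counting is deliberate and reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy import stats

from .discovery import PreMiR
from .homology import HomologyCall
from .io_formats import GenomicFeature

logger = logging.getLogger("beemir")

CATEGORIES = (
    "intergenic", "exon", "intron", "transposable_element", "uncharacterized_repeat",
)
GENIC_KINDS = {"exon", "intron"}


@dataclass
class LocalizationSummary:
    #: category -> (same_strand_count, opposite_strand_count)
    counts: dict[str, tuple[int, int]]
    n_double_counted: int
    sense_fraction_genic: float
    #: pre-miR id -> True if it overlaps any gene feature on either strand
    intragenic: dict[str, bool] = field(default_factory=dict)


def intersect_features(
    premirs: list[PreMiR], features: list[GenomicFeature]
) -> dict[str, list[tuple[GenomicFeature, bool, int]]]:
    """All >= 1 bp overlaps between precursor loci and annotation features.

    Sorted two-list sweep per chromosome; returns pre-miR id ->
    [(feature, same_strand, overlap_bp)].  Results are identical to the
    all-pairs brute force and independent of input order.
    """
    by_chrom_p: dict[str, list[PreMiR]] = {}
    by_chrom_f: dict[str, list[GenomicFeature]] = {}
    for p in premirs:
        by_chrom_p.setdefault(p.chrom, []).append(p)
    for f in features:
        by_chrom_f.setdefault(f.chrom, []).append(f)
    out: dict[str, list[tuple[GenomicFeature, bool, int]]] = {p.id: [] for p in premirs}
    for chrom, plist in by_chrom_p.items():
        flist = sorted(by_chrom_f.get(chrom, []), key=lambda f: (f.start, f.end))
        plist = sorted(plist, key=lambda p: (p.start, p.end))
        if not flist:
            continue
        active: list[GenomicFeature] = []
        fi = 0
        for p in plist:
            while fi < len(flist) and flist[fi].start < p.end:
                active.append(flist[fi])
                fi += 1
            active = [f for f in active if f.end > p.start]
            for f in active:
                overlap = min(p.end, f.end) - max(p.start, f.start)
                if overlap >= 1:
                    out[p.id].append((f, f.strand == p.strand, overlap))
    for p in premirs:
        out[p.id].sort(key=lambda t: (t[0].start, t[0].end, t[0].kind, t[0].gene_id))
    return out


def summarize_localization(
    premirs: list[PreMiR], features: list[GenomicFeature]
) -> LocalizationSummary:
    """Category x strand-relation counts with the double-counting convention.

    Gene features (gene/exon/intron rows) decide genic vs intergenic;
    repeats are counted independently of genic status.  The sense fraction
    is same-strand genic assignments over all genic assignments.
    """
    overlaps = intersect_features(premirs, features)
    counts = {cat: [0, 0] for cat in CATEGORIES}
    n_double = 0
    sense = antisense = 0
    intragenic: dict[str, bool] = {}
    for p in premirs:
        cells: set[tuple[str, bool]] = set()
        gene_strands: set[bool] = set()
        for feat, same_strand, _bp in overlaps[p.id]:
            if feat.kind == "gene":
                gene_strands.add(same_strand)
                continue  # the gene row itself is not a category; exons/introns are
            cells.add((feat.kind, same_strand))
            if feat.kind in GENIC_KINDS:
                gene_strands.add(same_strand)
        intragenic[p.id] = bool(gene_strands)
        if not gene_strands:
            counts["intergenic"][0] += 1
        if len(gene_strands) == 2:
            n_double += 1
        for kind, same_strand in cells:
            counts[kind][0 if same_strand else 1] += 1
            if kind in GENIC_KINDS:
                if same_strand:
                    sense += 1
                else:
                    antisense += 1
    total_genic = sense + antisense
    return LocalizationSummary(
        counts={cat: (c[0], c[1]) for cat, c in counts.items()},
        n_double_counted=n_double,
        sense_fraction_genic=sense / total_genic if total_genic else float("nan"),
        intragenic=intragenic,
    )


def intra_inter_chi2(
    calls: list[HomologyCall],
    intragenic: dict[str, bool],
    yates: bool = True,
) -> tuple[float, float]:
    """2x2 test: lineage-specific vs homologous x intragenic vs intergenic.

    Yates-corrected chi-squared by default (matching R's ``chisq.test``
    behaviour on 2x2 tables); when any expected cell is below 1 the test
    falls back to Fisher's exact test with a warning and returns
    (nan, fisher_p).
    """
    table = [[0, 0], [0, 0]]
    for call in calls:
        if call.mirna_id not in intragenic:
            continue
        row = 0 if call.lineage_specific else 1
        col = 0 if intragenic[call.mirna_id] else 1
        table[row][col] += 1
    total = sum(map(sum, table))
    if total == 0:
        raise ValueError("no miRNAs with both homology call and localization")
    row_sums = [sum(r) for r in table]
    col_sums = [table[0][c] + table[1][c] for c in (0, 1)]
    expected = [[row_sums[r] * col_sums[c] / total for c in (0, 1)] for r in (0, 1)]
    if min(min(r) for r in expected) < 1:
        logger.warning("expected cell < 1; reporting Fisher exact test")
        _odds, p = stats.fisher_exact(table)
        return float("nan"), float(p)
    chi2, p, _dof, _exp = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)
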