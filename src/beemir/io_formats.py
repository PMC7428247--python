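"""Readers and writers for the file formats the pipeline touches.

All genomic intervals are 0-based half-open (BED convention) internally;
GFF3's 1-based closed coordinates are converted at the boundary.  Genome
sequences are stored as DNA (T), miRNA sequences as RNA (U); comparisons
always go through :func:`to_dna` / :func:`to_rna`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("beemir")

DNA_ALPHABET = set("ACGTN")
RNA_ALPHABET = set("ACGUN")

#: repeat name prefixes treated as transposable elements when reading BED6
#: repeat annotations (RepeatMasker-style class labels); everything else is
#: filed as uncharacterized repetitive DNA, mirroring the two repeat columns
#: of the localization summary.
DEFAULT_TE_CLASSES = (
    "DNA", "LINE", "SINE", "LTR", "RC", "Helitron", "Mariner", "Gypsy",
    "Copia", "Penelope", "TE",
)

#: branch length substituted for zero-length internal branches so that
#: independent contrasts remain defined.
ZERO_BRANCH_EPSILON = 1e-8


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def to_dna(seq: str) -> str:
    """Uppercase and U->T normalize."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and T->U normalize."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA)."""
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

FEATURE_KINDS = {
    "gene", "exon", "intron", "transposable_element", "uncharacterized_repeat",
}


@dataclass(frozen=True)
class GenomicFeature:
    """An interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind in {"exon", "intron"} and not self.gene_id:
            raise ValueError(f"{self.kind} feature requires a gene_id")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeBundle:
    """One species' genome with gene and repeat annotations."""

    species_id: str
    chrom_sequences: dict[str, str]
    genes: list[GenomicFeature] = field(default_factory=list)
    repeats: list[GenomicFeature] = field(default_factory=list)

    def validate(self) -> None:
        for chrom, seq in self.chrom_sequences.items():
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(f"{chrom}: non-DNA characters {sorted(bad)}")
        for feat in list(self.genes) + list(self.repeats):
            if feat.chrom not in self.chrom_sequences:
                raise ValueError(f"feature chrom {feat.chrom!r} not in genome")
            if feat.end > len(self.chrom_sequences[feat.chrom]):
                raise ValueError(
                    f"feature [{feat.start},{feat.end}) exceeds {feat.chrom} bounds"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chrom_sequences.values())


@dataclass
class ReadSet:
    """Collapsed small-RNA reads: unique sequence with its read count."""

    species_id: str
    reads: list[tuple[str, int]]

    def validate(self) -> None:
        for seq, count in self.reads:
            if not seq:
                raise ValueError("empty read sequence")
            if count < 1:
                raise ValueError(f"read count {count} < 1 for {seq}")

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.reads)


@dataclass
class Phylogeny:
    """A rooted binary tree with branch lengths, wrapping a dendropy tree."""

    tree: dendropy.Tree

    @property
    def leaf_ids(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            self.tree.as_string(schema="newick", suppress_rooting=True)
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "dna") -> dict[str, str]:
    """Read a FASTA file into an ordered id->sequence map.

    ``alphabet`` declares the caller's convention: ``"dna"`` applies U->T,
    ``"rna"`` applies T->U.  Duplicate identifiers and empty records are
    hard errors.
    """
    if alphabet not in {"dna", "rna"}:
        raise ValueError(f"alphabet must be 'dna' or 'rna', got {alphabet!r}")
    norm = to_dna if alphabet == "dna" else to_rna
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate identifier {record.id!r} in {path}")
        seq = norm(str(record.seq))
        if not seq:
            raise ValueError(f"empty record {record.id!r} in {path}")
        out[record.id] = seq
    return out


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def _gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gff3_genes(path: str | Path) -> list[GenomicFeature]:
    """Read gene and exon rows from a GFF3 file.

    1-based closed GFF coordinates become 0-based half-open.  Introns are
    derived as the gaps between consecutive exons of the same gene.  An exon
    extending outside its gene span is clipped with a warning; strand "."
    is treated as "+" with a warning; an exon without a resolvable parent
    gene is a hard error.
    """
    genes: dict[str, tuple[str, int, int, str]] = {}
    exon_rows: list[tuple[str, int, int, str, str]] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{line_no}: expected 9 columns")
            chrom, _source, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if ftype not in {"gene", "exon"}:
                continue
            start, end = int(start1) - 1, int(end1)
            if strand == ".":
                logger.warning("%s:%d: strand '.' treated as '+'", path, line_no)
                strand = "+"
            attr = _gff_attributes(attrs)
            if ftype == "gene":
                gene_id = attr.get("ID", "")
                if not gene_id:
                    raise ValueError(f"{path}:{line_no}: gene without ID")
                genes[gene_id] = (chrom, start, end, strand)
            else:
                parent = attr.get("Parent", "")
                exon_rows.append((chrom, start, end, strand, parent))

    features: list[GenomicFeature] = []
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for gene_id, (chrom, start, end, strand) in genes.items():
        features.append(GenomicFeature(chrom, start, end, strand, "gene", gene_id))
    for chrom, start, end, strand, parent in exon_rows:
        if parent not in genes:
            raise ValueError(f"orphan exon [{start},{end}) with Parent={parent!r}")
        g_chrom, g_start, g_end, g_strand = genes[parent]
        if start < g_start or end > g_end:
            logger.warning(
                "exon [%d,%d) outside gene %s span; clipping", start, end, parent
            )
            start, end = max(start, g_start), min(end, g_end)
        features.append(GenomicFeature(chrom, start, end, g_strand, "exon", parent))
        exons_by_gene.setdefault(parent, []).append((start, end))

    # introns: gaps between consecutive exons of one gene
    for gene_id, spans in exons_by_gene.items():
        chrom, _s, _e, strand = genes[gene_id]
        for (a_start, a_end), (b_start, b_end) in zip(
            sorted(spans), sorted(spans)[1:]
        ):
            if b_start > a_end:
                features.append(
                    GenomicFeature(chrom, a_end, b_start, strand, "intron", gene_id)
                )
    return features


def write_gff3_genes(path: str | Path, features: Iterable[GenomicFeature]) -> None:
    """Write gene and exon features as GFF3 (introns are derived, not written)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for feat in features:
            if feat.kind not in {"gene", "exon"}:
                continue
            attrs = (
                f"ID={feat.gene_id}" if feat.kind == "gene"
                else f"Parent={feat.gene_id}"
            )
            handle.write(
                "\t".join(
                    [
                        feat.chrom, "beemir", feat.kind,
                        str(feat.start + 1), str(feat.end), ".",
                        feat.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed6(
    path: str | Path,
    kind: str | None = None,
    te_classes: tuple[str, ...] = DEFAULT_TE_CLASSES,
) -> list[GenomicFeature]:
    """Read a BED6 file.

    With ``kind=None`` (repeat mode) the name column decides the kind: a name
    starting with one of ``te_classes`` (case-insensitive, e.g. "LINE/R2")
    becomes ``transposable_element``, anything else
    ``uncharacterized_repeat``.  With an explicit ``kind`` every record gets
    that kind and the name column is kept as ``gene_id``.
    """
    prefixes = tuple(c.upper() for c in te_classes)
    out = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}:{line_no}: BED6 requires 6 columns")
            chrom, start, end, name, _score, strand = cols[:6]
            if kind is None:
                record_kind = (
                    "transposable_element"
                    if name.upper().startswith(prefixes)
                    else "uncharacterized_repeat"
                )
                gene_id = ""
            else:
                record_kind, gene_id = kind, name
            out.append(
                GenomicFeature(chrom, int(start), int(end), strand, record_kind, gene_id)
            )
    return out


def write_bed6(path: str | Path, records: Iterable[tuple[str, int, int, str, str]]) -> None:
    """Write (chrom, start, end, name, strand) tuples as BED6 (score column 0)."""
    with open(path, "w") as handle:
        for chrom, start, end, name, strand in records:
            handle.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path, resolve_polytomies: bool = False) -> Phylogeny:
    """Read a rooted binary newick tree with branch lengths.

    Polytomies are a hard error unless ``resolve_polytomies`` is set, in
    which case they are split arbitrarily with zero-length branches.  Any
    zero-length internal branch is replaced by a small epsilon (with a
    warning) so that contrast variances stay positive.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for node in tree.preorder_node_iter():
        n_children = len(node.child_nodes())
        if n_children > 2:
            if not resolve_polytomies:
                raise ValueError(
                    f"polytomy ({n_children} children) — independent contrasts "
                    "require a binary tree; pass resolve_polytomies=True"
                )
            tree.resolve_polytomies(rng=None)
            break
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length == 0:
            logger.warning("zero-length branch replaced by epsilon %.1e", ZERO_BRANCH_EPSILON)
            edge.length = ZERO_BRANCH_EPSILON
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a mature/star support table: id, mature_count, star_count."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "mature_count", "star_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_orthogroups_tsv(path: str | Path) -> pd.DataFrame:
    """Read orthogroup membership: orthogroup_id, gene_id, species_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"orthogroup_id", "gene_id", "species_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_copy_number_tsv(path: str | Path) -> pd.DataFrame:
    """Read a miRNA copy-number matrix (rows = accessions, columns = species)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def copy_number_summary(matrix: pd.DataFrame) -> tuple[float, float]:
    """Mean and population SD of copy-number over all accession x species cells."""
    values = matrix.to_numpy(dtype=float).ravel()
    return float(values.mean()), float(values.std())
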