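"""Synthetic multi-species worlds with planted ground truth.

A world emulates the inputs of a comparative brain-miRNA study: per-species
genomes with gene models and repeat annotations, hairpin precursor loci
whose mature/star arms generate small-RNA reads, a species phylogeny with
sociality scores, orthogroup membership inducing a gene-age distribution,
and a miRNA copy-number matrix.  The planted structure gives every
downstream stage a truth manifest to be scored against:

* shared miRNA families carry one identical 7-nt seed in every species
  that expresses them;
* lineage-specific miRNAs have world-unique seeds; half of them ("unique")
  have no similar precursor in any other genome, the rest have an
  unexpressed, diverged genomic copy planted elsewhere ("premir_homolog");
* lineage-specific miRNAs are expressed lower than shared ones by a
  configurable ratio, with negative-binomial read counts and binomially
  thinned star arms so the five-read support filter has realistic
  failures;
* full-length reverse-complement target sites for lineage-specific miRNAs
  are planted in the 500-bp downstream flanks of genes, hitting "Unique"
  age-labelled genes at a configurable representation factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .discovery import PreMiR
from .gene_age import LADDER_LABELS, UNIQUE_LABEL, CladeLadder
from .homology import MatureMiR, extract_seed
from .io_formats import (
    GenomeBundle,
    GenomicFeature,
    Phylogeny,
    ReadSet,
    revcomp,
    to_dna,
    to_rna,
    write_bed6,
    write_fasta,
    write_gff3_genes,
)

MATURE_LEN = 22
LOOP_LEN = 16
PREMIR_LEN = 2 * MATURE_LEN + LOOP_LEN  # 60
FLANK = 500
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: external roster providing one representative per clade for orthogroups
EXTERNAL_CLADE_REPS = {
    "ext_vertebrate": "Vertebrata",
    "ext_mollusc": "Metazoa",
    "ext_spider": "Arthropoda",
    "ext_locust": "Insecta",
    "ext_fly": "Holometabola",
    "ext_wasp": "Hymenoptera",
    "ext_ant": "Aculeata",
    "ext_bee": "Apoidea",
}

DEFAULT_GENE_AGE_DISTRIBUTION = {
    "Vertebrata": 0.40, "Metazoa": 0.05, "Arthropoda": 0.05, "Insecta": 0.08,
    "Holometabola": 0.07, "Hymenoptera": 0.05, "Aculeata": 0.05,
    "Apoidea": 0.05, "Unique": 0.20,
}


@dataclass
class WorldConfig:
    n_species: int = 6
    genome_length_per_species: int = 500_000
    n_genes: int = 400
    n_shared_mirna_families: int = 60
    n_lineage_specific_per_species: int = 30
    lineage_specific_expression_ratio: float = 0.25
    planted_target_rf_young: float = 1.8
    gene_age_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_AGE_DISTRIBUTION)
    )
    rng_seed: int = 0
    # read-count model
    shared_mean_count: float = 300.0
    nb_dispersion: float = 0.3
    star_thinning: float = 0.2
    # hairpin placement: intergenic / intron / exon / repeat
    placement_proportions: tuple[float, float, float, float] = (0.45, 0.35, 0.05, 0.15)
    # lineage-specific subclassing
    unique_fraction: float = 0.5
    premir_homolog_divergence: float = 0.08
    # targets
    sites_per_ls_mirna: int = 3
    # shared families taking their seed from the known insect set
    known_seed_fraction: float = 0.2
    # contaminants
    n_contaminants: int = 4
    n_contaminant_decoys: int = 2
    # copy-number matrix
    n_copy_accessions: int = 50

    def validate(self) -> None:
        if abs(sum(self.gene_age_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("gene_age_distribution probabilities must sum to 1")
        for name in (
            "n_species", "genome_length_per_species", "n_genes",
            "n_shared_mirna_families", "n_lineage_specific_per_species",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.lineage_specific_expression_ratio < 1):
            raise ValueError("lineage_specific_expression_ratio must be in (0, 1)")
        if self.planted_target_rf_young < 0:
            raise ValueError("planted_target_rf_young must be >= 0")
        slot = self.genome_length_per_species // self.n_genes
        if slot < 1100:
            raise ValueError(
                "genome too small to place genes with full downstream flanks: "
                f"needs >= {self.n_genes * 1100} bp "
                f"({self.n_genes} genes x 1100 bp slots)"
            )


@dataclass
class PlantedSite:
    mirna_id: str
    gene_id: str
    utr_offset: int  # offset of the 7-nt seed complement within the UTR proxy
    chrom: str = ""
    genome_start: int = 0
    genome_end: int = 0


@dataclass
class SyntheticTruth:
    """Ground truth of a generated world."""

    #: species -> mirna_id -> {"class": "shared"|"lineage_specific",
    #:   "family": str, "subclass": "unique"|"premir_homolog"|"",
    #:   "true_mean": float}
    mirna_class: dict[str, dict[str, dict]]
    #: species -> gene_id -> age label
    gene_ages: dict[str, dict[str, str]]
    #: species -> planted sites
    planted_sites: dict[str, list[PlantedSite]]
    #: species -> realized representation factor of planted young-gene targeting
    realized_rf: dict[str, float]
    #: species -> contaminant-derived decoy hairpin ids
    decoys: dict[str, list[str]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mirna_class": self.mirna_class,
            "gene_ages": self.gene_ages,
            "planted_sites": {
                sp: [asdict(s) for s in sites]
                for sp, sites in self.planted_sites.items()
            },
            "realized_rf": self.realized_rf,
            "decoys": self.decoys,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            mirna_class=payload["mirna_class"],
            gene_ages=payload["gene_ages"],
            planted_sites={
                sp: [PlantedSite(**s) for s in sites]
                for sp, sites in payload["planted_sites"].items()
            },
            realized_rf=payload["realized_rf"],
            decoys=payload["decoys"],
        )


@dataclass
class World:
    config: WorldConfig
    species: list[str]
    genomes: dict[str, GenomeBundle]
    premirs: dict[str, list[PreMiR]]
    reads: dict[str, ReadSet]
    known_mirs: list[MatureMiR]
    contaminants: dict[str, str]
    orthogroups: pd.DataFrame
    ladder: CladeLadder
    phylogeny: Phylogeny
    sociality: dict[str, int]
    copy_matrix: pd.DataFrame
    truth: SyntheticTruth


def load_known_mirs() -> list[MatureMiR]:
    """The packaged synthetic stand-in for a known insect mature-miRNA set."""
    text = (
        resources.files("beemir.data")
        .joinpath("known_insect_mirnas.synthetic.fa")
        .read_text()
    )
    mirs = []
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
        elif line.strip() and name:
            mirs.append(MatureMiR(id=name, species_id="known", sequence=line.strip()))
            name = None
    return mirs


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _random_rna(length: int, rng: np.random.Generator) -> str:
    return to_rna(bytes(_BASES[rng.integers(4, size=length)]).decode())


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    out = list(seq)
    alphabet = "ACGU" if "U" in seq or "T" not in seq else "ACGT"
    for pos in positions:
        current = out[pos]
        choices = [c for c in alphabet if c != current]
        out[pos] = choices[rng.integers(3)]
    return "".join(out)


class _FreeZones:
    """Allocator over the intergenic, flank-free intervals of one genome."""

    def __init__(self, intervals: list[tuple[int, int]]) -> None:
        self.intervals = [iv for iv in intervals if iv[1] - iv[0] >= 10]

    def allocate(self, length: int, rng: np.random.Generator) -> tuple[int, int]:
        candidates = [
            i for i, (s, e) in enumerate(self.intervals) if e - s >= length + 2
        ]
        if not candidates:
            raise ValueError(
                "genome too small: no intergenic space left for a "
                f"{length}-bp feature"
            )
        idx = candidates[rng.integers(len(candidates))]
        s, e = self.intervals[idx]
        start = int(rng.integers(s, e - length + 1))
        # split the zone around the allocation
        del self.intervals[idx]
        if start - s >= 10:
            self.intervals.append((s, start))
        if e - (start + length) >= 10:
            self.intervals.append((start + length, e))
        self.intervals.sort()
        return start, start + length


def _build_hairpin(mature: str, rng: np.random.Generator) -> tuple[str, int, int]:
    """Precursor = mature + loop + mutated reverse complement (star).

    Returns (precursor RNA, star_offset, star_len)."""
    loop = _random_rna(LOOP_LEN, rng)
    star = to_rna(revcomp(mature))
    n_mut = 3
    positions = rng.choice(MATURE_LEN, size=n_mut, replace=False)
    star = _mutate(star, positions, rng)
    return mature + loop + star, MATURE_LEN + LOOP_LEN, MATURE_LEN


# ---------------------------------------------------------------------------
# enrichment planting
# ---------------------------------------------------------------------------

def plant_enrichment(
    genes: list[tuple[str, str]],
    mirna_ids: list[str],
    rf_target: float,
    rng: np.random.Generator,
    sites_per_mirna: int = 3,
    young_label: str = UNIQUE_LABEL,
) -> tuple[list[tuple[str, str]], float]:
    """Assign target genes to miRNAs so young genes are hit at ``rf_target``.

    ``genes`` is (gene_id, age_label) over the universe of N genes, D of
    which carry ``young_label``.  Each of the n = len(mirnas) x
    ``sites_per_mirna`` planted targets is a distinct gene, drawn young
    with probability q = rf_target·D/N so that the expected overlap x
    satisfies x/E = rf_target with E = nD/N.  Returns the (mirna, gene)
    assignment and the realized representation factor.
    """
    N = len(genes)
    young = [g for g, age in genes if age == young_label]
    old = [g for g, age in genes if age != young_label]
    D = len(young)
    if N == 0 or D == 0:
        raise ValueError("need a non-empty universe with young genes")
    q = rf_target * D / N
    if q > 1.0:
        raise ValueError(
            f"infeasible rf_target: {rf_target} x {D}/{N} = {q:.2f} > 1 "
            "(would require more young hits than targets)"
        )
    n_pairs = len(mirna_ids) * sites_per_mirna
    if n_pairs > N:
        raise ValueError("more planted targets than genes in the universe")
    k_young = int(rng.binomial(n_pairs, q))
    k_young = min(k_young, D, n_pairs)
    k_old = n_pairs - k_young
    if k_old > len(old):
        raise ValueError("not enough non-young genes for the requested planting")
    chosen = [
        (gene, True) for gene in rng.choice(young, size=k_young, replace=False)
    ] + [
        (gene, False) for gene in rng.choice(old, size=k_old, replace=False)
    ]
    rng.shuffle(chosen)
    assignment = [
        (mirna_ids[i // sites_per_mirna], gene)
        for i, (gene, _is_young) in enumerate(chosen)
    ]
    expected = n_pairs * D / N
    realized_rf = k_young / expected
    return assignment, realized_rf


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------

def _make_tree(species: list[str], rng: np.random.Generator) -> Phylogeny:
    def split(group: list[str]) -> str:
        if len(group) == 1:
            return f"{group[0]}:{rng.uniform(0.3, 1.5):.4f}"
        k = int(rng.integers(1, len(group)))
        left, right = group[:k], group[k:]
        return (
            f"({split(left)},{split(right)}):{rng.uniform(0.3, 1.5):.4f}"
        )
    order = list(species)
    rng.shuffle(order)
    k = int(rng.integers(1, len(order))) if len(order) > 1 else 1
    newick = f"({split(order[:k])},{split(order[k:])});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return Phylogeny(tree)


def generate_world(config: WorldConfig | None = None) -> World:
    """Generate a complete multi-species world; deterministic in rng_seed."""
    config = config or WorldConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n_sp = config.n_species
    species = [f"species{i + 1}" for i in range(n_sp)]
    known_mirs = load_known_mirs()
    known_seeds = {m.seed for m in known_mirs}

    # --- seeds for shared families and lineage-specific miRNAs -----------
    used_seeds = set(known_seeds)

    def fresh_seed() -> str:
        while True:
            seed = _random_rna(7, rng)
            if seed not in used_seeds:
                used_seeds.add(seed)
                return seed

    n_known_seeded = int(round(config.known_seed_fraction * config.n_shared_mirna_families))
    family_seeds: list[str] = []
    for f in range(config.n_shared_mirna_families):
        if f < n_known_seeded and f < len(known_mirs):
            family_seeds.append(known_mirs[f].seed)
        else:
            family_seeds.append(fresh_seed())
    family_members: list[list[str]] = []
    for f in range(config.n_shared_mirna_families):
        if rng.random() < 0.5 or n_sp == 2:
            members = list(species)
        else:
            size = int(rng.integers(2, n_sp + 1))
            members = sorted(rng.choice(species, size=size, replace=False))
        family_members.append(members)
    family_base_mature = []
    for seed in family_seeds:
        mature = _random_rna(MATURE_LEN, rng)
        mature = mature[0] + seed + mature[8:]
        family_base_mature.append(mature)

    # --- contaminants ------------------------------------------------------
    contaminants = {
        (f"rRNA_{i + 1}" if i % 2 == 0 else f"tRNA_{i + 1}"):
            to_dna(_random_rna(int(rng.integers(120, 1500)), rng))
        for i in range(config.n_contaminants)
    }

    # --- per-species structures -------------------------------------------
    genomes: dict[str, GenomeBundle] = {}
    premirs: dict[str, list[PreMiR]] = {}
    reads: dict[str, ReadSet] = {}
    matures: dict[str, list[MatureMiR]] = {}
    free_zones: dict[str, _FreeZones] = {}
    genome_arrays: dict[str, np.ndarray] = {}
    gene_features: dict[str, list[GenomicFeature]] = {}
    truth_class: dict[str, dict[str, dict]] = {sp: {} for sp in species}
    truth_ages: dict[str, dict[str, str]] = {}
    decoy_ids: dict[str, list[str]] = {sp: [] for sp in species}

    age_labels = list(config.gene_age_distribution)
    age_probs = np.array([config.gene_age_distribution[a] for a in age_labels])
    slot = config.genome_length_per_species // config.n_genes
    chrom = "chr1"

    for sp in species:
        L = config.genome_length_per_species
        arr = _BASES[rng.integers(4, size=L)].copy()
        genome_arrays[sp] = arr
        genes: list[GenomicFeature] = []
        features: list[GenomicFeature] = []
        flank_blocks: list[tuple[int, int]] = []
        for g in range(config.n_genes):
            base = g * slot
            start = base + int(rng.integers(0, 50))
            exon1 = 150
            intron = int(rng.integers(120, 200))
            exon2 = 150
            end = start + exon1 + intron + exon2
            strand = "+" if g in (0, config.n_genes - 1) else ("+" if rng.random() < 0.5 else "-")
            gid = f"{sp}_g{g + 1:04d}"
            genes.append(GenomicFeature(chrom, start, end, strand, "gene", gid))
            features.append(GenomicFeature(chrom, start, end, strand, "gene", gid))
            features.append(GenomicFeature(chrom, start, start + exon1, strand, "exon", gid))
            features.append(
                GenomicFeature(chrom, start + exon1, start + exon1 + intron, strand, "intron", gid)
            )
            features.append(GenomicFeature(chrom, start + exon1 + intron, end, strand, "exon", gid))
            if strand == "+":
                flank_blocks.append((end, min(end + FLANK, L)))
            else:
                flank_blocks.append((max(0, start - FLANK), start))
        gene_features[sp] = features

        # flank-free intergenic zones
        blocked = sorted(
            [(f.start, f.end) for f in genes] + flank_blocks
        )
        merged: list[tuple[int, int]] = []
        for s, e in blocked:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        free: list[tuple[int, int]] = []
        cursor = 0
        for s, e in merged:
            if s > cursor:
                free.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < L:
            free.append((cursor, L))
        zones = _FreeZones(free)
        free_zones[sp] = zones

        # repeats in flank-free intergenic space
        repeats: list[GenomicFeature] = []
        n_repeats = 60
        te_names = ["LINE/R1", "LTR/Gypsy", "DNA/Mariner", "SINE/tRNA"]
        for r in range(n_repeats):
            length = int(rng.integers(150, 300))
            try:
                r_start, r_end = zones.allocate(length, rng)
            except ValueError:
                break
            is_te = rng.random() < 0.4
            kind = "transposable_element" if is_te else "uncharacterized_repeat"
            strand = "+" if rng.random() < 0.5 else "-"
            repeats.append(GenomicFeature(chrom, r_start, r_end, strand, kind, ""))
        genomes[sp] = GenomeBundle(
            species_id=sp, chrom_sequences={}, genes=features, repeats=repeats
        )

        # gene ages
        draws = rng.choice(len(age_labels), size=config.n_genes, p=age_probs)
        truth_ages[sp] = {
            gene.gene_id: age_labels[d] for gene, d in zip(genes, draws)
        }

    # --- miRNA complements --------------------------------------------------
    placement = np.array(config.placement_proportions, dtype=float)
    placement = placement / placement.sum()

    def place_premir(sp: str, pid: str, hairpin_rna: str, rng: np.random.Generator,
                     star_offset: int) -> PreMiR:
        """Choose a genomic context per the placement proportions and write
        the hairpin into the genome."""
        arr = genome_arrays[sp]
        category = ["intergenic", "intron", "exon", "repeat"][
            int(rng.choice(4, p=placement))
        ]
        length = len(hairpin_rna)
        host: GenomicFeature | None = None
        if category in ("intron", "exon"):
            pool = [
                f for f in gene_features[sp]
                if f.kind == category and f.length >= length + 10
                and not _region_used(sp, f.start, f.end)
            ]
            if pool:
                host = pool[int(rng.integers(len(pool)))]
        elif category == "repeat":
            pool = [
                f for f in genomes[sp].repeats
                if f.length >= length + 6 and not _region_used(sp, f.start, f.end)
            ]
            if pool:
                host = pool[int(rng.integers(len(pool)))]
        if host is not None:
            start = int(rng.integers(host.start + 2, host.end - length - 2))
            end = start + length
        else:
            start, end = free_zones[sp].allocate(length, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        dna = to_dna(hairpin_rna)
        written = dna if strand == "+" else revcomp(dna)
        arr[start:end] = np.frombuffer(written.encode(), dtype=np.uint8)
        _mark_region(sp, start, end)
        return PreMiR(
            id=pid, species_id=sp, chrom=chrom, start=start, end=end,
            strand=strand, sequence=hairpin_rna,
            mature_offset=0, mature_len=MATURE_LEN,
            star_offset=star_offset, star_len=MATURE_LEN,
        )

    used_regions: dict[str, list[tuple[int, int]]] = {sp: [] for sp in species}

    def _mark_region(sp: str, start: int, end: int) -> None:
        used_regions[sp].append((start, end))

    def _region_used(sp: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in used_regions[sp])

    for sp in species:
        premirs[sp] = []
        matures[sp] = []

    # shared families
    for f, (seed, members, base) in enumerate(
        zip(family_seeds, family_members, family_base_mature)
    ):
        for sp in species:
            if sp not in members:
                continue
            mature = base
            non_seed = np.array([0] + list(range(8, MATURE_LEN)))
            n_mut = int(rng.integers(0, 3))
            if n_mut:
                mature = _mutate(mature, rng.choice(non_seed, size=n_mut, replace=False), rng)
            pid = f"{sp}-fam{f + 1:03d}"
            hairpin, star_off, _ = _build_hairpin(mature, rng)
            pre = place_premir(sp, pid, hairpin, rng, star_off)
            premirs[sp].append(pre)
            truth_class[sp][pid] = {
                "class": "shared", "family": f"fam{f + 1:03d}", "subclass": "",
                "true_mean": 0.0,
            }

    # lineage-specific miRNAs
    ls_ids: dict[str, list[str]] = {sp: [] for sp in species}
    homolog_copies: list[tuple[str, str]] = []  # (target species, hairpin RNA)
    for sp in species:
        for i in range(config.n_lineage_specific_per_species):
            seed = fresh_seed()
            mature = _random_rna(MATURE_LEN, rng)
            mature = mature[0] + seed + mature[8:]
            pid = f"{sp}-ls{i + 1:03d}"
            hairpin, star_off, _ = _build_hairpin(mature, rng)
            pre = place_premir(sp, pid, hairpin, rng, star_off)
            premirs[sp].append(pre)
            subclass = "unique" if rng.random() < config.unique_fraction else "premir_homolog"
            if subclass == "premir_homolog" and n_sp > 1:
                others = [s for s in species if s != sp]
                target = others[int(rng.integers(len(others)))]
                n_mut = rng.binomial(PREMIR_LEN, config.premir_homolog_divergence)
                positions = rng.choice(PREMIR_LEN, size=max(1, n_mut), replace=False)
                homolog_copies.append((target, _mutate(hairpin, positions, rng)))
            truth_class[sp][pid] = {
                "class": "lineage_specific", "family": "", "subclass": subclass,
                "true_mean": 0.0,
            }
            ls_ids[sp].append(pid)

    # contaminant decoys
    contaminant_list = sorted(contaminants)
    for sp in species:
        for i in range(config.n_contaminant_decoys):
            source = contaminants[contaminant_list[int(rng.integers(len(contaminant_list)))]]
            if len(source) < PREMIR_LEN + 2:
                continue
            off = int(rng.integers(0, len(source) - PREMIR_LEN))
            decoy_rna = to_rna(source[off:off + PREMIR_LEN])
            pid = f"{sp}-decoy{i + 1}"
            pre = place_premir(sp, pid, decoy_rna, rng, MATURE_LEN + LOOP_LEN)
            premirs[sp].append(pre)
            decoy_ids[sp].append(pid)
            truth_class[sp][pid] = {
                "class": "decoy", "family": "", "subclass": "", "true_mean": 0.0,
            }

    # unexpressed diverged precursor copies in other genomes
    for target_sp, hairpin_rna in homolog_copies:
        start, end = free_zones[target_sp].allocate(PREMIR_LEN, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        dna = to_dna(hairpin_rna)
        written = dna if strand == "+" else revcomp(dna)
        genome_arrays[target_sp][start:end] = np.frombuffer(written.encode(), np.uint8)
        _mark_region(target_sp, start, end)

    # --- planted target sites ----------------------------------------------
    planted_sites: dict[str, list[PlantedSite]] = {sp: [] for sp in species}
    realized_rf: dict[str, float] = {}
    gene_by_id = {
        sp: {f.gene_id: f for f in gene_features[sp] if f.kind == "gene"}
        for sp in species
    }
    for sp in species:
        genes_with_age = sorted(truth_ages[sp].items())
        assignment, _rf = plant_enrichment(
            genes_with_age, ls_ids[sp], config.planted_target_rf_young, rng,
            config.sites_per_ls_mirna,
        )
        arr = genome_arrays[sp]
        mature_by_id = {p.id: p.mature_seq for p in premirs[sp]}
        for mirna_id, gene_id in assignment:
            gene = gene_by_id[sp][gene_id]
            site = revcomp(to_dna(mature_by_id[mirna_id]))  # UTR-orientation
            utr_off = int(rng.integers(20, FLANK - MATURE_LEN - 20))
            if gene.strand == "+":
                g_start = gene.end + utr_off
                g_end = g_start + MATURE_LEN
                written = site
            else:
                g_end = gene.start - utr_off
                g_start = g_end - MATURE_LEN
                written = revcomp(site)
            if _region_used(sp, g_start, g_end):
                continue  # rare flank collision with another planted feature
            arr[g_start:g_end] = np.frombuffer(written.encode(), np.uint8)
            _mark_region(sp, g_start, g_end)
            planted_sites[sp].append(
                PlantedSite(
                    mirna_id=mirna_id, gene_id=str(gene_id),
                    utr_offset=utr_off + MATURE_LEN - 8,
                    chrom=chrom, genome_start=g_start, genome_end=g_end,
                )
            )
        # realized RF from the sites actually planted (collisions may have
        # dropped a few assignments)
        target_genes = {s.gene_id for s in planted_sites[sp]}
        d_young = sum(1 for a in truth_ages[sp].values() if a == UNIQUE_LABEL)
        n_genes = len(truth_ages[sp])
        x = sum(1 for g in target_genes if truth_ages[sp][g] == UNIQUE_LABEL)
        expected = len(target_genes) * d_young / n_genes
        realized_rf[sp] = x / expected if expected else float("nan")

    # --- finalize genomes, expression and reads ------------------------------
    for sp in species:
        genomes[sp].chrom_sequences = {chrom: bytes(genome_arrays[sp]).decode()}
        genomes[sp].validate()

        read_list: list[tuple[str, int]] = []
        r = 1.0 / config.nb_dispersion
        for pre in premirs[sp]:
            info = truth_class[sp][pre.id]
            if info["class"] == "shared":
                mean = config.shared_mean_count * float(rng.lognormal(0.0, 0.4))
            elif info["class"] == "lineage_specific":
                mean = (
                    config.shared_mean_count
                    * config.lineage_specific_expression_ratio
                    * float(rng.lognormal(0.0, 0.4))
                )
            else:  # decoy
                mean = 40.0
            info["true_mean"] = mean
            p = r / (r + mean)
            mature_count = int(rng.negative_binomial(r, p))
            star_count = int(rng.binomial(mature_count, config.star_thinning))
            if mature_count > 0:
                read_list.append((pre.mature_seq, mature_count))
            if star_count > 0:
                read_list.append((pre.star_seq, star_count))
        # junk reads exercising QC and the unmapped path
        for _ in range(5):
            read_list.append((_random_rna(int(rng.integers(10, 18)), rng), int(rng.integers(1, 6))))
        for _ in range(3):
            junk = list(_random_rna(22, rng))
            junk[int(rng.integers(22))] = "N"
            read_list.append(("".join(junk), int(rng.integers(1, 4))))
        for _ in range(5):
            read_list.append((_random_rna(22, rng), int(rng.integers(1, 6))))
        reads[sp] = ReadSet(species_id=sp, reads=read_list)

    # --- orthogroups, ladder, phylogeny, sociality, copy numbers -------------
    ladder_map = {sp: "Apoidea" for sp in species}
    ladder_map.update(EXTERNAL_CLADE_REPS)
    ladder = CladeLadder(ladder_map)
    rep_by_clade = {clade: sp for sp, clade in EXTERNAL_CLADE_REPS.items()}
    og_rows = []
    for sp in species:
        for gene_id, age in sorted(truth_ages[sp].items()):
            if age == UNIQUE_LABEL:
                continue
            og_id = f"OG_{gene_id}"
            og_rows.append({"orthogroup_id": og_id, "gene_id": gene_id, "species_id": sp})
            if age != "Apoidea":
                og_rows.append(
                    {
                        "orthogroup_id": og_id,
                        "gene_id": f"{rep_by_clade[age]}_{gene_id}",
                        "species_id": rep_by_clade[age],
                    }
                )
            else:
                og_rows.append(
                    {
                        "orthogroup_id": og_id,
                        "gene_id": f"ext_bee_{gene_id}",
                        "species_id": "ext_bee",
                    }
                )
    orthogroups = pd.DataFrame(og_rows)

    phylogeny = _make_tree(species, rng)
    levels = [3, 2, 2, 1, 0, 0]
    while len(levels) < n_sp:
        levels.append(int(rng.integers(0, 4)))
    levels = levels[:n_sp]
    rng.shuffle(levels)
    sociality = {sp: int(lv) for sp, lv in zip(species, levels)}

    n_acc = config.n_copy_accessions
    matrix = np.empty((n_acc, n_sp), dtype=int)
    for a in range(n_acc):
        if a == 0:  # planted monotone relation with sociality
            matrix[a] = [1 + sociality[sp] for sp in species]
        elif a < n_acc // 2:  # constant copy number, the common case
            matrix[a] = int(rng.integers(1, 3))
        else:
            matrix[a] = rng.integers(1, 4, size=n_sp)
    copy_matrix = pd.DataFrame(
        matrix, index=[f"acc{a + 1:03d}" for a in range(n_acc)], columns=species
    )

    truth = SyntheticTruth(
        mirna_class=truth_class,
        gene_ages=truth_ages,
        planted_sites=planted_sites,
        realized_rf=realized_rf,
        decoys=decoy_ids,
    )
    return World(
        config=config, species=species, genomes=genomes, premirs=premirs,
        reads=reads, known_mirs=known_mirs, contaminants=contaminants,
        orthogroups=orthogroups, ladder=ladder, phylogeny=phylogeny,
        sociality=sociality, copy_matrix=copy_matrix, truth=truth,
    )


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def write_world(world: World, outdir: str | Path) -> None:
    """Write the full input bundle plus truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in world.species:
        sp_dir = outdir / sp
        sp_dir.mkdir(exist_ok=True)
        write_fasta(sp_dir / "genome.fa", world.genomes[sp].chrom_sequences)
        write_gff3_genes(sp_dir / "genes.gff3", world.genomes[sp].genes)
        write_bed6(
            sp_dir / "repeats.bed",
            [
                (f.chrom, f.start, f.end,
                 "TE" if f.kind == "transposable_element" else "Unknown", f.strand)
                for f in world.genomes[sp].repeats
            ],
        )
        with open(sp_dir / "hairpins.tsv", "w") as fh:
            fh.write(
                "id\tchrom\tstart\tend\tstrand\tsequence\t"
                "mature_offset\tmature_len\tstar_offset\tstar_len\n"
            )
            for p in world.premirs[sp]:
                fh.write(
                    f"{p.id}\t{p.chrom}\t{p.start}\t{p.end}\t{p.strand}\t"
                    f"{p.sequence}\t{p.mature_offset}\t{p.mature_len}\t"
                    f"{p.star_offset}\t{p.star_len}\n"
                )
        write_fasta(
            sp_dir / "reads.fa",
            {
                f"read{i + 1}_x{count}": seq
                for i, (seq, count) in enumerate(world.reads[sp].reads)
            },
        )
    write_fasta(outdir / "known_mirnas.fa",
                {m.id: m.sequence for m in world.known_mirs})
    write_fasta(outdir / "contaminants.fa", world.contaminants)
    world.orthogroups.to_csv(outdir / "orthogroups.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(world.ladder.species_clades.items()),
        columns=["species_id", "most_specific_clade"],
    ).to_csv(outdir / "ladder.tsv", sep="\t", index=False)
    world.phylogeny.write(outdir / "tree.nwk")
    pd.DataFrame(
        sorted(world.sociality.items()), columns=["species_id", "level"]
    ).to_csv(outdir / "sociality.tsv", sep="\t", index=False)
    world.copy_matrix.to_csv(outdir / "copynumber.tsv", sep="\t")
    world.truth.to_json(outdir / "truth.json")
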