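"""Gene age from orthogroup taxonomic breadth.

Each gene inherits the age of its orthogroup: the oldest clade on the
ladder Vertebrata > Metazoa > Arthropoda > Insecta > Holometabola >
Hymenoptera > Aculeata > Apoidea that contains an orthogroup member not
belonging to the next lower clade.  Since every species is mapped to its
single most specific clade, this is the oldest most-specific clade among
the members.  Vertebrata sits outside the nested invertebrate chain: any
vertebrate member makes the orthogroup Vertebrata-aged.  Genes without an
orthogroup are "Unique".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

LADDER_LABELS = (
    "Vertebrata", "Metazoa", "Arthropoda", "Insecta",
    "Holometabola", "Hymenoptera", "Aculeata", "Apoidea",
)
UNIQUE_LABEL = "Unique"
AGE_LABELS = LADDER_LABELS + (UNIQUE_LABEL,)


@dataclass
class CladeLadder:
    """Species -> most-specific-clade map over the fixed clade ladder."""

    species_clades: dict[str, str]

    def __post_init__(self) -> None:
        bad = {
            s: c for s, c in self.species_clades.items() if c not in LADDER_LABELS
        }
        if bad:
            raise ValueError(f"species mapped to unknown clades: {bad}")

    @classmethod
    def from_tsv(cls, path) -> "CladeLadder":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["species_id"], df["most_specific_clade"])))

    def rank(self, species: str) -> int:
        return LADDER_LABELS.index(self.species_clades[species])


@dataclass
class GeneAge:
    gene_id: str
    age_label: str
    orthogroup_id: str = ""

    def __post_init__(self) -> None:
        if (self.age_label == UNIQUE_LABEL) != (not self.orthogroup_id):
            raise ValueError(
                f"{self.gene_id}: Unique label iff no orthogroup "
                f"(got {self.age_label!r} / {self.orthogroup_id!r})"
            )


def assign_age(orthogroup_species: set[str], ladder: CladeLadder) -> str:
    """Age label of an orthogroup: the oldest most-specific clade among its
    species.  Duplicates and ordering are irrelevant; a species missing
    from the ladder is a hard error."""
    if not orthogroup_species:
        raise ValueError("empty orthogroup")
    missing = sorted(s for s in orthogroup_species if s not in ladder.species_clades)
    if missing:
        raise ValueError(f"species not mapped in the clade ladder: {missing}")
    return LADDER_LABELS[min(ladder.rank(s) for s in orthogroup_species)]


def assign_gene_ages(
    orthogroups: pd.DataFrame,
    ladder: CladeLadder,
    focal_species: str,
    all_gene_ids: list[str],
    single_species_unique: bool = False,
) -> list[GeneAge]:
    """Age every focal-species gene from the orthogroup table.

    ``orthogroups`` has columns orthogroup_id, gene_id, species_id.  Genes
    absent from the table are Unique.  An orthogroup containing only the
    focal species is labelled Apoidea by default (``single_species_unique``
    flips that to Unique, dropping the orthogroup id).
    """
    og_species: dict[str, set[str]] = {}
    gene_og: dict[str, str] = {}
    for row in orthogroups.itertuples(index=False):
        og_species.setdefault(row.orthogroup_id, set()).add(row.species_id)
        if row.species_id == focal_species:
            gene_og[row.gene_id] = row.orthogroup_id
    ages = []
    for gene_id in all_gene_ids:
        og = gene_og.get(gene_id, "")
        if not og:
            ages.append(GeneAge(gene_id, UNIQUE_LABEL, ""))
            continue
        members = og_species[og]
        if single_species_unique and members == {focal_species}:
            ages.append(GeneAge(gene_id, UNIQUE_LABEL, ""))
        else:
            ages.append(GeneAge(gene_id, assign_age(members, ladder), og))
    return ages


def age_distribution(genes: list[GeneAge]) -> dict[str, int]:
    """Counts per age label; values sum to the number of genes."""
    counts = Counter(g.age_label for g in genes)
    return {label: counts.get(label, 0) for label in AGE_LABELS if counts.get(label, 0)}
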