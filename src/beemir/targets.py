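"""miRNA target prediction on 3'-UTR proxy regions.

The 500 bp immediately downstream of each gene model stands in for the
3' UTR.  A candidate site requires an exact Watson–Crick match to the full
7-nt seed (no G:U in the seed).  From the seed anchor a banded
dynamic program extends the duplex outward, allowing pairs, symmetric
(1x1) mismatches and single-nt bulges, and the one optimal pairing is
scored under two linear models:

* an alignment score (+5 per WC pair — tripled inside the seed, +1 per
  G:U, −3 per mismatch, −9 per bulge), thresholded at the miRanda-style
  cutoff >= 140;
* a duplex energy (−3 per GC, −2 per AU, −1 per GU, +3 per interior-loop
  or bulge opening), thresholded at <= −20;

plus a permutation p-value (< 0.01) that ranks the site's energy against
the same miRNA implanted at random positions of dinucleotide-shuffled
UTRs.  Only sites passing all three are retained, and gene-level pairs are
deduplicated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .discovery import dinucleotide_shuffle, permutation_pvalue
from .homology import MatureMiR, extract_seed
from .io_formats import GenomeBundle, GenomicFeature, revcomp, to_dna

logger = logging.getLogger("beemir")

#: score of a Watson–Crick pair outside the seed
PAIR_SCORE = 5.0
#: multiplier on pair scores inside the seed (seed-region weighting in the
#: style of miRanda's scale factor; makes the 140 cutoff attainable for
#: 18-26 nt miRNAs while a seed-only site still fails it)
SEED_SCALE = 3.0
GU_SCORE = 1.0
MISMATCH_SCORE = -3.0
BULGE_SCORE = -9.0

ENERGY_GC = -3.0
ENERGY_AU = -2.0
ENERGY_GU = -1.0
LOOP_OPEN_ENERGY = 3.0

FLANK_LENGTH = 500
MIN_ALIGN_SCORE = 140.0
MAX_DUPLEX_ENERGY = -20.0
SITE_ALPHA = 0.01
DEFAULT_N_PERM = 500
MAX_BULGES_PER_SIDE = 3

_WC = {("A", "T"): "AU", ("T", "A"): "AU", ("G", "C"): "GC", ("C", "G"): "GC"}
_GU = {("G", "T"), ("T", "G")}
_PAIR_ENERGY = {"AU": ENERGY_AU, "GC": ENERGY_GC, "GU": ENERGY_GU}


@dataclass
class UtrProxy:
    gene_id: str
    sequence: str  # DNA, 5'->3' of the mRNA, <= 500 nt
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class TargetSite:
    mirna_id: str
    gene_id: str
    utr_offset: int
    align_score: float
    duplex_energy: float
    p_value: float


# ---------------------------------------------------------------------------
# UTR proxy extraction
# ---------------------------------------------------------------------------

def extract_utr_proxy(
    gene: GenomicFeature, genome: GenomeBundle, flank: int = FLANK_LENGTH
) -> UtrProxy | None:
    """The ``flank`` bp downstream of a gene, oriented 5'->3' of the mRNA.

    "+" genes read forward from the gene end; "−" genes read the reverse
    complement of the ``flank`` bp before the gene start.  The interval is
    clipped at chromosome bounds (never at neighbouring genes, matching
    bedtools flank); a zero-length result returns None with a warning.
    """
    chrom_seq = genome.chrom_sequences[gene.chrom]
    if gene.strand == "+":
        start, end = gene.end, min(gene.end + flank, len(chrom_seq))
        seq = chrom_seq[start:end]
    else:
        start, end = max(0, gene.start - flank), gene.start
        seq = revcomp(chrom_seq[start:end])
    if start >= end:
        logger.warning("gene %s at chromosome edge: no downstream flank; skipped",
                       gene.gene_id)
        return None
    return UtrProxy(gene.gene_id, seq, gene.chrom, start, end, gene.strand)


# ---------------------------------------------------------------------------
# seed sites and duplex scoring
# ---------------------------------------------------------------------------

def find_seed_sites(mirna: MatureMiR, utr: UtrProxy) -> list[int]:
    """Offsets where the UTR holds the exact WC reverse complement of the seed."""
    probe = revcomp(to_dna(extract_seed(mirna.sequence)))
    sites, pos = [], utr.sequence.find(probe)
    while pos != -1:
        sites.append(pos)
        pos = utr.sequence.find(probe, pos + 1)
    return sites


_PAIR_KIND_TABLE: dict[tuple[str, str], str | None] = {}
for _m in "ACGU":
    for _u in "ACGT":
        _key = ("T" if _m == "U" else _m, _u)
        _PAIR_KIND_TABLE[(_m, _u)] = _WC.get(_key) or ("GU" if _key in _GU else None)


def _pair_kind(m_base_rna: str, utr_base_dna: str) -> str | None:
    """Classify the pairing of a miRNA base (RNA) with a UTR base (DNA)."""
    return _PAIR_KIND_TABLE.get((m_base_rna, utr_base_dna))


def _extend(mir_ext: str, ctx: str) -> tuple[float, float]:
    """Best-scoring extension of the duplex along one side.

    ``mir_ext``: miRNA bases to pair (in pairing order); ``ctx``: UTR bases
    in pairing order.  DP over (i, j, last-event) maximizing the alignment
    score (ties broken toward lower energy); returns (score, energy) of the
    optimum, which is (0, 0) when not extending at all is best.
    """
    n, L = len(mir_ext), len(ctx)
    B = MAX_BULGES_PER_SIDE
    width = 2 * B + 1
    best_score, best_energy = 0.0, 0.0
    # layered over miRNA index i; slot d = (j - i) + B in [0, 2B]; states
    # P=0 pair, M=1 mismatch, Bm=2 miRNA bulge, Bu=3 UTR bulge;
    # cell value (score, energy) or None
    layer: list[list[tuple[float, float] | None]] = [
        [None] * 4 for _ in range(width)
    ]
    layer[B][0] = (0.0, 0.0)
    for i in range(n + 1):
        # UTR-side bulges stay within the layer; single-nt bulges cannot
        # chain, so one pass from P states suffices
        for d in range(width - 2, -1, -1):
            cell = layer[d][0]
            if cell is not None and (i + d - B) < L and d + 1 < width:
                score = cell[0] + BULGE_SCORE
                energy = cell[1] + LOOP_OPEN_ENERGY
                old = layer[d + 1][3]
                if old is None or (score, -energy) > (old[0], -old[1]):
                    layer[d + 1][3] = (score, energy)
        next_layer: list[list[tuple[float, float] | None]] = [
            [None] * 4 for _ in range(width)
        ]
        any_next = False
        for d in range(width):
            j = i + d - B
            if j < 0:
                continue
            cells = layer[d]
            for state in range(4):
                cell = cells[state]
                if cell is None:
                    continue
                score, energy = cell
                if state == 0 and (score, -energy) > (best_score, -best_energy):
                    best_score, best_energy = score, energy
                if i >= n:
                    continue
                if j < L:
                    kind = _PAIR_KIND_TABLE.get((mir_ext[i], ctx[j]))
                    if kind is not None:
                        s2 = score + (GU_SCORE if kind == "GU" else PAIR_SCORE)
                        e2 = energy + _PAIR_ENERGY[kind]
                        old = next_layer[d][0]
                        if old is None or (s2, -e2) > (old[0], -old[1]):
                            next_layer[d][0] = (s2, e2)
                            any_next = True
                    s2 = score + MISMATCH_SCORE
                    e2 = energy + (LOOP_OPEN_ENERGY if state == 0 else 0.0)
                    old = next_layer[d][1]
                    if old is None or (s2, -e2) > (old[0], -old[1]):
                        next_layer[d][1] = (s2, e2)
                        any_next = True
                if state == 0 and d > 0:
                    s2 = score + BULGE_SCORE
                    e2 = energy + LOOP_OPEN_ENERGY
                    old = next_layer[d - 1][2]
                    if old is None or (s2, -e2) > (old[0], -old[1]):
                        next_layer[d - 1][2] = (s2, e2)
                        any_next = True
        if not any_next:
            break
        layer = next_layer
    return best_score, best_energy


def score_duplex(
    mirna: MatureMiR, utr: UtrProxy, offset: int
) -> tuple[float, float]:
    """Alignment score and duplex energy of the optimal pairing at a seed site.

    The seed (miRNA positions 2-8) pairs ``utr[offset:offset+7]``
    antiparallel; the miRNA 3' end extends into the UTR upstream of the
    site and miRNA position 1 pairs the base just downstream of it.
    """
    seq = mirna.sequence
    site = utr.sequence[offset:offset + 7]
    score = 0.0
    energy = 0.0
    for t in range(7):
        kind = _pair_kind(seq[1 + t], site[6 - t])
        if kind is None or kind == "GU":
            raise ValueError("seed site is not an exact WC complement")
        score += PAIR_SCORE * SEED_SCALE
        energy += _PAIR_ENERGY[kind]
    # miRNA 3' extension pairs UTR bases upstream of the site
    left_score, left_energy = _extend(seq[8:], utr.sequence[offset - 1::-1])
    # miRNA position 1 pairs the single base downstream of the site
    right_score = right_energy = 0.0
    if offset + 7 < len(utr.sequence):
        kind = _pair_kind(seq[0], utr.sequence[offset + 7])
        if kind is not None:
            right_score = GU_SCORE if kind == "GU" else PAIR_SCORE
            right_energy = _PAIR_ENERGY[kind]
    return (score + left_score + right_score,
            energy + left_energy + right_energy)


# ---------------------------------------------------------------------------
# permutation null and retention
# ---------------------------------------------------------------------------

class DuplexNullModel:
    """Null distribution of duplex energies for one miRNA.

    Each draw implants the seed complement at a random position of a
    dinucleotide-shuffled UTR drawn from the pool and records the energy of
    the optimal duplex there — the energy a seed site of this miRNA reaches
    in sequence of the same composition but no planted complementarity.
    """

    def __init__(
        self,
        mirna: MatureMiR,
        utr_pool: list[str],
        n_perm: int = DEFAULT_N_PERM,
        rng: np.random.Generator | None = None,
    ) -> None:
        if rng is None:
            rng = np.random.default_rng()
        if not utr_pool:
            raise ValueError("empty UTR pool")
        self._mirna = mirna
        self._probe = revcomp(to_dna(extract_seed(mirna.sequence)))
        # context window: the duplex reaches at most mirna-length +
        # bulge-budget nucleotides around the seed, so shuffling a window
        # of that size (drawn from a random pool position) preserves the
        # local dinucleotide composition the duplex actually sees
        self._margin = len(mirna.sequence) - 8 + MAX_BULGES_PER_SIDE + 2
        self._window = self._margin + 7 + 4
        self._pool = [u for u in utr_pool if len(u) >= self._window]
        if not self._pool:
            raise ValueError("UTR pool sequences too short for the null model")
        self.energies = np.array([self._draw(rng) for _ in range(n_perm)])

    def _draw(self, rng: np.random.Generator) -> float:
        base = self._pool[rng.integers(len(self._pool))]
        start = int(rng.integers(0, len(base) - self._window + 1))
        shuffled = dinucleotide_shuffle(base[start:start + self._window], rng)
        pos = self._margin
        planted = shuffled[:pos] + self._probe + shuffled[pos + 7:]
        fake = UtrProxy("null", planted, "null", 0, len(planted), "+")
        _score, energy = score_duplex(self._mirna, fake, pos)
        return energy

    def pvalue(self, observed_energy: float, rng: np.random.Generator) -> float:
        return permutation_pvalue(observed_energy, self.energies, rng)


def site_pvalue(
    duplex_energy: float,
    mirna: MatureMiR,
    utr_pool: list[str],
    null_model: DuplexNullModel | None = None,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for a site's duplex energy (smaller energy = more
    extreme).  Builds a null model for the miRNA unless one is supplied."""
    if rng is None:
        rng = np.random.default_rng()
    if null_model is None:
        null_model = DuplexNullModel(mirna, utr_pool, n_perm, rng)
    return null_model.pvalue(duplex_energy, rng)


@dataclass
class TargetPredictions:
    sites: list[TargetSite]
    #: deduplicated (mirna_id, gene_id) pairs
    gene_pairs: set[tuple[str, str]] = field(default_factory=set)


def predict_targets(
    mirnas: list[MatureMiR],
    utrs: list[UtrProxy],
    n_perm: int = DEFAULT_N_PERM,
    min_score: float = MIN_ALIGN_SCORE,
    max_energy: float = MAX_DUPLEX_ENERGY,
    alpha: float = SITE_ALPHA,
    rng: np.random.Generator | None = None,
) -> TargetPredictions:
    """All retained miRNA->gene target sites over a set of UTR proxies.

    A site is retained iff align_score >= ``min_score`` AND duplex_energy
    <= ``max_energy`` AND permutation p < ``alpha``.  The permutation null
    is built once per miRNA (against the shuffled UTR pool) and reused for
    all its sites.  Gene-level pairs count a gene once per miRNA.
    """
    if rng is None:
        rng = np.random.default_rng()
    pool = [u.sequence for u in utrs if len(u.sequence) >= 60]
    result = TargetPredictions(sites=[])
    null_cache: dict[str, DuplexNullModel] = {}
    for mirna in mirnas:
        for utr in utrs:
            for offset in find_seed_sites(mirna, utr):
                score, energy = score_duplex(mirna, utr, offset)
                if score < min_score or energy > max_energy:
                    continue
                if mirna.id not in null_cache:
                    null_cache[mirna.id] = DuplexNullModel(mirna, pool, n_perm, rng)
                p = null_cache[mirna.id].pvalue(energy, rng)
                if p < alpha:
                    result.sites.append(
                        TargetSite(mirna.id, utr.gene_id, offset, score, energy, p)
                    )
                    result.gene_pairs.add((mirna.id, utr.gene_id))
    return result
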