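"""Cross-species homology classification of expressed miRNAs.

Expressed miRNAs are sorted into three mutually exclusive tiers:

``seed_match``
    the 7-nt seed (mature positions 2-8) is identical to the seed of a
    miRNA expressed in another species or of a known insect miRNA;
``premir_homolog``
    no seed twin, but the hairpin precursor has a significant local
    alignment (identity >= 50%, E-value <= 1e-5) in at least one other
    species' genome;
``unique``
    neither.

A miRNA is *lineage specific* when it is expressed in exactly one species
and is not in the ``seed_match`` tier — genomic similarity of the precursor
elsewhere is not evidence that a mature miRNA is transcribed there.

The precursor search is a Smith–Waterman local alignment (blastn-like
scoring, default match +2 / mismatch −3 / gap open −5 / gap extend −2) with
significance judged by the ungapped Karlin–Altschul E-value
``E = K·m·n·exp(−λ·S)`` applied to the gapped score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io_formats import GenomeBundle, revcomp, to_dna, to_rna

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

#: 0-based half-open slice of the mature sequence that forms the seed.
#: (1, 8) is the common miRBase-style convention "positions 2-8"; (1, 7)
#: selects the shorter 2-7 hexamer-style seed.
DEFAULT_SEED_SPAN = (1, 8)


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class KarlinAltschulParams:
    """λ and K for the E-value formula, with the scoring they were solved for."""

    lam: float
    k: float
    scoring: ScoringScheme


@dataclass
class MatureMiR:
    """A mature miRNA with its expression level (reads per million)."""

    id: str
    species_id: str
    sequence: str  # RNA, 18-26 nt
    expression: float = 0.0
    pre_mir_id: str = ""

    def __post_init__(self) -> None:
        self.sequence = to_rna(self.sequence)
        if not (18 <= len(self.sequence) <= 26):
            raise ValueError(
                f"{self.id}: mature length {len(self.sequence)} outside 18-26"
            )
        if self.expression < 0:
            raise ValueError(f"{self.id}: negative expression")

    @property
    def seed(self) -> str:
        return extract_seed(self.sequence)


@dataclass
class AlignmentHit:
    score: float
    identity_pct: float
    aligned_cols: int
    e_value: float
    subject_species: str


@dataclass
class HomologyCall:
    mirna_id: str
    species_id: str
    tier: str  # seed_match | premir_homolog | unique
    expressed_in: set[str]
    lineage_specific: bool
    premir_hit_species: set[str] = field(default_factory=set)
    group_id: str = ""  # seed string of the seed-equivalence group


# ---------------------------------------------------------------------------
# seed extraction and grouping
# ---------------------------------------------------------------------------

def extract_seed(mature: str, span: tuple[int, int] = DEFAULT_SEED_SPAN) -> str:
    """Seed of a mature miRNA: positions 2-8 (1-based), returned as RNA."""
    seq = to_rna(mature)
    if len(seq) < span[1]:
        raise ValueError(
            f"mature sequence of length {len(seq)} too short for seed span {span}"
        )
    return seq[span[0]:span[1]]


def seed_match_classes(
    catalogs: dict[str, list[MatureMiR]],
    known_insect_mirs: list[MatureMiR] | None = None,
    span: tuple[int, int] = DEFAULT_SEED_SPAN,
) -> dict[str, dict]:
    """Partition all miRNAs into seed-equivalence groups.

    Returns seed -> {"members": [(species, MatureMiR)...],
    "species": set, "known": bool}.  A group whose seed occurs in >= 2
    species, or matches a known miRNA's seed, makes all its members tier
    ``seed_match``.
    """
    known_seeds = {extract_seed(m.sequence, span) for m in (known_insect_mirs or [])}
    groups: dict[str, dict] = {}
    for species in sorted(catalogs):
        for mir in catalogs[species]:
            seed = extract_seed(mir.sequence, span)
            group = groups.setdefault(
                seed, {"members": [], "species": set(), "known": seed in known_seeds}
            )
            group["members"].append((species, mir))
            group["species"].add(species)
    return groups


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics
# ---------------------------------------------------------------------------

def solve_karlin_altschul(
    scoring: ScoringScheme = ScoringScheme(),
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    tol: float = 1e-12,
) -> KarlinAltschulParams:
    """Solve for λ (bisection) and estimate K for ungapped match/mismatch scores.

    λ is the unique positive root of ``Σ p_i p_j exp(λ s_ij) − 1``; it exists
    iff the expected pair score is negative and the maximum score positive.
    K has no closed form; it is estimated once per scoring scheme from the
    excursion statistics of the induced one-dimensional score random walk
    (deterministic, internally seeded; see docs/methods.md).
    """
    p = np.asarray(base_freqs, dtype=float)
    p = p / p.sum()
    p_match = float(np.sum(p * p))
    p_mismatch = 1.0 - p_match
    expected = p_match * scoring.match + p_mismatch * scoring.mismatch
    if expected >= 0 or scoring.match <= 0:
        raise ValueError(
            "invalid scoring system: expected pair score must be negative "
            "and the match score positive"
        )

    def f(lam: float) -> float:
        return (
            p_match * math.exp(lam * scoring.match)
            + p_mismatch * math.exp(lam * scoring.mismatch)
            - 1.0
        )

    lo, hi = 1e-9, 10.0
    while f(hi) < 0:  # pragma: no cover - defensive, f grows without bound
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    lam = 0.5 * (lo + hi)
    k = _estimate_k(scoring.match, scoring.mismatch, p_match, lam)
    return KarlinAltschulParams(lam=lam, k=k, scoring=scoring)


@lru_cache(maxsize=16)
def _estimate_k(
    match: float, mismatch: float, p_match: float, lam: float,
    n_steps: int = 2_000_000,
) -> float:
    """Estimate K from excursion peaks of the 1-D score walk.

    The expected number of maximal local-alignment segments scoring >= x in
    a search space of size m·n is K·m·n·exp(−λx); restricted to one long
    diagonal of length n the same density applies, so counting excursion
    peaks >= x in a simulated walk and inverting gives K.  The simulation
    seed is fixed, making the estimate deterministic.
    """
    rng = np.random.default_rng(20200517)
    steps = np.where(
        rng.random(n_steps) < p_match, float(match), float(mismatch)
    )
    walk = np.cumsum(steps)
    floor = np.minimum.accumulate(np.minimum(walk, 0.0))
    excess = walk - floor  # >= 0; zero marks excursion boundaries
    # segment maxima between successive zeros of `excess`
    boundaries = np.flatnonzero(excess == 0.0)
    if boundaries.size < 100:  # pragma: no cover - pathological scoring
        boundaries = np.array([0, n_steps - 1])
    starts = np.concatenate(([0], boundaries + 1))
    starts = starts[starts < n_steps]
    peaks = np.maximum.reduceat(excess, starts)
    xs = np.arange(1.0, max(2.0, peaks.max()))
    estimates = []
    for x in xs:
        count = int(np.sum(peaks >= x))
        if count < 50:
            break
        estimates.append(count * math.exp(lam * x) / n_steps)
    # small-x counts are biased by the finite-size excursion structure;
    # use the median of the asymptotic (larger-x) half
    half = estimates[len(estimates) // 2:]
    return float(np.median(half)) if half else 0.1


def evalue(score: float, query_len: int, search_len: int, params: KarlinAltschulParams) -> float:
    """Karlin–Altschul E-value for a local alignment score."""
    return params.k * query_len * search_len * math.exp(-params.lam * score)


# ---------------------------------------------------------------------------
# Smith–Waterman local alignment (affine gaps, Gotoh)
# ---------------------------------------------------------------------------

@dataclass
class LocalAlignment:
    score: float
    identity_pct: float
    aligned_cols: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


def smith_waterman(
    query: str, subject: str, scoring: ScoringScheme = ScoringScheme()
) -> LocalAlignment:
    """Best local alignment of two DNA strings with affine gap penalties.

    Identity is computed over aligned columns (end gaps do not exist in a
    local alignment).  Traceback ties prefer diagonal, then gap-in-subject,
    then gap-in-query, which makes the reported alignment deterministic.
    """
    a, b = to_dna(query), to_dna(subject)
    n, m = len(a), len(b)
    neg = -math.inf
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in query (consume subject)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in subject (consume query)
    best, best_pos = 0.0, (0, 0)
    go, ge = scoring.gap_open, scoring.gap_extend
    match, mismatch = scoring.match, scoring.mismatch
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            e = Ei[j] = max(Hi[j - 1] + go, Ei[j - 1] + ge)
            f = Fi[j] = max(Hi1[j] + go, Fi1[j] + ge)
            h = Hi1[j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            Hi[j] = h
            if h > best:
                best, best_pos = h, (i, j)
    # traceback
    i, j = best_pos
    end_i, end_j = i, j
    matches = cols = 0
    state = "H"
    while i > 0 and j > 0 and H[i][j] > 0:
        if state == "H":
            s = match if a[i - 1] == b[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                matches += int(a[i - 1] == b[j - 1])
                cols += 1
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "E":
            cols += 1
            if E[i][j] == E[i][j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            cols += 1
            if F[i][j] == F[i - 1][j] + ge:
                i -= 1
            else:
                i -= 1
                state = "H"
    identity = 100.0 * matches / cols if cols else 0.0
    return LocalAlignment(
        score=float(best),
        identity_pct=identity,
        aligned_cols=cols,
        query_span=(i, end_i),
        subject_span=(j, end_j),
    )


# ---------------------------------------------------------------------------
# precursor homology search (seed-and-extend)
# ---------------------------------------------------------------------------

_CODE_LUT = np.zeros(256, dtype=np.uint32)
for _i, _c in enumerate("ACGT"):
    _CODE_LUT[ord(_c)] = _i


def _kmer_hashes(seq: str, k: int) -> np.ndarray:
    """Base-4 rolling hashes of every k-mer of a DNA string (N counts as A)."""
    codes = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint32)
    H = np.zeros(n, dtype=np.uint32)
    for t in range(k):
        H = H * np.uint32(4) + codes[t:t + n]
    return H


class GenomeWordIndex:
    """Sorted word-hash index over both strands of a genome.

    Locating every exact ``word_size``-mer occurrence becomes a binary
    search instead of a full-genome scan, which is what makes the
    precursor homology search cheap for dozens of queries.
    """

    def __init__(self, genome, word_size: int = 11) -> None:
        self.word_size = word_size
        self.strands: list[tuple[str, str, str, np.ndarray, np.ndarray]] = []
        for chrom in sorted(genome.chrom_sequences):
            fwd = genome.chrom_sequences[chrom]
            for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
                H = _kmer_hashes(seq, word_size)
                order = np.argsort(H, kind="stable").astype(np.int32)
                self.strands.append((chrom, strand, seq, H[order], order))

    def word_positions(self, strand_entry, word: str) -> np.ndarray:
        _chrom, _strand, _seq, H_sorted, order = strand_entry
        h = _kmer_hashes(word, self.word_size)
        if h.size == 0:
            return np.zeros(0, dtype=np.int32)
        lo = np.searchsorted(H_sorted, h[0], side="left")
        hi = np.searchsorted(H_sorted, h[0], side="right")
        return order[lo:hi]


def premir_homology_search(
    pre_mir_seq: str,
    other_genomes: dict[str, GenomeBundle],
    params: KarlinAltschulParams | None = None,
    min_identity: float = 50.0,
    max_evalue: float = 1e-5,
    word_size: int = 11,
    word_stride: int = 2,
    indexes: dict[str, GenomeWordIndex] | None = None,
) -> list[AlignmentHit]:
    """Search other species' genomes for the hairpin precursor.

    Blastn-style seed-and-extend: exact ``word_size``-mers of the query
    (every ``word_stride`` positions) are located on both genome strands and
    each hit is extended by Smith–Waterman in a window around the seeded
    diagonal.  A hit is reported iff identity >= ``min_identity`` percent
    AND the Karlin–Altschul E-value (search space = query length x both
    strands of the genome) <= ``max_evalue``.  At most one (best) hit per
    species is returned.
    """
    if params is None:
        params = solve_karlin_altschul()
    query = to_dna(pre_mir_seq)
    qlen = len(query)
    words = [
        (off, query[off:off + word_size])
        for off in range(0, qlen - word_size + 1, word_stride)
    ]
    hits: list[AlignmentHit] = []
    for species in sorted(other_genomes):
        genome = other_genomes[species]
        index = (indexes or {}).get(species) or GenomeWordIndex(genome, word_size)
        search_len = 2 * genome.total_length
        best: AlignmentHit | None = None
        for strand_entry in index.strands:
            strand_seq = strand_entry[2]
            # collect word hits as diagonals (genome position − query offset)
            diag_hits: list[int] = []
            for offset, word in words:
                for pos in index.word_positions(strand_entry, word):
                    diag_hits.append(int(pos) - offset)
            diag_hits.sort()
            # cluster nearby diagonals; extend clusters with >= 2 word
            # hits (the blast-style two-hit rule suppresses the random
            # single-word background)
            clusters: list[list[int]] = []
            for diag in diag_hits:
                if clusters and diag - clusters[-1][-1] <= 8:
                    clusters[-1].append(diag)
                else:
                    clusters.append([diag])
            for cluster in clusters:
                if len(cluster) < 2:
                    continue
                anchor = cluster[0]
                window_start = max(0, anchor - 10)
                window = strand_seq[window_start:window_start + qlen + 20]
                aln = smith_waterman(query, window, params.scoring)
                e = evalue(aln.score, qlen, search_len, params)
                if (
                    aln.identity_pct >= min_identity
                    and e <= max_evalue
                    and (best is None or aln.score > best.score)
                ):
                    best = AlignmentHit(
                        score=aln.score,
                        identity_pct=aln.identity_pct,
                        aligned_cols=aln.aligned_cols,
                        e_value=e,
                        subject_species=species,
                    )
        if best is not None:
            hits.append(best)
    return hits


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_all(
    catalogs: dict[str, list[MatureMiR]],
    known_insect_mirs: list[MatureMiR] | None,
    genomes: dict[str, GenomeBundle],
    premir_seqs: dict[str, dict[str, str]] | None = None,
    params: KarlinAltschulParams | None = None,
    seed_span: tuple[int, int] = DEFAULT_SEED_SPAN,
) -> list[HomologyCall]:
    """Assign every expressed miRNA a homology tier and lineage-specific flag.

    Tier priority is seed_match > premir_homolog > unique.  The precursor
    genomic search runs only for miRNAs without a cross-species or known
    seed match, against every *other* species' genome; ``premir_seqs`` maps
    species -> pre_mir_id -> precursor sequence.
    """
    if params is None:
        params = solve_karlin_altschul()
    groups = seed_match_classes(catalogs, known_insect_mirs, seed_span)
    calls: list[HomologyCall] = []
    premir_seqs = premir_seqs or {}
    indexes = {sp: GenomeWordIndex(g) for sp, g in genomes.items()} if premir_seqs else {}
    for seed, group in groups.items():
        is_seed_match = group["known"] or len(group["species"]) >= 2
        for species, mir in group["members"]:
            if is_seed_match:
                calls.append(
                    HomologyCall(
                        mirna_id=mir.id,
                        species_id=species,
                        tier="seed_match",
                        expressed_in=set(group["species"]),
                        lineage_specific=False,
                        group_id=seed,
                    )
                )
                continue
            pre_seq = premir_seqs.get(species, {}).get(mir.pre_mir_id, "")
            hit_species: set[str] = set()
            if pre_seq:
                others = {s: g for s, g in genomes.items() if s != species}
                hit_species = {
                    h.subject_species
                    for h in premir_homology_search(
                        pre_seq, others, params, indexes=indexes
                    )
                }
            tier = "premir_homolog" if hit_species else "unique"
            calls.append(
                HomologyCall(
                    mirna_id=mir.id,
                    species_id=species,
                    tier=tier,
                    expressed_in=set(group["species"]),
                    lineage_specific=len(group["species"]) == 1,
                    premir_hit_species=hit_species,
                    group_id=seed,
                )
            )
    return calls


def homology_summary(calls: list[HomologyCall]):
    """Per-species totals in the style of the localization table header:
    expressed miRNAs, and of the lineage-restricted ones the seed_match /
    pre-miR / unique split."""
    import pandas as pd

    rows = []
    for species in sorted({c.species_id for c in calls}):
        mine = [c for c in calls if c.species_id == species]
        rows.append(
            {
                "species": species,
                "expressed_mirs": len(mine),
                "seed_match": sum(c.tier == "seed_match" for c in mine),
                "premir_homolog": sum(c.tier == "premir_homolog" for c in mine),
                "unique": sum(c.tier == "unique" for c in mine),
                "lineage_specific": sum(c.lineage_specific for c in mine),
            }
        )
    return pd.DataFrame(rows)


def upset_sets(calls: list[HomologyCall]) -> dict[frozenset[str], int]:
    """Count seed-equivalence groups expressed in exactly each species subset."""
    by_group: dict[str, set[str]] = {}
    for call in calls:
        by_group.setdefault(call.group_id, set()).update({call.species_id})
    out: dict[frozenset[str], int] = {}
    for species_set in by_group.values():
        key = frozenset(species_set)
        out[key] = out.get(key, 0) + 1
    return out
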