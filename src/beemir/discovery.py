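"""Read QC, support counting and structure filters for novel miRNA candidates.

A candidate hairpin is retained when it has no rRNA/tRNA similarity, at
least five reads on each of the mature and star arms, and folds
significantly more stably than dinucleotide-preserving shuffles of itself
(permutation p < 0.05, the randfold criterion).

The folding engine is a weighted Nussinov maximum-pairing algorithm
(GC=3, AU=2, GU=1, minimum loop 3) rather than a thermodynamic
nearest-neighbour model: the permutation decision only needs a consistent
energy ordering between a sequence and its shuffles.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field

import numpy as np

from .homology import ScoringScheme, smith_waterman
from .io_formats import GenomeBundle, ReadSet, revcomp, to_dna, to_rna

logger = logging.getLogger("beemir")

MIN_READ_LENGTH = 18
MIN_ARM_READS = 5
RANDFOLD_ALPHA = 0.05
ARM_SLOP = 2  # nt tolerance when assigning mapped reads to hairpin arms

PAIR_WEIGHTS = {("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
                ("G", "U"): 1, ("U", "G"): 1}
MIN_LOOP = 3

# contaminant screen: local alignment identity/length cutoffs approximating
# an rRNA/tRNA exclusion step (not printed in any reference; configurable)
CONTAMINANT_MIN_IDENTITY = 80.0
CONTAMINANT_MIN_COLS = 20


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PreMiR:
    """A hairpin precursor locus with its two arms.

    ``sequence`` is the precursor read 5'->3' (RNA); arm offsets index into
    it.  ``start``/``end`` locate the precursor on the genome (0-based
    half-open); for "-" strand loci the sequence is the reverse complement
    of the genomic plus strand.
    """

    id: str
    species_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    mature_offset: int
    mature_len: int
    star_offset: int
    star_len: int

    def __post_init__(self) -> None:
        self.sequence = to_rna(self.sequence)
        m0, m1 = self.mature_offset, self.mature_offset + self.mature_len
        s0, s1 = self.star_offset, self.star_offset + self.star_len
        if not (0 <= m0 < m1 <= len(self.sequence)):
            raise ValueError(f"{self.id}: mature arm outside precursor")
        if not (0 <= s0 < s1 <= len(self.sequence)):
            raise ValueError(f"{self.id}: star arm outside precursor")
        if max(m0, s0) < min(m1, s1):
            raise ValueError(f"{self.id}: malformed hairpin — arms overlap")

    @property
    def mature_seq(self) -> str:
        return self.sequence[self.mature_offset:self.mature_offset + self.mature_len]

    @property
    def star_seq(self) -> str:
        return self.sequence[self.star_offset:self.star_offset + self.star_len]

    def arm_genomic_interval(self, arm: str) -> tuple[int, int]:
        """Genomic (start, end) of an arm, strand-aware."""
        off, length = (
            (self.mature_offset, self.mature_len)
            if arm == "mature"
            else (self.star_offset, self.star_len)
        )
        if self.strand == "+":
            return self.start + off, self.start + off + length
        return self.end - off - length, self.end - off


@dataclass
class FoldResult:
    pairing: list[tuple[int, int]]
    energy_score: float


@dataclass
class MiRCandidate:
    pre_mir: PreMiR
    mature_count: int = 0
    star_count: int = 0
    randfold_p: float = 1.0
    contaminant_hit: bool = False
    retained: bool = False
    reject_reason: str = ""

    @property
    def mature_seq(self) -> str:
        return self.pre_mir.mature_seq

    @property
    def star_seq(self) -> str:
        return self.pre_mir.star_seq


# ---------------------------------------------------------------------------
# read QC and exact mapping
# ---------------------------------------------------------------------------

def qc_reads(reads: ReadSet, min_length: int = MIN_READ_LENGTH) -> ReadSet:
    """Drop reads shorter than ``min_length`` or containing non-standard bases."""
    kept = [
        (seq, count)
        for seq, count in reads.reads
        if len(seq) >= min_length and set(to_dna(seq)) <= set("ACGT")
    ]
    dropped = len(reads.reads) - len(kept)
    if dropped:
        logger.info("%s: QC dropped %d of %d read sequences",
                    reads.species_id, dropped, len(reads.reads))
    return ReadSet(species_id=reads.species_id, reads=kept)


def map_reads_exact(
    reads: ReadSet, genome: GenomeBundle
) -> dict[str, list[tuple[str, int, str]]]:
    """Map each read to every exact genomic occurrence (both strands).

    Returns read sequence -> [(chrom, start, strand)]; hits on "-" report
    the plus-strand start of the matching interval.  Unmapped reads map to
    an empty list; the overall mapping fraction is logged.
    """
    hits: dict[str, list[tuple[str, int, str]]] = {}
    for seq, _count in reads.reads:
        dna = to_dna(seq)
        rc = revcomp(dna)
        found: list[tuple[str, int, str]] = []
        for chrom, chrom_seq in genome.chrom_sequences.items():
            for probe, strand in ((dna, "+"), (rc, "-")):
                pos = chrom_seq.find(probe)
                while pos != -1:
                    found.append((chrom, pos, strand))
                    pos = chrom_seq.find(probe, pos + 1)
        hits[seq] = found
    mapped = sum(c for s, c in reads.reads if hits[s])
    total = reads.total_count
    if total:
        logger.info("%s: %.1f%% of reads mapped", reads.species_id,
                    100.0 * mapped / total)
    return hits


def count_support(
    candidate: MiRCandidate,
    reads: ReadSet,
    mapped: dict[str, list[tuple[str, int, str]]],
    slop: int = ARM_SLOP,
) -> MiRCandidate:
    """Sum read counts landing on the mature and star arms (± ``slop`` nt)."""
    pre = candidate.pre_mir
    mature_iv = pre.arm_genomic_interval("mature")
    star_iv = pre.arm_genomic_interval("star")
    mature_count = star_count = 0
    for seq, count in reads.reads:
        for chrom, start, strand in mapped.get(seq, []):
            if chrom != pre.chrom or strand != pre.strand:
                continue
            end = start + len(seq)
            if abs(start - mature_iv[0]) <= slop and abs(end - mature_iv[1]) <= slop:
                mature_count += count
            elif abs(start - star_iv[0]) <= slop and abs(end - star_iv[1]) <= slop:
                star_count += count
    candidate.mature_count = mature_count
    candidate.star_count = star_count
    return candidate


# ---------------------------------------------------------------------------
# contaminant screen
# ---------------------------------------------------------------------------

def contaminant_screen(
    pre_mir_seq: str,
    contaminant_seqs: dict[str, str],
    min_identity: float = CONTAMINANT_MIN_IDENTITY,
    min_cols: int = CONTAMINANT_MIN_COLS,
    word_size: int = 11,
) -> bool:
    """True iff the precursor locally aligns to any rRNA/tRNA sequence at
    >= ``min_identity`` % identity over >= ``min_cols`` columns (either
    orientation).

    A shared exact ``word_size``-mer seeds each Smith–Waterman extension
    (an 80%-identity alignment over 20+ columns almost surely contains
    one); alignment is then confirmed in a window around the seed.
    """
    query = to_dna(pre_mir_seq)
    scoring = ScoringScheme(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0)
    for seq in contaminant_seqs.values():
        subject = to_dna(seq)
        for probe in (query, revcomp(query)):
            hit_positions = []
            seen_words: set[str] = set()
            for off in range(0, len(probe) - word_size + 1):
                word = probe[off:off + word_size]
                if word in seen_words:
                    continue
                seen_words.add(word)
                pos = subject.find(word)
                if pos != -1:
                    hit_positions.append(pos)
            for pos in hit_positions[:4]:
                lo = max(0, pos - len(probe) - 10)
                window = subject[lo:pos + len(probe) + 10]
                aln = smith_waterman(probe, window, scoring)
                if aln.aligned_cols >= min_cols and aln.identity_pct >= min_identity:
                    return True
    return False


# ---------------------------------------------------------------------------
# weighted Nussinov folding
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    mapping = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
    return np.array([mapping.get(c, 4) for c in to_rna(seq)], dtype=np.int8)


_WEIGHT_MATRIX = np.zeros((5, 5), dtype=np.int16)
for (_a, _b), _w in PAIR_WEIGHTS.items():
    _idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    _WEIGHT_MATRIX[_idx[_a], _idx[_b]] = _w


def nussinov_fold(seq: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Maximum-weight nested pairing of an RNA sequence.

    Pair weights GC=3, AU=2, GU=1; hairpin loops must enclose at least
    ``min_loop`` unpaired nucleotides.  ``energy_score`` is minus the total
    pair weight.  The traceback is deterministic: at each interval the
    closing pair is preferred, then leaving an end unpaired, then the
    leftmost optimal bifurcation.
    """
    codes = _encode(seq)
    n = len(codes)
    if n == 0:
        raise ValueError("empty sequence")
    W = _WEIGHT_MATRIX[codes[:, None], codes[None, :]]
    M = np.zeros((n, n), dtype=np.int32)
    for d in range(min_loop + 1, n):
        for i in range(0, n - d):
            j = i + d
            best = max(M[i + 1, j], M[i, j - 1])
            if W[i, j] > 0:
                inner = M[i + 1, j - 1] if j - 1 >= i + 1 else 0
                best = max(best, inner + W[i, j])
            for k in range(i + 1, j):
                v = M[i, k] + M[k + 1, j]
                if v > best:
                    best = v
            M[i, j] = best

    pairs: list[tuple[int, int]] = []

    def traceback(i: int, j: int) -> None:
        while i < j:
            score = M[i, j]
            if score == 0:
                return
            if W[i, j] > 0 and j - i > min_loop:
                inner = M[i + 1, j - 1] if j - 1 >= i + 1 else 0
                if score == inner + W[i, j]:
                    pairs.append((i, j))
                    i, j = i + 1, j - 1
                    continue
            if score == M[i + 1, j]:
                i += 1
                continue
            if score == M[i, j - 1]:
                j -= 1
                continue
            for k in range(i + 1, j):
                if score == M[i, k] + M[k + 1, j]:
                    traceback(i, k)
                    i = k + 1
                    break
            else:  # pragma: no cover - DP guarantees a branch matches
                return

    traceback(0, n - 1)
    pairs.sort()
    return FoldResult(pairing=pairs, energy_score=-float(M[0, n - 1]))


def nussinov_energies_batch(sequences: list[str], min_loop: int = MIN_LOOP) -> np.ndarray:
    """Energy scores (no traceback) for many equal-length sequences at once.

    The DP stores one slab per diagonal span d — ``diag[d][:, i]`` is the
    optimum for interval (i, i+d) — so every recurrence is a contiguous
    slice, vectorized over the batch and the interval start.  This is what
    makes the 999-shuffle randfold test tractable.  All sequences must
    share one length.
    """
    if not sequences:
        return np.zeros(0)
    n = len(sequences[0])
    if any(len(s) != n for s in sequences):
        raise ValueError("batch folding requires equal-length sequences")
    codes = np.stack([_encode(s) for s in sequences])  # (batch, n)
    batch = codes.shape[0]
    diag: list[np.ndarray] = [
        np.zeros((batch, n - d), dtype=np.int16) for d in range(n)
    ]
    for d in range(min_loop + 1, n):
        width = n - d
        # leave i or j unpaired
        best = np.maximum(diag[d - 1][:, 1:], diag[d - 1][:, :width])
        # close the pair (i, j) over interval (i+1, j-1)
        w = _WEIGHT_MATRIX[codes[:, :width], codes[:, d:]]
        np.maximum(best, diag[d - 2][:, 1:width + 1] + w, out=best)
        # bifurcation: (i, i+t) + (i+t+1, i+d) for t = 1..d-2
        for t in range(1, d - 1):
            np.maximum(
                best,
                diag[t][:, :width] + diag[d - t - 1][:, t + 1:t + 1 + width],
                out=best,
            )
        diag[d] = best
    return -diag[n - 1][:, 0].astype(float)


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul–Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random sequence with exactly the original's dinucleotide counts.

    Altschul–Erickson: view characters as vertices and dinucleotides as
    directed edges; sample a uniform last-edge tree toward the final
    character, then permute the remaining out-edges and walk the Eulerian
    path from the first character.
    """
    s = seq.upper()
    n = len(s)
    if n <= 2:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = list(edges.keys())
    if all(len(set(edges[v])) == 1 for v in vertices) and len(vertices) == 1:
        return s  # e.g. homopolymer: only one Eulerian path
    # scalar draws through the (much faster) stdlib PRNG, seeded from the
    # caller's generator so determinism is preserved
    prng = _pyrandom.Random(int(rng.integers(2**63)))
    # sample a last-edge arborescence toward `last` by random walks; the
    # recorded edge for each vertex is its last exit in a walk that reached
    # `last`, which cannot form cycles
    last_edge: dict[str, str] = {}
    for v in vertices:
        if v == last:
            continue
        walk_v = v
        path: dict[str, str] = {}
        while walk_v != last:
            outs = edges[walk_v]
            nxt = outs[prng.randrange(len(outs))] if len(outs) > 1 else outs[0]
            path[walk_v] = nxt
            walk_v = nxt
        for src, dst in path.items():
            if src not in last_edge:
                last_edge[src] = dst
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        prng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        shuffled[v] = pool
    out = [s[0]]
    cursor = {v: 0 for v in vertices}
    v = s[0]
    for _ in range(n - 1):
        nxt = shuffled[v][cursor[v]]
        cursor[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# randfold permutation test
# ---------------------------------------------------------------------------

def permutation_pvalue(
    observed: float, null_values: np.ndarray, rng: np.random.Generator
) -> float:
    """Exact randomized add-one permutation p-value (smaller = more extreme).

    Strictly smaller null values always count; ties are split uniformly at
    random, which keeps the p-value exactly uniform under the null even
    with the discrete integer-valued energy models used here.  p ∈ (0, 1].
    """
    null_values = np.asarray(null_values, dtype=float)
    n = null_values.size
    less = int(np.sum(null_values < observed))
    ties = int(np.sum(null_values == observed))
    k = less + (int(rng.integers(ties + 1)) if ties else 0)
    return (1.0 + k) / (n + 1.0)


def randfold_test(
    pre_mir_seq: str,
    n_shuffles: int = 999,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value that the precursor folds more stably than chance.

    The native weighted-Nussinov energy is ranked among the energies of
    ``n_shuffles`` dinucleotide-preserving shuffles.  Sequences whose
    dinucleotide graph admits no alternative ordering get p = 1.
    """
    if rng is None:
        rng = np.random.default_rng()
    seq = to_rna(pre_mir_seq)
    if len(seq) < 20:
        raise ValueError("sequence too short for a meaningful fold test")
    shuffles = [dinucleotide_shuffle(seq, rng) for _ in range(n_shuffles)]
    if all(s == seq for s in shuffles):
        logger.warning("sequence admits no dinucleotide shuffle; p = 1")
        return 1.0
    energies = nussinov_energies_batch([seq] + shuffles)
    return permutation_pvalue(energies[0], energies[1:], rng)


def randfold_test_batch(
    candidates: list[MiRCandidate],
    n_shuffles: int,
    rng: np.random.Generator,
) -> None:
    """Fill ``randfold_p`` for many candidates, batching equal-length folds."""
    by_length: dict[int, list[int]] = {}
    for idx, cand in enumerate(candidates):
        by_length.setdefault(len(cand.pre_mir.sequence), []).append(idx)
    for _length, indices in sorted(by_length.items()):
        seqs: list[str] = []
        for idx in indices:
            native = candidates[idx].pre_mir.sequence
            seqs.append(native)
            seqs.extend(
                dinucleotide_shuffle(native, rng) for _ in range(n_shuffles)
            )
        energies = nussinov_energies_batch(seqs)
        stride = n_shuffles + 1
        for slot, idx in enumerate(indices):
            block = energies[slot * stride:(slot + 1) * stride]
            candidates[idx].randfold_p = permutation_pvalue(block[0], block[1:], rng)


# ---------------------------------------------------------------------------
# the combined novel-miRNA filter
# ---------------------------------------------------------------------------

def apply_novel_filters(
    candidates: list[MiRCandidate],
    min_arm_reads: int = MIN_ARM_READS,
    alpha: float = RANDFOLD_ALPHA,
) -> list[MiRCandidate]:
    """Retain candidates with no contaminant hit, >= ``min_arm_reads`` reads
    on each arm, and randfold p strictly below ``alpha``.  Reject reasons
    are recorded per candidate; the retained sublist is returned."""
    retained = []
    for cand in candidates:
        reasons = []
        if cand.contaminant_hit:
            reasons.append("contaminant")
        if cand.mature_count < min_arm_reads:
            reasons.append(f"mature_reads<{min_arm_reads}")
        if cand.star_count < min_arm_reads:
            reasons.append(f"star_reads<{min_arm_reads}")
        if not (cand.randfold_p < alpha):
            reasons.append(f"randfold_p>={alpha}")
        cand.retained = not reasons
        cand.reject_reason = ";".join(reasons)
        if cand.retained:
            retained.append(cand)
        else:
            logger.debug("%s rejected: %s", cand.pre_mir.id, cand.reject_reason)
    return retained
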