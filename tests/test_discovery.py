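"""Discovery filters: read QC, exact mapping, support counting, the
contaminant screen, weighted Nussinov folding and the randfold-style
permutation test."""

import itertools

import numpy as np
import pytest

from beemir.discovery import (
    MiRCandidate,
    PAIR_WEIGHTS,
    PreMiR,
    apply_novel_filters,
    contaminant_screen,
    count_support,
    dinucleotide_shuffle,
    map_reads_exact,
    nussinov_energies_batch,
    nussinov_fold,
    permutation_pvalue,
    qc_reads,
    randfold_test,
)
from beemir.io_formats import GenomeBundle, ReadSet, revcomp


def _hairpin(seq="GGCAUGCAUGCAUGCAUGCAUG", loop="AACGAAUCGA", rng=None):
    """A strong synthetic hairpin: mature + loop + perfect revcomp star."""
    star = revcomp(seq).replace("T", "U")
    return seq + loop + star


# ---------------------------------------------------------------------------
# read QC and mapping
# ---------------------------------------------------------------------------

class TestQcReads:
    @pytest.mark.parametrize(
        "read,kept",
        [
            ("ACGUACGUACGUACGUAC", True),   # exactly 18 nt
            ("ACGUACGUACGUACGUA", False),   # 17 nt boundary
            ("ACGTNNNACGTACGTACGT", False), # non-standard base
            ("ACGTACGTACGTACGTACGT", True),
        ],
    )
    def test_length_and_alphabet_filters(self, read, kept):
        out = qc_reads(ReadSet("sp", [(read, 3)]))
        assert bool(out.reads) is kept
        if kept:
            assert out.reads[0][1] == 3  # counts preserved


class TestExactMapping:
    def test_forward_reverse_and_unmapped(self, rng):
        chrom = "".join(rng.choice(list("ACGT"), size=400))
        read_fwd = chrom[100:120]
        read_rev = revcomp(chrom[200:220])
        genome = GenomeBundle("sp", {"chr1": chrom})
        reads = ReadSet("sp", [(read_fwd, 1), (read_rev, 1), ("A" * 25, 1)])
        hits = map_reads_exact(reads, genome)
        assert ("chr1", 100, "+") in hits[read_fwd]
        assert ("chr1", 200, "-") in hits[read_rev]
        assert hits["A" * 25] == []

    def test_reported_locus_matches_genome(self, rng):
        chrom = "".join(rng.choice(list("ACGT"), size=500))
        read = chrom[50:72]
        genome = GenomeBundle("sp", {"chr1": chrom})
        hits = map_reads_exact(ReadSet("sp", [(read, 1)]), genome)
        for c, start, strand in hits[read]:
            segment = chrom[start:start + len(read)]
            assert segment == read if strand == "+" else revcomp(segment) == read


class TestCountSupport:
    def _candidate(self, chrom_seq, start=100):
        hairpin = _hairpin()
        pre = PreMiR(
            id="m1", species_id="sp", chrom="chr1",
            start=start, end=start + len(hairpin), strand="+",
            sequence=hairpin, mature_offset=0, mature_len=22,
            star_offset=32, star_len=22,
        )
        return MiRCandidate(pre)

    def test_support_counting_with_slop(self, rng):
        hairpin = _hairpin()
        chrom = "".join(rng.choice(list("ACGT"), size=300))
        chrom = chrom[:100] + hairpin.replace("U", "T") + chrom[100 + len(hairpin):]
        genome = GenomeBundle("sp", {"chr1": chrom})
        cand = self._candidate(chrom)
        mature, star = cand.mature_seq, cand.star_seq
        reads = ReadSet("sp", [(mature, 5), (star, 5)])
        mapped = map_reads_exact(reads, genome)
        count_support(cand, reads, mapped)
        assert (cand.mature_count, cand.star_count) == (5, 5)

    def test_overlapping_arms_rejected(self):
        with pytest.raises(ValueError, match="arms overlap"):
            PreMiR(
                id="bad", species_id="sp", chrom="chr1", start=0, end=60,
                strand="+", sequence="A" * 60, mature_offset=0, mature_len=30,
                star_offset=20, star_len=30,
            )


# ---------------------------------------------------------------------------
# contaminant screen
# ---------------------------------------------------------------------------

class TestContaminantScreen:
    def test_exact_trna_substring_is_hit(self, rng):
        trna = "".join(rng.choice(list("ACGT"), size=90))
        pre = "ACGU" * 10 + trna[30:55].replace("T", "U") + "GCAU" * 5
        assert contaminant_screen(pre, {"tRNA_1": trna}) is True

    def test_empty_contaminant_set_no_hit(self, rng):
        pre = "".join(rng.choice(list("ACGU"), size=70))
        assert contaminant_screen(pre, {}) is False

    def test_sub_threshold_identity_no_hit(self, rng):
        # 75% identity over 20 columns stays below the 80% cutoff
        pre = "".join(rng.choice(list("ACGU"), size=60))
        corrupted = list(pre[:20])
        for pos in (2, 7, 12, 17, 3):
            corrupted[pos] = {"A": "C", "C": "A", "G": "U", "U": "G"}[corrupted[pos]]
        contaminant = "".join(corrupted).replace("U", "T")
        assert contaminant_screen(pre, {"rRNA_1": contaminant}) is False


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

def _brute_force_best_weight(seq, min_loop=3):
    """Exhaustive enumeration of nested structures (oracle for <= 12 nt)."""
    weight = {k: v for k, v in PAIR_WEIGHTS.items()}

    def best(i, j):
        if j - i < min_loop + 1:
            return 0
        candidates = [best(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            w = weight.get((seq[i], seq[k]), 0)
            if w:
                candidates.append(w + best(i + 1, k - 1) + best(k + 1, j))
        return max(candidates)

    return best(0, len(seq) - 1)


class TestNussinovFold:
    def test_ggg_aaa_ccc(self):
        result = nussinov_fold("GGGAAACCC")
        assert result.pairing == [(0, 8), (1, 7), (2, 6)]
        assert result.energy_score == -9.0

    def test_no_complementarity(self):
        assert nussinov_fold("AAAAAA").energy_score == 0.0

    def test_min_loop_blocks_short_pair(self):
        assert nussinov_fold("GC").pairing == []

    def test_pairing_is_valid_structure(self, rng):
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGU"), size=40))
            result = nussinov_fold(seq)
            seen = set()
            for i, j in result.pairing:
                assert j - i > 3
                assert PAIR_WEIGHTS.get((seq[i], seq[j]), 0) > 0
                assert i not in seen and j not in seen
                seen.update((i, j))
            for (i1, j1), (i2, j2) in itertools.combinations(result.pairing, 2):
                # nested or disjoint, never crossing
                assert (j1 < i2) or (j2 < i1) or (i1 < i2 <= j2 < j1) or (i2 < i1 <= j1 < j2)
            total = sum(PAIR_WEIGHTS[(seq[i], seq[j])] for i, j in result.pairing)
            assert result.energy_score == -float(total)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 13))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            assert -nussinov_fold(seq).energy_score == _brute_force_best_weight(seq)

    def test_batch_equals_scalar(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), size=35)) for _ in range(30)]
        batch = nussinov_energies_batch(seqs)
        scalar = [nussinov_fold(s).energy_score for s in seqs]
        assert np.allclose(batch, scalar)


# ---------------------------------------------------------------------------
# dinucleotide shuffle and randfold
# ---------------------------------------------------------------------------

class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        from collections import Counter

        for _ in range(50):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(20, 80))))
            shuffled = dinucleotide_shuffle(seq, rng)
            assert Counter(zip(seq, seq[1:])) == Counter(zip(shuffled, shuffled[1:]))
            assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]

    def test_produces_variation(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=60))
        shuffles = {dinucleotide_shuffle(seq, rng) for _ in range(20)}
        assert len(shuffles) > 10


class TestRandfold:
    def test_rank_arithmetic_add_one(self, rng):
        # native strictly below all 99 null values -> p = 1/100
        p = permutation_pvalue(-50.0, np.full(99, -10.0), rng)
        assert p == pytest.approx(0.01)

    def test_planted_hairpin_significant(self, rng):
        hairpin = _hairpin("GGCAUGGCAUCGUAGCAUGCAUGCA", "AACGAAUCG")
        hits = sum(
            randfold_test(hairpin, n_shuffles=99, rng=rng) < 0.05 for _ in range(20)
        )
        assert hits >= 19

    def test_pvalue_in_unit_interval(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=40))
        p = randfold_test(seq, n_shuffles=49, rng=rng)
        assert 0 < p <= 1


class TestApplyNovelFilters:
    def _cand(self, hit, mature, star, p):
        pre = PreMiR(
            id="x", species_id="sp", chrom="chr1", start=0, end=60, strand="+",
            sequence=_hairpin(), mature_offset=0, mature_len=22,
            star_offset=32, star_len=22,
        )
        cand = MiRCandidate(pre, mature_count=mature, star_count=star,
                            randfold_p=p, contaminant_hit=hit)
        return cand

    @pytest.mark.parametrize(
        "hit,mature,star,p,retained,reason_part",
        [
            (False, 10, 7, 0.01, True, ""),
            (False, 10, 7, 0.05, False, "randfold"),  # strict <
            (True, 10, 7, 0.001, False, "contaminant"),
            (False, 5, 4, 0.01, False, "star_reads"),
            (False, 5, 5, 0.01, True, ""),
            (False, 0, 0, 0.01, False, "mature_reads"),
        ],
    )
    def test_filter_logic(self, hit, mature, star, p, retained, reason_part):
        cand = self._cand(hit, mature, star, p)
        kept = apply_novel_filters([cand])
        assert cand.retained is retained
        assert (cand in kept) is retained
        if reason_part:
            assert reason_part in cand.reject_reason
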