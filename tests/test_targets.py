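"""Target prediction: UTR proxy extraction, strict seed sites, the
two-model duplex scorer and the permutation retention rule."""

import numpy as np
import pytest

from beemir.homology import MatureMiR
from beemir.io_formats import GenomeBundle, GenomicFeature, revcomp, to_dna
from beemir.targets import (
    DuplexNullModel,
    MAX_BULGES_PER_SIDE,
    UtrProxy,
    _extend,
    extract_utr_proxy,
    find_seed_sites,
    predict_targets,
    score_duplex,
    site_pvalue,
)


def _genome(rng, length=12_000):
    chrom = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeBundle("sp", {"chr1": chrom})


class TestExtractUtrProxy:
    def test_plus_strand_forward_flank(self, rng):
        genome = _genome(rng)
        gene = GenomicFeature("chr1", 1000, 2000, "+", "gene", "g1")
        utr = extract_utr_proxy(gene, genome)
        assert (utr.start, utr.end) == (2000, 2500)
        assert utr.sequence == genome.chrom_sequences["chr1"][2000:2500]

    def test_minus_strand_reverse_complement(self, rng):
        genome = _genome(rng)
        gene = GenomicFeature("chr1", 1000, 2000, "-", "gene", "g1")
        utr = extract_utr_proxy(gene, genome)
        assert (utr.start, utr.end) == (500, 1000)
        assert utr.sequence == revcomp(genome.chrom_sequences["chr1"][500:1000])

    def test_clipped_at_chromosome_end(self, rng):
        genome = _genome(rng, length=10_000)
        gene = GenomicFeature("chr1", 9000, 9800, "+", "gene", "g1")
        utr = extract_utr_proxy(gene, genome)
        assert (utr.start, utr.end) == (9800, 10_000)
        assert len(utr.sequence) == 200

    def test_gene_at_edge_skipped(self, rng):
        genome = _genome(rng, length=5_000)
        gene = GenomicFeature("chr1", 4500, 5000, "+", "gene", "g1")
        assert extract_utr_proxy(gene, genome) is None


def _mirna(seq, mid="mir-x"):
    return MatureMiR(id=mid, species_id="sp", sequence=seq, expression=5.0)


class TestFindSeedSites:
    def test_reverse_complement_site(self):
        mir = _mirna("UGAGGUAGUAGGUUGUAUAGUU")  # seed GAGGUAG -> CTACCTC
        utr = UtrProxy("g", "AAAA" + "CTACCTC" + "AAAA", "chr1", 0, 15, "+")
        assert find_seed_sites(mir, utr) == [4]

    def test_two_offsets(self):
        mir = _mirna("UGAGGUAGUAGGUUGUAUAGUU")
        utr = UtrProxy("g", "CTACCTC" + "GGGG" + "CTACCTC", "chr1", 0, 18, "+")
        assert find_seed_sites(mir, utr) == [0, 11]

    def test_one_mismatch_is_no_site(self):
        mir = _mirna("UGAGGUAGUAGGUUGUAUAGUU")
        utr = UtrProxy("g", "AAAA" + "CTACGTC" + "AAAA", "chr1", 0, 15, "+")
        assert find_seed_sites(mir, utr) == []

    def test_gu_wobble_not_allowed_in_seed(self):
        # T->C at a position that would give a G:U wobble against the seed
        mir = _mirna("UGAGGUAGUAGGUUGUAUAGUU")
        utr = UtrProxy("g", "AAAA" + "CTACCTT" + "AAAA", "chr1", 0, 15, "+")
        assert find_seed_sites(mir, utr) == []


class TestScoreDuplex:
    def test_seed_only_site(self):
        # extension context pairs nothing: score is 7 seed pairs x 5 x 3,
        # energy the seed pairs alone (4 GC + 3 AU here)
        mir = _mirna("A" + "GAGGUAG" + "A" * 14)
        utr_seq = "C" * 20 + "CTACCTC" + "C" * 20
        utr = UtrProxy("g", utr_seq, "chr1", 0, len(utr_seq), "+")
        (offset,) = find_seed_sites(mir, utr)
        score, energy = score_duplex(mir, utr, offset)
        assert score == pytest.approx(105.0)
        assert energy == pytest.approx(-(4 * 3 + 3 * 2))
        # a seed-only site fails the miRanda-style score cutoff
        assert score < 140.0

    def test_perfect_full_length_duplex(self):
        mir = _mirna("A" + "GAGGUAG" + "A" * 14)
        site = revcomp(to_dna(mir.sequence))
        utr_seq = "C" * 20 + site + "C" * 20
        utr = UtrProxy("g", utr_seq, "chr1", 0, len(utr_seq), "+")
        (offset,) = find_seed_sites(mir, utr)
        score, energy = score_duplex(mir, utr, offset)
        # 105 (seed) + 14 extension pairs x 5 + position-1 pair x 5
        assert score == pytest.approx(180.0)
        # seed -18, extension 14 AU = -28, position-1 AU = -2
        assert energy == pytest.approx(-48.0)
        assert score >= 140.0 and energy <= -20.0

    def test_energy_of_21mer_duplex_11gc_10au(self):
        # 11 G/C + 10 A/U bases fully paired: energy -(11*3 + 10*2) = -53
        mir = _mirna("C" + "GCAGGCU" + "GCGCGUAUAUAUA")
        assert len(mir.sequence) == 21
        assert sum(c in "GC" for c in mir.sequence) == 11
        site = revcomp(to_dna(mir.sequence))
        utr_seq = "A" * 25 + site + "A" * 25
        utr = UtrProxy("g", utr_seq, "chr1", 0, len(utr_seq), "+")
        (offset,) = find_seed_sites(mir, utr)
        _score, energy = score_duplex(mir, utr, offset)
        assert energy == pytest.approx(-53.0)


def _extend_oracle(mir_ext, ctx):
    """Exhaustive recursion over the extension state space (toy sizes)."""
    from beemir.targets import (
        BULGE_SCORE, GU_SCORE, LOOP_OPEN_ENERGY, MISMATCH_SCORE, PAIR_SCORE,
        _PAIR_ENERGY, _PAIR_KIND_TABLE,
    )

    best = [(0.0, 0.0)]

    def recurse(i, j, last, score, energy):
        if last == "P" and (score, -energy) > (best[0][0], -best[0][1]):
            best[0] = (score, energy)
        if i < len(mir_ext) and j < len(ctx):
            kind = _PAIR_KIND_TABLE.get((mir_ext[i], ctx[j]))
            if kind is not None:
                add = GU_SCORE if kind == "GU" else PAIR_SCORE
                recurse(i + 1, j + 1, "P", score + add, energy + _PAIR_ENERGY[kind])
            recurse(i + 1, j + 1, "M", score + MISMATCH_SCORE,
                    energy + (LOOP_OPEN_ENERGY if last == "P" else 0.0))
        if last == "P":
            if i < len(mir_ext) and (j - (i + 1)) > -MAX_BULGES_PER_SIDE:
                recurse(i + 1, j, "Bm", score + BULGE_SCORE,
                        energy + LOOP_OPEN_ENERGY)
            if j < len(ctx) and (j + 1 - i) < MAX_BULGES_PER_SIDE:
                recurse(i, j + 1, "Bu", score + BULGE_SCORE,
                        energy + LOOP_OPEN_ENERGY)

    recurse(0, 0, "P", 0.0, 0.0)
    return best[0]


class TestExtendDP:
    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 9))
            m = int(rng.integers(1, 11))
            mir_ext = "".join(rng.choice(list("ACGU"), size=n))
            ctx = "".join(rng.choice(list("ACGT"), size=m))
            assert _extend(mir_ext, ctx) == _extend_oracle(mir_ext, ctx)


class TestSitePvalueAndPrediction:
    def test_rank_arithmetic(self, rng):
        mir = _mirna("UGAGGUAGUAGGUUGUAUAGUU")
        pool = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(5)]
        null = DuplexNullModel(mir, pool, n_perm=499, rng=rng)
        assert null.pvalue(-999.0, rng) == pytest.approx(1 / 500)
        assert null.pvalue(+999.0, rng) == pytest.approx(1.0)

    def test_site_pvalue_in_unit_interval(self, rng):
        mir = _mirna("UGAGGUAGUAGGUUGUAUAGUU")
        pool = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(5)]
        p = site_pvalue(-20.0, mir, pool, n_perm=99, rng=rng)
        assert 0 < p <= 1

    def test_planted_strong_site_recovered_and_deduplicated(self, rng):
        mir = _mirna("UGAGGUAGUAGGUUGUAUAGUU")
        site = revcomp(to_dna(mir.sequence))
        background = "".join(rng.choice(list("ACGT"), size=400))
        seq = background[:50] + site + background[50:150] + site + background[150:]
        utrs = [
            UtrProxy("hit", seq, "chr1", 0, len(seq), "+"),
            UtrProxy("bg", "".join(rng.choice(list("ACGT"), size=400)),
                     "chr1", 0, 400, "+"),
        ]
        result = predict_targets([mir], utrs, n_perm=149, rng=rng)
        # two physical sites, one gene-level pair
        assert ("mir-x", "hit") in result.gene_pairs
        assert sum(s.gene_id == "hit" for s in result.sites) == 2
        assert len([p for p in result.gene_pairs if p[1] == "hit"]) == 1

    def test_no_seed_no_predictions(self, rng):
        mir = _mirna("UGAGGUAGUAGGUUGUAUAGUU")
        # UTRs free of the 7-mer seed complement
        utrs = []
        probe = revcomp(to_dna(mir.sequence[1:8]))
        while len(utrs) < 5:
            s = "".join(rng.choice(list("ACGT"), size=300))
            if probe not in s:
                utrs.append(UtrProxy(f"g{len(utrs)}", s, "chr1", 0, 300, "+"))
        result = predict_targets([mir], utrs, n_perm=99, rng=rng)
        assert result.sites == [] and result.gene_pairs == set()

    def test_false_positive_rate_on_shuffled_utrs(self, rng):
        # random miRNAs vs random UTRs: gene-level prediction rate <= 1%
        n_pairs = 0
        n_tested = 0
        for _ in range(6):
            mir = _mirna("".join(rng.choice(list("ACGU"), size=22)), "m")
            utrs = [
                UtrProxy(f"g{i}", "".join(rng.choice(list("ACGT"), size=500)),
                         "chr1", 0, 500, "+")
                for i in range(50)
            ]
            result = predict_targets([mir], utrs, n_perm=149, rng=rng)
            n_pairs += len(result.gene_pairs)
            n_tested += len(utrs)
        assert n_pairs / n_tested <= 0.01
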