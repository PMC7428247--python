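"""Homology classification: seed extraction/grouping, Karlin–Altschul
statistics, Smith–Waterman alignment and the precursor genome search."""

import math

import numpy as np
import pytest
from scipy import optimize

from beemir.homology import (
    MatureMiR,
    ScoringScheme,
    classify_all,
    evalue,
    extract_seed,
    premir_homology_search,
    seed_match_classes,
    smith_waterman,
    solve_karlin_altschul,
    upset_sets,
)
from beemir.io_formats import GenomeBundle, revcomp


class TestExtractSeed:
    def test_positions_two_to_eight(self):
        assert extract_seed("UGAGGUAGUAGGUUGUAUAGUU") == "GAGGUAG"

    def test_eight_nt_boundary(self):
        assert extract_seed("ACGUACGU") == "CGUACGU"

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            extract_seed("ACGUACG")

    def test_alternative_span(self):
        assert extract_seed("UGAGGUAGUAGGUUGUAUAGUU", span=(1, 7)) == "GAGGUA"


def _mir(mid, sp, seq, expr=10.0):
    return MatureMiR(id=mid, species_id=sp, sequence=seq, expression=expr,
                     pre_mir_id=mid)


class TestSeedGrouping:
    def test_identical_seed_across_species_groups_together(self):
        a = _mir("a1", "A", "UGAGGUAGUAGGUUGUAUAGUU")
        b = _mir("b1", "B", "AGAGGUAGUCGGUUGUAUACCA")  # same seed, different elsewhere
        groups = seed_match_classes({"A": [a], "B": [b]})
        assert groups["GAGGUAG"]["species"] == {"A", "B"}

    def test_single_mismatch_splits_groups(self):
        a = _mir("a1", "A", "UGAGGUAGUAGGUUGUAUAGUU")
        b = _mir("b1", "B", "UGAGCUAGUAGGUUGUAUAGUU")
        groups = seed_match_classes({"A": [a], "B": [b]})
        assert len(groups) == 2

    def test_order_invariance(self, rng):
        mirs = [
            _mir(f"m{i}", sp, "".join(rng.choice(list("ACGU"), size=22)))
            for i, sp in enumerate(["A", "B", "A", "B", "C"] * 4)
        ]
        catalogs = {}
        for m in mirs:
            catalogs.setdefault(m.species_id, []).append(m)
        shuffled = {
            sp: list(reversed(members)) for sp, members in catalogs.items()
        }
        g1 = seed_match_classes(catalogs)
        g2 = seed_match_classes(shuffled)
        assert {s: frozenset(m.id for _sp, m in g["members"]) for s, g in g1.items()} \
            == {s: frozenset(m.id for _sp, m in g["members"]) for s, g in g2.items()}


class TestKarlinAltschul:
    def test_lambda_closed_form_plus1_minus1(self):
        params = solve_karlin_altschul(ScoringScheme(1, -1, -2, -1))
        assert params.lam == pytest.approx(math.log(3), abs=1e-9)

    def test_lambda_against_independent_root_finder(self):
        scoring = ScoringScheme(2, -3, -5, -2)
        params = solve_karlin_altschul(scoring)

        def f(lam):
            return 0.25 * math.exp(2 * lam) + 0.75 * math.exp(-3 * lam) - 1.0

        oracle = optimize.brentq(f, 1e-9, 10.0, xtol=1e-12)
        assert params.lam == pytest.approx(oracle, abs=1e-9)

    def test_all_positive_scoring_is_error(self):
        with pytest.raises(ValueError, match="invalid scoring"):
            solve_karlin_altschul(ScoringScheme(1, 1, -2, -1))

    def test_k_is_plausible(self):
        params = solve_karlin_altschul(ScoringScheme(1, -1, -2, -1))
        # published ungapped K for +1/-1 on uniform DNA is ~0.33
        assert 0.2 < params.k < 0.5

    def test_evalue_monotone_in_score(self):
        params = solve_karlin_altschul()
        es = [evalue(s, 70, 1_000_000, params) for s in range(10, 100, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))


class TestSmithWaterman:
    def test_matches_biotite_oracle(self, rng):
        import biotite.sequence as bseq
        import biotite.sequence.align as balign

        scoring = ScoringScheme(2, -3, -5, -2)
        alphabet = bseq.NucleotideSequence.alphabet_unamb
        matrix = balign.SubstitutionMatrix(
            alphabet, alphabet,
            np.where(np.eye(4, dtype=bool), int(scoring.match), int(scoring.mismatch)),
        )
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 31))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 31))))
            ours = smith_waterman(a, b, scoring)
            oracle = balign.align_optimal(
                bseq.NucleotideSequence(a), bseq.NucleotideSequence(b), matrix,
                local=True,
                gap_penalty=(int(scoring.gap_open), int(scoring.gap_extend)),
            )[0]
            assert ours.score == pytest.approx(oracle.score)

    def test_identity_of_perfect_match(self):
        aln = smith_waterman("ACGTACGTAC", "TTACGTACGTACTT")
        assert aln.identity_pct == 100.0
        assert aln.aligned_cols == 10


def _random_genome(rng, length=20_000):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestPremirSearch:
    def test_verbatim_copy_found(self, rng):
        query = "".join(rng.choice(list("ACGT"), size=70))
        chrom = _random_genome(rng)
        chrom = chrom[:5000] + query + chrom[5000 + 70:]
        genomes = {"other": GenomeBundle("other", {"chr1": chrom})}
        hits = premir_homology_search(query, genomes)
        assert len(hits) == 1
        assert hits[0].identity_pct == 100.0
        assert hits[0].e_value < 1e-5

    def test_reverse_strand_copy_found(self, rng):
        query = "".join(rng.choice(list("ACGT"), size=70))
        chrom = _random_genome(rng)
        chrom = chrom[:8000] + revcomp(query) + chrom[8000 + 70:]
        genomes = {"other": GenomeBundle("other", {"chr1": chrom})}
        assert premir_homology_search(query, genomes)

    def test_low_identity_copy_rejected(self, rng):
        # ~45% identity: below the 50% identity filter even if it scored
        query = "".join(rng.choice(list("ACGT"), size=70))
        corrupted = list(query)
        positions = rng.choice(70, size=38, replace=False)
        for pos in positions:
            corrupted[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[corrupted[pos]]
        chrom = _random_genome(rng)
        chrom = chrom[:3000] + "".join(corrupted) + chrom[3000 + 70:]
        genomes = {"other": GenomeBundle("other", {"chr1": chrom})}
        hits = premir_homology_search(query, genomes)
        assert not [h for h in hits if h.identity_pct >= 50.0 and h.e_value <= 1e-5]

    def test_random_genomes_yield_no_hits(self, rng):
        # calibration of the E-value threshold on composition-matched noise
        query = "".join(rng.choice(list("ACGT"), size=70))
        misses = 0
        n_genomes = 30
        for _ in range(n_genomes):
            genomes = {"g": GenomeBundle("g", {"chr1": _random_genome(rng, 30_000)})}
            if not premir_homology_search(query, genomes):
                misses += 1
        assert misses >= n_genomes - 1


class TestClassification:
    def _mini_world(self, rng):
        """Three species, one shared family, one unique miRNA, one with a
        planted genomic (never expressed) precursor copy elsewhere."""
        shared_seed = "GAGGUAG"
        mirs = {
            "A": [_mir("A-shared", "A", "U" + shared_seed + "UAGGUUGUAUAGUU")],
            "B": [_mir("B-shared", "B", "C" + shared_seed + "UCGGUUGUAUACCA"),
                  _mir("B-unique", "B", "UCCGAUACGGAUUACGGACAUA"),
                  _mir("B-copy", "B", "UGGCCAUAGCAUGGAACGGAUA")],
            "C": [_mir("C-lone", "C", "AUUGUACUUCAUCAGGUGCUCU")],  # known seed
        }
        hairpins = {}
        genomes = {}
        for sp in ("A", "B", "C"):
            chrom = _random_genome(rng, 30_000)
            for i, m in enumerate(mirs[sp]):
                pre = m.sequence.replace("U", "T")
                pre = pre + "AACGAATCGA" + revcomp(pre)
                hairpins.setdefault(sp, {})[m.id] = pre
                pos = 2000 + 500 * i
                chrom = chrom[:pos] + pre + chrom[pos + len(pre):]
            genomes[sp] = chrom
        # plant a diverged copy of B-copy's precursor in genome A
        copy = list(hairpins["B"]["B-copy"])
        for pos in rng.choice(len(copy), size=4, replace=False):
            copy[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[pos]]
        genomes["A"] = genomes["A"][:15_000] + "".join(copy) + genomes["A"][15_000 + len(copy):]
        bundles = {
            sp: GenomeBundle(sp, {"chr1": chrom}) for sp, chrom in genomes.items()
        }
        known = [_mir("kno-mir-305", "known", "AUUGUACUUCAUCAGGUGCUCU")]
        return mirs, bundles, hairpins, known

    def test_tiers_and_lineage_specificity(self, rng):
        catalogs, genomes, premir_seqs, known = self._mini_world(rng)
        calls = {
            c.mirna_id: c
            for c in classify_all(catalogs, known, genomes, premir_seqs)
        }
        assert calls["A-shared"].tier == "seed_match"
        assert calls["B-shared"].tier == "seed_match"
        assert not calls["A-shared"].lineage_specific
        # known-seed match in a single species: seed_match, never lineage-specific
        assert calls["C-lone"].tier == "seed_match"
        assert not calls["C-lone"].lineage_specific
        # unexpressed genomic copy elsewhere: premir_homolog, still lineage-specific
        assert calls["B-copy"].tier == "premir_homolog"
        assert calls["B-copy"].lineage_specific
        assert "A" in calls["B-copy"].premir_hit_species
        # no seed twin, no genomic homologue
        assert calls["B-unique"].tier == "unique"
        assert calls["B-unique"].lineage_specific

    def test_upset_counts_partition_groups(self, rng):
        catalogs, genomes, premir_seqs, known = self._mini_world(rng)
        calls = classify_all(catalogs, known, genomes, premir_seqs)
        cells = upset_sets(calls)
        n_groups = len({c.group_id for c in calls})
        assert sum(cells.values()) == n_groups
        assert cells[frozenset({"A", "B"})] == 1  # the shared family
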