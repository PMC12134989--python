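"""Protein similarity, reciprocal best hits, chromosome homology, dot plots."""

import numpy as np
import pytest

from conftest import best_assignment_oracle, random_dna, rbh_oracle
from killistat.homology_synteny import (
    RbhPair,
    SimilarityHit,
    align_protein_pair,
    chromosome_homology,
    kmer_anchor_dotplot,
    reciprocal_best_hits,
    revcomp,
)


class TestAlignProteinPair:
    def test_identical_sequences(self):
        hit = align_protein_pair("MKVLNNPQ", "MKVLNNPQ")
        assert hit.identity == 1.0

    def test_single_substitution(self):
        # no-gap alignment is optimal under BLOSUM62 affine scoring
        hit = align_protein_pair("MKF", "MNF")
        assert hit.identity == pytest.approx(2 / 3)

    def test_gap_columns_count_in_denominator(self):
        hit = align_protein_pair("MKKKF", "MF")
        assert hit.identity < 1.0

    @pytest.mark.parametrize("a,b", [("", "MKF"), ("MKF", "")])
    def test_empty_sequence_rejected(self, a, b):
        with pytest.raises(ValueError):
            align_protein_pair(a, b)


def hits_from_scores(scores):
    out = []
    for (q, s), sc in scores.items():
        out.append(SimilarityHit(q, s, sc, min(1.0, sc / 100.0)))
    return out


class TestReciprocalBestHits:
    def test_two_by_two_table(self):
        scores = {
            ("A1", "B1"): 100, ("A1", "B2"): 50, ("A2", "B2"): 90, ("A2", "B1"): 40,
            ("B1", "A1"): 100, ("B2", "A1"): 50, ("B2", "A2"): 90, ("B1", "A2"): 40,
        }
        pairs = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(hits_from_scores(scores))}
        assert pairs == {("A1", "B1"), ("A2", "B2")}
        assert pairs == rbh_oracle(scores)

    def test_non_reciprocal_best_leaves_gene_unpaired(self):
        # A1's best is B1, but B1's best is A2
        scores = {
            ("A1", "B1"): 80, ("B1", "A1"): 80,
            ("A2", "B1"): 95, ("B1", "A2"): 95,
        }
        pairs = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(hits_from_scores(scores))}
        assert pairs == {("A2", "B1")}
        assert pairs == rbh_oracle(scores)

    def test_empty_input(self):
        assert reciprocal_best_hits([]) == []

    def test_self_hits_ignored(self):
        scores = {("A1", "A1"): 500, ("A1", "B1"): 10, ("B1", "A1"): 10}
        pairs = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(hits_from_scores(scores))}
        assert pairs == {("A1", "B1")}

    def test_symmetric_under_genome_swap(self):
        rng = np.random.default_rng(3)
        genes_a = [f"A{i}" for i in range(6)]
        genes_b = [f"B{i}" for i in range(6)]
        scores = {}
        for a in genes_a:
            for b in genes_b:
                sc = float(rng.integers(1, 1000))
                scores[(a, b)] = sc
                scores[(b, a)] = sc
        fwd = reciprocal_best_hits(hits_from_scores(scores))
        # feed hits in the reversed direction order
        rev = reciprocal_best_hits(list(reversed(hits_from_scores(scores))))
        assert fwd == rev
        assert {(p.gene_a, p.gene_b) for p in fwd} == rbh_oracle(scores)

    def test_matches_double_argmax_oracle_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            na, nb = rng.integers(2, 7, size=2)
            unique = iter(rng.permutation(np.arange(1, 500)))
            scores = {}
            for i in range(na):
                for j in range(nb):
                    sc = float(next(unique))
                    scores[(f"A{i}", f"B{j}")] = sc
                    scores[(f"B{j}", f"A{i}")] = sc
            got = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(hits_from_scores(scores))}
            assert got == rbh_oracle(scores)


class TestChromosomeHomology:
    def make_rbh(self, counts):
        pairs, loc_a, loc_b = [], {}, {}
        i = 0
        for (ca, cb), n in counts.items():
            for _ in range(n):
                ga, gb = f"a{i}", f"b{i}"
                pairs.append(RbhPair(ga, gb, 1.0))
                loc_a[ga], loc_b[gb] = ca, cb
                i += 1
        return pairs, loc_a, loc_b

    def test_example_counts(self):
        counts = {("c1", "d2"): 30, ("c1", "d1"): 2, ("c2", "d1"): 25}
        pairs, loc_a, loc_b = self.make_rbh(counts)
        hom = chromosome_homology(pairs, loc_a, loc_b)
        assert hom.assignment == {"c1": "d2", "c2": "d1"}
        _, oracle_map = best_assignment_oracle(counts)
        assert hom.assignment == oracle_map

    def test_single_chromosome_pair(self):
        pairs, loc_a, loc_b = self.make_rbh({("c1", "d1"): 3})
        assert chromosome_homology(pairs, loc_a, loc_b).assignment == {"c1": "d1"}

    def test_missing_location_rejected(self):
        pairs, loc_a, loc_b = self.make_rbh({("c1", "d1"): 1})
        with pytest.raises(ValueError, match="a0"):
            chromosome_homology(pairs, {}, loc_b)

    def test_greedy_equals_bruteforce_on_diagonal_instances(self):
        """On synteny-like count tables — each chromosome sharing most genes
        with one partner — greedy matches the exhaustive maximum."""
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            perm = rng.permutation(n)
            counts = {}
            for i in range(n):
                for j in range(n):
                    base = int(rng.integers(20, 60)) if perm[i] == j else int(rng.integers(0, 5))
                    if base:
                        counts[(f"c{i}", f"d{j}")] = base
            pairs, loc_a, loc_b = self.make_rbh(counts)
            hom = chromosome_homology(pairs, loc_a, loc_b)
            oracle_total, _ = best_assignment_oracle(counts)
            greedy_total = sum(c for _, _, c in hom.pairs)
            assert greedy_total == oracle_total
            # the dominant diagonal is the (unique) true pairing
            assert {a: b for a, b in hom.assignment.items()} == {
                f"c{i}": f"d{int(perm[i])}" for i in range(n)
            }


class TestDotplot:
    def test_self_comparison_covers_diagonal(self):
        rng = np.random.default_rng(1)
        s = random_dna(rng, 300)
        anchors = kmer_anchor_dotplot(s, s, k=15, max_occurrences=10)
        diag = {a.x_pos for a in anchors if a.x_pos == a.y_pos and a.strand == "+"}
        assert diag == set(range(300 - 15 + 1))

    def test_reverse_complement_gives_minus_anchors(self):
        rng = np.random.default_rng(2)
        s = random_dna(rng, 200)
        anchors = kmer_anchor_dotplot(s, revcomp(s), k=15)
        assert anchors and all(a.strand == "-" for a in anchors)
        # anti-diagonal: x + y is constant for an exact reverse complement
        assert len({a.x_pos + a.y_pos for a in anchors}) == 1

    def test_unrelated_sequences_share_nothing(self):
        rng = np.random.default_rng(3)
        anchors = kmer_anchor_dotplot(random_dna(rng, 400), random_dna(rng, 400), k=15)
        assert anchors == []

    def test_n_containing_kmers_suppressed(self):
        s = "ACGTACGTACGTACG" + "N" + "ACGTACGTACGTACG"
        anchors = kmer_anchor_dotplot(s, s, k=15)
        assert all(
            "N" not in s[a.x_pos : a.x_pos + 15] and "N" not in s[a.y_pos : a.y_pos + 15]
            for a in anchors
        )

    def test_high_copy_kmers_suppressed(self):
        s = "ACGTTGACCTGGATC" * 20  # every 15-mer occurs 20 times
        assert kmer_anchor_dotplot(s, s, k=15, max_occurrences=10) == []

    def test_transposition_symmetry(self):
        rng = np.random.default_rng(4)
        x = random_dna(rng, 150) + "TTACGGATCCGATTACA" + random_dna(rng, 150)
        y = random_dna(rng, 100) + "TTACGGATCCGATTACA" + random_dna(rng, 100)
        fwd = {(a.x_pos, a.y_pos, a.strand) for a in kmer_anchor_dotplot(x, y, k=15)}
        swapped = {(a.y_pos, a.x_pos, a.strand) for a in kmer_anchor_dotplot(y, x, k=15)}
        assert fwd == swapped

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            kmer_anchor_dotplot("ACGTACGT", "ACGTACGT", k=4)
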