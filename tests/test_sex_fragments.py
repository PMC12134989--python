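"""Marker location, X/Y calling, divergence, and pseudogene detection."""

import numpy as np
import pytest

from conftest import random_dna
from killistat.genome_io import GenomeAssembly, SeqRecord
from killistat.homology_synteny import revcomp
from killistat.sex_fragments import (
    DiagnosticFeature,
    cds_divergence,
    classify_haplotype,
    locate_marker,
    pseudogene_scan,
    region_gene_divergence,
)
from killistat.synthetic_genome import (
    SexRegionConfig,
    SimulationConfig,
    simulate_diploid_sex_region,
)

RNG = np.random.default_rng(42)
MARKER = "ATG" + random_dna(RNG, 1197)  # 1200-bp marker


def contig_with(insert, flank=800, rng=None, strand="+"):
    rng = rng or np.random.default_rng(0)
    if strand == "-":
        insert = revcomp(insert)
    left, right = random_dna(rng, flank), random_dna(rng, flank)
    return SeqRecord("c1", left + insert + right), flank, flank + len(insert)


class TestLocateMarker:
    def test_exact_planted_copy(self):
        contig, begin, end = contig_with(MARKER)
        [hit] = locate_marker(MARKER, GenomeAssembly([contig]))
        assert (hit.begin, hit.end, hit.strand) == (begin, end, "+")
        assert hit.identity == 1.0

    def test_reverse_strand_copy(self):
        contig, begin, end = contig_with(MARKER, strand="-")
        [hit] = locate_marker(MARKER, GenomeAssembly([contig]))
        assert hit.strand == "-"
        assert (hit.begin, hit.end) == (begin, end)

    def test_two_percent_substituted_copy(self):
        rng = np.random.default_rng(7)
        mutant = list(MARKER)
        sites = rng.choice(len(mutant), size=24, replace=False)  # 2% of 1200
        for i in sites:
            mutant[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[i]]
        contig, _, _ = contig_with("".join(mutant))
        [hit] = locate_marker(MARKER, GenomeAssembly([contig]))
        assert hit.identity == pytest.approx(0.98, abs=0.01)

    def test_absent_marker(self):
        rng = np.random.default_rng(8)
        contig = SeqRecord("c", random_dna(rng, 3000))
        assert locate_marker(MARKER, GenomeAssembly([contig])) == []

    def test_marker_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            locate_marker("ACGTACGT", GenomeAssembly([SeqRecord("c", "ACGT" * 100)]))


DIAGS = [
    DiagnosticFeature("cds_del", "deletion", "CDS", 9, (400, 409)),
    DiagnosticFeature("utr_del", "deletion", "UTR3", 100, (900, 1000)),
]


def delete(seq, lo, hi):
    return seq[:lo] + seq[hi:]


class TestClassifyHaplotype:
    def test_identical_region_is_x(self):
        call = classify_haplotype(MARKER, MARKER, DIAGS)
        assert call.call == "X"
        assert set(call.evidence.values()) == {"absent"}

    def test_both_deletions_is_y(self):
        region = delete(delete(MARKER, 900, 1000), 400, 409)
        call = classify_haplotype(region, MARKER, DIAGS)
        assert call.call == "Y"
        assert set(call.evidence.values()) == {"present"}

    def test_single_deletion_is_ambiguous(self):
        region = delete(MARKER, 400, 409)
        call = classify_haplotype(region, MARKER, DIAGS)
        assert call.call == "ambiguous"
        assert call.evidence == {"cds_del": "present", "utr_del": "absent"}

    def test_truncated_region_is_ambiguous(self):
        # region stops inside the UTR diagnostic: untestable, not absent
        region = delete(MARKER, 400, 409)[:940]
        call = classify_haplotype(region, MARKER, DIAGS)
        assert call.call == "ambiguous"
        assert call.evidence["utr_del"] == "untestable"

    def test_deletion_offset_by_one_still_detected(self):
        region = delete(MARKER, 401, 410)
        call = classify_haplotype(region, MARKER, [DIAGS[0]])
        assert call.evidence["cds_del"] == "present"

    def test_wrong_length_deletion_absent(self):
        region = delete(MARKER, 400, 430)  # 30 bp, expected 9
        call = classify_haplotype(region, MARKER, [DIAGS[0]])
        assert call.evidence["cds_del"] == "absent"


class TestCdsDivergence:
    def test_identical(self):
        rec = cds_divergence("ATGAAATTTCCC", "ATGAAATTTCCC")
        assert (rec.nt_divergence, rec.aa_divergence) == (0.0, 0.0)

    def test_single_nonsynonymous_substitution(self):
        rec = cds_divergence("ATGAAATTT", "ATGAACTTT")
        assert rec.nt_divergence == pytest.approx(1 / 9)
        assert rec.aa_divergence == pytest.approx(1 / 3)  # MKF vs MNF
        assert rec.substitutions == 1
        assert rec.aligned_columns == 9

    def test_synonymous_third_position_substitution(self):
        rec = cds_divergence("ATGAAATTT", "ATGAAGTTT")  # K codon AAA->AAG
        assert rec.nt_divergence == pytest.approx(1 / 9)
        assert rec.aa_divergence == 0.0

    def test_symmetry(self):
        a, b = "ATGAAATTTGGGCCC", "ATGAACTTTGGCCCC"
        r1, r2 = cds_divergence(a, b), cds_divergence(b, a)
        assert r1.nt_divergence == pytest.approx(r2.nt_divergence)
        assert r1.aa_divergence == pytest.approx(r2.aa_divergence)

    def test_indel_excluded_from_default_denominator(self):
        a = "ATGAAATTTCCCGGG"
        b = delete(a, 6, 9)
        rec = cds_divergence(a, b)
        assert rec.nt_divergence == 0.0
        assert rec.indel_events == 1
        rec2 = cds_divergence(a, b, denominator="alignment")
        assert rec2.nt_divergence == 0.0  # substitution count is still zero

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cds_divergence("", "ATG")

    def test_zero_iff_identical(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = random_dna(rng, 300)
            assert cds_divergence(s, s).nt_divergence == 0.0
            mutant = "C" + s[1:] if s[0] != "C" else "A" + s[1:]
            assert cds_divergence(s, mutant).nt_divergence > 0.0


class TestPseudogeneScan:
    def build(self, rng):
        exons = ["ATG" + random_dna(rng, 117)] + [random_dna(rng, 120) for _ in range(6)]
        spacers = [random_dna(rng, 200) for _ in range(8)]
        return exons, spacers

    def test_intact_locus_not_flagged(self):
        rng = np.random.default_rng(11)
        exons, spacers = self.build(rng)
        target = spacers[0] + "".join(e + s for e, s in zip(exons, spacers[1:]))
        rep = pseudogene_scan(exons, SeqRecord("t", target))
        assert not rep.flagged
        assert rep.exons_missing == 0 and rep.start_codon_present

    def test_ablated_start_and_missing_exons_flagged(self):
        rng = np.random.default_rng(11)
        exons, spacers = self.build(rng)
        broken = exons.copy()
        broken[0] = "ATC" + broken[0][3:]
        kept = [broken[i] for i in range(7) if i not in (2, 4, 6)]
        target = spacers[0] + "".join(e + s for e, s in zip(kept, spacers[1:]))
        rep = pseudogene_scan(exons, SeqRecord("t", target))
        assert rep.flagged
        assert rep.exons_missing == 3
        assert not rep.start_codon_present

    def test_locus_entirely_absent(self):
        rng = np.random.default_rng(12)
        exons, _ = self.build(rng)
        rep = pseudogene_scan(exons, SeqRecord("t", random_dna(rng, 3000)))
        assert rep.flagged and rep.exons_missing == rep.exons_total == 7


class TestRegionGeneDivergence:
    CFG = SimulationConfig(
        seed=31,
        sex_region=SexRegionConfig(n_genes=6, gene_nt_subst_rate=0.016),
    )

    def test_planted_rates_recovered(self):
        x, y, marker, genes, truth = simulate_diploid_sex_region(self.CFG)
        pairs = region_gene_divergence(genes, x, y)
        assert len(pairs) == 6
        for p in pairs:
            edits = truth.gene_edits[p.gene_id]
            planted = edits["substitutions"] / edits["length"]
            assert p.x is not None and p.y is not None
            assert p.x.nt_divergence == 0.0
            assert p.y.nt_divergence == pytest.approx(planted, abs=1e-4)

    def test_gene_missing_from_fragment_reported_none(self):
        x, y, marker, genes, _ = simulate_diploid_sex_region(self.CFG)
        rng = np.random.default_rng(1)
        fake = SeqRecord("empty", random_dna(rng, 5000))
        pairs = region_gene_divergence(genes[:2], x, fake)
        assert all(p.x is not None and p.y is None for p in pairs)


def test_substitution_counts_recovered_exactly_without_indels():
    """With substitutions only, the alignment recovers every planted edit."""
    rng = np.random.default_rng(202)
    L = 1500
    for r in (0.001, 0.005, 0.016):
        for _ in range(3):
            ref = "ATG" + random_dna(rng, L - 3)
            arr = list(ref)
            n_planted = 0
            for i in range(L):
                if rng.random() < r:
                    arr[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[arr[i]]
                    n_planted += 1
            rec = cds_divergence(ref, "".join(arr))
            assert rec.substitutions == n_planted
            assert rec.nt_divergence == pytest.approx(n_planted / L)
            assert rec.indel_events == 0
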