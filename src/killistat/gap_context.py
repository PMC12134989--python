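"""Classify protein-coding genes by assembly gaps in their neighborhood.

For each gene the scan asks whether at least one gap base falls within a
flanking window upstream of the gene, downstream of it, inside its coding
sequence, or inside an intron.  Upstream/downstream are strand-aware by
default (upstream = 5' of the gene span in transcription direction); the
coding-sequence check uses CDS intervals by default, with the whole-exon
variant behind a flag.  Flank windows are clipped to the scaffold but not
truncated at neighboring genes.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from .gap_metrics import find_gap_runs
from .genome_io import AnnotationSet, GeneModel, GenomeAssembly, Interval

__all__ = ["GeneGapContext", "GapContextReport", "scan_gene_context"]


@dataclass(frozen=True)
class GeneGapContext:
    gene_id: str
    has_N_upstream: bool
    has_N_downstream: bool
    has_N_cds: bool
    has_N_intron: bool


@dataclass
class GapContextReport:
    genes_considered: int
    n_upstream: int
    n_downstream: int
    n_cds: int
    n_intron: int
    flank_size: int

    def fraction(self, count: int) -> float:
        return count / self.genes_considered if self.genes_considered else 0.0


class _GapIndex:
    """Sorted gap intervals on one scaffold with O(log n) overlap queries."""

    def __init__(self, intervals: list[Interval]):
        self.starts = [s for s, _ in intervals]
        self.ends = [e for _, e in intervals]

    def overlaps(self, start: int, end: int) -> bool:
        if start >= end:
            return False
        # rightmost gap starting before `end`
        i = bisect_right(self.starts, end - 1) - 1
        return i >= 0 and self.ends[i] > start

    def overlaps_any(self, intervals: list[Interval]) -> bool:
        return any(self.overlaps(s, e) for s, e in intervals)


def _flanks(gene: GeneModel, flank: int, seq_len: int, strand_aware: bool) -> tuple[Interval, Interval]:
    left = (max(0, gene.start - flank), gene.start)
    right = (gene.end, min(seq_len, gene.end + flank))
    if strand_aware and gene.strand == "-":
        return right, left  # upstream, downstream
    return left, right


def scan_gene_context(
    assembly: GenomeAssembly,
    annotation: AnnotationSet,
    flank_size: int = 10_000,
    cds_mode: str = "cds",
    strand_aware: bool = True,
) -> tuple[GapContextReport, list[GeneGapContext]]:
    """Scan every protein-coding gene for gaps in flanks, CDS, and introns.

    ``cds_mode`` selects what the coding-sequence column means: ``"cds"``
    tests CDS intervals, ``"exon"`` tests the whole exon union.  Returns the
    summary report plus the per-gene flag list (sorted by gene id).
    """
    if cds_mode not in ("cds", "exon"):
        raise ValueError(f"cds_mode must be 'cds' or 'exon', got {cds_mode!r}")

    gap_index: dict[str, _GapIndex] = {}
    genes = sorted(annotation.protein_coding(), key=lambda g: g.gene_id)
    contexts: list[GeneGapContext] = []
    for gene in genes:
        if gene.seq_id not in assembly:
            raise ValueError(
                f"gene {gene.gene_id!r} is on unknown scaffold {gene.seq_id!r}"
            )
        if gene.seq_id not in gap_index:
            runs = find_gap_runs(assembly[gene.seq_id])
            gap_index[gene.seq_id] = _GapIndex([(g.start, g.end) for g in runs])
        gaps = gap_index[gene.seq_id]
        seq_len = len(assembly[gene.seq_id])

        upstream, downstream = _flanks(gene, flank_size, seq_len, strand_aware)
        coding = gene.cds_union() if cds_mode == "cds" else gene.exon_union()
        contexts.append(
            GeneGapContext(
                gene_id=gene.gene_id,
                has_N_upstream=gaps.overlaps(*upstream),
                has_N_downstream=gaps.overlaps(*downstream),
                has_N_cds=gaps.overlaps_any(coding),
                has_N_intron=gaps.overlaps_any(gene.introns()),
            )
        )

    report = GapContextReport(
        genes_considered=len(contexts),
        n_upstream=sum(c.has_N_upstream for c in contexts),
        n_downstream=sum(c.has_N_downstream for c in contexts),
        n_cds=sum(c.has_N_cds for c in contexts),
        n_intron=sum(c.has_N_intron for c in contexts),
        flank_size=flank_size,
    )
    return report, contexts
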