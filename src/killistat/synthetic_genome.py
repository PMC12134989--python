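"""Seeded generator of toy assemblies with complete ground truth.

The generator emulates the statistical structure the analyses assume:
multi-scaffold assemblies whose scaffolds carry protein-coding genes with
exon/intron structure on both strands, classified repeat insertions in
intergenic and intronic space, N-run gaps outside coding sequence, and a
diploid sex-determining region where a Y haplotype diverges from an X
haplotype by per-gene substitutions, short diagnostic deletions (9 bp in
the marker CDS, 241 bp in its 3'-UTR by default) and a satellite
expansion.  Every planted feature is recorded in a truth object so each
downstream stage can be validated without external data.

All randomness flows from one ``numpy`` generator seeded once; sub-steps
draw in a fixed order (plan, sequence, repeats, gaps) so identical
configurations yield byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import (
    AnnotationSet,
    GeneModel,
    GenomeAssembly,
    Interval,
    RepeatHit,
    SeqRecord,
    Transcript,
)
from .sex_fragments import DiagnosticFeature

__all__ = [
    "RepeatTemplate",
    "SexRegionConfig",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genome",
    "simulate_diploid_sex_region",
    "fragment_and_scaffold",
    "simulate_homologous_gene_sets",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class RepeatTemplate:
    name: str
    class_family: str
    length: int
    tandem_motif: str | None = None  # if set, the insert is motif repeated to length


DEFAULT_REPEAT_LIBRARY: tuple[RepeatTemplate, ...] = (
    RepeatTemplate("L2-syn1", "LINE/L2", 300),
    RepeatTemplate("SINE-syn1", "SINE/tRNA-V", 150),
    RepeatTemplate("Gypsy-syn1", "LTR/Gypsy", 400),
    RepeatTemplate("hAT-syn1", "DNA/hAT-Ac", 250),
    RepeatTemplate("TcMar-syn1", "DNA/TcMar-Tc1", 220),
    RepeatTemplate("Helitron-syn1", "RC/Helitron", 350),
    RepeatTemplate("Unknown-syn1", "Unknown", 280),
    RepeatTemplate("SAT-syn1", "Satellite", 240, tandem_motif="AACCCTG"),
    RepeatTemplate("AC-rich", "Simple_repeat", 60, tandem_motif="AC"),
)


@dataclass(frozen=True)
class SexRegionConfig:
    """Parameters of the diploid sex-determining region.

    Defaults follow the study conditions the pipeline is built around:
    ~20 genes flanking the marker, a 9-bp CDS deletion and a 241-bp 3'-UTR
    deletion diagnostic for the Y copy of the marker, a marker substitution
    rate of 1.6% with a lower background rate for the flanking genes, and a
    satellite expansion private to the Y haplotype.
    """

    n_genes: int = 20
    gene_cds_len_bp: tuple[int, int] = (300, 1500)
    gene_nt_subst_rate: float = 0.002
    marker_cds_len: int = 1500
    marker_utr3_len: int = 600
    marker_nt_subst_rate: float = 0.016
    planted_deletions: tuple[DiagnosticFeature, ...] = (
        DiagnosticFeature("cds_del_9bp", "deletion", "CDS", 9, (750, 759)),
        DiagnosticFeature("utr3_del_241bp", "deletion", "UTR3", 241, (1700, 1941)),
    )
    satellite_expansion_bp: int = 2000
    satellite_motif: str = "AACCCTG"
    flank_len: int = 2000
    spacer_len_bp: tuple[int, int] = (200, 800)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length_bp: tuple[int, int] = (30_000, 50_000)
    genes_per_chromosome: int = 8
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_len_bp: tuple[int, int] = (90, 240)
    intron_len_bp: tuple[int, int] = (100, 400)
    intergenic_len_bp: tuple[int, int] = (300, 1500)
    gc_content: float = 0.42
    repeat_library: tuple[RepeatTemplate, ...] = DEFAULT_REPEAT_LIBRARY
    repeat_insertions_per_chrom: int = 15
    gap_rate: float = 2.0e-4  # per bp of eligible (non-coding) segment
    gap_len_bp: tuple[int, int] = (50, 500)
    n_breaks: int = 5
    min_contig_bp: int = 1_000
    homolog_subst_rate: float = 0.03
    sex_region: SexRegionConfig = field(default_factory=SexRegionConfig)


@dataclass
class SyntheticTruth:
    """Ground truth recorded while planting features."""

    gap_positions: dict[str, list[Interval]] = field(default_factory=dict)
    gene_contexts: dict[str, dict[str, bool]] = field(default_factory=dict)
    repeat_intervals: list[RepeatHit] = field(default_factory=list)
    chrom_map: dict[str, str] = field(default_factory=dict)
    gene_map: dict[str, str] = field(default_factory=dict)
    haplotype_identity: dict[str, str] = field(default_factory=dict)
    marker_reference: str = ""
    diagnostics: tuple[DiagnosticFeature, ...] = ()
    gene_edits: dict[str, dict[str, int]] = field(default_factory=dict)
    satellite_interval: Interval | None = None
    contig_lengths: dict[str, int] = field(default_factory=dict)
    inserted_gap_lengths: list[int] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _tandem(motif: str, length: int) -> str:
    reps = length // len(motif) + 1
    return (motif * reps)[:length]


# ---------------------------------------------------------------------------
# Whole-genome simulation


@dataclass
class _PlannedGene:
    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    exons: list[Interval]
    introns: list[Interval]


def _plan_chromosome(
    rng: np.random.Generator, cfg: SimulationConfig, seq_id: str
) -> tuple[int, list[_PlannedGene], list[Interval], list[Interval]]:
    """Lay out genes along one chromosome.

    Returns (length, genes, intergenic segments, intron segments); segments
    are where repeats and gaps may later be planted.
    """

    def u(bounds: tuple[int, int]) -> int:
        return int(rng.integers(bounds[0], bounds[1] + 1))

    cursor = 0
    genes: list[_PlannedGene] = []
    intergenic: list[Interval] = []
    introns_all: list[Interval] = []
    for gi in range(cfg.genes_per_chromosome):
        seg = u(cfg.intergenic_len_bp)
        intergenic.append((cursor, cursor + seg))
        cursor += seg
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = u(cfg.exons_per_gene)
        start = cursor
        exons: list[Interval] = []
        introns: list[Interval] = []
        for ei in range(n_exons):
            if ei:
                ilen = u(cfg.intron_len_bp)
                introns.append((cursor, cursor + ilen))
                cursor += ilen
            elen = u(cfg.exon_len_bp)
            exons.append((cursor, cursor + elen))
            cursor += elen
        genes.append(
            _PlannedGene(
                gene_id=f"{seq_id}_g{gi + 1:02d}",
                seq_id=seq_id,
                strand=strand,
                start=start,
                end=cursor,
                exons=exons,
                introns=introns,
            )
        )
        introns_all.extend(introns)
    tail = u(cfg.intergenic_len_bp)
    intergenic.append((cursor, cursor + tail))
    cursor += tail
    target = u(cfg.chrom_length_bp)
    if cursor < target:
        intergenic[-1] = (intergenic[-1][0], target)
        cursor = target
    return cursor, genes, intergenic, introns_all


def _place_in_segments(
    rng: np.random.Generator,
    segments: list[Interval],
    length: int,
    occupied: list[Interval],
    margin: int = 1,
    attempts: int = 20,
) -> Interval | None:
    """Random placement of an interval of `length` inside one of `segments`,
    avoiding `occupied` (with a 1-bp margin so planted N-runs stay maximal)."""
    fitting = [s for s in segments if s[1] - s[0] >= length + 2 * margin]
    if not fitting:
        return None
    for _ in range(attempts):
        s, e = fitting[int(rng.integers(len(fitting)))]
        start = int(rng.integers(s + margin, e - length - margin + 1))
        iv = (start, start + length)
        if all(iv[1] + margin <= os or iv[0] >= oe + margin for os, oe in occupied):
            occupied.append(iv)
            return iv
    return None


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeAssembly, AnnotationSet, list[RepeatHit], SyntheticTruth]:
    """Simulate a gapped, repeat-bearing annotated assembly with truth.

    Genes never overlap; repeats are planted into intergenic and intronic
    space by overwriting the background sequence (so all planned
    coordinates stay fixed); gaps are planted the same way and never touch
    coding sequence, mirroring an assembly whose coding regions are
    complete but whose repeat-rich surroundings are not.
    """
    if config.n_chromosomes < 1 or config.genes_per_chromosome < 1:
        raise ValueError("need at least one chromosome and one gene per chromosome")
    min_needed = (
        config.genes_per_chromosome
        * (config.exons_per_gene[1] * config.exon_len_bp[1]
           + (config.exons_per_gene[1] - 1) * config.intron_len_bp[1])
        + (config.genes_per_chromosome + 1) * config.intergenic_len_bp[1]
    )
    if min_needed > config.chrom_length_bp[1]:
        raise ValueError(
            "infeasible config: worst-case gene layout "
            f"({min_needed} bp) exceeds the chromosome length cap "
            f"({config.chrom_length_bp[1]} bp)"
        )

    rng = np.random.default_rng(config.seed)
    records: list[SeqRecord] = []
    genes: dict[str, GeneModel] = {}
    repeat_hits: list[RepeatHit] = []
    truth = SyntheticTruth()

    for ci in range(config.n_chromosomes):
        seq_id = f"chr{ci + 1:02d}"
        length, planned, intergenic, introns = _plan_chromosome(rng, config, seq_id)
        arr = _random_seq(rng, length, config.gc_content)
        segments = intergenic + introns
        occupied: list[Interval] = []

        for _ in range(config.repeat_insertions_per_chrom):
            tmpl = config.repeat_library[int(rng.integers(len(config.repeat_library)))]
            iv = _place_in_segments(rng, segments, tmpl.length, occupied)
            if iv is None:
                continue
            if tmpl.tandem_motif:
                insert = _tandem(tmpl.tandem_motif, tmpl.length)
            else:
                insert = _to_str(_random_seq(rng, tmpl.length, 0.5))
            arr[iv[0] : iv[1]] = np.frombuffer(insert.encode(), dtype="S1")
            strand = "+" if rng.random() < 0.5 else "-"
            hit = RepeatHit(
                seq_id=seq_id,
                begin=iv[0],
                end=iv[1],
                strand=strand,
                repeat_name=tmpl.name,
                class_family=tmpl.class_family,
                divergence_pct=float(np.round(rng.uniform(0, 30), 1)),
            )
            repeat_hits.append(hit)

        gaps: list[Interval] = []
        for s, e in segments:
            if rng.random() < min(1.0, config.gap_rate * (e - s)):
                glen = int(rng.integers(config.gap_len_bp[0], config.gap_len_bp[1] + 1))
                iv = _place_in_segments(rng, [(s, e)], min(glen, e - s - 2), occupied)
                if iv is not None:
                    arr[iv[0] : iv[1]] = b"N"
                    gaps.append(iv)
        gaps.sort()
        truth.gap_positions[seq_id] = gaps

        records.append(SeqRecord(id=seq_id, seq=_to_str(arr)))
        for pg in planned:
            genes[pg.gene_id] = GeneModel(
                gene_id=pg.gene_id,
                seq_id=seq_id,
                strand=pg.strand,
                start=pg.start,
                end=pg.end,
                biotype="protein_coding",
                transcripts=[Transcript(pg.gene_id + ".t1", list(pg.exons), list(pg.exons))],
            )
            truth.gene_contexts[pg.gene_id] = _context_flags(pg, gaps, length)

    truth.repeat_intervals = list(repeat_hits)
    assembly = GenomeAssembly(records)
    return assembly, AnnotationSet(genes), repeat_hits, truth


def _context_flags(
    gene: _PlannedGene, gaps: list[Interval], seq_len: int, flank: int = 10_000
) -> dict[str, bool]:
    """Truth gap-context flags from planted coordinates (plain arithmetic)."""

    def hit(lo: int, hi: int) -> bool:
        return any(s < hi and e > lo for s, e in gaps)

    left = hit(max(0, gene.start - flank), gene.start)
    right = hit(gene.end, min(seq_len, gene.end + flank))
    upstream, downstream = (left, right) if gene.strand == "+" else (right, left)
    return {
        "has_N_upstream": upstream,
        "has_N_downstream": downstream,
        "has_N_cds": any(hit(s, e) for s, e in gene.exons),
        "has_N_intron": any(hit(s, e) for s, e in gene.introns),
    }


# ---------------------------------------------------------------------------
# Fragmentation and rescaffolding


def fragment_and_scaffold(
    assembly: GenomeAssembly, config: SimulationConfig
) -> tuple[GenomeAssembly, GenomeAssembly, SyntheticTruth]:
    """Break an assembly into contigs and rejoin them with N-run gaps.

    Break points avoid existing N bases (so planted gap runs stay maximal)
    and leave every contig at least ``min_contig_bp`` long.  The truth
    records every inserted gap; scaffolded total length equals contig total
    plus the summed gap lengths.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = SyntheticTruth()
    weights = np.array([len(r) for r in assembly.records], dtype=float)
    breaks_per_record: dict[str, list[int]] = {r.id: [] for r in assembly.records}

    placed = 0
    attempts = 0
    while placed < config.n_breaks and attempts < config.n_breaks * 50:
        attempts += 1
        rec = assembly.records[int(rng.choice(len(weights), p=weights / weights.sum()))]
        if len(rec) < 2 * config.min_contig_bp + 2:
            continue
        pos = int(rng.integers(config.min_contig_bp, len(rec) - config.min_contig_bp))
        cuts = breaks_per_record[rec.id]
        if any(abs(pos - c) < config.min_contig_bp for c in cuts):
            continue
        if "N" in rec.seq[pos - 1 : pos + 1].upper():
            continue
        cuts.append(pos)
        placed += 1

    contigs: list[SeqRecord] = []
    scaffolds: list[SeqRecord] = []
    for rec in assembly.records:
        cuts = sorted(breaks_per_record[rec.id])
        bounds = [0] + cuts + [len(rec)]
        pieces = [rec.seq[a:b] for a, b in zip(bounds, bounds[1:])]
        for i, piece in enumerate(pieces, 1):
            contigs.append(SeqRecord(id=f"{rec.id}_ctg{i}", seq=piece))
        joined: list[str] = []
        gap_positions: list[Interval] = []
        cursor = 0
        for i, piece in enumerate(pieces):
            if i:
                glen = int(rng.integers(config.gap_len_bp[0], config.gap_len_bp[1] + 1))
                gap_positions.append((cursor, cursor + glen))
                truth.inserted_gap_lengths.append(glen)
                joined.append("N" * glen)
                cursor += glen
            joined.append(piece)
            cursor += len(piece)
        scaffolds.append(SeqRecord(id=rec.id, seq="".join(joined), description=rec.description))
        truth.gap_positions[rec.id] = gap_positions
    for c in contigs:
        truth.contig_lengths[c.id] = len(c)
    return GenomeAssembly(contigs), GenomeAssembly(scaffolds), truth


# ---------------------------------------------------------------------------
# Diploid sex region


def _mutate(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, int]:
    """Substitute bases i.i.d. at ``rate``; returns (mutant, n_substitutions)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return _to_str(arr), int(len(hit))


def simulate_diploid_sex_region(
    config: SimulationConfig,
) -> tuple[SeqRecord, SeqRecord, SeqRecord, list[tuple[str, str]], SyntheticTruth]:
    """Simulate phased X and Y contigs around a sex-determining marker.

    The X contig carries the marker (CDS + 3'-UTR) and ``n_genes`` flanking
    gene CDSs over background sequence.  The Y contig is derived from it:
    per-gene substitutions at the configured rates, the planted diagnostic
    deletions inside the marker, and a satellite expansion inserted into a
    spacer.  Returns (x_contig, y_contig, x_marker_reference record,
    [(gene_id, reference CDS)], truth).
    """
    sx = config.sex_region
    for feat in sx.planted_deletions:
        lo, hi = feat.reference_coords
        if hi > sx.marker_cds_len + sx.marker_utr3_len or lo < 0:
            raise ValueError(f"deletion {feat.name} lies outside the marker")
    rng = np.random.default_rng(config.seed + 2)

    def u(bounds: tuple[int, int]) -> int:
        return int(rng.integers(bounds[0], bounds[1] + 1))

    def make_cds(length: int) -> str:
        body = _to_str(_random_seq(rng, length - 3, config.gc_content))
        return "ATG" + body

    # Plan X contig: flank, genes, marker in the middle, genes, flank.
    marker = make_cds(sx.marker_cds_len) + _to_str(
        _random_seq(rng, sx.marker_utr3_len, config.gc_content)
    )
    gene_set: list[tuple[str, str]] = [
        (f"sexg{i + 1:02d}", make_cds(u(sx.gene_cds_len_bp) // 3 * 3))
        for i in range(sx.n_genes)
    ]

    parts: list[tuple[str, str]] = [("flank", _to_str(_random_seq(rng, sx.flank_len, config.gc_content)))]
    half = sx.n_genes // 2
    for i, (gid, cds) in enumerate(gene_set):
        if i == half:
            parts.append(("spacer", _to_str(_random_seq(rng, u(sx.spacer_len_bp), config.gc_content))))
            parts.append(("marker", marker))
        parts.append(("spacer", _to_str(_random_seq(rng, u(sx.spacer_len_bp), config.gc_content))))
        parts.append((gid, cds))
    parts.append(("flank", _to_str(_random_seq(rng, sx.flank_len, config.gc_content))))

    x_seq = "".join(seq for _, seq in parts)
    truth = SyntheticTruth(
        marker_reference=marker,
        diagnostics=tuple(sx.planted_deletions),
        haplotype_identity={"x_contig": "X", "y_contig": "Y"},
    )

    # Derive Y: mutate genes and marker, apply deletions, expand satellite.
    y_parts: list[str] = []
    spacer_seen = 0
    satellite_spacer = 1  # expand the satellite in the first spacer
    y_cursor = 0
    for label, seq in parts:
        if label == "marker":
            mutant, n_sub = _mutate(rng, seq, sx.marker_nt_subst_rate)
            deleted = _apply_deletions(mutant, sx.planted_deletions)
            truth.gene_edits["marker"] = {
                "substitutions": n_sub,
                "length": len(seq),
                "deleted_bp": len(seq) - len(deleted),
            }
            y_parts.append(deleted)
            y_cursor += len(deleted)
        elif label.startswith("sexg"):
            mutant, n_sub = _mutate(rng, seq, sx.gene_nt_subst_rate)
            truth.gene_edits[label] = {"substitutions": n_sub, "length": len(seq)}
            y_parts.append(mutant)
            y_cursor += len(mutant)
        elif label == "spacer":
            spacer_seen += 1
            y_parts.append(seq)
            y_cursor += len(seq)
            if spacer_seen == satellite_spacer and sx.satellite_expansion_bp > 0:
                sat = _tandem(sx.satellite_motif, sx.satellite_expansion_bp)
                truth.satellite_interval = (y_cursor, y_cursor + len(sat))
                y_parts.append(sat)
                y_cursor += len(sat)
        else:
            y_parts.append(seq)
            y_cursor += len(seq)

    x_contig = SeqRecord(id="x_contig", seq=x_seq, description="synthetic X haplotype")
    y_contig = SeqRecord(id="y_contig", seq="".join(y_parts), description="synthetic Y haplotype")
    marker_rec = SeqRecord(id="marker_x_ref", seq=marker, description="X-reference marker (CDS+3'UTR)")
    return x_contig, y_contig, marker_rec, gene_set, truth


def _apply_deletions(seq: str, deletions: Sequence[DiagnosticFeature]) -> str:
    drop = sorted((f.reference_coords for f in deletions), reverse=True)
    for lo, hi in drop:
        seq = seq[:lo] + seq[hi:]
    return seq


# ---------------------------------------------------------------------------
# Homologous gene sets for synteny tests


def simulate_homologous_gene_sets(
    config: SimulationConfig,
) -> tuple[
    dict[str, str], dict[str, str], dict[str, str], dict[str, str], SyntheticTruth
]:
    """Two genomes' CDS sets with a known gene and chromosome homolog map.

    Genome A comes from :func:`simulate_genome`; genome B clones every gene
    with substitutions at ``homolog_subst_rate`` onto renamed, permuted
    chromosomes.  Returns (cds_a, loc_a, cds_b, loc_b, truth) where the cds
    dicts map gene id to spliced CDS nucleotide sequence and the loc dicts
    map gene id to chromosome id.
    """
    assembly, annotation, _, _ = simulate_genome(config)
    rng = np.random.default_rng(config.seed + 3)
    truth = SyntheticTruth()

    order = rng.permutation(config.n_chromosomes)
    chrom_map = {
        f"chr{i + 1:02d}": f"B_chr{int(order[i]) + 1:02d}"
        for i in range(config.n_chromosomes)
    }
    truth.chrom_map = chrom_map

    cds_a: dict[str, str] = {}
    loc_a: dict[str, str] = {}
    cds_b: dict[str, str] = {}
    loc_b: dict[str, str] = {}
    for gid, gene in sorted(annotation.genes.items()):
        chrom_seq = assembly[gene.seq_id].seq
        spliced = "".join(chrom_seq[s:e] for s, e in gene.cds_union())
        cds_a[gid] = spliced
        loc_a[gid] = gene.seq_id
        bid = "B_" + gid
        cds_b[bid], _ = _mutate(rng, spliced, config.homolog_subst_rate)
        loc_b[bid] = chrom_map[gene.seq_id]
        truth.gene_map[gid] = bid
    return cds_a, loc_a, cds_b, loc_b, truth
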