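"""Phased X/Y fragment identification and gametolog divergence.

Workflow mirrors how sex-chromosome fragments are pulled out of a phased
diploid assembly: locate a sex-linked marker gene in each haplotype contig
set, call each hit X or Y from diagnostic structural features (e.g. short
deletions fixed on the Y relative to the X-chromosomal reference), then
quantify per-gene nucleotide and amino-acid divergence between each
haplotype and the reference across the surrounding nonrecombining region.

Divergence is reported as substitutions over aligned non-gap columns by
default, so an indel does not inflate the substitution proportion; the
alignment-length denominator is available behind a flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genome_io import GenomeAssembly, SeqRecord
from .homology_synteny import revcomp

__all__ = [
    "MarkerHit",
    "DiagnosticFeature",
    "HaplotypeCall",
    "DivergenceRecord",
    "GeneDivergencePair",
    "PseudogeneReport",
    "locate_marker",
    "classify_haplotype",
    "cds_divergence",
    "pseudogene_scan",
    "region_gene_divergence",
]

SEED_K = 15


@dataclass(frozen=True)
class MarkerHit:
    contig_id: str
    begin: int
    end: int
    strand: str
    identity: float
    score: float


@dataclass(frozen=True)
class DiagnosticFeature:
    """A structural difference diagnostic for one haplotype.

    ``reference_coords`` is the half-open interval on the X-reference marker
    where the feature sits; a Y-diagnostic deletion of ``length`` bp is
    scored present when the haplotype-to-reference alignment shows a
    deletion of that length (within 1 bp) at those coordinates.
    """

    name: str
    kind: str  # deletion | insertion | substitution
    region: str  # CDS | UTR3 | UTR5 | other
    length: int
    reference_coords: tuple[int, int]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("diagnostic feature length must be >= 1")


@dataclass
class HaplotypeCall:
    contig_id: str
    call: str  # X | Y | ambiguous
    evidence: dict[str, str]  # feature name -> present | absent | untestable


@dataclass(frozen=True)
class DivergenceRecord:
    gene_id: str
    nt_divergence: float
    aa_divergence: float
    aligned_columns: int
    substitutions: int
    indel_events: int


@dataclass
class GeneDivergencePair:
    gene_id: str
    x: DivergenceRecord | None
    y: DivergenceRecord | None


@dataclass
class PseudogeneReport:
    gene_id: str
    start_codon_present: bool
    exons_total: int
    exons_missing: int
    flagged: bool = field(init=False)

    def __post_init__(self) -> None:
        self.flagged = (not self.start_codon_present) or self.exons_missing >= 1


# ---------------------------------------------------------------------------
# Seed-and-extend marker search


def _seed_clusters(query: str, text: str, k: int) -> list[tuple[int, int]]:
    """Candidate text windows from exact k-mer seed matches, merged by locality."""
    kmers: dict[str, int] = {}
    for i in range(len(query) - k + 1):
        kmers.setdefault(query[i : i + k], i)
    starts: list[int] = []
    for j in range(len(text) - k + 1):
        qoff = kmers.get(text[j : j + k])
        if qoff is not None:
            starts.append(j - qoff)  # projected query start on the text
    if not starts:
        return []
    starts.sort()
    pad = max(50, len(query) // 10)
    windows: list[tuple[int, int]] = []
    lo = hi = starts[0]
    for s in starts[1:]:
        if s - hi > len(query):
            windows.append((lo, hi))
            lo = s
        hi = s
    windows.append((lo, hi))
    return [
        (max(0, a - pad), min(len(text), b + len(query) + pad)) for a, b in windows
    ]


def _struct_aligner(mode: str) -> "Align.PairwiseAligner":
    """Affine aligner for structural comparison: cheap gap extension keeps a
    long deletion as one contiguous gap instead of smearing it over
    background sequence, and lets a local alignment cross it."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    return aligner


_LOCAL_ALIGNER = _struct_aligner("local")
_GLOBAL_STRUCT_ALIGNER = _struct_aligner("global")


def _align_in_window(
    query: str, text: str, win: tuple[int, int]
) -> tuple[int, int, float, float] | None:
    """Best local alignment of query inside text[win]; (begin, end, identity, score).

    Identity is matches over alignment columns including internal gaps, so a
    diverged copy with a long deletion scores below a mere substituted copy.
    """
    sub = text[win[0] : win[1]]
    alns = _LOCAL_ALIGNER.align(sub, query)
    if not alns or alns.score <= 0:
        return None
    aln = alns[0]
    t_blocks, q_blocks = aln.aligned
    if t_blocks.size == 0:
        return None
    begin, end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    # A local alignment trims terminal mismatches; re-extend the hit so the
    # query is fully covered, preserving the homolog's reading frame.
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    begin = max(0, begin - q_start) + win[0]
    end = min(len(sub), end + (len(query) - q_end)) + win[0]
    counts = aln.counts()
    identity = counts.identities / aln.length if aln.length else 0.0
    return begin, end, identity, float(aln.score)


def locate_marker(
    marker_cds: str | SeqRecord,
    contigs: GenomeAssembly,
    min_identity: float = 0.9,
    k: int = SEED_K,
) -> list[MarkerHit]:
    """Find a marker sequence in a contig set by seed-and-extend search.

    Exact k-mer matches seed candidate windows; each window is refined with
    a banded infix alignment.  Both strands are searched; overlapping hits
    on a contig are merged keeping the best score.  Hits below
    ``min_identity`` are dropped; the result is sorted by descending score.
    """
    marker = (marker_cds.seq if isinstance(marker_cds, SeqRecord) else marker_cds).upper()
    if len(marker) < k:
        raise ValueError(f"marker length {len(marker)} is shorter than seed k={k}")

    hits: list[MarkerHit] = []
    for rec in contigs.records:
        text = rec.seq.upper()
        per_contig: list[MarkerHit] = []
        for strand, query in (("+", marker), ("-", revcomp(marker))):
            for win in _seed_clusters(query, text, k):
                refined = _align_in_window(query, text, win)
                if refined is None:
                    continue
                begin, end, identity, score = refined
                if identity >= min_identity:
                    per_contig.append(
                        MarkerHit(rec.id, begin, end, strand, identity, score)
                    )
        hits.extend(_merge_overlapping(per_contig))
    hits.sort(key=lambda h: (-h.score, h.contig_id, h.begin))
    return hits


def _merge_overlapping(hits: list[MarkerHit]) -> list[MarkerHit]:
    kept: list[MarkerHit] = []
    for h in sorted(hits, key=lambda h: -h.score):
        if all(h.end <= k.begin or h.begin >= k.end for k in kept):
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# X/Y classification from diagnostic features


def _cigar_walk(cigar: str):
    """Yield (op, length) from an edlib extended CIGAR string."""
    for m in re.finditer(r"(\d+)([=XIDM])", cigar):
        yield m.group(2), int(m.group(1))


def classify_haplotype(
    hit_region_sequence: str,
    x_reference_marker: str,
    diagnostics: list[DiagnosticFeature],
    contig_id: str = "",
    coord_tolerance: int = 1,
) -> HaplotypeCall:
    """Call a marker hit region X or Y from diagnostic features.

    The region is globally aligned to the X reference with affine gap
    penalties (a long deletion stays one gap instead of smearing into
    scattered edits against background sequence).  A deletion diagnostic is
    "present" when the alignment shows a deletion run overlapping the
    expected reference coordinates (±``coord_tolerance`` bp) whose length is
    within 1 bp of the expected length.  Y requires every diagnostic
    present, X requires every one absent; anything else — including a
    region truncated over a diagnostic, which makes that feature
    untestable — is ambiguous.
    """
    region = hit_region_sequence.upper()
    ref = x_reference_marker.upper()
    aln = _GLOBAL_STRUCT_ALIGNER.align(ref, region)[0]
    ref_row, reg_row = str(aln[0]), str(aln[1])

    # Gap runs in reference coordinates; terminal runs mean truncation.
    deletions: list[tuple[int, int, bool]] = []  # (ref_start, length, terminal)
    insertions: list[tuple[int, int, bool]] = []
    mismatch_ref: set[int] = set()
    tpos = 0
    col = 0
    ncols = len(ref_row)
    while col < ncols:
        if reg_row[col] == "-":
            start_col, start_t = col, tpos
            while col < ncols and reg_row[col] == "-":
                tpos += ref_row[col] != "-"
                col += 1
            deletions.append(
                (start_t, tpos - start_t, start_col == 0 or col == ncols)
            )
        elif ref_row[col] == "-":
            start_col = col
            n = 0
            while col < ncols and ref_row[col] == "-":
                n += 1
                col += 1
            insertions.append((tpos, n, start_col == 0 or col == ncols))
        else:
            if ref_row[col] != reg_row[col]:
                mismatch_ref.add(tpos)
            tpos += 1
            col += 1

    evidence: dict[str, str] = {}
    for feat in diagnostics:
        lo, hi = feat.reference_coords
        lo -= coord_tolerance
        hi += coord_tolerance
        if feat.kind == "deletion":
            events = deletions
        elif feat.kind == "insertion":
            events = insertions
        else:  # substitution
            evidence[feat.name] = (
                "present" if any(p in mismatch_ref for p in range(lo, hi)) else "absent"
            )
            continue
        # Alignment wobble can split one planted indel across short
        # coincidental matches, so presence is judged on the summed gap
        # length overlapping the window, not on any single run.
        status = "absent"
        total = 0
        for start, length, terminal in events:
            span_end = start + length if feat.kind == "deletion" else start + 1
            if start < hi and span_end > lo:
                if terminal:
                    status = "untestable"
                    break
                total += length
        if status != "untestable" and total > 0 and abs(total - feat.length) <= 1:
            status = "present"
        evidence[feat.name] = status

    statuses = set(evidence.values())
    if "untestable" in statuses:
        call = "ambiguous"
    elif statuses == {"present"}:
        call = "Y"
    elif statuses == {"absent"} or not statuses:
        call = "X"
    else:
        call = "ambiguous"
    return HaplotypeCall(contig_id=contig_id, call=call, evidence=evidence)


# ---------------------------------------------------------------------------
# Divergence

_NT_ALIGNER = Align.PairwiseAligner()
_NT_ALIGNER.mode = "global"
_NT_ALIGNER.match_score = 2
_NT_ALIGNER.mismatch_score = -3
_NT_ALIGNER.open_gap_score = -5
_NT_ALIGNER.extend_gap_score = -2

_AA_ALIGNER = Align.PairwiseAligner()
_AA_ALIGNER.mode = "global"
_AA_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_AA_ALIGNER.open_gap_score = -11
_AA_ALIGNER.extend_gap_score = -1


def _pairwise_stats(row_a: str, row_b: str) -> tuple[int, int, int]:
    """(non-gap aligned columns, substitutions, indel events) from gapped rows."""
    aligned = subs = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            aligned += 1
            if ca != cb:
                subs += 1
    indels = len(re.findall(r"-+", row_a)) + len(re.findall(r"-+", row_b))
    return aligned, subs, indels


def _translate(cds: str) -> str:
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


def cds_divergence(
    cds_a: str,
    cds_b: str,
    gene_id: str = "",
    denominator: str = "aligned",
) -> DivergenceRecord:
    """Nucleotide and amino-acid divergence between two coding sequences.

    Sequences are globally aligned; nt divergence is substitutions over
    aligned non-gap columns (``denominator="alignment"`` divides by the full
    alignment length instead).  Each input is translated in frame 1 with the
    standard genetic code — partial codons at the tail are dropped — and the
    protein alignment is scored the same way for aa divergence.  Indel
    events are maximal gap runs in either row of the nucleotide alignment.
    """
    if not cds_a or not cds_b:
        raise ValueError("empty coding sequence")
    if denominator not in ("aligned", "alignment"):
        raise ValueError(f"unknown denominator mode {denominator!r}")

    aln = _NT_ALIGNER.align(cds_a.upper(), cds_b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    aligned, subs, indels = _pairwise_stats(row_a, row_b)
    nt_den = aligned if denominator == "aligned" else aln.length

    prot_a, prot_b = _translate(cds_a.upper()), _translate(cds_b.upper())
    if prot_a and prot_b:
        paln = _AA_ALIGNER.align(prot_a, prot_b)[0]
        pa, pb = str(paln[0]), str(paln[1])
        p_aligned, p_subs, _ = _pairwise_stats(pa, pb)
        p_den = p_aligned if denominator == "aligned" else paln.length
        aa_div = p_subs / p_den if p_den else 0.0
    else:
        aa_div = 0.0

    return DivergenceRecord(
        gene_id=gene_id,
        nt_divergence=subs / nt_den if nt_den else 0.0,
        aa_divergence=aa_div,
        aligned_columns=aligned,
        substitutions=subs,
        indel_events=indels,
    )


# ---------------------------------------------------------------------------
# Pseudogene detection and regional divergence


def pseudogene_scan(
    reference_exons: list[str],
    target: SeqRecord,
    gene_id: str = "",
    min_exon_identity: float = 0.8,
) -> PseudogeneReport:
    """Check a locus for pseudogenization in a target sequence.

    Each reference exon is searched in the target; exons without a hit at
    ``min_exon_identity`` count as missing.  The start codon is checked at
    the position of the first exon's hit homologous to the reference start.
    Flagged when the start codon is absent or any exon is missing.
    """
    if not reference_exons:
        raise ValueError("at least one reference exon required")
    target_asm = GenomeAssembly([target])
    missing = 0
    first_exon_region: str | None = None
    for i, exon in enumerate(reference_exons):
        hits = locate_marker(exon, target_asm, min_identity=min_exon_identity)
        if not hits:
            missing += 1
            continue
        if i == 0:
            h = hits[0]
            region = target.seq[h.begin : h.end]
            first_exon_region = revcomp(region) if h.strand == "-" else region

    start_present = False
    if first_exon_region is not None:
        start_present = _starts_with_atg(first_exon_region, reference_exons[0])
    return PseudogeneReport(
        gene_id=gene_id,
        start_codon_present=start_present,
        exons_total=len(reference_exons),
        exons_missing=missing,
    )


def _starts_with_atg(region: str, reference_exon: str) -> bool:
    """True if the region bases aligned to the reference's first codon read ATG."""
    res = edlib.align(region.upper(), reference_exon.upper(), mode="NW", task="path")
    qpos = tpos = 0
    codon: list[str] = []
    for op, n in _cigar_walk(res["cigar"]):
        for _ in range(n):
            if op in ("=", "X", "M"):
                if tpos < 3:
                    codon.append(region[qpos].upper())
                qpos += 1
                tpos += 1
            elif op == "I":
                qpos += 1
            else:  # D: reference base absent from region
                if tpos < 3:
                    return False
                tpos += 1
            if tpos >= 3 and len(codon) == 3:
                return "".join(codon) == "ATG"
    return "".join(codon) == "ATG"


def region_gene_divergence(
    gene_set: list[tuple[str, str]],
    x_fragment: SeqRecord,
    y_fragment: SeqRecord,
    min_identity: float = 0.8,
) -> list[GeneDivergencePair]:
    """Per-gene divergence of X- and Y-fragment loci against reference CDSs.

    For each (gene_id, reference CDS): locate the best hit in each fragment,
    extract its strand-corrected sequence, and compute divergence against
    the reference.  A gene without a hit in a fragment is reported with
    ``None`` for that side.
    """
    out: list[GeneDivergencePair] = []
    for gene_id, ref_cds in gene_set:
        records: dict[str, DivergenceRecord | None] = {}
        for side, frag in (("x", x_fragment), ("y", y_fragment)):
            hits = locate_marker(ref_cds, GenomeAssembly([frag]), min_identity=min_identity)
            if not hits:
                records[side] = None
                continue
            h = hits[0]
            region = frag.seq[h.begin : h.end]
            if h.strand == "-":
                region = revcomp(region)
            records[side] = cds_divergence(ref_cds, region, gene_id=gene_id)
        out.append(GeneDivergencePair(gene_id=gene_id, x=records["x"], y=records["y"]))
    return out
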