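"""Protein similarity, reciprocal best hits, and chromosome homology.

Chromosome homology between two assemblies follows the shared-gene rule:
count reciprocal-best-hit gene pairs per chromosome pair and greedily match
chromosomes in descending shared-gene order.  Exact k-mer anchors provide a
dot-plot view of homologous chromosome pairs; high-copy and N-containing
k-mers are suppressed so satellite blocks do not saturate the plot.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SimilarityHit",
    "RbhPair",
    "ChromHomologyMap",
    "AnchorPoint",
    "align_protein_pair",
    "reciprocal_best_hits",
    "chromosome_homology",
    "kmer_anchor_dotplot",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


@dataclass(frozen=True)
class RbhPair:
    gene_a: str
    gene_b: str
    score: float


@dataclass
class ChromHomologyMap:
    pairs: list[tuple[str, str, int]]  # (chrom_a, chrom_b, shared_gene_count)
    assignment: dict[str, str]


@dataclass(frozen=True)
class AnchorPoint:
    x_pos: int
    y_pos: int
    strand: str
    length: int


def _protein_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_protein_pair(
    a: str,
    b: str,
    query_id: str = "a",
    subject_id: str = "b",
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> SimilarityHit:
    """Global affine-gap protein alignment; identity over all aligned columns.

    Identity counts matches over alignment columns *including* gap columns,
    so a large indel lowers identity even when the aligned residues agree.
    """
    for name, seq in (("first", a), ("second", b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
    aligner = _protein_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        score=aln.score,
        identity=counts.identities / aln.length,
    )


def reciprocal_best_hits(hits: Iterable[SimilarityHit]) -> list[RbhPair]:
    """Pairs (a, b) where each is the other's highest-scoring hit.

    Ties on score break by higher identity, then by lexicographically
    smaller partner id; self-hits are ignored.  Each pair is reported once,
    with gene_a the lexicographically smaller member, so the output does not
    depend on which genome supplied the queries.
    """
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) > _hit_rank(cur):
            best[h.query_id] = h
    out: list[RbhPair] = []
    for q, h in best.items():
        partner = best.get(h.subject_id)
        if partner is not None and partner.subject_id == q and q < h.subject_id:
            out.append(RbhPair(q, h.subject_id, max(h.score, partner.score)))
    return sorted(out, key=lambda p: (p.gene_a, p.gene_b))


def _hit_rank(h: SimilarityHit) -> tuple[float, float, tuple[int, ...]]:
    # Lexicographically smaller subject wins ties: invert its byte ordering.
    return (h.score, h.identity, tuple(-b for b in h.subject_id.encode()))


def chromosome_homology(
    rbh: Iterable[RbhPair],
    loc_a: dict[str, str],
    loc_b: dict[str, str],
) -> ChromHomologyMap:
    """Assign homologous chromosome pairs by shared RBH gene counts.

    Greedy: sort chromosome pairs by descending shared-gene count (ties by
    chromosome id) and accept each pair whose chromosomes are both still
    free.  ``loc_a``/``loc_b`` map gene id to chromosome id; gene_a of every
    pair must be located in loc_a and gene_b in loc_b.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for pair in rbh:
        # Pairs are unordered; orient each one by location-map membership.
        if pair.gene_a in loc_a and pair.gene_b in loc_b:
            ga, gb = pair.gene_a, pair.gene_b
        elif pair.gene_b in loc_a and pair.gene_a in loc_b:
            ga, gb = pair.gene_b, pair.gene_a
        else:
            missing = pair.gene_a if pair.gene_a not in loc_a | loc_b else pair.gene_b
            raise ValueError(f"gene {missing!r} has no location in either genome")
        counts[(loc_a[ga], loc_b[gb])] += 1

    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    assignment: dict[str, str] = {}
    used_b: set[str] = set()
    pairs: list[tuple[str, str, int]] = []
    for (ca, cb), n in ordered:
        if ca in assignment or cb in used_b:
            continue
        assignment[ca] = cb
        used_b.add(cb)
        pairs.append((ca, cb, n))
    return ChromHomologyMap(pairs=pairs, assignment=assignment)


def kmer_anchor_dotplot(
    seq_x: str,
    seq_y: str,
    k: int = 15,
    max_occurrences: int = 10,
) -> list[AnchorPoint]:
    """Exact shared k-mer anchors between two sequences, both strands.

    A forward match of the y k-mer against x yields strand ``+``; a match of
    its reverse complement yields strand ``-`` (anchor coordinates are the
    k-mer start on each forward strand).  K-mers containing N, or occurring
    more than ``max_occurrences`` times in either sequence, are suppressed.
    """
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    if not seq_x or not seq_y:
        raise ValueError("sequences must be non-empty")
    sx, sy = seq_x.upper(), seq_y.upper()

    def kmer_positions(s: str) -> dict[str, list[int]]:
        pos: dict[str, list[int]] = defaultdict(list)
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" not in kmer:
                pos[kmer].append(i)
        return pos

    px = kmer_positions(sx)
    py = kmer_positions(sy)
    # Suppress saturating k-mers by forward-strand copy number in either sequence.
    anchors: list[AnchorPoint] = []
    for kmer, ys in py.items():
        if len(ys) > max_occurrences:
            continue
        for strand, xk in (("+", kmer), ("-", revcomp(kmer))):
            xs = px.get(xk)
            if not xs or len(xs) > max_occurrences:
                continue
            anchors.extend(
                AnchorPoint(x, y, strand, k) for x in xs for y in ys
            )
    anchors.sort(key=lambda a: (a.x_pos, a.y_pos, a.strand))
    return anchors
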