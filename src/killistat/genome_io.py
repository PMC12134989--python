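"""Readers and writers for the file formats the pipeline touches.

All coordinates are 0-based half-open internally; conversion from the
1-based inclusive conventions of GFF3 and RepeatMasker ``.out`` happens
here, at the file boundary, and nowhere else.  Sequence case is preserved
on I/O (soft-masking survives a round trip); analyses downstream are
case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "GenomeAssembly",
    "Transcript",
    "GeneModel",
    "AnnotationSet",
    "RepeatHit",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_blast_tab",
]

Interval = tuple[int, int]


class GenomeIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence (scaffold, contig, or marker CDS)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise GenomeIOError("sequence record with empty id")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeAssembly:
    """Ordered collection of sequence records with an id index."""

    records: list[SeqRecord]
    index: dict[str, SeqRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {}
        for rec in self.records:
            if rec.id in self.index:
                raise GenomeIOError(f"duplicate sequence id: {rec.id!r}")
            self.index[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.index

    def __getitem__(self, seq_id: str) -> SeqRecord:
        return self.index[seq_id]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def total_length(self) -> int:
        return sum(len(r) for r in self.records)


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval]
    cds: list[Interval]


@dataclass
class GeneModel:
    """One gene: genomic span, strand, biotype and its transcripts.

    Gene-level exon and CDS sets are the interval unions over transcripts,
    because the analyses operate per gene, not per isoform.
    """

    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    def exon_union(self) -> list[Interval]:
        return merge_intervals(iv for t in self.transcripts for iv in t.exons)

    def cds_union(self) -> list[Interval]:
        return merge_intervals(iv for t in self.transcripts for iv in t.cds)

    def introns(self) -> list[Interval]:
        """Gene span minus the exon union."""
        out: list[Interval] = []
        cursor = self.start
        for s, e in self.exon_union():
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < self.end:
            out.append((cursor, self.end))
        return out


@dataclass
class AnnotationSet:
    """Genes keyed by id plus a per-scaffold index."""

    genes: dict[str, GeneModel]
    by_seq: dict[str, list[GeneModel]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.by_seq = {}
        for g in self.genes.values():
            self.by_seq.setdefault(g.seq_id, []).append(g)
        for lst in self.by_seq.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def protein_coding(self) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.biotype == "protein_coding"]


@dataclass
class RepeatHit:
    """One RepeatMasker annotation row in internal coordinates."""

    seq_id: str
    begin: int
    end: int
    strand: str
    repeat_name: str
    class_family: str
    divergence_pct: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.begin < self.end:
            raise GenomeIOError(
                f"repeat hit with invalid interval [{self.begin}, {self.end}) on {self.seq_id}"
            )


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals, sorted, overlaps and abutments merged."""
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a multi-record FASTA into an assembly, preserving file order.

    Raises on an empty file or duplicate record ids.
    """
    records = [
        SeqRecord(id=r.id, seq=str(r.seq), description=_strip_id(r.description, r.id))
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise GenomeIOError(f"no FASTA records in {path}")
    return GenomeAssembly(records)


def _strip_id(description: str, rec_id: str) -> str:
    # Biopython's description includes the id itself.
    if description == rec_id:
        return ""
    if description.startswith(rec_id + " "):
        return description[len(rec_id) + 1 :]
    return description


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in assembly.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3 (NCBI RefSeq dialect: ID, Parent, gene_biotype attributes)

_GENE_TYPES = {"gene", "pseudogene"}
_TRANSCRIPT_TYPES = {
    "mRNA",
    "transcript",
    "lnc_RNA",
    "ncRNA",
    "tRNA",
    "rRNA",
    "snRNA",
    "snoRNA",
    "primary_transcript",
}


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | Path) -> AnnotationSet:
    """Read gene/mRNA/exon/CDS features from a GFF3 file.

    1-based inclusive coordinates become 0-based half-open.  Biotype comes
    from the ``gene_biotype`` attribute when present; otherwise a gene with
    at least one CDS is called protein_coding, anything else noncoding.
    A ``pseudogene`` feature type forces biotype pseudogene.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, Transcript] = {}
    transcript_parent: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seq_id, _, ftype, start_s, end_s, _, strand, _, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GenomeIOError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if end1 < start1:
                raise GenomeIOError(f"{path}:{lineno}: end < start ({end1} < {start1})")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(attr_s)

            if ftype in _GENE_TYPES:
                gid = attrs.get("ID") or attrs.get("gene_id")
                if not gid:
                    raise GenomeIOError(f"{path}:{lineno}: gene feature without ID")
                biotype = attrs.get("gene_biotype", "")
                if ftype == "pseudogene":
                    biotype = biotype or "pseudogene"
                genes[gid] = GeneModel(
                    gene_id=gid,
                    seq_id=seq_id,
                    strand=strand,
                    start=start,
                    end=end,
                    biotype=biotype,  # may be "" until inference below
                )
            elif ftype in _TRANSCRIPT_TYPES:
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if not tid or not parent:
                    raise GenomeIOError(f"{path}:{lineno}: transcript without ID/Parent")
                if parent not in genes:
                    raise GenomeIOError(
                        f"{path}:{lineno}: unresolvable Parent {parent!r} for {tid!r}"
                    )
                transcripts[tid] = Transcript(transcript_id=tid, exons=[], cds=[])
                transcript_parent[tid] = parent
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if not parent:
                    raise GenomeIOError(f"{path}:{lineno}: {ftype} without Parent")
                # NCBI exons point at the transcript; tolerate direct gene children.
                if parent in transcripts:
                    tr = transcripts[parent]
                elif parent in genes:
                    tr = transcripts.setdefault(
                        parent + ".t0", Transcript(parent + ".t0", [], [])
                    )
                    transcript_parent[parent + ".t0"] = parent
                else:
                    raise GenomeIOError(
                        f"{path}:{lineno}: unresolvable Parent {parent!r} for {ftype}"
                    )
                (tr.exons if ftype == "exon" else tr.cds).append((start, end))

    for tid, tr in transcripts.items():
        tr.exons = merge_intervals(tr.exons)
        tr.cds = merge_intervals(tr.cds)
        genes[transcript_parent[tid]].transcripts.append(tr)

    for g in genes.values():
        g.transcripts.sort(key=lambda t: t.transcript_id)
        if not g.biotype:
            g.biotype = "protein_coding" if g.cds_union() else "noncoding"
    return AnnotationSet(genes)


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    """Emit the annotation in the same NCBI-style dialect read_gff3 reads."""

    def fmt(seq_id: str, ftype: str, start: int, end: int, strand: str, attrs: str) -> str:
        return f"{seq_id}\tkillistat\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"

    lines = ["##gff-version 3"]
    for seq_id in sorted(annotation.by_seq):
        for g in annotation.by_seq[seq_id]:
            lines.append(
                fmt(
                    g.seq_id, "gene", g.start, g.end, g.strand,
                    f"ID={g.gene_id};gene_biotype={g.biotype}",
                )
            )
            for t in g.transcripts:
                t_start = min(s for s, _ in t.exons) if t.exons else g.start
                t_end = max(e for _, e in t.exons) if t.exons else g.end
                lines.append(
                    fmt(
                        g.seq_id, "mRNA", t_start, t_end, g.strand,
                        f"ID={t.transcript_id};Parent={g.gene_id}",
                    )
                )
                for s, e in t.exons:
                    lines.append(
                        fmt(g.seq_id, "exon", s, e, g.strand, f"Parent={t.transcript_id}")
                    )
                for s, e in t.cds:
                    lines.append(
                        fmt(g.seq_id, "CDS", s, e, g.strand, f"Parent={t.transcript_id}")
                    )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query            matching"
    "        repeat             position in repeat\n"
    "score   div. del. ins.  sequence  begin end          (left)   repeat"
    "          class/family      begin  end    (left)  ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` file (3 header lines, then one row per hit).

    Query begin/end (1-based inclusive) become 0-based half-open.  ``C`` in
    the orientation column is reported as strand ``-``.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], 4):
        if not line.strip():
            continue
        cols = line.split()
        if len(cols) < 11:
            raise GenomeIOError(f"{path}:{lineno}: expected >=11 columns, got {len(cols)}")
        try:
            divergence = float(cols[1])
            begin1 = int(cols[5])
            end1 = int(cols[6])
        except ValueError as exc:
            raise GenomeIOError(f"{path}:{lineno}: non-numeric coordinates") from exc
        if end1 < begin1:
            raise GenomeIOError(f"{path}:{lineno}: end < begin ({end1} < {begin1})")
        strand = "-" if cols[8] in ("C", "-") else "+"
        hits.append(
            RepeatHit(
                seq_id=cols[4],
                begin=begin1 - 1,
                end=end1,
                strand=strand,
                repeat_name=cols[9],
                class_family=cols[10],
                divergence_pct=divergence,
            )
        )
    return hits


def write_repeatmasker_out(hits: Iterable[RepeatHit], path: str | Path) -> None:
    """Emit hits in RepeatMasker ``.out`` layout (for the simulator)."""
    rows = []
    for i, h in enumerate(hits, 1):
        strand = "C" if h.strand == "-" else "+"
        rows.append(
            f"{1000:>5} {h.divergence_pct:>5.1f}  0.0  0.0  {h.seq_id:<10}"
            f"{h.begin + 1:>8} {h.end:>8} (0) {strand} {h.repeat_name:<15}"
            f" {h.class_family:<18} 1 {h.end - h.begin} (0) {i}"
        )
    Path(path).write_text(_RM_HEADER + "\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)


def read_blast_tab(path: str | Path) -> Iterator[tuple[str, str, float, float]]:
    """Yield (query_id, subject_id, identity_fraction, bitscore) from outfmt-6 TSV.

    Standard 12-column layout: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore.  Percent identity is rescaled
    to a fraction.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2, 11])
    for q, s, pid, score in df.itertuples(index=False):
        yield str(q), str(s), float(pid) / 100.0, float(score)
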