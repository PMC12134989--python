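"""Gap-run detection and assembly contiguity statistics.

A *gap* is a maximal run of N characters (case-insensitive) in a scaffold;
other IUPAC ambiguity codes do not count.  Nx statistics carry both the
length value and its 1-based rank n — the number of sequences at least that
long needed to reach the given percentage of the total — matching the
"N50 of 42,375,988 (n = 13)" style of assembly reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genome_io import GenomeAssembly, SeqRecord

__all__ = ["GapRun", "NxStat", "AssemblyReport", "find_gap_runs", "nx", "assembly_report"]

_GAP_RE = re.compile(r"[Nn]+")


@dataclass(frozen=True)
class GapRun:
    seq_id: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NxStat:
    level: float
    value: int
    rank: int


@dataclass
class AssemblyReport:
    total_length: int
    num_sequences: int
    n50: NxStat
    n90: NxStat
    total_N: int
    num_gaps: int
    per_seq_lengths: dict[str, int] = field(repr=False)
    placed_length: int = 0
    unplaced_count: int = 0
    unplaced_length: int = 0


def find_gap_runs(record: SeqRecord, min_length: int = 1) -> list[GapRun]:
    """Maximal runs of N/n in a sequence, sorted by start position.

    ``min_length`` filters short runs for sensitivity checks; the standard
    definition (any run of Ns is a gap) is the default of 1.
    """
    return [
        GapRun(record.id, m.start(), m.end())
        for m in _GAP_RE.finditer(record.seq)
        if m.end() - m.start() >= min_length
    ]


def nx(lengths: list[int], level: float) -> NxStat:
    """Nx statistic of a set of sequence lengths.

    Sort descending; the value is the length of the first sequence at which
    the cumulative sum reaches ``level`` percent of the total, and the rank
    is its 1-based position in that ordering.
    """
    if not lengths:
        raise ValueError("nx of an empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("sequence lengths must be positive")
    if not 0 < level <= 100:
        raise ValueError(f"level must be in (0, 100], got {level}")
    ordered = sorted(lengths, reverse=True)
    threshold = level / 100.0 * sum(ordered)
    cum = 0
    for i, l in enumerate(ordered, 1):
        cum += l
        if cum >= threshold:
            return NxStat(level=level, value=l, rank=i)
    raise AssertionError("unreachable: cumulative sum covers the total")


def assembly_report(
    assembly: GenomeAssembly,
    chromosome_ids: list[str] | None = None,
    exclude_ids: list[str] | None = None,
    min_gap_length: int = 1,
) -> AssemblyReport:
    """Contiguity report: lengths, N50/N90, gap and N counts, chromosome accounting.

    ``chromosome_ids`` are the records considered placed; records in neither
    list are unplaced.  ``exclude_ids`` (e.g. the mtDNA record) are dropped
    from the placed/unplaced split but still count toward the totals.
    """
    chrom = list(chromosome_ids or [])
    excl = set(exclude_ids or [])
    unknown = [c for c in chrom if c not in assembly]
    if unknown:
        raise ValueError(f"chromosome ids not in assembly: {unknown}")

    per_seq = {r.id: len(r) for r in assembly.records}
    lengths = list(per_seq.values())
    gaps = [g for r in assembly.records for g in find_gap_runs(r, min_gap_length)]
    chrom_set = set(chrom)
    unplaced = [r.id for r in assembly.records if r.id not in chrom_set and r.id not in excl]
    return AssemblyReport(
        total_length=sum(lengths),
        num_sequences=len(lengths),
        n50=nx(lengths, 50),
        n90=nx(lengths, 90),
        total_N=sum(len(g) for g in gaps),
        num_gaps=len(gaps),
        per_seq_lengths=per_seq,
        placed_length=sum(per_seq[c] for c in chrom),
        unplaced_count=len(unplaced),
        unplaced_length=sum(per_seq[u] for u in unplaced),
    )
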