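"""Aggregate RepeatMasker annotations into a repeat-landscape report.

Rows are the categories of a standard RepeatMasker summary table: the
retroelement and DNA-transposon subfamilies, rolling circles, unclassified
interspersed repeats, small RNAs, satellites, simple repeats and low
complexity.  Masked percentages use interval unions, so overlapping
annotations within a category are not double-counted, and the overall
masked percentage is the union across all categories.  The denominator is
the assembly's non-N length by convention; pass total length explicitly to
use it instead.

The class/family → category mapping ships as an editable table of glob
patterns because RepeatMasker naming varies with the repeat library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fnmatch import fnmatch
from typing import Iterable

from .genome_io import RepeatHit, merge_intervals

__all__ = [
    "CATEGORY_PARENTS",
    "DEFAULT_CLASS_MAP",
    "RepeatCategoryStats",
    "RepeatSummaryReport",
    "categorize",
    "summarize_repeats",
]

# Category -> parent grouping (None = top-level row).
CATEGORY_PARENTS: dict[str, str | None] = {
    "SINEs": "Retroelements",
    "LINEs": "Retroelements",
    "LTR elements": "Retroelements",
    "hobo-Activator": "DNA transposons",
    "Tc1-IS630-Pogo": "DNA transposons",
    "En-Spm": "DNA transposons",
    "MULE-MuDR": "DNA transposons",
    "PiggyBac": "DNA transposons",
    "Tourist/Harbinger": "DNA transposons",
    "DNA-other": "DNA transposons",
    "Rolling-circles": None,
    "Unclassified": None,
    "Small RNA": None,
    "Satellites": None,
    "Simple repeats": None,
    "Low complexity": None,
}

INTERSPERSED = {
    c for c, p in CATEGORY_PARENTS.items()
    if p in ("Retroelements", "DNA transposons")
} | {"Rolling-circles", "Unclassified"}

# First matching glob pattern wins; order matters.
DEFAULT_CLASS_MAP: list[tuple[str, str]] = [
    ("SINE*", "SINEs"),
    ("LINE*", "LINEs"),
    ("LTR*", "LTR elements"),
    ("Retroposon*", "LINEs"),
    ("DNA/hAT*", "hobo-Activator"),
    ("DNA/TcMar*", "Tc1-IS630-Pogo"),
    ("DNA/CMC-EnSpm*", "En-Spm"),
    ("DNA/En-Spm*", "En-Spm"),
    ("DNA/MULE*", "MULE-MuDR"),
    ("DNA/MuDR*", "MULE-MuDR"),
    ("DNA/PiggyBac*", "PiggyBac"),
    ("DNA/PIF-Harbinger*", "Tourist/Harbinger"),
    ("DNA/Harbinger*", "Tourist/Harbinger"),
    ("DNA/Tourist*", "Tourist/Harbinger"),
    ("DNA*", "DNA-other"),
    ("RC/Helitron*", "Rolling-circles"),
    ("RC*", "Rolling-circles"),
    ("Unknown*", "Unclassified"),
    ("Unspecified*", "Unclassified"),
    ("snRNA*", "Small RNA"),
    ("tRNA*", "Small RNA"),
    ("rRNA*", "Small RNA"),
    ("srpRNA*", "Small RNA"),
    ("scRNA*", "Small RNA"),
    ("Satellite*", "Satellites"),
    ("Simple_repeat*", "Simple repeats"),
    ("Low_complexity*", "Low complexity"),
]


@dataclass
class RepeatCategoryStats:
    name: str
    element_count: int = 0
    masked_bases: int = 0
    pct_of_sequence: float = 0.0


@dataclass
class RepeatSummaryReport:
    categories: dict[str, RepeatCategoryStats]
    parents: dict[str, RepeatCategoryStats]
    total_interspersed_pct: float
    overall_masked_pct: float
    overall_masked_bases: int
    denominator_bases: int
    unmapped_class_families: list[str] = field(default_factory=list)


def categorize(
    class_family: str, class_map: list[tuple[str, str]] | None = None
) -> str | None:
    """Map a RepeatMasker class/family string to a report category."""
    for pattern, category in class_map or DEFAULT_CLASS_MAP:
        if fnmatch(class_family, pattern):
            return category
    return None


def summarize_repeats(
    hits: Iterable[RepeatHit],
    denominator_bases: int,
    seq_lengths: dict[str, int] | None = None,
    class_map: list[tuple[str, str]] | None = None,
) -> RepeatSummaryReport:
    """Build the repeat-landscape table from annotation rows.

    ``denominator_bases`` is the sequence total the percentages refer to
    (non-N assembly length by convention).  When ``seq_lengths`` is given,
    hits extending beyond a sequence raise.  Hits whose class/family maps to
    no category are skipped and listed in ``unmapped_class_families``.
    """
    if denominator_bases <= 0:
        raise ValueError("denominator_bases must be positive")

    cats = {name: RepeatCategoryStats(name) for name in CATEGORY_PARENTS}
    per_cat_intervals: dict[str, dict[str, list[tuple[int, int]]]] = {
        name: {} for name in CATEGORY_PARENTS
    }
    all_intervals: dict[str, list[tuple[int, int]]] = {}
    unmapped: list[str] = []

    for hit in hits:
        if seq_lengths is not None:
            length = seq_lengths.get(hit.seq_id)
            if length is not None and hit.end > length:
                raise ValueError(
                    f"repeat hit [{hit.begin}, {hit.end}) exceeds {hit.seq_id} length {length}"
                )
        category = categorize(hit.class_family, class_map)
        if category is None:
            if hit.class_family not in unmapped:
                unmapped.append(hit.class_family)
            continue
        cats[category].element_count += 1
        per_cat_intervals[category].setdefault(hit.seq_id, []).append((hit.begin, hit.end))
        all_intervals.setdefault(hit.seq_id, []).append((hit.begin, hit.end))

    for name, stats in cats.items():
        stats.masked_bases = sum(
            e - s
            for ivs in per_cat_intervals[name].values()
            for s, e in merge_intervals(ivs)
        )
        stats.pct_of_sequence = 100.0 * stats.masked_bases / denominator_bases

    parents: dict[str, RepeatCategoryStats] = {}
    for parent in ("Retroelements", "DNA transposons"):
        children = [c for c, p in CATEGORY_PARENTS.items() if p == parent]
        parents[parent] = RepeatCategoryStats(
            name=parent,
            element_count=sum(cats[c].element_count for c in children),
            masked_bases=sum(cats[c].masked_bases for c in children),
            pct_of_sequence=sum(cats[c].pct_of_sequence for c in children),
        )

    overall_masked = sum(
        e - s for ivs in all_intervals.values() for s, e in merge_intervals(ivs)
    )
    interspersed_pct = sum(cats[c].pct_of_sequence for c in INTERSPERSED)
    return RepeatSummaryReport(
        categories=cats,
        parents=parents,
        total_interspersed_pct=interspersed_pct,
        overall_masked_pct=100.0 * overall_masked / denominator_bases,
        overall_masked_bases=overall_masked,
        denominator_bases=denominator_bases,
        unmapped_class_families=unmapped,
    )
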