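"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately use brute-force or one-pass formulations that are
independent of the library's implementations: gap runs by a character scan,
Nx by an explicit cumulative sum, interval unions by a boolean mask, and
chromosome assignment by exhaustive enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from killistat.synthetic_genome import SimulationConfig, simulate_genome

# --- small-but-representative simulation, shared across tests -------------

SMALL_CFG = SimulationConfig(
    seed=101,
    n_chromosomes=2,
    genes_per_chromosome=5,
    chrom_length_bp=(15_000, 25_000),
    repeat_insertions_per_chrom=10,
    gap_rate=5.0e-4,
    n_breaks=3,
)


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(SMALL_CFG)


# --- oracles ----------------------------------------------------------------


def gap_runs_oracle(seq: str) -> list[tuple[int, int]]:
    """One-pass character scan for maximal N-runs."""
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c in "Nn":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def nx_oracle(lengths: list[int], level: float) -> tuple[int, int]:
    """Explicit cumulative-sum Nx: (value, 1-based rank)."""
    ordered = sorted(lengths, reverse=True)
    cum = np.cumsum(ordered)
    idx = int(np.argmax(cum >= level / 100.0 * cum[-1]))
    return ordered[idx], idx + 1


def interval_union_oracle(intervals: list[tuple[int, int]], size: int) -> int:
    """Union length of half-open intervals via a boolean mask."""
    mask = np.zeros(size, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())


def best_assignment_oracle(
    counts: dict[tuple[str, str], int]
) -> tuple[int, dict[str, str]]:
    """Exhaustive maximum-weight injective chromosome assignment."""
    chroms_a = sorted({a for a, _ in counts})
    chroms_b = sorted({b for _, b in counts})
    best_total, best_map = -1, {}
    k = min(len(chroms_a), len(chroms_b))
    for subset_a in itertools.combinations(chroms_a, k):
        for perm_b in itertools.permutations(chroms_b, k):
            total = sum(counts.get((a, b), 0) for a, b in zip(subset_a, perm_b))
            if total > best_total:
                best_total = total
                best_map = {
                    a: b for a, b in zip(subset_a, perm_b) if counts.get((a, b), 0) > 0
                }
    return best_total, best_map


def rbh_oracle(score: dict[tuple[str, str], float]) -> set[tuple[str, str]]:
    """Reciprocal best hits by explicit double argmax over a score table."""
    queries = {q for q, _ in score}
    subjects = {s for _, s in score}
    out = set()
    for q in queries:
        partners = [(s, sc) for (qq, s), sc in score.items() if qq == q]
        best_s = max(partners, key=lambda p: (p[1], tuple(-b for b in p[0].encode())))[0]
        back = [(qq, sc) for (qq, s), sc in score.items() if s == q and qq == best_s]
        fwd = [(s, sc) for (qq, s), sc in score.items() if qq == best_s]
        if not fwd:
            continue
        best_back = max(fwd, key=lambda p: (p[1], tuple(-b for b in p[0].encode())))[0]
        if best_back == q:
            out.add(tuple(sorted((q, best_s))))
    return out


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    arr = np.frombuffer(alphabet.encode(), dtype="S1")
    return rng.choice(arr, size=n).tobytes().decode()
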