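"""Contig-level assembly statistics.

Assemblies are compared after two filters that remove uninformative
records: contigs shorter than 100 bases, and singletons (reads that were
never joined to anything — identified by an assembler-specific id
pattern such as MIRA's ``_s`` suffix, or from an ACE layout when one is
available).  On the filtered set the module computes the usual summary
numbers — contig count, total span, counts and bases at >= 1 kb, max and
mean length, N50 and the number of contigs in the N50 — plus the
cumulative-length curve used to visualise length distributions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .formats import SeqRecord
from .util import round_half_away

__all__ = [
    "DEFAULT_MIN_CONTIG_LEN",
    "ContigSet",
    "AssemblyMetrics",
    "filter_contigs",
    "n50",
    "summary_metrics",
    "cumulative_curve",
]

DEFAULT_MIN_CONTIG_LEN = 100


@dataclass
class ContigSet:
    """A named collection of contigs from one assembly."""

    name: str
    records: list[SeqRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
            raise ValueError(f"{self.name}: duplicate contig ids {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lengths(self) -> list[int]:
        return [len(r) for r in self.records]

    @property
    def total_bases(self) -> int:
        return sum(len(r) for r in self.records)

    def ids(self) -> set[str]:
        return {r.id for r in self.records}


@dataclass
class AssemblyMetrics:
    n_contigs: int
    total_bases: int
    n_ge_1kb: int
    bases_ge_1kb: int
    max_len: int
    mean_len: int  # nearest integer, half away from zero
    n50_len: int
    n50_count: int


def filter_contigs(
    records: Sequence[SeqRecord],
    name: str = "assembly",
    min_len: int = DEFAULT_MIN_CONTIG_LEN,
    singleton_id_pattern: str | None = None,
) -> ContigSet:
    """Drop short contigs and singletons before any comparison.

    ``singleton_id_pattern`` is a regex matched with ``re.search``
    against contig ids (e.g. ``r'_s\\d*$'`` for MIRA, whose ``_s``
    records are unassembled reads; ``_c`` records are true contigs).
    """
    pat = re.compile(singleton_id_pattern) if singleton_id_pattern else None
    kept = [
        r
        for r in records
        if len(r) >= min_len and (pat is None or not pat.search(r.id))
    ]
    return ContigSet(name=name, records=kept)


def n50(lengths: Sequence[int]) -> tuple[int, int]:
    """N50 length and the number of contigs in the N50.

    Sort descending and accumulate until the running total first reaches
    half the assembly span; the contig that crosses the half-way point
    defines the N50 length, and the count includes it.  The half-total
    comparison is done in exact integer arithmetic (2*cum >= total), so
    even totals are unambiguous.
    """
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    if min(lengths) <= 0:
        raise ValueError("contig lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    cum = 0
    for i, ln in enumerate(ordered, start=1):
        cum += ln
        if 2 * cum >= total:
            return ln, i
    raise AssertionError("unreachable")  # pragma: no cover


def summary_metrics(cs: ContigSet) -> AssemblyMetrics:
    """All summary statistics for one (already filtered) contig set."""
    if not cs.records:
        raise ValueError(f"{cs.name}: no contigs to summarize")
    lengths = cs.lengths
    total = sum(lengths)
    ge_1kb = [ln for ln in lengths if ln >= 1000]
    n50_len, n50_count = n50(lengths)
    return AssemblyMetrics(
        n_contigs=len(lengths),
        total_bases=total,
        n_ge_1kb=len(ge_1kb),
        bases_ge_1kb=sum(ge_1kb),
        max_len=max(lengths),
        mean_len=int(round_half_away(total / len(lengths), 0)),
        n50_len=n50_len,
        n50_count=n50_count,
    )


def cumulative_curve(cs: ContigSet) -> list[tuple[int, int]]:
    """(contig length, cumulative bases) in ascending length order.

    One point per contig; the last cumulative value equals the total
    assembly span.
    """
    out: list[tuple[int, int]] = []
    cum = 0
    for ln in sorted(cs.lengths):
        cum += ln
        out.append((ln, cum))
    return out
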