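"""Read pre-processing: adapter masking, trim-point selection, N filter.

cDNA libraries built with template-switching kits carry the same short
adapter at both ends of every read.  The pipeline implemented here
mirrors common 454-era practice: align the adapter against each read
externally (BLASTN), mask every hit whose bit-score exceeds a threshold
(default 25, strictly greater), keep the **longest unmasked portion** of
the read as the new trim window, and finally discard any read whose
trimmed sequence contains more than one ``N``.  Poly(A/T) tails are
deliberately left untouched: they are informative about transcript ends
and assemblers handle them, so no poly(A/T) clipping happens anywhere in
this module.  The single allowed ``N`` accommodates the degenerate
oligo-dT priming artifact that places one N mid-way through a poly(A)
run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats import AlignmentRecord, ResolvableError, SeqRecord

__all__ = [
    "DEFAULT_MIN_BITSCORE",
    "DEFAULT_MAX_N",
    "MaskSet",
    "TrimSpec",
    "TrimStats",
    "mask_from_hits",
    "longest_unmasked",
    "n_filter",
    "build_trim_specs",
    "apply_trims",
    "length_histogram",
]

DEFAULT_MIN_BITSCORE = 25.0
DEFAULT_MAX_N = 1


@dataclass
class MaskSet:
    """Disjoint, sorted masked intervals on one read (0-based half-open)."""

    read_id: str
    read_len: int
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.intervals:
            if not (0 <= s < e <= self.read_len):
                raise ValueError(
                    f"{self.read_id}: mask [{s},{e}) outside read of "
                    f"length {self.read_len}"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.read_id}: mask intervals overlap")
            prev_end = e

    @property
    def masked_bases(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class TrimSpec:
    """The trim window chosen for one read; ``keep=False`` drops it."""

    read_id: str
    start: int
    end: int
    keep: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"{self.read_id}: bad trim window")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TrimStats:
    reads_in: int
    reads_kept: int
    bases_kept: int
    mean_len: float  # of kept reads, 2 decimals
    median_len: int  # lower middle for even counts


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def mask_from_hits(
    read_id: str,
    read_len: int,
    hits: Sequence[AlignmentRecord],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
) -> MaskSet:
    """Mask the read intervals of adapter hits above the bit-score cut.

    ``hits`` are adapter-vs-read alignments with the read as the query.
    Only hits with bit-score **strictly greater** than ``min_bitscore``
    mask; a hit at exactly the threshold leaves the read untouched.
    Overlapping hit intervals are merged.
    """
    keep: list[tuple[int, int]] = []
    for h in hits:
        if h.bit_score is None:
            raise ResolvableError(
                f"{read_id}: adapter hit without a bit-score"
            )
        if h.bit_score <= min_bitscore:
            continue
        if not (0 <= h.q_start < h.q_end <= read_len):
            raise ValueError(
                f"{read_id}: hit interval [{h.q_start},{h.q_end}) outside "
                f"read of length {read_len}"
            )
        keep.append((h.q_start, h.q_end))
    return MaskSet(read_id=read_id, read_len=read_len, intervals=_merge_intervals(keep))


def longest_unmasked(read_len: int, mask: MaskSet) -> TrimSpec:
    """Pick the longest mask-free window as the new trim points.

    Ties are broken toward the leftmost window.  A fully-masked read
    gets ``keep=False``.
    """
    gaps: list[tuple[int, int]] = []
    pos = 0
    for s, e in mask.intervals:
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < read_len:
        gaps.append((pos, read_len))
    if not gaps:
        return TrimSpec(read_id=mask.read_id, start=0, end=0, keep=False)
    best = max(gaps, key=lambda g: g[1] - g[0])  # max is stable: leftmost tie
    return TrimSpec(read_id=mask.read_id, start=best[0], end=best[1], keep=True)


def n_filter(seq: str, max_n: int = DEFAULT_MAX_N) -> bool:
    """True (keep) iff the sequence has at most ``max_n`` Ns (any case)."""
    return seq.upper().count("N") <= max_n


def build_trim_specs(
    records: Sequence[SeqRecord],
    adapter_hits: Sequence[AlignmentRecord],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    max_n: int = DEFAULT_MAX_N,
) -> list[TrimSpec]:
    """Run masking, window selection and the N filter for every read.

    The N filter is applied to the *trimmed* sequence, after the window
    is chosen, so adapter bases cannot cause a discard.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    for h in adapter_hits:
        by_read.setdefault(h.query_id, []).append(h)
    specs: list[TrimSpec] = []
    for rec in records:
        mask = mask_from_hits(
            rec.id, len(rec), by_read.get(rec.id, []), min_bitscore
        )
        spec = longest_unmasked(len(rec), mask)
        if spec.keep and not n_filter(rec.seq[spec.start : spec.end], max_n):
            spec.keep = False
        specs.append(spec)
    return specs


def _median_lower(values: list[int]) -> int:
    values = sorted(values)
    return values[(len(values) - 1) // 2]


def apply_trims(
    records: Sequence[SeqRecord], trims: Sequence[TrimSpec]
) -> tuple[list[SeqRecord], TrimStats]:
    """Slice every record to its trim window and tally the outcome.

    Quality scores are sliced identically.  The mean kept length is
    reported to 2 decimals; the median uses the lower of the two middle
    values for even counts.
    """
    by_id = {t.read_id: t for t in trims}
    unknown = set(by_id) - {r.id for r in records}
    if unknown:
        raise ResolvableError(
            f"trim specs for unknown read ids: {sorted(unknown)[:10]}"
        )
    missing = [r.id for r in records if r.id not in by_id]
    if missing:
        raise ResolvableError(
            f"records without a trim spec: {missing[:10]}"
        )
    kept: list[SeqRecord] = []
    for rec in records:
        t = by_id[rec.id]
        if not t.keep or t.length == 0:
            continue
        if t.end > len(rec):
            raise ValueError(
                f"{rec.id}: trim window [{t.start},{t.end}) exceeds read "
                f"length {len(rec)}"
            )
        kept.append(
            SeqRecord(
                id=rec.id,
                seq=rec.seq[t.start : t.end],
                description=rec.description,
                qual=None if rec.qual is None else rec.qual[t.start : t.end],
            )
        )
    lens = [len(r) for r in kept]
    stats = TrimStats(
        reads_in=len(records),
        reads_kept=len(kept),
        bases_kept=sum(lens),
        mean_len=round(sum(lens) / len(lens), 2) if lens else 0.0,
        median_len=_median_lower(lens) if lens else 0,
    )
    return kept, stats


def length_histogram(
    records: Sequence[SeqRecord], bin_width: int
) -> list[tuple[int, int]]:
    """Histogram of read lengths over half-open bins [k*w, (k+1)*w).

    Bins with zero count are omitted; returned in ascending bin order.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    counts: dict[int, int] = {}
    for r in records:
        b = (len(r) // bin_width) * bin_width
        counts[b] = counts.get(b, 0) + 1
    return sorted(counts.items())
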