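"""Reference-coverage, novelty and read-usage statistics.

Three ways of scoring an assembly against something else:

* **Reference recovery** — align contigs to a reference set (EST
  clusters by BLAT, proteomes by BLASTX) and report the fraction of
  targets hit and of target bases covered, plus the stricter variants
  where a target only counts if a *single* alignment record (one PSL
  record, one HSP) covers at least 80% of it.  Grouped references
  (gene-family tribes, KOGs) count a group as hit when any member is.
* **Novel bases** — for an ordered pair of assemblies, the bases of the
  "other" assembly's contigs covered by no alignment to the focal
  assembly.  The matrix is asymmetric by construction.
* **Mapping stats** — from a read-vs-assembly SAM, how many distinct
  reads mapped at all, and how many mapped to more than one place.

All intervals are the 0-based half-open plus-strand convention of
:mod:`asmeval.formats`.  For translated searches target coverage is
measured in residues on the target; novelty is always measured on the
query (nucleotide) side, so units never mix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formats import AlignmentRecord, ResolvableError, SamHit
from .metrics import ContigSet
from .util import round_half_away

__all__ = [
    "DEFAULT_COV_THRESHOLD",
    "DEFAULT_MAX_EVALUE",
    "ReferenceSet",
    "CoverageSummary",
    "NoveltyResult",
    "MappingStats",
    "union_len",
    "filter_hits",
    "coverage_report",
    "grouped_hit_report",
    "novel_bases",
    "mapping_stats",
]

DEFAULT_COV_THRESHOLD = 0.8
DEFAULT_MAX_EVALUE = 1e-5


@dataclass
class ReferenceSet:
    """Targets with lengths (bases or residues) and optional grouping."""

    name: str
    targets: dict[str, int]
    group_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        bad = [t for t, ln in self.targets.items() if ln <= 0]
        if bad:
            raise ValueError(f"{self.name}: non-positive target lengths: {bad[:5]}")
        if self.group_map is not None:
            orphans = set(self.group_map) - set(self.targets)
            if orphans:
                raise ValueError(
                    f"{self.name}: group_map ids not in targets: "
                    f"{sorted(orphans)[:5]}"
                )

    @property
    def total_bases(self) -> int:
        return sum(self.targets.values())


@dataclass
class CoverageSummary:
    """Percentages (1 decimal) for one assembly vs one reference set."""

    pct_targets_hit: float
    pct_bases_covered: float
    pct_targets_hit_80: float
    pct_bases_covered_80: float


@dataclass
class NoveltyResult:
    focal: str
    other: str
    novel_bases: int
    other_total: int

    @property
    def fraction(self) -> float:
        return self.novel_bases / self.other_total if self.other_total else 0.0


@dataclass
class MappingStats:
    reads_used: int
    multi_hit: int


def union_len(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the set-union of half-open intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if s >= e:
            raise ValueError(f"invalid interval [{s},{e})")
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def filter_hits(
    hits: Sequence[AlignmentRecord],
    max_evalue: float | None = DEFAULT_MAX_EVALUE,
) -> list[AlignmentRecord]:
    """Keep hits with e-value strictly below ``max_evalue``.

    With ``max_evalue=None`` the filter is disabled and records without
    e-values (e.g. PSL) pass untouched; when the filter is active a
    record lacking an e-value is an error rather than a silent pass.
    """
    if max_evalue is None:
        return list(hits)
    missing = [h for h in hits if h.e_value is None]
    if missing:
        raise ResolvableError(
            "e-value filter requested but records lack e-values "
            f"(first: {missing[0].query_id} vs {missing[0].target_id})"
        )
    return [h for h in hits if h.e_value < max_evalue]


def _pct(numer: float, denom: float) -> float:
    return round_half_away(100.0 * numer / denom, 1)


def _check_targets(hits: Sequence[AlignmentRecord], refset: ReferenceSet) -> None:
    unknown = {h.target_id for h in hits} - set(refset.targets)
    if unknown:
        raise ResolvableError(
            f"hits to targets absent from reference set {refset.name!r}: "
            f"{sorted(unknown)[:10]}"
        )


def coverage_report(
    hits: Sequence[AlignmentRecord],
    refset: ReferenceSet,
    cov_threshold: float = DEFAULT_COV_THRESHOLD,
) -> CoverageSummary:
    """Targets-hit and bases-covered percentages, plain and 80%-rule.

    The plain percentages count every hit; base coverage is the union of
    target-side spans per target, summed over all targets.  The ``_80``
    variants admit only hits whose **single-record** target coverage
    ``(t_end - t_start) / target_len`` reaches ``cov_threshold``: a
    target qualifies when at least one such hit exists, and base
    coverage is the union over qualifying hits only.  Two 50% hits never
    qualify a target, however completely they tile it.
    """
    if not refset.targets:
        raise ValueError(f"{refset.name}: empty reference set")
    _check_targets(hits, refset)
    by_target: dict[str, list[AlignmentRecord]] = {}
    for h in hits:
        by_target.setdefault(h.target_id, []).append(h)
    n_targets = len(refset.targets)
    total_len = refset.total_bases
    n_hit = len(by_target)
    covered = sum(
        union_len((h.t_start, h.t_end) for h in th)
        for th in by_target.values()
    )
    n_hit_80 = 0
    covered_80 = 0
    for tid, th in by_target.items():
        tlen = refset.targets[tid]
        qual = [h for h in th if (h.t_end - h.t_start) / tlen >= cov_threshold]
        if qual:
            n_hit_80 += 1
            covered_80 += union_len((h.t_start, h.t_end) for h in qual)
    return CoverageSummary(
        pct_targets_hit=_pct(n_hit, n_targets),
        pct_bases_covered=_pct(covered, total_len),
        pct_targets_hit_80=_pct(n_hit_80, n_targets),
        pct_bases_covered_80=_pct(covered_80, total_len),
    )


def grouped_hit_report(
    hits: Sequence[AlignmentRecord],
    refset: ReferenceSet,
    cov_threshold: float = DEFAULT_COV_THRESHOLD,
) -> tuple[float, float]:
    """Percent of groups hit, plain and under the single-hit 80% rule.

    A group (tribe, KOG) is hit when **any** member target is hit;
    denominators are the number of distinct groups.
    """
    if refset.group_map is None:
        raise ResolvableError(
            f"{refset.name}: grouped report requested but no group_map"
        )
    _check_targets(hits, refset)
    groups = set(refset.group_map.values())
    if not groups:
        raise ValueError(f"{refset.name}: group_map has no groups")
    hit_groups: set[str] = set()
    hit_groups_80: set[str] = set()
    for h in hits:
        g = refset.group_map.get(h.target_id)
        if g is None:
            continue  # targets outside the grouping don't count
        hit_groups.add(g)
        if (h.t_end - h.t_start) / refset.targets[h.target_id] >= cov_threshold:
            hit_groups_80.add(g)
    return _pct(len(hit_groups), len(groups)), _pct(len(hit_groups_80), len(groups))


def novel_bases(
    other: ContigSet,
    hits_other_vs_focal: Sequence[AlignmentRecord],
    focal_name: str = "focal",
) -> NoveltyResult:
    """Bases of ``other`` with no alignment to the focal assembly.

    ``hits_other_vs_focal`` must have the *other* assembly's contigs as
    queries and the focal assembly's contigs as targets.  Each contig
    contributes its length minus the union of its query-side aligned
    intervals; contigs with no hits contribute their full length.
    """
    known = other.ids()
    unknown = {h.query_id for h in hits_other_vs_focal} - known
    if unknown:
        raise ResolvableError(
            f"alignment queries absent from assembly {other.name!r}: "
            f"{sorted(unknown)[:10]}"
        )
    by_query: dict[str, list[tuple[int, int]]] = {}
    for h in hits_other_vs_focal:
        by_query.setdefault(h.query_id, []).append((h.q_start, h.q_end))
    novel = 0
    for rec in other.records:
        iv = by_query.get(rec.id)
        novel += len(rec) - (union_len(iv) if iv else 0)
    return NoveltyResult(
        focal=focal_name,
        other=other.name,
        novel_bases=novel,
        other_total=other.total_bases,
    )


def mapping_stats(samhits: Sequence[SamHit]) -> MappingStats:
    """Distinct reads with >=1 mapped hit, and with >=2 (multi-hit).

    Secondary alignments count toward multi-hit status; unmapped
    records never count.
    """
    counts: dict[str, int] = {}
    for h in samhits:
        if h.mapped:
            counts[h.read_id] = counts.get(h.read_id, 0) + 1
    used = len(counts)
    multi = sum(1 for c in counts.values() if c >= 2)
    return MappingStats(reads_used=used, multi_hit=multi)
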