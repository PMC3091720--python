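"""Assembly merging: pooling pseudo-reads and extracting robust contigs.

Different assemblers make different mistakes, so a contig reconstructed
independently by two of them is far more credible than one seen only
once.  The merging protocol: take the contigs of two (or more)
first-order assemblies, tag each with its source, pool them as
**pseudo-reads**, co-assemble the pool with a conventional OLC assembler
(CAP3 with default settings), and keep only the second-order contigs
whose members come from at least two — or, for three-way merges, all —
constituent assemblies.  These are the *robust contigs*.

The co-assembly itself is external; this module prepares its input
(tagged FASTA, optionally with uniform qualities, since some OLC
assemblers demand a quality file) and classifies the resulting ACE
layout.  Source tracking is by id prefix — ``<source>|<original_id>`` —
which survives the round trip through any assembler that preserves read
names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .formats import AceAssembly, ResolvableError, SeqRecord
from .metrics import ContigSet

__all__ = [
    "PseudoReadSet",
    "ContigClass",
    "MergeClassification",
    "tag_and_pool",
    "classify_second_order",
    "robust_report",
    "extract_robust_fasta",
]


@dataclass
class PseudoReadSet:
    """Pooled, source-tagged first-order contigs ready for co-assembly."""

    records: list[SeqRecord]
    source_of: dict[str, str]
    delimiter: str = "|"
    sources: list[str] = field(default_factory=list)


@dataclass
class ContigClass:
    contig_id: str
    member_ids: list[str]
    source_counts: dict[str, int]
    robust: bool
    unpadded_len: int


@dataclass
class MergeClassification:
    rule: str
    n_sources: int
    contigs: list[ContigClass]

    def robust_contigs(self) -> list[ContigClass]:
        return [c for c in self.contigs if c.robust]


def tag_and_pool(
    assemblies: Mapping[str, ContigSet],
    delimiter: str = "|",
    uniform_qual: int | None = None,
) -> PseudoReadSet:
    """Concatenate assemblies into one pseudo-read pool with tagged ids.

    Every pseudo-read id is ``<source><delimiter><original_id>``; the
    original ids must not contain the delimiter, or the tagging would be
    ambiguous.  ``uniform_qual`` emits a flat quality value per base for
    assemblers that require quality input.
    """
    if len(assemblies) < 2:
        raise ValueError("pooling needs at least two assemblies")
    records: list[SeqRecord] = []
    source_of: dict[str, str] = {}
    for name, cs in assemblies.items():
        if delimiter in name:
            raise ValueError(
                f"assembly name {name!r} contains the delimiter {delimiter!r}"
            )
        for rec in cs.records:
            if delimiter in rec.id:
                raise ValueError(
                    f"contig id {rec.id!r} in assembly {name!r} contains "
                    f"the delimiter {delimiter!r}"
                )
            new_id = f"{name}{delimiter}{rec.id}"
            if new_id in source_of:
                raise ValueError(f"duplicate pseudo-read id {new_id!r}")
            qual = [uniform_qual] * len(rec) if uniform_qual is not None else None
            records.append(
                SeqRecord(id=new_id, seq=rec.seq, description=rec.description,
                          qual=qual)
            )
            source_of[new_id] = name
    return PseudoReadSet(
        records=records,
        source_of=source_of,
        delimiter=delimiter,
        sources=list(assemblies),
    )


def classify_second_order(
    ace: AceAssembly,
    source_of: Mapping[str, str],
    rule: Literal["at_least_two", "all_sources"] = "at_least_two",
    n_sources: int | None = None,
) -> MergeClassification:
    """Mark each second-order contig robust or not.

    ``at_least_two``: robust iff members come from >= 2 distinct source
    assemblies.  ``all_sources``: robust iff members come from all
    ``n_sources`` assemblies (the stricter three-way criterion).
    Pseudo-reads the co-assembler left out as singletons simply never
    appear in the ACE and so are never robust.
    """
    if rule not in ("at_least_two", "all_sources"):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "all_sources":
        if n_sources is None:
            n_sources = len(set(source_of.values()))
    else:
        n_sources = n_sources or len(set(source_of.values()))
    unknown: set[str] = set()
    for co in ace.contigs:
        unknown.update(m for m in co.read_ids if m not in source_of)
    if unknown:
        raise ResolvableError(
            f"ACE read ids absent from the pseudo-read pool: "
            f"{sorted(unknown)[:10]}"
        )
    out: list[ContigClass] = []
    for co in ace.contigs:
        counts: dict[str, int] = {}
        for m in co.read_ids:
            s = source_of[m]
            counts[s] = counts.get(s, 0) + 1
        if rule == "at_least_two":
            robust = len(counts) >= 2
        else:
            robust = len(counts) == n_sources
        out.append(
            ContigClass(
                contig_id=co.contig_id,
                member_ids=list(co.read_ids),
                source_counts=counts,
                robust=robust,
                unpadded_len=co.unpadded_len,
            )
        )
    return MergeClassification(rule=rule, n_sources=n_sources, contigs=out)


def robust_report(cls: MergeClassification) -> tuple[int, int]:
    """(number of robust contigs, summed unpadded consensus bases)."""
    robust = cls.robust_contigs()
    return len(robust), sum(c.unpadded_len for c in robust)


def extract_robust_fasta(
    cls: MergeClassification, consensus_source: ContigSet
) -> ContigSet:
    """Pull the consensus sequences of the robust contigs only.

    ``consensus_source`` is the co-assembler's contig FASTA; every
    robust contig id must be present in it.
    """
    by_id = {r.id: r for r in consensus_source.records}
    robust = cls.robust_contigs()
    missing = [c.contig_id for c in robust if c.contig_id not in by_id]
    if missing:
        raise ResolvableError(
            f"no consensus sequence for robust contigs: {missing[:10]}"
        )
    return ContigSet(
        name=f"{consensus_source.name}.robust",
        records=[by_id[c.contig_id] for c in robust],
    )
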