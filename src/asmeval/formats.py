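"""Readers and writers for the file formats the toolkit consumes.

Everything is normalized to a single internal coordinate convention:
**0-based, half-open intervals on the plus strand** of both query and
target.  All conversion from the on-disk conventions (PSL's plus-strand
half-open columns, BLAST tabular's 1-based inclusive and possibly
reversed coordinates) happens here, so downstream interval arithmetic
never has to think about it again.

Supported formats: FASTA (with optional sibling ``.qual`` files of
phred-style space-separated integers), BLAT PSL (21 columns, optional
psLayout header), BLAST tabular 12-column (``-outfmt 6``), consed ACE,
and SAM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import PairedFastaQualIterator
from Bio.Sequencing import Ace
import pysam

__all__ = [
    "AsmevalError",
    "FormatError",
    "ResolvableError",
    "SeqRecord",
    "AlignmentRecord",
    "AlignmentBlock",
    "AceContig",
    "AceAssembly",
    "SamHit",
    "read_fasta",
    "write_fasta",
    "read_psl",
    "read_blast6",
    "read_ace",
    "read_sam_min",
]


class AsmevalError(Exception):
    """Base class for toolkit errors."""


class FormatError(AsmevalError):
    """A file does not conform to its declared format."""


class ResolvableError(AsmevalError):
    """Inconsistent inputs the user can fix (missing ids, bad pairing)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SeqRecord:
    """One sequence: a read, a contig, or a reference target.

    ``qual``, when present, is a list of per-base integer phred-style
    scores of the same length as ``seq``.
    """

    id: str
    seq: str
    description: str = ""
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token: {self.id!r}")
        self.seq = self.seq.upper()
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"{self.id}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentBlock:
    """One ungapped aligned segment, as plus-strand offsets."""

    q_off: int
    t_off: int
    length: int


@dataclass
class AlignmentRecord:
    """One alignment (a BLAT PSL record or a BLAST HSP), normalized.

    Intervals are 0-based half-open on the plus strand.  For translated
    searches (BLASTX) the target interval is in residues while the query
    interval stays in nucleotides; ``translated`` records this.
    """

    query_id: str
    target_id: str
    query_len: int
    target_len: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int = 0
    program: str = "psl"
    translated: bool = False
    bit_score: float | None = None
    e_value: float | None = None
    blocks: list[AlignmentBlock] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end <= self.query_len):
            raise ValueError(
                f"{self.query_id} vs {self.target_id}: bad query interval "
                f"[{self.q_start},{self.q_end}) for length {self.query_len}"
            )
        if not (0 <= self.t_start < self.t_end <= self.target_len):
            raise ValueError(
                f"{self.query_id} vs {self.target_id}: bad target interval "
                f"[{self.t_start},{self.t_end}) for length {self.target_len}"
            )
        if self.blocks:
            self.blocks = sorted(self.blocks, key=lambda b: b.q_off)
            prev_end = None
            for b in self.blocks:
                if b.q_off < self.q_start or b.q_off + b.length > self.q_end:
                    raise ValueError(
                        f"{self.query_id}: block outside query interval"
                    )
                if prev_end is not None and b.q_off < prev_end:
                    raise ValueError(f"{self.query_id}: overlapping blocks")
                prev_end = b.q_off + b.length

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_span(self) -> int:
        return self.t_end - self.t_start

    def target_coverage(self, target_len: int | None = None) -> float:
        """Fraction of the target spanned by this single record."""
        tl = self.target_len if target_len is None else target_len
        return self.t_span / tl


@dataclass
class AceContig:
    contig_id: str
    padded_len: int
    unpadded_len: int
    read_ids: list[str]


@dataclass
class AceAssembly:
    """Layout of a (merged) assembly: membership only, no per-base data."""

    contigs: list[AceContig] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def total_unpadded_bases(self) -> int:
        return sum(c.unpadded_len for c in self.contigs)


@dataclass(frozen=True)
class SamHit:
    """One SAM alignment line, reduced to what read accounting needs."""

    read_id: str
    mapped: bool
    target_id: str | None = None
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if self.mapped != (self.target_id is not None):
            raise ValueError(
                f"{self.read_id}: target_id must be present iff mapped"
            )


# ---------------------------------------------------------------------------
# FASTA (+ .qual)
# ---------------------------------------------------------------------------


def _check_fasta_shape(path: Path) -> None:
    # Bio.SeqIO silently skips junk before the first '>'; we want a
    # line-numbered error instead.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}:{lineno}: expected FASTA header starting "
                    f"with '>', got {line.strip()[:40]!r}"
                )
            return


def read_fasta(path: str | Path, with_qual: bool = False) -> list[SeqRecord]:
    """Read a FASTA file, optionally pairing a sibling ``.qual`` file.

    The record id is the first whitespace-delimited token after ``>``;
    the remainder of the header line becomes the description.  Sequences
    are uppercased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_fasta_shape(path)
    if not with_qual:
        return [
            SeqRecord(
                id=r.id,
                seq=str(r.seq),
                description=r.description[len(r.id):].strip(),
            )
            for r in SeqIO.parse(path, "fasta")
        ]
    qual_path = path.with_suffix(path.suffix + ".qual")
    if not qual_path.exists():
        qual_path = path.with_suffix(".qual")
    if not qual_path.exists():
        raise ResolvableError(f"no quality file found next to {path}")
    out: list[SeqRecord] = []
    with open(path) as fa, open(qual_path) as fq:
        try:
            for r in PairedFastaQualIterator(fa, fq):
                out.append(
                    SeqRecord(
                        id=r.id,
                        seq=str(r.seq),
                        description=r.description[len(r.id):].strip(),
                        qual=list(r.letter_annotations["phred_quality"]),
                    )
                )
        except ValueError as exc:  # id mismatch or length mismatch
            raise FormatError(f"{path} / {qual_path}: {exc}") from exc
    return out


def write_fasta(
    records: Iterable[SeqRecord],
    path: str | Path,
    wrap: int = 60,
    with_qual: bool = False,
) -> None:
    """Write FASTA (and a sibling ``.qual`` when requested)."""
    path = Path(path)
    records = list(records)
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id} {r.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.seq), wrap):
                fh.write(r.seq[i : i + wrap] + "\n")
    if with_qual:
        qpath = path.with_suffix(path.suffix + ".qual")
        with open(qpath, "w") as fh:
            for r in records:
                fh.write(f">{r.id}\n")
                q = r.qual if r.qual is not None else []
                for i in range(0, len(q), 20):
                    fh.write(" ".join(str(v) for v in q[i : i + 20]) + "\n")


# ---------------------------------------------------------------------------
# BLAT PSL
# ---------------------------------------------------------------------------

_PSL_NCOL = 21


def _split_csv_ints(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x]


def read_psl(path: str | Path) -> list[AlignmentRecord]:
    """Read a 21-column BLAT PSL file (optional psLayout header).

    PSL's qStart/qEnd/tStart/tEnd columns are already 0-based half-open
    on the plus strand and are adopted directly.  ``matches`` is the sum
    of the *matches* and *repMatches* columns.  Per-block query offsets
    reported on the minus strand are converted to plus-strand
    coordinates (``q_off = qSize - reported_start - block_len``).
    """
    path = Path(path)
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        all_lines = fh.readlines()
    start_at = 0
    if all_lines and all_lines[0].startswith("psLayout"):
        start_at = 5  # canonical 5-line psLayout header
    for lineno, raw in enumerate(all_lines, start=1):
        if lineno <= start_at:
            continue
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != _PSL_NCOL:
            raise FormatError(
                f"{path}:{lineno}: expected {_PSL_NCOL} tab-separated "
                f"columns, got {len(fields)}"
            )
        try:
            matches = int(fields[0])
            rep_matches = int(fields[2])
            strand = fields[8]
            q_name, q_size = fields[9], int(fields[10])
            q_start, q_end = int(fields[11]), int(fields[12])
            t_name, t_size = fields[13], int(fields[14])
            t_start, t_end = int(fields[15]), int(fields[16])
            block_count = int(fields[17])
            block_sizes = _split_csv_ints(fields[18])
            q_starts = _split_csv_ints(fields[19])
            t_starts = _split_csv_ints(fields[20])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if not (
            len(block_sizes) == len(q_starts) == len(t_starts) == block_count
        ):
            raise FormatError(
                f"{path}:{lineno}: blockSizes/qStarts/tStarts "
                f"inconsistent with blockCount={block_count}"
            )
        q_minus = strand[0] == "-"
        blocks = []
        for size, qs, ts in zip(block_sizes, q_starts, t_starts):
            q_off = q_size - qs - size if q_minus else qs
            blocks.append(AlignmentBlock(q_off=q_off, t_off=ts, length=size))
        try:
            out.append(
                AlignmentRecord(
                    query_id=q_name,
                    target_id=t_name,
                    query_len=q_size,
                    target_len=t_size,
                    q_start=q_start,
                    q_end=q_end,
                    t_start=t_start,
                    t_end=t_end,
                    matches=matches + rep_matches,
                    program="psl",
                    translated=len(strand) == 2,
                    blocks=blocks,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# BLAST tabular (-outfmt 6)
# ---------------------------------------------------------------------------

_BLAST6_NCOL = 12


def read_blast6(
    path: str | Path,
    target_lens: Mapping[str, int],
    query_lens: Mapping[str, int],
    translated: bool = False,
) -> list[AlignmentRecord]:
    """Read 12-column BLAST tabular output.

    The format carries neither query nor target lengths, so explicit
    length maps (typically built from the FASTA files that were
    searched) are required.  1-based inclusive coordinates are converted
    to 0-based half-open; reverse-orientation target coordinates
    (sstart > send) are normalized so t_start < t_end.
    """
    path = Path(path)
    out: list[AlignmentRecord] = []
    missing_q: set[str] = set()
    missing_t: set[str] = set()
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST6_NCOL:
                raise FormatError(
                    f"{path}:{lineno}: expected {_BLAST6_NCOL} columns, "
                    f"got {len(fields)}"
                )
            qid, tid = fields[0], fields[1]
            if qid not in query_lens:
                missing_q.add(qid)
            if tid not in target_lens:
                missing_t.add(tid)
            rows.append((lineno, fields))
    if missing_q or missing_t:
        raise ResolvableError(
            f"{path}: ids absent from supplied length maps — "
            f"queries: {sorted(missing_q)}; targets: {sorted(missing_t)}"
        )
    for lineno, fields in rows:
        try:
            qid, tid = fields[0], fields[1]
            pident = float(fields[2])
            aln_len = int(fields[3])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            e_value = float(fields[10])
            bit_score = float(fields[11])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        q_start, q_end = min(qstart, qend) - 1, max(qstart, qend)
        t_start, t_end = min(sstart, send) - 1, max(sstart, send)
        try:
            out.append(
                AlignmentRecord(
                    query_id=qid,
                    target_id=tid,
                    query_len=query_lens[qid],
                    target_len=target_lens[tid],
                    q_start=q_start,
                    q_end=q_end,
                    t_start=t_start,
                    t_end=t_end,
                    # tabular output has no exact match count; estimate
                    # from identity x alignment length
                    matches=round(pident * aln_len / 100.0),
                    program="blastx" if translated else "blastn",
                    translated=translated,
                    bit_score=bit_score,
                    e_value=e_value,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# ACE (consed)
# ---------------------------------------------------------------------------


def read_ace(path: str | Path) -> AceAssembly:
    """Read a consed ACE file, keeping only what merging needs.

    Per contig: id, padded consensus length, unpadded length (pads
    ``*`` removed) and the ids of the placed reads (AF lines).  A
    mismatch between the AS header counts and the parsed counts is a
    warning, not fatal.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().split()
        if not first or first[0] != "AS":
            raise FormatError(f"{path}: missing AS header line")
        try:
            as_contigs, as_reads = int(first[1]), int(first[2])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed AS line") from exc
    if as_contigs == 0:
        return AceAssembly()
    try:
        with open(path) as fh:
            record = Ace.read(fh)
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: truncated or malformed ACE: {exc}") from exc
    contigs: list[AceContig] = []
    seen_ids: set[str] = set()
    n_reads_parsed = 0
    for co in record.contigs:
        if co.name in seen_ids:
            raise FormatError(f"{path}: duplicate contig id {co.name!r}")
        seen_ids.add(co.name)
        read_ids = [af.name for af in co.af]
        if len(read_ids) != len(set(read_ids)):
            dupes = sorted(
                {r for r in read_ids if read_ids.count(r) > 1}
            )
            raise FormatError(
                f"{path}: contig {co.name}: duplicate read ids {dupes}"
            )
        padded = len(co.sequence)
        contigs.append(
            AceContig(
                contig_id=co.name,
                padded_len=padded,
                unpadded_len=padded - co.sequence.count("*"),
                read_ids=read_ids,
            )
        )
        n_reads_parsed += len(read_ids)
    if len(contigs) != as_contigs or n_reads_parsed != as_reads:
        warnings.warn(
            f"{path}: AS header declares {as_contigs} contigs / {as_reads} "
            f"reads but {len(contigs)} / {n_reads_parsed} were parsed",
            stacklevel=2,
        )
    return AceAssembly(contigs=contigs)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def read_sam_min(path: str | Path) -> list[SamHit]:
    """Read a SAM file into minimal per-line hits.

    ``mapped`` mirrors FLAG bit 0x4 (unset = mapped); ``is_secondary``
    mirrors bit 0x100.  Unmapped records are retained with
    ``mapped=False`` so read accounting can see them.
    """
    path = Path(path)
    hits: list[SamHit] = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for aln in sam:
                mapped = not aln.is_unmapped
                hits.append(
                    SamHit(
                        read_id=aln.query_name,
                        mapped=mapped,
                        target_id=aln.reference_name if mapped else None,
                        is_secondary=aln.is_secondary,
                    )
                )
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a valid SAM file: {exc}") from exc
    return hits
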