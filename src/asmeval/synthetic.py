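"""Synthetic transcriptome fixtures with planted ground truth.

Everything the toolkit evaluates — reads, contig sets, pairwise
alignments, merged-assembly layouts, read mappings — can be generated
here with a known truth table, so every reader and every statistic is
testable without external assemblers or aligners.

The generator emulates a 454-era non-normalised cDNA sequencing study:
transcripts around 1.2 kb, per-transcript read depth drawn log-normally
(abundances span orders of magnitude), reads of a few hundred bases
carrying the same synthetic 29-base adapter at both ends, an optional
poly(A) tail with a single N planted mid-way (the degenerate oligo-dT
priming artifact), and substitution errors.  Mock assemblies plant
known redundancy (duplicated contigs), fragmentation (split contigs)
and novelty (transcripts private to one assembly), which downstream
statistics must recover exactly in the error-free case.

All randomness flows from a single integer seed through per-purpose
numpy Generator streams, so identical seeds give identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formats import AlignmentRecord, SeqRecord
from .merge import PseudoReadSet
from .metrics import ContigSet
from .refcov import MappingStats

__all__ = [
    "SYNTHETIC_ADAPTER",
    "SimConfig",
    "ReadTruth",
    "ContigTruth",
    "PlantedHit",
    "gen_transcriptome",
    "gen_reads",
    "gen_adapter_hits",
    "gen_mock_assemblies",
    "planted_homologies",
    "gen_mock_alignments",
    "gen_mock_ace",
    "gen_mock_sam",
    "gen_lengths_with_total",
    "contig_set_from_lengths",
]

# Synthetic stand-in for a 29-base template-switching adapter (the real
# kit sequence is proprietary); only its length and placement matter.
SYNTHETIC_ADAPTER = "AAGCAGTGGTATCAACGCAGAGTGGCCAT"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for the synthetic fixtures.

    Defaults are a desk-scale rendering of a 454 transcriptome project:
    transcript lengths N(1200, 400) truncated at 100 bases, log-normal
    read depth (mu=1.5, sigma=1.2: roughly 1-100 reads per transcript),
    read lengths N(277, 60), 0.5% substitution errors, the 29-base
    adapter at both read ends, a 12-base poly(A) tail with one mid-tail
    N, and 10% planted novelty per assembly.
    """

    seed: int = 0
    n_transcripts: int = 300
    transcript_len: tuple[float, float] = (1200.0, 400.0)  # (mean, sd)
    depth: tuple[float, float] = (1.5, 1.2)  # log-normal (mu, sigma)
    read_len: tuple[float, float] = (277.0, 60.0)  # (mean, sd)
    error_rate: float = 0.005
    adapter_seq: str = SYNTHETIC_ADAPTER
    polyA_len: int = 12
    novelty_fraction: float = 0.1
    redundancy_rate: float = 0.05
    fragmentation_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("error_rate", "novelty_fraction", "redundancy_rate",
                     "fragmentation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_transcripts < 0 or self.polyA_len < 0:
            raise ValueError("counts must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        """An independent, reproducible stream for one sub-generator."""
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class ReadTruth:
    """Where one synthetic read came from and how it is structured."""

    read_id: str
    transcript_id: str
    t_start: int
    t_end: int
    insert_start: int  # non-adapter portion of the read
    insert_end: int
    adapter_intervals: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class ContigTruth:
    """Provenance of one mock-assembly contig."""

    assembly: str
    contig_id: str
    transcript_id: str
    t_start: int
    t_end: int
    status: str  # "shared" | "private"
    duplicate: bool

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class PlantedHit:
    """One planted homology between a query and a target contig."""

    query_id: str
    query_len: int
    q_start: int
    q_end: int
    target_id: str
    target_len: int
    t_start: int
    t_end: int


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != bytes(arr[i])]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Transcripts and reads
# ---------------------------------------------------------------------------


def gen_transcriptome(cfg: SimConfig) -> list[SeqRecord]:
    """Random transcripts with N(mean, sd) lengths, floored at 100 bp."""
    rng = cfg.rng(1)
    mean, sd = cfg.transcript_len
    lengths = np.maximum(
        100, np.rint(rng.normal(mean, sd, size=cfg.n_transcripts))
    ).astype(int)
    return [
        SeqRecord(id=f"t{i:05d}", seq=_random_seq(rng, int(ln)))
        for i, ln in enumerate(lengths)
    ]


def gen_reads(
    transcripts: Sequence[SeqRecord], cfg: SimConfig
) -> tuple[list[SeqRecord], list[ReadTruth]]:
    """Simulate reads plus a truth table, one row per read.

    Per transcript the read count is ``max(1, round(lognormal(mu,
    sigma)))``.  Each read is a uniformly placed fragment, given
    substitution errors, then decorated: adapter at both ends and, when
    ``polyA_len > 0``, a poly(A) tail carrying one N at its midpoint
    (placed between the fragment and the 3' adapter).
    """
    if not transcripts:
        raise ValueError("gen_reads needs at least one transcript")
    rng = cfg.rng(2)
    mu, sigma = cfg.depth
    rmean, rsd = cfg.read_len
    la = len(cfg.adapter_seq)
    tail = ""
    if cfg.polyA_len > 0:
        half = cfg.polyA_len // 2
        tail = "A" * half + "N" + "A" * (cfg.polyA_len - half - 1)
    reads: list[SeqRecord] = []
    truth: list[ReadTruth] = []
    k = 0
    for tr in transcripts:
        count = max(1, int(np.rint(rng.lognormal(mu, sigma))))
        for _ in range(count):
            rlen = int(np.clip(np.rint(rng.normal(rmean, rsd)), 40, len(tr)))
            start = int(rng.integers(0, len(tr) - rlen + 1))
            frag = _mutate(rng, tr.seq[start : start + rlen], cfg.error_rate)
            insert = frag + tail
            seq = cfg.adapter_seq + insert + cfg.adapter_seq
            rid = f"r{k:07d}"
            k += 1
            adapters: list[tuple[int, int]] = []
            if la:
                adapters = [(0, la), (la + len(insert), len(seq))]
            reads.append(SeqRecord(id=rid, seq=seq))
            truth.append(
                ReadTruth(
                    read_id=rid,
                    transcript_id=tr.id,
                    t_start=start,
                    t_end=start + rlen,
                    insert_start=la,
                    insert_end=la + len(insert),
                    adapter_intervals=tuple(adapters),
                )
            )
    return reads, truth


def gen_adapter_hits(
    reads: Sequence[SeqRecord],
    truth: Sequence[ReadTruth],
    bit_score: float = 57.0,
) -> list[AlignmentRecord]:
    """Perfect adapter-vs-read hits at the planted adapter positions.

    Stands in for an external BLASTN of the adapter against the reads;
    the default bit-score is what a full-length 29-base exact match
    would earn, comfortably above the masking threshold.
    """
    by_id = {r.id: r for r in reads}
    hits: list[AlignmentRecord] = []
    for t in truth:
        read = by_id[t.read_id]
        for s, e in t.adapter_intervals:
            hits.append(
                AlignmentRecord(
                    query_id=t.read_id,
                    target_id="adapter",
                    query_len=len(read),
                    target_len=e - s,
                    q_start=s,
                    q_end=e,
                    t_start=0,
                    t_end=e - s,
                    matches=e - s,
                    program="blastn",
                    bit_score=bit_score,
                    e_value=1e-10,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Mock assemblies, planted homology, mock alignments
# ---------------------------------------------------------------------------


def gen_mock_assemblies(
    transcripts: Sequence[SeqRecord],
    cfg: SimConfig,
    n_assemblies: int = 2,
) -> tuple[dict[str, ContigSet], list[ContigTruth]]:
    """Mock assemblies with planted novelty, fragmentation, redundancy.

    Each assembly holds ``m`` transcripts of which ``k`` are private to
    it (disjoint private sets) and ``m - k`` are shared by all; ``m`` is
    chosen as large as the pool allows subject to ``k / m`` equalling
    ``novelty_fraction`` exactly whenever the fraction is commensurable,
    so planted-novelty recovery checks can demand exact equality.  Per
    assembly, each of its transcripts yields one exact-copy contig,
    split in two with probability ``fragmentation_rate`` and duplicated
    with probability ``redundancy_rate``.
    """
    if n_assemblies < 2:
        raise ValueError("need at least two mock assemblies")
    rng = cfg.rng(3)
    n = len(transcripts)
    f = cfg.novelty_fraction
    # pool usage: m shared+private per assembly, total m + (A-1)*k <= n
    m_max = int(n / (1.0 + (n_assemblies - 1) * f))
    if m_max < 1:
        raise ValueError("novelty_fraction too large for the transcript count")
    m = m_max
    for cand in range(m_max, 0, -1):
        if abs(f * cand - round(f * cand)) < 1e-9:
            m = cand
            break
    k_private = int(round(f * m))
    order = rng.permutation(n)
    private: list[set[int]] = [
        set(order[a * k_private : (a + 1) * k_private])
        for a in range(n_assemblies)
    ]
    shared = set(order[n_assemblies * k_private :
                       n_assemblies * k_private + (m - k_private)])
    assemblies: dict[str, ContigSet] = {}
    truth: list[ContigTruth] = []
    for a in range(n_assemblies):
        name = f"asm{chr(65 + a)}"
        records: list[SeqRecord] = []
        c = 0

        def add(tr: SeqRecord, s: int, e: int, status: str, dup: bool) -> None:
            nonlocal c
            cid = f"{name}_c{c:05d}"
            c += 1
            records.append(SeqRecord(id=cid, seq=tr.seq[s:e]))
            truth.append(
                ContigTruth(
                    assembly=name,
                    contig_id=cid,
                    transcript_id=tr.id,
                    t_start=s,
                    t_end=e,
                    status=status,
                    duplicate=dup,
                )
            )

        for idx in sorted(shared | private[a]):
            tr = transcripts[idx]
            status = "private" if idx in private[a] else "shared"
            pieces: list[tuple[int, int]] = [(0, len(tr))]
            if (
                len(tr) >= 200
                and rng.random() < cfg.fragmentation_rate
            ):
                cut = int(rng.integers(100, len(tr) - 99))
                pieces = [(0, cut), (cut, len(tr))]
            for s, e in pieces:
                add(tr, s, e, status, dup=False)
                if rng.random() < cfg.redundancy_rate:
                    add(tr, s, e, status, dup=True)
        assemblies[name] = ContigSet(name=name, records=records)
    return assemblies, truth


def planted_homologies(
    query_truth: Sequence[ContigTruth],
    target_truth: Sequence[ContigTruth],
) -> list[PlantedHit]:
    """Exact homologies implied by shared transcript provenance.

    For every query/target contig pair drawn from the same transcript,
    the overlap of their transcript intervals, mapped into each contig's
    own coordinates.
    """
    by_tr: dict[str, list[ContigTruth]] = {}
    for t in target_truth:
        by_tr.setdefault(t.transcript_id, []).append(t)
    hits: list[PlantedHit] = []
    for q in query_truth:
        for t in by_tr.get(q.transcript_id, []):
            s = max(q.t_start, t.t_start)
            e = min(q.t_end, t.t_end)
            if s >= e:
                continue
            hits.append(
                PlantedHit(
                    query_id=q.contig_id,
                    query_len=q.length,
                    q_start=s - q.t_start,
                    q_end=e - q.t_start,
                    target_id=t.contig_id,
                    target_len=t.length,
                    t_start=s - t.t_start,
                    t_end=e - t.t_start,
                )
            )
    return hits


def gen_mock_alignments(hits: Sequence[PlantedHit]) -> tuple[str, str]:
    """Render planted homologies as PSL text and BLAST-6 text.

    Both encodings describe identical single-block, full-identity
    alignments, so the two readers must decode them to the same
    interval sets.
    """
    psl_lines: list[str] = []
    b6_lines: list[str] = []
    for h in hits:
        ln = h.q_end - h.q_start
        psl_lines.append(
            "\t".join(
                str(x)
                for x in (
                    ln, 0, 0, 0, 0, 0, 0, 0, "+",
                    h.query_id, h.query_len, h.q_start, h.q_end,
                    h.target_id, h.target_len, h.t_start, h.t_end,
                    1, f"{ln},", f"{h.q_start},", f"{h.t_start},",
                )
            )
        )
        b6_lines.append(
            "\t".join(
                str(x)
                for x in (
                    h.query_id, h.target_id, "100.00", ln, 0, 0,
                    h.q_start + 1, h.q_end, h.t_start + 1, h.t_end,
                    "1e-180", f"{2 * ln:.1f}",
                )
            )
        )
    psl = "\n".join(psl_lines) + ("\n" if psl_lines else "")
    b6 = "\n".join(b6_lines) + ("\n" if b6_lines else "")
    return psl, b6


# ---------------------------------------------------------------------------
# Mock ACE and SAM
# ---------------------------------------------------------------------------


def gen_mock_ace(
    pool: PseudoReadSet, grouping: Sequence[Sequence[str]]
) -> str:
    """A minimal consed ACE laying out the given pseudo-read groups.

    One CO per group; the consensus is the longest member's sequence
    (no pads), so the unpadded length matches what an OLC consensus of
    exact-copy members would produce.  Groups must be disjoint subsets
    of the pool.
    """
    by_id = {r.id: r for r in pool.records}
    seen: set[str] = set()
    for grp in grouping:
        for m in grp:
            if m not in by_id:
                raise ValueError(f"group member {m!r} not in the pool")
            if m in seen:
                raise ValueError(f"read {m!r} appears in more than one group")
            seen.add(m)
    n_reads = sum(len(g) for g in grouping)
    lines: list[str] = [f"AS {len(grouping)} {n_reads}", ""]
    for i, grp in enumerate(grouping, start=1):
        members = [by_id[m] for m in grp]
        consensus = max(members, key=len).seq
        lines.append(f"CO Contig{i} {len(consensus)} {len(grp)} 0 U")
        for j in range(0, len(consensus), 50):
            lines.append(consensus[j : j + 50])
        lines.append("")
        lines.append("BQ")
        for j in range(0, len(consensus), 20):
            lines.append(" ".join(["40"] * len(consensus[j : j + 20])))
        lines.append("")
        for m in members:
            lines.append(f"AF {m.id} U 1")
        for m in members:
            lines.append(f"BS 1 {len(m.seq)} {m.id}")
        lines.append("")
        for m in members:
            lines.append(f"RD {m.id} {len(m.seq)} 0 0")
            for j in range(0, len(m.seq), 50):
                lines.append(m.seq[j : j + 50])
            lines.append("")
            lines.append(f"QA 1 {len(m.seq)} 1 {len(m.seq)}")
            lines.append(
                f"DS CHROMAT_FILE: {m.id} PHD_FILE: {m.id}.phd.1 TIME: "
                "Thu Jan 1 00:00:00 1970"
            )
            lines.append("")
    return "\n".join(lines) + "\n"


def gen_mock_sam(
    read_ids: Sequence[str],
    targets: ContigSet,
    rng: np.random.Generator,
    p_mapped: float = 0.9,
    p_multi: float = 0.3,
) -> tuple[str, MappingStats]:
    """A SAM file with planted mapped / multi-hit / unmapped reads.

    Each read maps with probability ``p_mapped``; mapped reads gain one
    secondary alignment with probability ``p_multi``.  Returns the SAM
    text and the true mapping statistics it encodes.
    """
    if not targets.records:
        raise ValueError("need at least one target contig")
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for r in targets.records:
        lines.append(f"@SQ\tSN:{r.id}\tLN:{len(r)}")
    tids = [r.id for r in targets.records]
    tlens = {r.id: len(r) for r in targets.records}
    used = multi = 0
    for rid in read_ids:
        if rng.random() < p_mapped:
            used += 1
            n_hits = 2 if rng.random() < p_multi else 1
            if n_hits == 2:
                multi += 1
            for h in range(n_hits):
                tid = tids[int(rng.integers(0, len(tids)))]
                pos = int(rng.integers(1, max(2, tlens[tid] - 30)))
                flag = 0 if h == 0 else 256
                lines.append(
                    f"{rid}\t{flag}\t{tid}\t{pos}\t255\t30M\t*\t0\t0\t*\t*"
                )
        else:
            lines.append(f"{rid}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*")
    return "\n".join(lines) + "\n", MappingStats(reads_used=used, multi_hit=multi)


# ---------------------------------------------------------------------------
# Length multisets with exact totals (for summary-statistic checks)
# ---------------------------------------------------------------------------


def gen_lengths_with_total(
    n: int, total: int, rng: np.random.Generator, min_len: int = 100
) -> list[int]:
    """``n`` random contig lengths >= ``min_len`` summing exactly to
    ``total`` (the surplus over the floor is spread multinomially)."""
    if n <= 0:
        raise ValueError("n must be positive")
    surplus = total - n * min_len
    if surplus < 0:
        raise ValueError(f"total {total} too small for {n} x {min_len}")
    extra = rng.multinomial(surplus, np.full(n, 1.0 / n))
    return [min_len + int(e) for e in extra]


def contig_set_from_lengths(name: str, lengths: Sequence[int]) -> ContigSet:
    """Contigs of prescribed lengths (constant sequence content —
    length statistics do not depend on composition)."""
    return ContigSet(
        name=name,
        records=[
            SeqRecord(id=f"{name}_c{i:06d}", seq="A" * ln)
            for i, ln in enumerate(lengths)
        ],
    )
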