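"""Format readers: coordinate normalization, round trips, error paths."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from asmeval.formats import (
    AlignmentRecord,
    FormatError,
    ResolvableError,
    SeqRecord,
    read_ace,
    read_blast6,
    read_fasta,
    read_psl,
    read_sam_min,
    write_fasta,
)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


class TestFasta:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_basic_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a desc\nACG\nT\n")
        (rec,) = read_fasta(p)
        assert (rec.id, rec.seq, rec.description) == ("a", "ACGT", "desc")

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACGT\n>y\nacgt\n")
        recs = read_fasta(p)
        assert [r.seq for r in recs] == ["ACGT", "ACGT"]

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("ACGT\n>a\nACGT\n")
        with pytest.raises(FormatError, match=r":1:"):
            read_fasta(p)

    def test_qual_length_mismatch(self, tmp_path):
        p = tmp_path / "r.fasta"
        p.write_text(">a\nACGT\n")
        (tmp_path / "r.fasta.qual").write_text(">a\n30 30 30\n")
        with pytest.raises(FormatError):
            read_fasta(p, with_qual=True)

    seqs = st.text(alphabet="ACGTNacgtn", min_size=0, max_size=150)
    ids = st.from_regex(r"[A-Za-z][A-Za-z0-9_.-]{0,15}", fullmatch=True)

    @given(st.lists(st.tuples(ids, seqs), min_size=0, max_size=8,
                    unique_by=lambda t: t[0]),
           st.booleans())
    def test_round_trip(self, tmp_path_factory, items, with_qual):
        """write(read(x)) == x up to case normalization and wrapping."""
        d = tmp_path_factory.mktemp("rt")
        records = [
            SeqRecord(id=i, seq=s,
                      qual=[30] * len(s) if with_qual else None)
            for i, s in items
        ]
        p = d / "x.fasta"
        write_fasta(records, p, wrap=17, with_qual=with_qual)
        back = read_fasta(p, with_qual=with_qual)
        assert [(r.id, r.seq, r.qual) for r in back] == [
            (r.id, r.seq.upper(), r.qual) for r in records
        ]


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------


def _psl_line(**kw):
    f = dict(matches=100, mis=0, rep=0, n=0, qni=0, qbi=0, tni=0, tbi=0,
             strand="+", qname="q1", qsize=120, qstart=0, qend=100,
             tname="t1", tsize=300, tstart=50, tend=150, bc=1,
             sizes="100,", qstarts="0,", tstarts="50,")
    f.update(kw)
    return "\t".join(str(v) for v in f.values())


class TestPsl:
    def test_field_by_field(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text(_psl_line(rep=5) + "\n")
        (rec,) = read_psl(p)
        assert rec.query_id == "q1" and rec.target_id == "t1"
        assert (rec.q_start, rec.q_end, rec.query_len) == (0, 100, 120)
        assert (rec.t_start, rec.t_end, rec.target_len) == (50, 150, 300)
        assert rec.matches == 105  # matches + repMatches
        assert rec.program == "psl" and not rec.translated
        assert rec.blocks[0].q_off == 0 and rec.blocks[0].t_off == 50

    def test_pslayout_header_skipped(self, tmp_path):
        p = tmp_path / "h.psl"
        p.write_text(
            "psLayout version 3\n\n"
            "match\tmis- \trep. \tN's\n"
            "     \tmatch\tmatch\t   \n"
            "---------------------------------\n"
            + _psl_line() + "\n"
        )
        assert len(read_psl(p)) == 1

    def test_minus_strand_block_conversion(self, tmp_path):
        # PSL spec: for strand '-', reported qStarts are minus-strand
        # offsets; plus-strand q_off = qSize - reported - size.
        p = tmp_path / "m.psl"
        p.write_text(
            _psl_line(strand="-", qsize=120, qstart=10, qend=40,
                      matches=30, sizes="30,", qstarts="80,", tstarts="50,",
                      tend=80)
            + "\n"
        )
        (rec,) = read_psl(p)
        assert rec.blocks[0].q_off == 120 - 80 - 30 == 10
        assert rec.blocks[0].q_off + rec.blocks[0].length == rec.q_end

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "bad.psl"
        p.write_text("1\t2\t3\n")
        with pytest.raises(FormatError, match="21"):
            read_psl(p)

    def test_blockcount_mismatch(self, tmp_path):
        p = tmp_path / "bad.psl"
        p.write_text(_psl_line(bc=2) + "\n")
        with pytest.raises(FormatError, match="blockCount"):
            read_psl(p)


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------


def _b6_line(q="q1", t="t1", qs=1, qe=90, ss=1, se=30, e="1e-20", bits="50.1"):
    return f"{q}\t{t}\t95.00\t90\t4\t0\t{qs}\t{qe}\t{ss}\t{se}\t{e}\t{bits}\n"


class TestBlast6:
    def test_translated_coordinates(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(_b6_line())
        (rec,) = read_blast6(p, target_lens={"t1": 30},
                             query_lens={"q1": 90}, translated=True)
        assert (rec.q_start, rec.q_end) == (0, 90)
        assert (rec.t_start, rec.t_end) == (0, 30)
        assert rec.translated and rec.program == "blastx"
        assert rec.e_value == pytest.approx(1e-20)
        assert rec.bit_score == pytest.approx(50.1)

    def test_reversed_target_normalized(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(_b6_line(ss=30, se=1))
        (rec,) = read_blast6(p, target_lens={"t1": 30}, query_lens={"q1": 90})
        assert (rec.t_start, rec.t_end) == (0, 30)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert read_blast6(p, target_lens={}, query_lens={}) == []

    def test_missing_ids_listed(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(_b6_line())
        with pytest.raises(ResolvableError, match="q1"):
            read_blast6(p, target_lens={"t1": 30}, query_lens={})


# ---------------------------------------------------------------------------
# ACE
# ---------------------------------------------------------------------------


def _mini_ace(consensus="AC*GT", reads=("r1", "r2")):
    lines = [f"AS 1 {len(reads)}", "",
             f"CO Contig1 {len(consensus)} {len(reads)} 0 U",
             consensus, "", "BQ",
             " ".join(["40"] * (len(consensus) - consensus.count("*"))), ""]
    lines += [f"AF {r} U 1" for r in reads]
    lines.append("")
    for r in reads:
        lines += [f"RD {r} 4 0 0", "ACGT", "", "QA 1 4 1 4",
                  f"DS CHROMAT_FILE: {r} PHD_FILE: {r}.phd.1 TIME: x", ""]
    return "\n".join(lines) + "\n"


class TestAce:
    def test_padded_and_unpadded_lengths(self, tmp_path):
        p = tmp_path / "a.ace"
        p.write_text(_mini_ace())
        asm = read_ace(p)
        (co,) = asm.contigs
        assert (co.padded_len, co.unpadded_len) == (5, 4)
        assert co.read_ids == ["r1", "r2"]

    def test_empty_assembly(self, tmp_path):
        p = tmp_path / "e.ace"
        p.write_text("AS 0 0\n")
        assert len(read_ace(p)) == 0

    def test_duplicate_read_id_rejected(self, tmp_path):
        p = tmp_path / "d.ace"
        p.write_text(_mini_ace(reads=("r1", "r1")))
        with pytest.raises(FormatError, match="duplicate read"):
            read_ace(p)

    def test_header_count_mismatch_warns(self, tmp_path):
        p = tmp_path / "w.ace"
        p.write_text(_mini_ace().replace("AS 1 2", "AS 1 5"))
        with pytest.warns(UserWarning, match="AS header"):
            asm = read_ace(p)
        assert len(asm) == 1


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:500\n"


def _sam_line(rid, flag, rname="c1"):
    pos = "10" if not flag & 0x4 else "0"
    rn = rname if not flag & 0x4 else "*"
    cig = "30M" if not flag & 0x4 else "*"
    return f"{rid}\t{flag}\t{rn}\t{pos}\t255\t{cig}\t*\t0\t0\t*\t*\n"


class TestSam:
    def test_header_only(self, tmp_path):
        p = tmp_path / "h.sam"
        p.write_text(SAM_HEADER)
        assert read_sam_min(p) == []

    def test_flag_bits(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(SAM_HEADER + _sam_line("r1", 0) + _sam_line("r1", 256)
                     + _sam_line("r2", 4))
        hits = read_sam_min(p)
        assert [(h.read_id, h.mapped, h.is_secondary) for h in hits] == [
            ("r1", True, False), ("r1", True, True), ("r2", False, False)
        ]
        assert hits[0].target_id == "c1" and hits[2].target_id is None


# ---------------------------------------------------------------------------
# Cross-format agreement
# ---------------------------------------------------------------------------


@given(st.lists(
    st.tuples(st.integers(0, 400), st.integers(1, 200), st.integers(0, 400)),
    min_size=1, max_size=10))
def test_psl_and_blast6_agree_on_intervals(tmp_path_factory, raw):
    """The same ungapped alignment in both encodings decodes to
    identical query and target intervals."""
    from asmeval.synthetic import PlantedHit, gen_mock_alignments

    hits = []
    for i, (qs, ln, ts) in enumerate(raw):
        hits.append(PlantedHit(
            query_id=f"q{i}", query_len=qs + ln + 5, q_start=qs, q_end=qs + ln,
            target_id=f"t{i}", target_len=ts + ln + 5, t_start=ts,
            t_end=ts + ln,
        ))
    psl_text, b6_text = gen_mock_alignments(hits)
    d = tmp_path_factory.mktemp("agree")
    (d / "x.psl").write_text(psl_text)
    (d / "x.tsv").write_text(b6_text)
    from_psl = read_psl(d / "x.psl")
    from_b6 = read_blast6(
        d / "x.tsv",
        target_lens={h.target_id: h.target_len for h in hits},
        query_lens={h.query_id: h.query_len for h in hits},
    )
    key = lambda r: (r.query_id, r.q_start, r.q_end, r.target_id,
                     r.t_start, r.t_end)
    assert sorted(map(key, from_psl)) == sorted(map(key, from_b6))
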