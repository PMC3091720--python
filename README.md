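# asmeval

Evaluate, compare and merge *de novo* transcriptome assemblies.

When a transcriptome is sequenced for an organism with no reference
genome — classically with long-read 454 pyrosequencing of cDNA — the
reads must be assembled *de novo*, and different assemblers (OLC
programs like CAP3, MIRA, Newbler or SeqMan; de Bruijn graph programs
like CLC) produce noticeably different contig sets from the same reads.
`asmeval` is a toolkit for the evaluation half of that problem.  It does
not assemble or align anything itself; it consumes the standard outputs
of assemblers and aligners — FASTA contig sets (plus `.qual`), BLAT PSL
and 12-column BLAST tabular alignments, consed ACE layouts, SAM read
mappings — and computes the statistics used to judge assemblies and to
combine them:

* **Read pre-processing** — mask adapter hits with bit-score > 25,
  re-trim each read to its longest unmasked window, and discard reads
  with more than one `N` (poly(A/T) tails are deliberately retained).
* **Contig metrics** — after discarding contigs < 100 bp and singletons:
  contig and base counts (total and ≥ 1 kb), max and mean length, N50
  (the smallest contig size in which half the assembly is represented)
  with its contig count, and cumulative length curves.  For lengths
  `L₁ ≥ L₂ ≥ …`, N50 is `L_k` where `k = min{k : Σ_{i≤k} L_i ≥ ½ Σ L_i}`.
* **Reference recovery** — % of targets hit and % of target bases
  covered against ESTs (BLAT) or proteomes / gene-family groupings
  (BLASTX, e < 10⁻⁵), plus the stricter variants where a *single*
  alignment record must cover ≥ 80 % of the target.
* **Novel bases** — for an ordered assembly pair, the bases of one
  assembly's contigs covered by no alignment to the focal assembly
  (an asymmetric matrix over all pairs).
* **Read usage** — distinct reads mapped, and reads mapped to more than
  one place, from a read-vs-assembly SAM.
* **Assembly merging** — pool first-order contigs as tagged
  pseudo-reads, co-assemble them externally with an OLC assembler, and
  extract the **robust contigs**: second-order contigs containing
  pseudo-reads from at least two (or all) constituent assemblies.

A synthetic-data module generates transcripts, reads, mock assemblies
with planted redundancy/fragmentation/novelty, mock alignments in both
PSL and BLAST tabular form, mock ACE layouts and SAM mappings — all with
truth tables — so the whole pipeline runs and is tested without any
external data or binaries.

## Worked example

Generate a small synthetic study (30 transcripts, two mock assemblies
with 10 % planted novelty each) and run the evaluation:

```sh
asmeval simulate --seed 7 --n-transcripts 30 --outdir demo
asmeval compare --asm A=demo/asmA.fasta --asm B=demo/asmB.fasta
```

```text
metric	A	B
Number of contigs	24	25
Total Bases	24347	27598
Number of contigs (>= 1 kbp)	14	17
Total Bases (in contigs >= 1 kbp)	18487	22510
Max contig length	1527	1483
Mean contig length	1014	1104
N50	1303	1303
Number of contigs in N50	9	10
```

Both mock assemblies recover similar contig sets (they share 80 % of the
planted transcripts): assembly B spans 27,598 bases in 25 contigs, of
which 17 are ≥ 1 kb; half of B's span lives in its 10 largest contigs,
the smallest of which is 1,303 bases (the N50).  How much of B is
genuinely absent from A:

```sh
asmeval novelty --other demo/asmB.fasta --hits demo/asmB_vs_asmA.psl --focal-name asmA
```

```text
other	focal	novel_bases	other_total
asmB	asmA	2439	27598
```

2,439 of B's 27,598 bases (8.8 %) have no alignment to A — B's planted
private transcripts.  Merging the two and keeping only second-order
contigs supported by both:

```sh
asmeval merge classify --ace demo/merged.ace | tail -1
```

```text
TOTAL_ROBUST	18	...	20402
```

18 robust contigs totalling 20,402 bases — exactly the planted shared
transcripts; contigs private to one assembly are rejected.  Read
accounting against assembly A:

```sh
asmeval mapstats --sam demo/reads_vs_asmA.sam
```

```text
reads_used	multi_hit
213	59
```

All defaults (length floor 100 bp, adapter bit-score 25, coverage rule
0.8, e-value 10⁻⁵, max one N) are overridable flags; see
`asmeval --help` and `docs/methods.md`.

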