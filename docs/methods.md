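# Methods

## Scope and model

`asmeval` implements the evaluation-and-merging side of *de novo*
transcriptome assembly.  The objects it reasons about are contig sets
(one per assembler run), alignments between contig sets or between
contigs and reference sequences, merged-assembly layouts, and read
mappings.  The underlying model of assembly quality is deliberately
simple and assembler-agnostic:

* a good assembly uses many reads, spans many unique bases, and has a
  length distribution close to the expected transcriptome (mean contig
  length around 1.2 kb for a typical nematode transcriptome);
* a good assembly recapitulates independent reference sets — prior EST
  clusters for the same species, the proteome of a close relative,
  conserved gene families — both loosely (any significant hit) and
  strictly (one alignment record covering most of the target);
* contigs reconstructed independently by two assemblers with different
  algorithms are far more credible than contigs seen once ("robust
  contigs").

## Coordinate convention

All intervals are 0-based, half-open, on the plus strand, for both
queries and targets.  Conversion happens entirely in the format readers:
PSL's qStart/qEnd/tStart/tEnd columns already follow this convention and
are adopted directly (per-block query offsets reported on the minus
strand are converted with `q_off = qSize − reported_start − block_len`);
BLAST tabular's 1-based inclusive coordinates are shifted, and
reverse-orientation target coordinates are normalized so start < end.
A single internal convention removes the classic off-by-one drift
between interval-arithmetic call sites.

For translated searches (BLASTX) target intervals are in residues and
query intervals in nucleotides.  Units never mix because target
coverage (reference recovery) is always measured on the target, and
novelty is always measured on the query.

## Pre-processing

Adapter removal follows the mask-then-retrim scheme: every adapter-vs-
read alignment with bit-score **strictly greater** than 25 masks its
read interval (overlaps merged); the longest unmasked window becomes
the new trim points; ties go to the leftmost window (deterministic and
input-order independent).  The threshold is exposed as a flag with 25
as the default.  Reads whose trimmed sequence contains more than one N
are discarded — one N is allowed because degenerate oligo-dT priming
typically leaves a single N mid-way through a poly(A) tail.  The N
filter runs *after* trimming, so Ns inside masked adapter sequence can
never cause a discard.  Poly(A/T) runs are never clipped anywhere in
the pipeline; a pure-A read with no adapter hits passes through
unchanged (a property test asserts this).  The adapter search itself
(BLASTN of the adapter against the reads) is external; the module
consumes its tabular output.

## Contig metrics

Contigs shorter than 100 bases and singletons are removed before any
statistic.  Singleton detection is id-pattern based (e.g. MIRA's `_s`
suffix) because FASTA carries no read counts; when an ACE layout is
available, membership can be used instead.  N50 uses exact integer
arithmetic (`2·cum ≥ total`), so even totals are unambiguous; the
"contigs in N50" count *includes* the contig that crosses the half
total.  Mean contig length is rounded to the nearest integer, half away
from zero, matching published integer means; all percentages are
likewise rounded half away from zero to one decimal (`util.round_half_away`,
via `decimal`, since Python's `round` is half-to-even).

## Reference recovery and the 80 % rule

A target is *hit* when at least one filtered alignment record touches
it; base coverage is the union of target-side spans.  The strict
variants admit only records whose single-record target coverage
`(t_end − t_start)/target_len` reaches the threshold (default 0.8):
a target qualifies only if one such record exists — two 50 % hits that
tile the whole target do not qualify it — and base coverage under the
rule is the union over qualifying records only (the permissive
alternative, counting all hits to qualifying targets, was the other
defensible reading; the qualifying-hits-only form is implemented and
documented here).  BLAST hits are filtered at e-value strictly below
10⁻⁵ by default; hit granularity is one PSL record or one HSP — the
rule is never evaluated on unions.  Grouped references (tribes, KOGs)
count a group as hit when any member target is hit, with the number of
distinct groups as denominator.

Coverage percentages use alignment spans (t-interval unions), not
match counts: spans are what both PSL and tabular output state
directly, and the per-record coverage rule is span-based by definition.

## Novelty

`novel_bases(other, hits)` counts, per contig of *other*, the bases
covered by no query-side interval of any alignment to the focal
assembly; contigs with no hits contribute their full length.  The
other assembly is the query and the focal assembly the database — the
question asked is "which of *other's* bases are absent from *focal*" —
and the matrix is asymmetric by construction.  Novelty is measured on
query (nucleotide) coordinates.

## Merging and robust contigs

First-order contigs are pooled as pseudo-reads with ids
`<source>|<original_id>`; the id prefix is the source-tracking
mechanism and survives the round trip through any co-assembler that
preserves read names.  The co-assembly itself (CAP3 with default
settings, or any OLC assembler emitting ACE) is external; the module
prepares its input — optionally with a uniform per-base quality
(default 30) since some OLC assemblers require quality files — and
classifies the resulting ACE.  A second-order contig is robust when its
members come from ≥ 2 distinct sources (`at_least_two`) or from all
sources (`all_sources`, the stricter three-way criterion; always a
subset of the former).  Pseudo-reads left out of the ACE as singletons
are never robust.  Robust contig lengths are unpadded consensus lengths
(pads `*` removed), matching FASTA conventions.

## Synthetic data

The generator emulates a 454-era non-normalised cDNA study at desk
scale.  Defaults: 300 transcripts with lengths N(1200, 400) floored at
100 bp (the expected ~1.2 kb transcript mean); per-transcript read
depth `max(1, round(lognormal(μ=1.5, σ=1.2)))`, spanning roughly two
orders of magnitude as non-normalised libraries do; read lengths
N(277, 60) (a Titanium/standard-chemistry mixture's trimmed mean);
substitution errors at 0.5 %; a fixed synthetic 29-base adapter at both
read ends (the real kit adapter is proprietary; only length and
placement matter); a 12-base poly(A) tail with one N at its midpoint;
10 % planted novelty, 10 % fragmentation and 5 % duplication per mock
assembly.  These sizes keep the full suite and the acceptance script in
seconds while leaving every statistic's behaviour unchanged, since all
computations are exact interval/integer arithmetic whose correctness
does not depend on scale.

Mock assemblies plant novelty per assembly as `k` private transcripts
out of `m` total, with `m` chosen as large as the pool allows subject
to `k/m` equalling the requested fraction exactly whenever it is
commensurable — so planted-novelty recovery tests can demand exact
equality rather than approximation.  Planted homologies between mock
assemblies are rendered identically as PSL and BLAST tabular text, and
the two readers are required to decode them to identical interval sets.

Limitations of the generator: errors are substitution-only (454's
characteristic homopolymer indels are omitted — the toolkit never
aligns sequences itself, so indel realism would not exercise any
contract); quality scores are uniform; mock ACE consensus sequences
carry no pads by default; transcript sequences are i.i.d. uniform with
no repeats, paralogy or splice isoforms.  Passing tests therefore
demonstrate the correctness of the accounting — interval unions,
thresholds, classification rules — not robustness to alignment noise or
biological repeat structure.

## Numerical and degenerate-input choices

* Thresholds are strict where the convention says strict: masking needs
  bit-score > 25; significance needs e < 10⁻⁵; the coverage rule is ≥.
* Empty inputs: empty FASTA → empty list; N50 and summary metrics of an
  empty set are domain errors; `union_len([])` = 0; a fully masked read
  is dropped (`keep=False`), not zero-trimmed.
* Median trimmed-read length uses the lower of the two middle values
  for even counts; mean is reported to 2 decimals.
* ACE `AS` header counts disagreeing with parsed counts warn rather
  than fail (common with hand-edited files); truncated contig blocks
  and duplicate read ids are format errors.
* All synthetic randomness flows from one integer seed through
  per-purpose `numpy` Generator streams (`default_rng([seed, stream])`),
  so identical seeds give identical fixtures across platforms.

## Problem sizes

The test suite and the acceptance script use: 1,000 random length
multisets of up to 10⁴ contigs for the N50 oracle; 1,000 random
interval sets on a 10⁴-base axis for the union oracle; 100 equal-length
transcripts per planted-novelty condition; 20 randomized mock ACE
layouts over three 15-contig assemblies; 200 randomized masking trials.
Published summary-table (contig count, total bases) pairs are used as
inputs to length-multiset generation when checking integer mean
reproduction and the span-growth percentage.
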