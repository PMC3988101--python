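# Methods

## Problem setting

`denovobench` benchmarks *de novo* transcriptome assembly under controlled
conditions. Because assessing an assembly requires knowing the true
transcriptome, the framework works with simulated data: it builds a ground
truth (or loads a real reference transcriptome), simulates paired-end
RNA-seq reads from it, hands the reads to an assembler, and scores the
returned contigs against the truth. Two experimental axes are first-class:
the read length of the paired reads, and the transcriptome's alternative
splicing complexity measured as the average number of spliced isoforms per
gene.

## Synthetic transcriptomes

A synthetic gene is an ordered list of exons on an abstract locus; an
isoform selects a subset of those exons in gene order, and the transcript
sequence is the concatenation of the selected exon sequences. There are no
genomic coordinates or intron sequences — only the exon structure matters
for splicing-driven assembly ambiguity, because isoforms of one gene share
letter-identical exon blocks, which is exactly what entangles de Bruijn /
overlap graphs during assembly.

**Complexity design.** A complexity setting "lo~hi isoforms per gene" is
realized by alternation: even-indexed genes receive `lo` isoforms,
odd-indexed genes `hi`. With an even gene count the transcript total is
exactly `n_genes x (lo+hi)/2`, so a design table over the ranges
(1~2, 3~4, 5~6, 7~8, 9~10) at 4000 genes and 1500 read pairs per transcript
yields exact transcript totals 6000..38000 and pair totals 9M..57M. A
deterministic rule was chosen over random isoform counts because the
design's transcript totals are round numbers that a random draw would only
approximate; the alternating variant is the simplest such rule.

**Isoform choice.** The first isoform of every gene always contains all
exons, guaranteeing the gene's longest transcript exists in the truth set
(annotated transcriptomes behave this way); the remaining isoforms are
distinct random non-empty exon subsets. A gene supports at most `2^n - 1`
distinct isoforms; requesting more raises a capacity error, and the exon
count drawn for a gene is floored at `ceil(log2(k+1))` so the requested
count is always attainable.

**Defaults.** Exon lengths default to a clipped log-normal (median 150 bp,
sigma 0.7, clipped to [30, 2000] bp) and exon counts to uniform [4, 12] —
unremarkable values for annotated eukaryotic genomes, exposed in
configuration. Sequences are uppercase ACGT with i.i.d. uniform letters; no
ambiguity codes. Because the exon samplers are identical across complexity
settings, per-gene exon-count and isoform-length distributions are
invariant across the series (the test suite checks mean exon counts agree
within 5% between the 1~2 and 9~10 settings), so complexity is the only
moving part.

## Read simulation

**Fragment model.** `insert_size` is the *full fragment length*. This
interpretation is forced by the benchmarked regime of 200 bp reads on a
200 bp insert: under the "inner distance" reading such pairs would be
impossible, under the full-length reading the mates simply overlap
completely. Fragment starts are uniform on `[0, L - insert_size]`;
transcripts shorter than the insert are skipped and reported (never padded),
keeping the fragment model exact. Mates follow FR orientation: mate 1 is the
fragment's 5' prefix, mate 2 the reverse complement of its 3' suffix, both
of length `read_length <= insert_size`.

**Expression.** Two modes. `uniform_count` gives every transcript the same
pair count (the mode used for the complexity series, 1500 pairs per
transcript). `random_weights` draws log-uniform weights on [1, 1e4] — a
four-decade dynamic range typical of bulk RNA-seq — normalizes them, and
allocates a fixed total multinomially, so pair totals are conserved exactly.

**Errors.** Sequencing errors are independent per-base substitutions at a
single position-uniform rate; a substituted base becomes one of the three
other nucleotides uniformly. No indel errors, no quality ramp, no GC bias,
no PCR duplicates: the model is deliberately flat so that read length and
complexity are the only experimental variables. Constant 'I' quality
strings are emitted since the evaluation never consults qualities. Every
injected error's read offset is recorded in a truth table, from which the
empirical per-position error profile and a chi-square flatness test are
computed; at the suite's scale (1e5 reads of 75 bp at 1%) the profile is
statistically flat and the empirical rate sits in the 3-sigma binomial band.

**Determinism.** All randomness flows from `numpy.random.default_rng`
seeded from the configuration; transcripts are processed in sorted-id order
from a single stream, so a fixed config reproduces byte-identical FASTQ.

## Alignment

Evaluation consumes BLAT PSL rows (the 21-column format, 0-based half-open,
with the reversed-query convention for '-' strand block starts); a tolerant
parser handles the optional psLayout header. For desk-scale work without
BLAT, an internal Smith-Waterman/Gotoh local aligner produces the same
block structure: match +1, mismatch -1, affine gaps (-3 open including the
first base, -1 extend). Affine penalties matter for topology: with linear
gaps an indel can tie with an alignment that splits the gap around chance
matches, whereas the affine scores keep one clean gap run, matching what
BLAT reports on near-exact matches. Both strands are tried; alignments
scoring below 40 are discarded as spurious (random 300-500 bp sequence
pairs score far below this, so junk contigs produce no alignment at all).
The aligner is O(nm) per pair and JIT-compiled; it targets fixtures of
hundreds of bases to a few kilobases, not full-scale assemblies — at full
scale, BLAT's PSL output is the intended input.

## Evaluation metrics

Four metrics, all percentages, computed from identity-gated alignments
(identity = matches / (matches + mismatches), gate at >= 0.95; indels are
judged separately):

1. **Full-length percentage** — share of reference transcripts for which a
   *single* assembled transcript has an alignment spanning the entire
   reference (`t_start = 0`, `t_end = ref_len`) with total indel bases
   (`q_gap_bases + t_gap_bases`) at most 1% of the reference length.
   Unions of several contigs never count; several contigs reconstructing
   one reference count it once.
2. **False positive rate** — share of (length-filtered) assembled
   transcripts whose best single-target alignment covers less than 50% of
   the query (aligned bases = block-size sum, so mismatching columns count
   as aligned). Coverage is *not* summed across different references: a
   chimera half-matching two references is still a false positive.
3. **Nucleotide sensitivity** — correct bases over total reference bases. A
   reference base is correct when some prediction's aligned block covers it
   with the matching letter; the union over predictions counts each base
   once. Mismatching columns inside an accepted alignment do not count as
   correct — "correct" is taken literally at the letter level.
4. **Nucleotide specificity** — correct bases over total predicted bases,
   counted on each prediction's single best alignment.

Assembled transcripts shorter than 200 bp are removed before evaluation,
mirroring the downstream length filter assemblers are conventionally run
with. Best alignments are selected per (query, target) pair by most
matches, then fewest gap bases, then leftmost target start — an arbitrary
but deterministic tie-break. The denominator of the 1% indel allowance is
the reference length (the rule is about covering the reference). An empty
assembly has no predicted bases; specificity is then reported as 100.0 with
an explicit `specificity_undefined` flag rather than inventing a 0/0 value,
and the false positive rate is reported as 0.

Boundary behavior is exact by construction: identity exactly 0.95 passes,
aligned fraction exactly 0.50 is not a false positive, and gap bases
exactly equal to 1% of the reference length still pass full-length.

**Cross-validation.** The metric engine is checked against a brute-force
oracle (in the test suite) that re-derives all four metrics by literal
per-base marking with plain loops over every alignment; on randomized
fixtures of up to 20 transcripts the two agree exactly, including at the
three boundaries above.

**A subtlety of truncated assemblies.** With alternative splicing, a
truncated copy of a long isoform can legitimately be a full-length
reconstruction of a *different*, shorter isoform assembled from its leading
shared exons. The evaluator follows the metric definition rather than
provenance, so truncation drives full-length to 0% only on single-isoform
references; on spliced references it degrades without necessarily
vanishing.

## Experiment pipeline

Three sweep families — read length, error rate, complexity (isoform range)
— run the same chain per sweep value: build/load reference, simulate,
assemble, align, evaluate. External assemblers plug in as shell command
templates (`{reads1} {reads2} {out_fasta} {workdir}`); the conventional
full-scale command lines for Trinity and Velvet/Oases ship as documented
presets, and an assembler failure is recorded as a failed row without
aborting the sweep. Three reference-peeking stub assemblers (identity,
truncating, chimera) make the full pipeline testable with no external
binaries: the identity stub turns the end-to-end chain into a fixed-point
test whose correct output is exactly (100%, 0%, 100%, 100%) at every sweep
value. Each per-value directory carries the reads, truth table, reference
and a metrics JSON keyed by a config hash, so re-running a finished
experiment reloads rows instead of recomputing them.

**Plateau (threshold) detection.** For a read-length sweep sorted
ascending, the detected threshold is the smallest read length such that
every longer read length gains at most 1 percentage point of full-length
percentage, does not decrease the false positive rate, and gains at most 1
point of nucleotide sensitivity. Specificity is reported but not gated — a
sub-point decrease at long read lengths is tolerated. The last row alone
never qualifies (a plateau must be confirmed by at least one longer read
length), so a monotonically improving table yields no threshold.

## Problem sizes

The test suite and the reproduction script run at desk scale: transcriptomes
of ~10-60 genes, hundreds to thousands of read pairs, 50 randomized
evaluator fixtures of <= 20 transcripts x <= 500 bp, and error statistics
over 1e6 bases / 1e5 reads — sizes at which the statistical assertions
(3-sigma binomial bands, chi-square flatness at alpha = 0.01,
Kolmogorov-Smirnov uniformity at alpha = 0.01) are already sharp. The same
configuration objects scale to the full published regime (4000 genes,
9-57M pairs) when an external assembler and BLAT are available; nothing in
the code special-cases the small sizes.

## Limitations

* The error model is substitution-only and position-uniform; real Illumina
  data have 3'-ramped, context-dependent errors and indels.
* The generator does not emulate annotation-derived gene structures
  (UTR/CDS, biased exon usage, correlated isoform expression); transcripts
  are i.i.d. uniform sequences, so k-mer sharing between unrelated genes is
  lower than in real genomes. Passing benchmarks here demonstrates the
  framework's correctness, not an assembler's field performance.
* The internal aligner is quadratic and unbanded; it is a BLAT stand-in for
  fixtures, not a production mapper.
* Expression in `random_weights` mode is log-uniform and uncorrelated with
  transcript identity; no isoform-switching or condition structure.
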