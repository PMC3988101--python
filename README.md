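# denovobench

Simulation-driven benchmarking of *de novo* transcriptome assembly.

Judging a transcriptome assembly requires knowing the true transcriptome,
which real data never provide. `denovobench` builds that truth: it
generates synthetic transcriptomes with a controlled number of spliced
isoforms per gene (or loads a real reference FASTA, e.g. an Ensembl cDNA
set), simulates paired-end RNA-seq reads with a tunable substitution-error
rate, runs any external assembler through a pluggable command hook, and
scores the assembled contigs against the truth. It is aimed at method
developers and bioinformaticians who want to know *when* assemblers break —
as read length shrinks, error rates grow, or alternative splicing
multiplies isoforms per gene.

## The evaluation model

Assembled transcripts (length-filtered at ≥ 200 bp) are aligned to the
reference — via BLAT PSL files at full scale, or a built-in Smith–Waterman/
Gotoh local aligner at desk scale — and only alignments with identity

    identity = matches / (matches + mismatches) ≥ 0.95

are considered. Four metrics summarize the assembly:

| metric | definition |
|---|---|
| full-length % | reference transcripts entirely covered by a *single* contig with gap bases ≤ 1% of the reference length |
| false positive rate | contigs with < 50% of their sequence alignable to any single reference transcript |
| nucleotide sensitivity | letter-matching reference bases (union over contigs) / total reference bases |
| nucleotide specificity | letter-matching predicted bases (best alignment per contig) / total predicted bases |

Transcriptome complexity is swept through a design table built by an
alternating isoforms-per-gene rule, so e.g. 4000 genes at "1~2" isoforms
give exactly 6000 transcripts and, at 1500 pairs per transcript, exactly
9 M read pairs — up to 38 000 transcripts and 57 M pairs at "9~10".

## Worked example

Simulate a tiny spliced transcriptome, sequence it perfectly, "assemble"
with the identity stub, and score:

```bash
denovobench synthesize --genes 6 --isoforms 1-2 --seed 3 --out ref.fa
# wrote 9 transcripts to ref.fa
denovobench simulate --reference ref.fa --read-length 75 --insert-size 200 \
    --error-rate 0.0 --reads-per-transcript 10 --seed 42 --out reads
# wrote 90 pairs to reads_[12].fastq
denovobench evaluate --assembly ref.fa --reference ref.fa --align-internal
# Full-length Percentage   100.0
# False Positive Rate      0.0
# Nucleotide Sensitivity   100.0
# Nucleotide Specificity   100.0
```

A self-evaluation is a fixed point — every reference is full-length
reconstructed, nothing is a false positive, and every base on both sides is
correct. Degrade the assembly and the metrics respond: rerunning the last
step with a 40%-truncated copy of each transcript
(`stub:truncate:0.4` through the pipeline) drops full-length to 0% on
single-isoform genes while specificity stays at 100%, since every surviving
base still matches.

The same machinery runs as a sweep from a YAML config:

```yaml
experiment_kind: read_length_sweep     # or error_sweep / complexity_sweep
sweep_values: [50, 75, 100, 150]
sim: {read_length: 75, insert_size: 200, error_rate: 0.0,
      reads_per_transcript: 10, seed: 9}
synthesis: {n_genes: 20, isoform_range: [1, 2]}
assembler: "stub:identity"             # or a Trinity/Oases command template
output_dir: sweep_out
seed: 9
```

```bash
denovobench run-all --config sweep.yaml
```

which writes a per-value directory (reads, truth table, metrics) and a
TSV report, and — for read-length sweeps — detects the plateau threshold:
the shortest read length beyond which full-length percentage and
sensitivity gain ≤ 1 point and the false positive rate does not decrease.

## Layout

- `denovobench.transcriptome` — gene/isoform models, complexity design,
  synthetic sequence realization, FASTA I/O
- `denovobench.simulate` — expression assignment, fragment/pair sampling,
  error injection, FASTQ + truth-table I/O, error-profile diagnostics
- `denovobench.psl` / `denovobench.align` — PSL records and parsing; the
  internal local aligner
- `denovobench.evaluate` — the four-metric evaluator
- `denovobench.pipeline` / `denovobench.assemblers` — sweep orchestration,
  stub and external assembler hooks, report I/O
- `docs/methods.md` — model assumptions, parameter defaults and rationale,
  numerical choices, limitations
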