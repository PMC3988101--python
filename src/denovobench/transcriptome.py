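"""Synthetic transcriptome construction and reference-set handling.

A synthetic gene is an ordered list of exons on an abstract locus; its
isoforms are subsets of those exons in gene order, and a transcript is the
concatenation of the selected exon sequences.  Transcriptome complexity is
controlled through the number of spliced isoforms per gene: a dataset built
at "1~2 isoforms per gene" alternates one- and two-isoform genes, so the
total transcript count of a design is exact rather than an expectation.

The module also loads real reference transcriptomes from FASTA (one record
per transcript, optional ``gene=`` provenance in the header) so that the
same evaluation machinery runs on synthetic and downloaded references.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

ExonLengthSampler = Callable[[np.random.Generator], int]


class CapacityError(ValueError):
    """Requested more distinct isoforms than the gene's exons can yield."""


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A synthetic gene: ordered exon lengths plus a seed for its sequence."""

    gene_id: str
    exon_lengths: tuple[int, ...]
    locus_sequence_seed: int

    def __post_init__(self):
        object.__setattr__(self, "exon_lengths", tuple(int(x) for x in self.exon_lengths))
        if len(self.exon_lengths) < 1:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        if any(x < 1 for x in self.exon_lengths):
            raise ValueError(f"gene {self.gene_id}: exon lengths must be >= 1 bp")

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    @property
    def isoform_capacity(self) -> int:
        """Number of distinct non-empty ordered exon subsets: 2^n - 1."""
        return 2 ** self.n_exons - 1


@dataclass(frozen=True)
class IsoformModel:
    """One spliced isoform: a strictly increasing subset of gene exon indices."""

    transcript_id: str
    gene_id: str
    exon_indices: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "exon_indices", tuple(int(i) for i in self.exon_indices))
        if not self.exon_indices:
            raise ValueError(f"isoform {self.transcript_id}: empty exon selection")
        if any(b <= a for a, b in zip(self.exon_indices, self.exon_indices[1:])):
            raise ValueError(
                f"isoform {self.transcript_id}: exon indices must be strictly increasing"
            )

    def length(self, gene: GeneModel) -> int:
        return sum(gene.exon_lengths[i] for i in self.exon_indices)


class TranscriptSet:
    """Mapping transcript_id -> (sequence, gene_id or None).

    Ids are unique and sequences non-empty over {A,C,G,T}; this is the
    ground-truth container shared by the simulator and the evaluator.
    """

    def __init__(self, records: Mapping[str, tuple[str, str | None]] | None = None):
        self._records: dict[str, tuple[str, str | None]] = {}
        if records:
            for tid, (seq, gid) in records.items():
                self.add(tid, seq, gid)

    def add(self, transcript_id: str, sequence: str, gene_id: str | None = None) -> None:
        if transcript_id in self._records:
            raise ValueError(f"duplicate transcript id: {transcript_id}")
        if not sequence:
            raise ValueError(f"empty sequence for transcript {transcript_id}")
        self._records[transcript_id] = (sequence.upper(), gene_id)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._records

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def ids(self) -> list[str]:
        return list(self._records)

    def sequence(self, transcript_id: str) -> str:
        return self._records[transcript_id][0]

    def gene_of(self, transcript_id: str) -> str | None:
        return self._records[transcript_id][1]

    def items(self) -> Iterator[tuple[str, str, str | None]]:
        for tid, (seq, gid) in self._records.items():
            yield tid, seq, gid

    def lengths(self) -> dict[str, int]:
        return {tid: len(seq) for tid, (seq, _) in self._records.items()}

    def total_bases(self) -> int:
        return sum(len(seq) for seq, _ in self._records.values())

    # -- FASTA I/O -----------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path) -> "TranscriptSet":
        path = Path(path)
        _validate_fasta_shape(path)
        out = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            gene_id = None
            for token in rec.description.split()[1:]:
                if token.startswith("gene=") or token.startswith("gene:"):
                    gene_id = token[5:]
                    break
            if rec.id in out:
                raise FastaParseError(f"duplicate transcript id: {rec.id}")
            out.add(rec.id, str(rec.seq), gene_id)
        return out

    def to_fasta(self, path: str | Path) -> None:
        records = []
        for tid, seq, gid in self.items():
            desc = f"gene={gid}" if gid is not None else ""
            records.append(SeqRecord(Seq(seq), id=tid, description=desc))
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")  # 60-column wrap


def _validate_fasta_shape(path: Path) -> None:
    """Basic structural checks SeqIO is too forgiving about."""
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                saw_header = True
                if len(stripped) == 1:
                    raise FastaParseError("FASTA header without an id", lineno)
            elif not saw_header:
                raise FastaParseError("sequence data before any FASTA header", lineno)
    if not saw_header:
        raise FastaParseError("no FASTA records found", 1)


def load_reference_transcripts(path: str | Path) -> TranscriptSet:
    """Load a reference transcriptome (e.g. an Ensembl cDNA FASTA)."""
    return TranscriptSet.from_fasta(path)


def write_fasta(transcripts: TranscriptSet, path: str | Path) -> None:
    transcripts.to_fasta(path)


# ---------------------------------------------------------------------------
# complexity-series design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignRow:
    dataset_id: int
    isoform_range: tuple[int, int]
    n_genes: int
    n_transcripts: int
    reads_per_transcript: int
    total_read_pairs: int


@dataclass(frozen=True)
class ComplexityDesign:
    """The complexity-series design table: one row per isoforms-per-gene range."""

    rows: tuple[DesignRow, ...]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "DatasetID\tIsoformsPerGene\tGenes\tTranscripts\t"
                "TotalReadPairs\tReadsPerTranscript\n"
            )
            for r in self.rows:
                fh.write(
                    f"{r.dataset_id}\t{r.isoform_range[0]}~{r.isoform_range[1]}\t"
                    f"{r.n_genes}\t{r.n_transcripts}\t{r.total_read_pairs}\t"
                    f"{r.reads_per_transcript}\n"
                )


def design_complexity_series(
    n_genes: int,
    isoform_ranges: Sequence[tuple[int, int]],
    reads_per_transcript: int,
) -> ComplexityDesign:
    """Build the design table for a series of isoforms-per-gene settings.

    A range ``(lo, hi)`` is realized by alternating lo/hi across genes (even
    gene index -> lo, odd -> hi), so with an even gene count the transcript
    total equals ``n_genes * (lo + hi) / 2`` exactly and the read-pair total
    is proportional to the transcript count.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if reads_per_transcript < 0:
        raise ValueError("reads_per_transcript must be >= 0")
    rows = []
    for k, (lo, hi) in enumerate(isoform_ranges, start=1):
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid isoform range ({lo}, {hi})")
        n_lo = (n_genes + 1) // 2  # even indices 0, 2, ...
        n_hi = n_genes // 2
        n_tx = n_lo * lo + n_hi * hi
        rows.append(
            DesignRow(
                dataset_id=k,
                isoform_range=(lo, hi),
                n_genes=n_genes,
                n_transcripts=n_tx,
                reads_per_transcript=reads_per_transcript,
                total_read_pairs=n_tx * reads_per_transcript,
            )
        )
    return ComplexityDesign(rows=tuple(rows))


# ---------------------------------------------------------------------------
# gene / isoform synthesis
# ---------------------------------------------------------------------------


def fixed_length(length: int) -> ExonLengthSampler:
    """Sampler that always returns ``length``."""
    if length < 1:
        raise ValueError("exon length must be >= 1")
    return lambda rng: length


def log_normal_lengths(
    median: float = 150.0, sigma: float = 0.7, lo: int = 30, hi: int = 2000
) -> ExonLengthSampler:
    """Log-normal exon-length sampler, clipped to [lo, hi] bp.

    Defaults give a median near 150 bp with a right tail, the familiar shape
    of exon-length distributions in annotated genomes.
    """
    mu = math.log(median)

    def sample(rng: np.random.Generator) -> int:
        return int(np.clip(round(rng.lognormal(mu, sigma)), lo, hi))

    return sample


DEFAULT_EXON_SAMPLER = log_normal_lengths()
DEFAULT_EXON_COUNT_RANGE = (4, 12)


def synthesize_gene(
    gene_id: str,
    n_exons: int,
    exon_length_sampler: ExonLengthSampler | int,
    seed: int,
) -> GeneModel:
    """Draw a gene model with ``n_exons`` exons; reproducible for a fixed seed."""
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    if isinstance(exon_length_sampler, int):
        exon_length_sampler = fixed_length(exon_length_sampler)
    rng = np.random.default_rng(seed)
    lengths = tuple(exon_length_sampler(rng) for _ in range(n_exons))
    locus_seed = int(rng.integers(0, 2**31))
    return GeneModel(gene_id=gene_id, exon_lengths=lengths, locus_sequence_seed=locus_seed)


def enumerate_isoforms(gene: GeneModel, k: int, seed: int) -> list[IsoformModel]:
    """Pick ``k`` pairwise-distinct isoforms of ``gene``.

    The first isoform always contains every exon, so the gene's longest
    transcript is a real isoform; the remaining k-1 are distinct random
    non-empty exon subsets.  Raises :class:`CapacityError` when k exceeds
    the 2^n - 1 distinct subsets the gene supports.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    capacity = gene.isoform_capacity
    if k > capacity:
        raise CapacityError(
            f"gene {gene.gene_id}: {k} isoforms requested but only "
            f"{capacity} distinct exon subsets exist"
        )
    rng = np.random.default_rng(seed)
    n = gene.n_exons
    full = tuple(range(n))
    chosen: list[tuple[int, ...]] = [full]
    if k > 1:
        if capacity <= max(1024, 4 * k):
            pool = [
                subset
                for r in range(1, n + 1)
                for subset in itertools.combinations(range(n), r)
                if subset != full
            ]
            order = rng.permutation(len(pool))
            chosen.extend(pool[i] for i in order[: k - 1])
        else:
            seen = {full}
            while len(chosen) < k:
                mask = int(rng.integers(1, 2**n))
                subset = tuple(i for i in range(n) if mask >> i & 1)
                if subset not in seen:
                    seen.add(subset)
                    chosen.append(subset)
    return [
        IsoformModel(
            transcript_id=f"{gene.gene_id}.t{j + 1}",
            gene_id=gene.gene_id,
            exon_indices=subset,
        )
        for j, subset in enumerate(chosen)
    ]


def realize_sequences(
    genes: Sequence[GeneModel],
    isoforms: Sequence[IsoformModel],
    seed: int,
) -> TranscriptSet:
    """Materialize nucleotide sequences: each transcript is the concatenation
    of its gene's exon sequences at its exon indices, so isoforms of one gene
    share letter-identical exons."""
    gene_map = {g.gene_id: g for g in genes}
    for iso in isoforms:
        if iso.gene_id not in gene_map:
            raise KeyError(f"isoform {iso.transcript_id} references unknown gene {iso.gene_id}")
    exon_seqs: dict[str, list[str]] = {}
    for g in genes:
        rng = np.random.default_rng([seed, g.locus_sequence_seed])
        exon_seqs[g.gene_id] = [
            _DECODE[rng.integers(0, 4, size=length)].tobytes().decode()
            for length in g.exon_lengths
        ]
    out = TranscriptSet()
    for iso in isoforms:
        seq = "".join(exon_seqs[iso.gene_id][i] for i in iso.exon_indices)
        out.add(iso.transcript_id, seq, iso.gene_id)
    return out


def synthesize_transcriptome(
    n_genes: int,
    isoform_range: tuple[int, int],
    seed: int,
    exon_count_range: tuple[int, int] = DEFAULT_EXON_COUNT_RANGE,
    exon_length_sampler: ExonLengthSampler | int | None = None,
    gene_prefix: str = "g",
) -> tuple[list[GeneModel], list[IsoformModel], TranscriptSet]:
    """Build a full synthetic transcriptome at one complexity setting.

    Gene ``i`` receives ``lo`` isoforms when i is even and ``hi`` when odd
    (the alternating rule that makes design-table transcript counts exact).
    Exon counts are drawn uniformly from ``exon_count_range`` but floored at
    the minimum needed so that the requested isoform count is attainable.
    """
    lo, hi = isoform_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid isoform range ({lo}, {hi})")
    if exon_length_sampler is None:
        exon_length_sampler = DEFAULT_EXON_SAMPLER
    master = np.random.default_rng([seed, 1])
    genes: list[GeneModel] = []
    isoforms: list[IsoformModel] = []
    width = max(5, len(str(max(n_genes - 1, 0))))
    for i in range(n_genes):
        k = lo if i % 2 == 0 else hi
        n_min = max(exon_count_range[0], math.ceil(math.log2(k + 1)))
        n_exons = int(master.integers(n_min, max(exon_count_range[1], n_min) + 1))
        gene_seed = int(master.integers(0, 2**31))
        iso_seed = int(master.integers(0, 2**31))
        gene = synthesize_gene(f"{gene_prefix}{i:0{width}d}", n_exons, exon_length_sampler, gene_seed)
        genes.append(gene)
        isoforms.extend(enumerate_isoforms(gene, k, iso_seed))
    transcripts = realize_sequences(genes, isoforms, seed)
    return genes, isoforms, transcripts


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def summarize_distributions(
    genes: Sequence[GeneModel], isoforms: Sequence[IsoformModel]
) -> dict[str, dict[str, float]]:
    """Quartile/mean summaries of per-gene exon counts and per-isoform
    lengths, the two distributions that must stay invariant across
    complexity settings built with the same exon sampler."""
    if not genes or not isoforms:
        raise ValueError("summarize_distributions requires non-empty genes and isoforms")
    gene_map = {g.gene_id: g for g in genes}
    exon_counts = np.array([g.n_exons for g in genes], dtype=float)
    iso_lengths = np.array([iso.length(gene_map[iso.gene_id]) for iso in isoforms], dtype=float)

    def _summary(x: np.ndarray) -> dict[str, float]:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {
            "n": int(x.size),
            "mean": float(x.mean()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "min": float(x.min()),
            "max": float(x.max()),
        }

    return {"exon_count": _summary(exon_counts), "isoform_length": _summary(iso_lengths)}


def write_gff3(
    genes: Sequence[GeneModel],
    isoforms: Sequence[IsoformModel],
    path: str | Path,
    intron_length: int = 50,
) -> None:
    """Optional GFF3-like export of gene/isoform structures for inspection.

    Each gene sits on its own abstract locus; exons are laid out left to
    right with fixed ``intron_length`` spacers (1-based inclusive spans).
    """
    gene_map = {g.gene_id: g for g in genes}
    by_gene: dict[str, list[IsoformModel]] = {}
    for iso in isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            starts = []
            pos = 1
            for length in g.exon_lengths:
                starts.append(pos)
                pos += length + intron_length
            locus_end = starts[-1] + g.exon_lengths[-1] - 1
            seqid = f"locus_{g.gene_id}"
            fh.write(
                f"{seqid}\tdenovobench\tgene\t1\t{locus_end}\t.\t+\t.\tID={g.gene_id}\n"
            )
            for iso in by_gene.get(g.gene_id, []):
                first, last = iso.exon_indices[0], iso.exon_indices[-1]
                fh.write(
                    f"{seqid}\tdenovobench\tmRNA\t{starts[first]}\t"
                    f"{starts[last] + g.exon_lengths[last] - 1}\t.\t+\t.\t"
                    f"ID={iso.transcript_id};Parent={g.gene_id}\n"
                )
                for i in iso.exon_indices:
                    fh.write(
                        f"{seqid}\tdenovobench\texon\t{starts[i]}\t"
                        f"{starts[i] + g.exon_lengths[i] - 1}\t.\t+\t.\t"
                        f"Parent={iso.transcript_id}\n"
                    )
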