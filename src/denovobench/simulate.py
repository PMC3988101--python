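"""Paired-end RNA-seq read simulation with a flat substitution-error model.

Fragments of a fixed insert size (the *full* fragment length: 200 bp reads
with a 200 bp insert are fully overlapping mates) are drawn uniformly along
each transcript in proportion to its assigned expression.  Mate 1 reads the
fragment's 5' end forward, mate 2 the 3' end reverse-complemented (FR
orientation).  Sequencing errors are independent per-base substitutions at a
position-uniform rate; every injected error is recorded in a truth table so
the empirical error profile can be audited downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .transcriptome import TranscriptSet

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_ENCODE = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class TranscriptTooShortError(ValueError):
    """Skip signal: the transcript cannot hold one full fragment."""


# ---------------------------------------------------------------------------
# configuration and records
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Knobs of one simulation run.

    insert_size is the full fragment length in bp; read_length must not
    exceed it.  In ``uniform_count`` mode every transcript receives exactly
    ``reads_per_transcript`` pairs; in ``random_weights`` mode log-uniform
    expression weights are drawn and ``total_pairs`` pairs are allocated
    multinomially.
    """

    read_length: int
    insert_size: int
    error_rate: float = 0.0
    expression_mode: str = "uniform_count"
    reads_per_transcript: int | None = None
    total_pairs: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.read_length <= self.insert_size:
            raise ValueError(
                f"need 1 <= read_length <= insert_size, got "
                f"{self.read_length} / {self.insert_size}"
            )
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.expression_mode == "uniform_count":
            if self.reads_per_transcript is None or self.reads_per_transcript < 0:
                raise ValueError("uniform_count mode needs reads_per_transcript >= 0")
        elif self.expression_mode == "random_weights":
            if self.total_pairs is None or self.total_pairs < 0:
                raise ValueError("random_weights mode needs total_pairs >= 0")
        else:
            raise ValueError(f"unknown expression_mode: {self.expression_mode}")


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-transcript expression weights and realized pair counts."""

    weights: dict[str, float]
    pair_counts: dict[str, int]

    def total_pairs(self) -> int:
        return sum(self.pair_counts.values())


@dataclass(frozen=True)
class FragmentSpec:
    start: int
    insert_size: int


@dataclass(frozen=True)
class ReadPairRecord:
    """One simulated pair plus its ground truth (origin and injected errors)."""

    pair_id: str
    mate1_seq: str
    mate2_seq: str
    origin_transcript: str
    fragment_start: int
    insert_size: int
    error_positions_mate1: tuple[int, ...]
    error_positions_mate2: tuple[int, ...]


@dataclass(frozen=True)
class TruthRecord:
    pair_id: str
    origin_transcript: str
    fragment_start: int
    insert_size: int
    error_positions_mate1: tuple[int, ...]
    error_positions_mate2: tuple[int, ...]


@dataclass
class SimulationResult:
    pairs: list[ReadPairRecord]
    skipped: dict[str, int] = field(default_factory=dict)  # transcript -> pairs not emitted

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

DEFAULT_WEIGHT_RANGE = (1.0, 1.0e4)  # log-uniform span of "random expression levels"


def assign_expression(tx: TranscriptSet, config: SimulationConfig) -> ExpressionProfile:
    """Assign an expression level and a pair count to every transcript."""
    if len(tx) == 0:
        raise ValueError("cannot assign expression to an empty TranscriptSet")
    ids = sorted(tx.ids())
    n = len(ids)
    if config.expression_mode == "uniform_count":
        counts = {tid: int(config.reads_per_transcript) for tid in ids}
        weights = {tid: 1.0 / n for tid in ids}
        return ExpressionProfile(weights=weights, pair_counts=counts)
    rng = np.random.default_rng([config.seed, 7])
    lo, hi = DEFAULT_WEIGHT_RANGE
    raw = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    p = raw / raw.sum()
    alloc = rng.multinomial(int(config.total_pairs), p)
    return ExpressionProfile(
        weights={tid: float(w) for tid, w in zip(ids, p)},
        pair_counts={tid: int(c) for tid, c in zip(ids, alloc)},
    )


# ---------------------------------------------------------------------------
# fragment / pair / error primitives
# ---------------------------------------------------------------------------


def sample_fragment(
    transcript_seq: str, insert_size: int, rng: np.random.Generator
) -> FragmentSpec:
    """Uniform fragment start on [0, L - insert_size] (0-based half-open)."""
    L = len(transcript_seq)
    if L < insert_size:
        raise TranscriptTooShortError(
            f"transcript length {L} < insert size {insert_size}"
        )
    start = int(rng.integers(0, L - insert_size + 1))
    return FragmentSpec(start=start, insert_size=insert_size)


def make_pair(fragment_seq: str, read_length: int) -> tuple[str, str]:
    """FR mates: mate 1 = fragment 5' prefix, mate 2 = revcomp of the 3' suffix."""
    if read_length > len(fragment_seq):
        raise ValueError(
            f"read_length {read_length} exceeds fragment length {len(fragment_seq)}"
        )
    mate1 = fragment_seq[:read_length]
    mate2 = revcomp(fragment_seq[len(fragment_seq) - read_length :])
    return mate1, mate2


def inject_errors(
    seq: str, error_rate: float, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Substitute each base independently with probability ``error_rate``.

    A substituted base becomes one of the three other nucleotides uniformly;
    the returned offsets are exactly the mutated positions.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    if error_rate == 0.0 or not seq:
        return seq, ()
    codes = _encode(seq).copy()
    mask = rng.random(codes.size) < error_rate
    n_err = int(mask.sum())
    if n_err:
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        codes[mask] = (codes[mask] + shift) % 4
    positions = tuple(int(i) for i in np.flatnonzero(mask))
    return _DECODE[codes].tobytes().decode(), positions


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------


def simulate(
    tx: TranscriptSet, profile: ExpressionProfile, config: SimulationConfig
) -> SimulationResult:
    """Generate all read pairs dictated by ``profile``.

    Transcripts shorter than the insert size are skipped (their requested
    pair counts are returned in ``SimulationResult.skipped``) rather than
    padded, keeping the fragment model exact.  Deterministic for a fixed
    config seed: transcripts are processed in sorted-id order from a single
    generator stream.
    """
    unknown = set(profile.pair_counts) - set(tx.ids())
    if unknown:
        raise KeyError(f"expression profile references unknown transcripts: {sorted(unknown)[:3]}")
    rng = np.random.default_rng([config.seed, 11])
    rl, ins, rate = config.read_length, config.insert_size, config.error_rate
    pairs: list[ReadPairRecord] = []
    skipped: dict[str, int] = {}
    for tid in sorted(profile.pair_counts):
        count = profile.pair_counts[tid]
        if count == 0:
            continue
        seq = tx.sequence(tid)
        L = len(seq)
        if L < ins:
            skipped[tid] = count
            continue
        codes = _encode(seq)
        starts = rng.integers(0, L - ins + 1, size=count)
        frag = codes[starts[:, None] + np.arange(ins)]
        m1 = frag[:, :rl].copy()
        m2 = (3 - frag[:, ins - rl :][:, ::-1]).copy()  # revcomp: A<->T, C<->G
        if rate > 0.0:
            err1 = rng.random((count, rl)) < rate
            shift = rng.integers(1, 4, size=int(err1.sum())).astype(np.uint8)
            m1[err1] = (m1[err1] + shift) % 4
            err2 = rng.random((count, rl)) < rate
            shift = rng.integers(1, 4, size=int(err2.sum())).astype(np.uint8)
            m2[err2] = (m2[err2] + shift) % 4
        else:
            err1 = err2 = None
        b1 = _DECODE[m1].tobytes()
        b2 = _DECODE[m2].tobytes()
        for k in range(count):
            pos1 = tuple(int(i) for i in np.flatnonzero(err1[k])) if err1 is not None else ()
            pos2 = tuple(int(i) for i in np.flatnonzero(err2[k])) if err2 is not None else ()
            pairs.append(
                ReadPairRecord(
                    pair_id=f"{tid}|{k}",
                    mate1_seq=b1[k * rl : (k + 1) * rl].decode(),
                    mate2_seq=b2[k * rl : (k + 1) * rl].decode(),
                    origin_transcript=tid,
                    fragment_start=int(starts[k]),
                    insert_size=ins,
                    error_positions_mate1=pos1,
                    error_positions_mate2=pos2,
                )
            )
    return SimulationResult(pairs=pairs, skipped=skipped)


# ---------------------------------------------------------------------------
# FASTQ / truth I/O
# ---------------------------------------------------------------------------


def write_fastq(
    pairs: Iterable[ReadPairRecord],
    path1: str | Path,
    path2: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write record-aligned mate FASTQ files (constant 'I' qualities) and,
    optionally, a sidecar TSV truth table."""
    truth_fh = open(truth_path, "w") if truth_path is not None else None
    try:
        if truth_fh is not None:
            truth_fh.write(
                "pair_id\ttranscript_id\tfragment_start\tinsert_size\t"
                "errors_mate1\terrors_mate2\n"
            )
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for rec in pairs:
                qual = "I" * len(rec.mate1_seq)
                f1.write(f"@{rec.pair_id}/1\n{rec.mate1_seq}\n+\n{qual}\n")
                f2.write(f"@{rec.pair_id}/2\n{rec.mate2_seq}\n+\n{qual}\n")
                if truth_fh is not None:
                    e1 = ",".join(map(str, rec.error_positions_mate1)) or "."
                    e2 = ",".join(map(str, rec.error_positions_mate2)) or "."
                    truth_fh.write(
                        f"{rec.pair_id}\t{rec.origin_transcript}\t"
                        f"{rec.fragment_start}\t{rec.insert_size}\t{e1}\t{e2}\n"
                    )
    finally:
        if truth_fh is not None:
            truth_fh.close()


def read_truth(path: str | Path) -> list[TruthRecord]:
    """Parse the sidecar truth table written by :func:`write_fastq`."""

    def _offsets(cell: str) -> tuple[int, ...]:
        return () if cell == "." else tuple(int(x) for x in cell.split(","))

    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("pair_id\t"):
            raise ValueError("not a truth table: missing header")
        for line in fh:
            pid, tid, start, ins, e1, e2 = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    pair_id=pid,
                    origin_transcript=tid,
                    fragment_start=int(start),
                    insert_size=int(ins),
                    error_positions_mate1=_offsets(e1),
                    error_positions_mate2=_offsets(e2),
                )
            )
    return out


# ---------------------------------------------------------------------------
# error-profile diagnostics
# ---------------------------------------------------------------------------


def empirical_error_profile(
    pairs: Sequence[ReadPairRecord | TruthRecord],
) -> np.ndarray:
    """Per-position mismatch fraction, pooling both mates.

    Entry i is the fraction of reads carrying an injected error at offset i;
    for a position-uniform error model the vector is statistically flat.
    """
    if not pairs:
        raise ValueError("empirical_error_profile requires at least one pair")
    read_length = _infer_read_length(pairs)
    counts = np.zeros(read_length, dtype=np.int64)
    n_reads = 0
    for rec in pairs:
        for pos in rec.error_positions_mate1:
            counts[pos] += 1
        for pos in rec.error_positions_mate2:
            counts[pos] += 1
        n_reads += 2
    return counts / n_reads


def error_profile_flatness(
    pairs: Sequence[ReadPairRecord | TruthRecord],
) -> tuple[float, float]:
    """Chi-square test of the per-position error counts against uniformity.

    Returns (statistic, p-value); a flat profile is *not* rejected, so large
    p-values are the expected outcome under the simulator's error model.
    """
    if not pairs:
        raise ValueError("error_profile_flatness requires at least one pair")
    read_length = _infer_read_length(pairs)
    counts = np.zeros(read_length, dtype=np.int64)
    for rec in pairs:
        for pos in rec.error_positions_mate1:
            counts[pos] += 1
        for pos in rec.error_positions_mate2:
            counts[pos] += 1
    if counts.sum() == 0:
        return 0.0, 1.0
    stat, p = stats.chisquare(counts)
    return float(stat), float(p)


def _infer_read_length(pairs: Sequence[ReadPairRecord | TruthRecord]) -> int:
    first = pairs[0]
    if isinstance(first, ReadPairRecord):
        return len(first.mate1_seq)
    # truth records do not carry sequences; fall back to max offset + 1
    m = 0
    for rec in pairs:
        for pos in rec.error_positions_mate1 + rec.error_positions_mate2:
            m = max(m, pos + 1)
    return max(m, 1)
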