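"""Four-metric evaluation of assembled transcripts against a reference.

Assembled transcripts (length-filtered at 200 bp) are compared to the
reference truth through alignments at >= 95% sequence identity, where
identity = matches / (matches + mismatches) and indels are governed by a
separate rule:

* full-length percentage — the fraction of reference transcripts entirely
  covered by a single assembled transcript with total indel bases at most
  1% of the reference length;
* false positive rate — the fraction of assembled transcripts with less
  than 50% of their sequence alignable to any single reference transcript;
* nucleotide sensitivity — correct bases over reference bases, a reference
  base counting as correct when some aligned prediction matches its letter
  (each reference base counted once across all predictions);
* nucleotide specificity — correct bases over predicted bases, counted on
  each prediction's best alignment.

All coordinates follow the PSL convention (0-based half-open); minus-strand
alignments are normalized to plus-strand query coordinates before per-base
marking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .psl import PslAlignment
from .simulate import revcomp
from .transcriptome import TranscriptSet

DEFAULT_MIN_LENGTH = 200
DEFAULT_IDENTITY = 0.95
DEFAULT_INDEL_FRAC = 0.01
DEFAULT_FP_FRAC = 0.5


@dataclass(frozen=True)
class EvalCounts:
    n_reference: int
    n_assembled: int
    n_full_length: int
    n_false_positive: int
    correct_on_reference: int
    correct_on_predictions: int
    reference_bases: int
    predicted_bases: int


@dataclass(frozen=True)
class EvalMetrics:
    """The four assembly-quality metrics (percentages) plus raw counts."""

    full_length_pct: float
    false_positive_pct: float
    nt_sensitivity_pct: float
    nt_specificity_pct: float
    counts: EvalCounts
    specificity_undefined: bool = False  # no predicted bases (empty assembly)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.full_length_pct,
            self.false_positive_pct,
            self.nt_sensitivity_pct,
            self.nt_specificity_pct,
        )


# ---------------------------------------------------------------------------
# elementary rules
# ---------------------------------------------------------------------------


def filter_min_length(assembled: TranscriptSet, min_len: int = DEFAULT_MIN_LENGTH) -> TranscriptSet:
    """Keep transcripts with length >= min_len (default: no less than 200 bases)."""
    out = TranscriptSet()
    for tid, seq, gid in assembled.items():
        if len(seq) >= min_len:
            out.add(tid, seq, gid)
    return out


def alignment_identity(a: PslAlignment) -> float:
    """matches / (matches + mismatches); indels are judged by a separate rule."""
    denom = a.matches + a.mismatches
    if denom <= 0:
        raise ValueError("identity undefined for an alignment with no aligned bases")
    return a.matches / denom


def is_full_length(
    ref_id: str,
    ref_len: int,
    alignments: Iterable[PslAlignment],
    indel_frac: float = DEFAULT_INDEL_FRAC,
) -> bool:
    """True iff a single assembled transcript covers the whole reference.

    Requires an alignment (already identity-filtered) whose target span is
    the entire reference and whose total indel bases do not exceed
    ``indel_frac`` of the reference length.
    """
    for a in alignments:
        if a.t_name != ref_id:
            continue
        if a.t_end - a.t_start == ref_len and a.gap_bases <= indel_frac * ref_len:
            return True
    return False


def is_false_positive(
    q_id: str,
    q_len: int,
    alignments: Iterable[PslAlignment],
    fp_frac: float = DEFAULT_FP_FRAC,
) -> bool:
    """True iff less than ``fp_frac`` of the query aligns to its best single
    reference target (aligned bases = block-size sum of the best alignment
    to that target)."""
    best_by_target: dict[str, PslAlignment] = {}
    for a in alignments:
        if a.q_name != q_id:
            continue
        cur = best_by_target.get(a.t_name)
        if cur is None or _alignment_rank(a) < _alignment_rank(cur):
            best_by_target[a.t_name] = a
    if not best_by_target:
        return True
    best_frac = max(a.aligned_length / q_len for a in best_by_target.values())
    return best_frac < fp_frac


def _alignment_rank(a: PslAlignment) -> tuple:
    """Best-alignment order: most matches, then fewest gap bases, then
    leftmost target start (deterministic tie-break)."""
    return (-a.matches, a.gap_bases, a.t_start, a.t_name)


def _best_per_pair(alignments: Iterable[PslAlignment]) -> dict[tuple[str, str], PslAlignment]:
    best: dict[tuple[str, str], PslAlignment] = {}
    for a in alignments:
        key = (a.q_name, a.t_name)
        cur = best.get(key)
        if cur is None or _alignment_rank(a) < _alignment_rank(cur):
            best[key] = a
    return best


def _plus_query_seq(a: PslAlignment, query_seq: str) -> tuple[str, bool]:
    """Query sequence in the frame the block q_starts refer to."""
    if a.strand == "-":
        return revcomp(query_seq), True
    return query_seq, False


def correct_base_map(
    alignments: Iterable[PslAlignment],
    reference: TranscriptSet,
    assembled: TranscriptSet,
) -> tuple[int, int]:
    """Count correct bases on the reference side and the prediction side.

    A base is correct when it sits inside an aligned block and the query and
    reference letters agree.  Reference-side counting unions over the best
    alignment of every (query, target) pair, so each reference base counts
    at most once however many predictions cover it; prediction-side counting
    uses each query's single best alignment, each predicted base at most
    once.
    """
    best = _best_per_pair(alignments)

    correct_ref: dict[str, set[int]] = {}
    for (q_id, t_id), a in best.items():
        q_seq, _ = _plus_query_seq(a, assembled.sequence(q_id))
        t_seq = reference.sequence(t_id)
        marked = correct_ref.setdefault(t_id, set())
        for bs, qs, ts in zip(a.block_sizes, a.q_starts, a.t_starts):
            for k in range(bs):
                if q_seq[qs + k] == t_seq[ts + k]:
                    marked.add(ts + k)
    correct_on_reference = sum(len(s) for s in correct_ref.values())

    best_per_query: dict[str, PslAlignment] = {}
    for (q_id, _), a in best.items():
        cur = best_per_query.get(q_id)
        if cur is None or _alignment_rank(a) < _alignment_rank(cur):
            best_per_query[q_id] = a
    correct_on_predictions = 0
    for q_id, a in best_per_query.items():
        q_seq, _ = _plus_query_seq(a, assembled.sequence(q_id))
        t_seq = reference.sequence(a.t_name)
        seen: set[int] = set()
        for bs, qs, ts in zip(a.block_sizes, a.q_starts, a.t_starts):
            for k in range(bs):
                if q_seq[qs + k] == t_seq[ts + k]:
                    seen.add(qs + k)
        correct_on_predictions += len(seen)
    return correct_on_reference, correct_on_predictions


# ---------------------------------------------------------------------------
# the evaluator
# ---------------------------------------------------------------------------


def evaluate(
    assembled: TranscriptSet,
    reference: TranscriptSet,
    alignments: Sequence[PslAlignment],
    min_length: int = DEFAULT_MIN_LENGTH,
    apply_length_filter: bool = True,
    identity_threshold: float = DEFAULT_IDENTITY,
    indel_frac: float = DEFAULT_INDEL_FRAC,
    fp_frac: float = DEFAULT_FP_FRAC,
) -> EvalMetrics:
    """Score an assembly with the four metrics.

    ``alignments`` may contain every alignment found (e.g. a full BLAT PSL
    file); rows below the identity threshold, rows for filtered-out queries
    and rows naming unknown sequences are ignored here.
    """
    if len(reference) == 0:
        raise ValueError("reference transcriptome is empty")
    filtered = filter_min_length(assembled, min_length) if apply_length_filter else assembled

    usable = [
        a
        for a in alignments
        if a.q_name in filtered
        and a.t_name in reference
        and a.matches + a.mismatches > 0
        and alignment_identity(a) >= identity_threshold
    ]
    best = _best_per_pair(usable)
    best_list = list(best.values())

    n_ref = len(reference)
    ref_lengths = reference.lengths()
    n_full = sum(
        1
        for t_id, t_len in ref_lengths.items()
        if is_full_length(t_id, t_len, best_list, indel_frac)
    )

    n_assembled = len(filtered)
    n_fp = sum(
        1
        for q_id in filtered.ids()
        if is_false_positive(q_id, len(filtered.sequence(q_id)), best_list, fp_frac)
    )

    correct_ref, correct_pred = correct_base_map(best_list, reference, filtered)
    reference_bases = reference.total_bases()
    predicted_bases = filtered.total_bases()

    specificity_undefined = predicted_bases == 0
    return EvalMetrics(
        full_length_pct=100.0 * n_full / n_ref,
        false_positive_pct=(100.0 * n_fp / n_assembled) if n_assembled else 0.0,
        nt_sensitivity_pct=100.0 * correct_ref / reference_bases,
        nt_specificity_pct=(
            100.0 * correct_pred / predicted_bases if predicted_bases else 100.0
        ),
        counts=EvalCounts(
            n_reference=n_ref,
            n_assembled=n_assembled,
            n_full_length=n_full,
            n_false_positive=n_fp,
            correct_on_reference=correct_ref,
            correct_on_predictions=correct_pred,
            reference_bases=reference_bases,
            predicted_bases=predicted_bases,
        ),
        specificity_undefined=specificity_undefined,
    )
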