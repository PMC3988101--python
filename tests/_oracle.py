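"""Brute-force reference evaluator used to cross-check the metric engine.

Everything here is computed by literal per-base marking with plain Python
loops over every alignment row: boolean arrays are allocated per sequence,
each aligned column is inspected one base at a time, and the four metrics
are read off the marked arrays.  No code is shared with the package's
evaluator beyond the alignment records themselves.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _identity_ok(a, threshold: float) -> bool:
    denom = a.matches + a.mismatches
    return denom > 0 and a.matches / denom >= threshold


def _is_better(a, b) -> bool:
    """True when alignment a outranks b: more matches, then fewer gap bases,
    then leftmost target start, then lexicographic target name."""
    if a.matches != b.matches:
        return a.matches > b.matches
    ga = a.q_gap_bases + a.t_gap_bases
    gb = b.q_gap_bases + b.t_gap_bases
    if ga != gb:
        return ga < gb
    if a.t_start != b.t_start:
        return a.t_start < b.t_start
    return a.t_name < b.t_name


def _oriented_query(a, assembled: dict[str, str]) -> str:
    seq = assembled[a.q_name]
    return _revcomp(seq) if a.strand == "-" else seq


def oracle_evaluate(
    assembled: dict[str, str],
    reference: dict[str, str],
    alignments,
    min_length: int = 200,
    identity: float = 0.95,
    indel_frac: float = 0.01,
    fp_frac: float = 0.5,
):
    """Four metrics by exhaustive per-base marking; returns the same shape of
    numbers the package evaluator reports, plus the raw counts."""
    kept = {q: s for q, s in assembled.items() if len(s) >= min_length}

    rows = [
        a
        for a in alignments
        if a.q_name in kept and a.t_name in reference and _identity_ok(a, identity)
    ]

    best_pair: dict[tuple[str, str], object] = {}
    for a in rows:
        key = (a.q_name, a.t_name)
        if key not in best_pair or _is_better(a, best_pair[key]):
            best_pair[key] = a

    # -- full-length: one alignment spans the whole reference, few indels ----
    n_full = 0
    for t_id, t_seq in reference.items():
        t_len = len(t_seq)
        hit = False
        for a in best_pair.values():
            if a.t_name != t_id:
                continue
            covers = (a.t_end - a.t_start) == t_len
            indels = a.q_gap_bases + a.t_gap_bases
            if covers and indels <= indel_frac * t_len:
                hit = True
        if hit:
            n_full += 1

    # -- false positives: best single-target aligned fraction < fp_frac -----
    n_fp = 0
    for q_id, q_seq in kept.items():
        best_frac = 0.0
        for (q, t), a in best_pair.items():
            if q != q_id:
                continue
            aligned = 0
            for bs in a.block_sizes:
                aligned += bs
            best_frac = max(best_frac, aligned / len(q_seq))
        if best_frac < fp_frac:
            n_fp += 1

    # -- sensitivity: union of letter-matching reference bases ---------------
    ref_marked = {t_id: [False] * len(t_seq) for t_id, t_seq in reference.items()}
    for (q_id, t_id), a in best_pair.items():
        q_seq = _oriented_query(a, kept)
        t_seq = reference[t_id]
        for bs, qs, ts in zip(a.block_sizes, a.q_starts, a.t_starts):
            for k in range(bs):
                if q_seq[qs + k] == t_seq[ts + k]:
                    ref_marked[t_id][ts + k] = True
    correct_ref = sum(sum(marks) for marks in ref_marked.values())
    reference_bases = sum(len(s) for s in reference.values())

    # -- specificity: matching bases on each query's single best alignment ---
    best_query: dict[str, object] = {}
    for (q_id, _), a in best_pair.items():
        if q_id not in best_query or _is_better(a, best_query[q_id]):
            best_query[q_id] = a
    correct_pred = 0
    for q_id, a in best_query.items():
        q_seq = _oriented_query(a, kept)
        t_seq = reference[a.t_name]
        marked = [False] * len(q_seq)
        for bs, qs, ts in zip(a.block_sizes, a.q_starts, a.t_starts):
            for k in range(bs):
                if q_seq[qs + k] == t_seq[ts + k]:
                    marked[qs + k] = True
        correct_pred += sum(marked)
    predicted_bases = sum(len(s) for s in kept.values())

    n_ref = len(reference)
    n_asm = len(kept)
    return {
        "full_length_pct": 100.0 * n_full / n_ref,
        "false_positive_pct": 100.0 * n_fp / n_asm if n_asm else 0.0,
        "nt_sensitivity_pct": 100.0 * correct_ref / reference_bases,
        "nt_specificity_pct": 100.0 * correct_pred / predicted_bases if predicted_bases else 100.0,
        "n_full_length": n_full,
        "n_false_positive": n_fp,
        "correct_on_reference": correct_ref,
        "correct_on_predictions": correct_pred,
        "predicted_bases": predicted_bases,
    }
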