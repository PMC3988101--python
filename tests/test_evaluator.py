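"""The four-metric evaluator: elementary rules, boundary exactness, and
agreement with the brute-force per-base marking oracle."""

import numpy as np
import pytest

from denovobench.align import align_all
from denovobench.evaluate import (
    alignment_identity,
    correct_base_map,
    evaluate,
    filter_min_length,
    is_false_positive,
    is_full_length,
)
from denovobench.psl import PslAlignment
from denovobench.transcriptome import TranscriptSet

from _oracle import oracle_evaluate
from conftest import mutate, random_seq


def _block_row(q, t, q_size, t_size, blocks, mismatches=0, strand="+",
               q_gaps=(0, 0), t_gaps=(0, 0)):
    """Helper: build a PSL row from (size, q_start, t_start) blocks."""
    total = sum(b[0] for b in blocks)
    return PslAlignment(
        matches=total - mismatches,
        mismatches=mismatches,
        rep_matches=0,
        n_count=0,
        q_gap_count=q_gaps[0],
        q_gap_bases=q_gaps[1],
        t_gap_count=t_gaps[0],
        t_gap_bases=t_gaps[1],
        strand=strand,
        q_name=q,
        q_size=q_size,
        q_start=blocks[0][1],
        q_end=blocks[-1][1] + blocks[-1][0],
        t_name=t,
        t_size=t_size,
        t_start=blocks[0][2],
        t_end=blocks[-1][2] + blocks[-1][0],
        block_count=len(blocks),
        block_sizes=tuple(b[0] for b in blocks),
        q_starts=tuple(b[1] for b in blocks),
        t_starts=tuple(b[2] for b in blocks),
    )


class TestElementaryRules:
    def test_min_length_boundary(self, rng):
        tx = TranscriptSet()
        for n in (199, 200, 201):
            tx.add(f"t{n}", random_seq(rng, n))
        kept = filter_min_length(tx, 200)
        assert sorted(kept.ids()) == ["t200", "t201"]
        assert len(filter_min_length(TranscriptSet(), 200)) == 0
        assert len(filter_min_length(tx, 0)) == 3

    def test_identity_definition(self):
        a = _block_row("q", "t", 100, 100, [(100, 0, 0)], mismatches=5)
        assert alignment_identity(a) == pytest.approx(0.95)
        b = _block_row("q", "t", 100, 100, [(100, 0, 0)], mismatches=0)
        assert alignment_identity(b) == 1.0
        c = _block_row("q", "t", 100, 100, [(100, 0, 0)], mismatches=6)
        assert alignment_identity(c) == pytest.approx(0.94)

    def test_full_length_requires_total_coverage(self):
        full = _block_row("q", "r", 300, 300, [(300, 0, 0)])
        assert is_full_length("r", 300, [full])
        one_short = _block_row("q", "r", 300, 300, [(299, 0, 0)])
        assert not is_full_length("r", 300, [one_short])

    def test_full_length_indel_boundary(self):
        """1% of a 1000 bp reference is 10 gap bases: 10 passes, 11 fails."""
        ten = _block_row("q", "r", 990, 1000, [(500, 0, 0), (490, 500, 510)],
                         t_gaps=(1, 10))
        eleven = _block_row("q", "r", 989, 1000, [(500, 0, 0), (489, 500, 511)],
                           t_gaps=(1, 11))
        assert is_full_length("r", 1000, [ten])
        assert not is_full_length("r", 1000, [eleven])

    def test_false_positive_rules(self):
        assert is_false_positive("q", 400, [])  # nothing aligned at all
        half = _block_row("q", "r", 400, 400, [(200, 0, 0)])
        assert not is_false_positive("q", 400, [half])  # exactly 50% is not an FP
        small = _block_row("q", "r", 400, 400, [(150, 0, 0)])
        assert is_false_positive("q", 400, [small])  # 37.5% < 50%

    def test_false_positive_uses_best_single_target(self):
        """Two 30% alignments to different references do not add up."""
        a1 = _block_row("q", "r1", 400, 400, [(120, 0, 0)])
        a2 = _block_row("q", "r2", 400, 400, [(120, 280, 0)])
        assert is_false_positive("q", 400, [a1, a2])


class TestCorrectBaseMap:
    def test_identical_assembly(self, rng):
        seq = random_seq(rng, 300)
        ref = TranscriptSet({"r": (seq, None)})
        asm = TranscriptSet({"a": (seq, None)})
        aln = [_block_row("a", "r", 300, 300, [(300, 0, 0)])]
        assert correct_base_map(aln, ref, asm) == (300, 300)

    def test_duplicate_copies_union_on_reference(self, rng):
        """Two identical copies: reference bases count once (union), predicted
        bases count per copy."""
        seq = random_seq(rng, 300)
        ref = TranscriptSet({"r": (seq, None)})
        asm = TranscriptSet({"a1": (seq, None), "a2": (seq, None)})
        aln = [
            _block_row("a1", "r", 300, 300, [(300, 0, 0)]),
            _block_row("a2", "r", 300, 300, [(300, 0, 0)]),
        ]
        assert correct_base_map(aln, ref, asm) == (300, 600)

    def test_empty_alignments(self, rng):
        ref = TranscriptSet({"r": (random_seq(rng, 300), None)})
        assert correct_base_map([], ref, TranscriptSet()) == (0, 0)


class TestEvaluate:
    def test_perfect_assembly(self, rng):
        ref = TranscriptSet()
        for i in range(5):
            ref.add(f"r{i}", random_seq(rng, 300))
        asm = TranscriptSet({f"a{i}": (ref.sequence(f"r{i}"), None) for i in range(5)})
        aln = [_block_row(f"a{i}", f"r{i}", 300, 300, [(300, 0, 0)]) for i in range(5)]
        m = evaluate(asm, ref, aln)
        assert m.as_tuple() == (100.0, 0.0, 100.0, 100.0)

    def test_unalignable_assembly(self, rng):
        ref = TranscriptSet()
        for i in range(10):
            ref.add(f"r{i}", random_seq(rng, 300))
        asm = TranscriptSet({"junk": (random_seq(rng, 300), None)})
        m = evaluate(asm, ref, [])
        assert m.as_tuple() == (0.0, 100.0, 0.0, 0.0)

    def test_empty_reference_rejected(self, rng):
        asm = TranscriptSet({"a": (random_seq(rng, 300), None)})
        with pytest.raises(ValueError):
            evaluate(asm, TranscriptSet(), [])

    def test_empty_assembly_specificity_flagged(self, rng):
        ref = TranscriptSet({"r": (random_seq(rng, 300), None)})
        m = evaluate(TranscriptSet(), ref, [])
        assert m.full_length_pct == 0.0
        assert m.false_positive_pct == 0.0
        assert m.nt_sensitivity_pct == 0.0
        assert m.specificity_undefined
        assert m.counts.predicted_bases == 0

    def test_identity_gate_at_threshold(self, rng):
        """Exactly 95% identity passes the gate; just below does not."""
        seq = random_seq(rng, 500)
        ref = TranscriptSet({"r": (seq, None)})
        at = mutate(rng, seq, 25)  # 475/500 = 0.95
        below = mutate(rng, seq, 26)  # 474/500 < 0.95
        asm = TranscriptSet({"at": (at, None), "below": (below, None)})
        aln = [
            _block_row("at", "r", 500, 500, [(500, 0, 0)], mismatches=25),
            _block_row("below", "r", 500, 500, [(500, 0, 0)], mismatches=26),
        ]
        m = evaluate(asm, ref, aln)
        assert m.counts.n_full_length == 1  # only the 95% copy counts
        assert m.counts.n_false_positive == 1  # the gated-out copy has nothing left

    def test_minus_strand_normalized(self, rng):
        """A reverse-complement copy aligned on '-' still scores perfectly."""
        from denovobench.simulate import revcomp

        seq = random_seq(rng, 300)
        ref = TranscriptSet({"r": (seq, None)})
        asm = TranscriptSet({"a": (revcomp(seq), None)})
        aln = [_block_row("a", "r", 300, 300, [(300, 0, 0)], strand="-")]
        m = evaluate(asm, ref, aln)
        assert m.as_tuple() == (100.0, 0.0, 100.0, 100.0)

    def test_monotonicity_adding_perfect_contig(self, rng):
        """Adding a perfectly reconstructed reference never hurts."""
        ref = TranscriptSet()
        for i in range(6):
            ref.add(f"r{i}", random_seq(rng, 300))
        asm = TranscriptSet(
            {
                "good": (ref.sequence("r0"), None),
                "junk": (random_seq(rng, 250), None),
            }
        )
        before = evaluate(asm, ref, align_all(asm, ref))
        asm2 = TranscriptSet({tid: (seq, gid) for tid, seq, gid in asm.items()})
        asm2.add("extra", ref.sequence("r1"))
        after = evaluate(asm2, ref, align_all(asm2, ref))
        assert after.full_length_pct >= before.full_length_pct
        assert after.nt_sensitivity_pct >= before.nt_sensitivity_pct
        assert after.false_positive_pct <= before.false_positive_pct

    def test_self_evaluation_identity(self, rng):
        ref = TranscriptSet()
        for i in range(8):
            ref.add(f"r{i}", random_seq(rng, int(rng.integers(220, 420))))
        asm = TranscriptSet({f"a{i}": (ref.sequence(f"r{i}"), None) for i in range(8)})
        m = evaluate(asm, ref, align_all(asm, ref))
        assert m.as_tuple() == (100.0, 0.0, 100.0, 100.0)


def _random_fixture(rng):
    """A randomized desk-scale benchmark: reference set plus an assembly made
    of perfect copies, near-threshold mutants, truncations, duplicates,
    short contigs and junk."""
    n_ref = int(rng.integers(4, 11))
    ref = TranscriptSet()
    for i in range(n_ref):
        ref.add(f"r{i}", random_seq(rng, int(rng.integers(220, 501))))
    asm = TranscriptSet()
    k = 0
    for i in range(n_ref):
        seq = ref.sequence(f"r{i}")
        kind = int(rng.integers(0, 6))
        if kind == 0:  # perfect copy
            asm.add(f"a{k}", seq)
        elif kind == 1:  # mutant straddling the identity gate
            n_sub = int(rng.integers(1, max(2, int(0.08 * len(seq)))))
            asm.add(f"a{k}", mutate(rng, seq, n_sub))
        elif kind == 2:  # truncation around the 50% mark
            cut = int(len(seq) * rng.uniform(0.35, 0.75))
            if cut >= 200:
                asm.add(f"a{k}", seq[:cut])
            else:
                asm.add(f"a{k}", seq)
        elif kind == 3:  # duplicate pair
            asm.add(f"a{k}", seq)
            k += 1
            asm.add(f"a{k}", seq)
        elif kind == 4:  # junk contig
            asm.add(f"a{k}", random_seq(rng, int(rng.integers(210, 400))))
        else:  # short contig, removed by the length filter
            asm.add(f"a{k}", seq[:150])
        k += 1
    return ref, asm


@pytest.mark.parametrize("fixture_seed", [101, 202, 303, 404, 505])
def test_oracle_equivalence_randomized(fixture_seed):
    """evaluate() agrees exactly with the per-base marking oracle on all
    four metrics for randomized assemblies (deeper sweep lives in the
    acceptance suite)."""
    rng = np.random.default_rng(fixture_seed)
    ref, asm = _random_fixture(rng)
    alignments = align_all(asm, ref)
    m = evaluate(asm, ref, alignments)
    o = oracle_evaluate(
        {tid: seq for tid, seq, _ in asm.items()},
        {tid: seq for tid, seq, _ in ref.items()},
        alignments,
    )
    assert m.full_length_pct == o["full_length_pct"]
    assert m.false_positive_pct == o["false_positive_pct"]
    assert m.nt_sensitivity_pct == o["nt_sensitivity_pct"]
    assert m.nt_specificity_pct == o["nt_specificity_pct"]
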