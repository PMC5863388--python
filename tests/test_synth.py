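"""Synthetic reference generation, BLAST emulation, and evaluation tallies."""

import io

import numpy as np
import pytest

from bildcut import synth
from bildcut.blast_io import parse_blast_tab, write_blast_tab
from bildcut.errors import ValidationError
from bildcut.taxonomy import RANKS, Assignment, Lineage


def lin(*ranks):
    return Lineage(tuple(ranks))


class TestSimulateReference:
    def test_same_seed_gives_byte_identical_fasta(self):
        out = []
        for _ in range(2):
            ref = synth.simulate_reference(
                n_genera=4, seqs_per_genus=3, length=200, seed=42
            )
            buf = io.StringIO()
            ref.write_fasta(buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_sequence_and_lineage_counts(self):
        ref = synth.simulate_reference(n_genera=4, seqs_per_genus=3, length=120, seed=0)
        assert len(ref.sequences) == 12
        assert len(ref.taxonomy) == 12
        assert all(l.depth == 6 for l in ref.taxonomy.values())
        assert len({l.ranks[-1] for l in ref.taxonomy.values()}) == 4

    def test_zero_divergence_everywhere_collapses_to_one_sequence(self):
        ref = synth.simulate_reference(
            n_genera=4, seqs_per_genus=2, length=100,
            rank_divergences=(0,) * 6, seed=3,
        )
        assert len(set(ref.sequences.values())) == 1

    def test_divergence_beyond_random_distance_rejected(self):
        with pytest.raises(ValidationError):
            synth.simulate_reference(rank_divergences=(0.8, 0.3, 0.2, 0.1, 0.05, 0.01))

    def test_divergences_increasing_towards_genus_rejected(self):
        with pytest.raises(ValidationError):
            synth.simulate_reference(rank_divergences=(0.1, 0.1, 0.1, 0.1, 0.05, 0.2))

    def test_within_genus_closer_than_between_genera(self):
        ref = synth.simulate_reference(n_genera=4, seqs_per_genus=3, length=600, seed=5)
        ids = list(ref.sequences)

        def dist(a, b):
            sa, sb = ref.sequences[a], ref.sequences[b]
            return sum(1 for x, y in zip(sa, sb) if x != y)

        same = [dist(a, b) for a in ids for b in ids
                if a < b and ref.genus_of(a) == ref.genus_of(b)]
        cross = [dist(a, b) for a in ids for b in ids
                 if a < b and ref.genus_of(a) != ref.genus_of(b)]
        assert max(same) < min(cross)


class TestMutate:
    def test_mutation_count_is_rounded_fraction(self):
        rng = np.random.default_rng(0)
        seq = "A" * 200
        mutated = synth.mutate(seq, 0.1, rng)
        assert sum(1 for a, b in zip(seq, mutated) if a != b) == 20

    def test_zero_fraction_is_identity(self):
        rng = np.random.default_rng(0)
        assert synth.mutate("ACGTACGT", 0.0, rng) == "ACGTACGT"

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            synth.mutate("ACGT" * 10, 0.9, np.random.default_rng(0))


class TestEmulateBlast:
    def test_identical_query_ranks_first_with_full_identity(self, small_reference):
        qid = next(iter(small_reference.sequences))
        hits = synth.emulate_blast("q", small_reference.sequences[qid], small_reference)
        assert hits[0].subject_id == qid
        assert hits[0].percent_identity == 100.0

    def test_rows_round_trip_through_the_tabular_parser(self, small_reference):
        qid = next(iter(small_reference.sequences))
        hits = synth.emulate_blast("q", small_reference.sequences[qid], small_reference)
        buf = io.StringIO()
        write_blast_tab(hits, buf)
        parsed = parse_blast_tab(io.StringIO(buf.getvalue()))
        assert [(h.subject_id, h.bit_score) for h in parsed] == [
            (h.subject_id, h.bit_score) for h in hits
        ]

    def test_same_genus_outranks_other_genera(self, small_reference):
        rng = np.random.default_rng(1)
        qid = next(iter(small_reference.sequences))
        query = synth.mutate(small_reference.sequences[qid], 0.01, rng)
        hits = synth.emulate_blast("q", query, small_reference,
                                   exclude_ids={qid})
        genus = small_reference.genus_of(qid)
        same = [h for h in hits if small_reference.genus_of(h.subject_id) == genus]
        top = hits[: len(same)]
        assert {h.subject_id for h in top} == {h.subject_id for h in same}

    def test_scores_sorted_and_truncated(self, small_reference):
        qid = next(iter(small_reference.sequences))
        hits = synth.emulate_blast("q", small_reference.sequences[qid],
                                   small_reference, max_hits=5)
        assert len(hits) <= 5
        scores = [h.bit_score for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            synth.emulate_blast("q", "ACGT", {"r": "ACGTA"})


def asn(qid, lineage, n=1):
    return Assignment(query_id=qid, lineage=lineage, depth=lineage.depth, n_outliers=n)


class TestEvaluate:
    truth = {"q1": lin("K", "P", "C", "O", "F", "G")}

    def test_true_genus_present_and_assigned_is_correct_everywhere(self):
        db = [self.truth["q1"]] * 3
        counts = synth.evaluate([asn("q1", self.truth["q1"])], self.truth, db)
        assert counts.correctly_classified == (1,) * 6
        assert counts.misclassified == (0,) * 6

    def test_unassigned_genus_absent_in_leave_one_genus_out_is_correct(self):
        db = [self.truth["q1"], lin("K", "P", "C", "O", "F", "G2")]
        counts = synth.evaluate(
            [asn("q1", lin("K", "P", "C", "O", "F"))],
            self.truth, db, mode=synth.LEAVE_ONE_GENUS_OUT,
        )
        assert counts.correctly_classified[5] == 1
        assert counts.falsely_unclassified[5] == 0

    def test_unassigned_genus_present_elsewhere_is_falsely_unclassified(self):
        db = [self.truth["q1"], self.truth["q1"]]
        counts = synth.evaluate(
            [asn("q1", lin("K", "P", "C", "O", "F"))],
            self.truth, db, mode=synth.LEAVE_ONE_SEQUENCE_OUT,
        )
        assert counts.falsely_unclassified[5] == 1

    def test_wrong_family_label_is_misclassified_at_family_and_genus(self):
        db = [self.truth["q1"]] * 2
        wrong = lin("K", "P", "C", "O", "F2", "G2")
        counts = synth.evaluate([asn("q1", wrong)], self.truth, db)
        assert counts.misclassified == (0, 0, 0, 0, 1, 1)
        assert counts.correctly_classified == (1, 1, 1, 1, 0, 0)

    def test_tallies_sum_to_query_count_at_every_rank(self):
        truth = {
            "q1": lin("K", "P", "C", "O", "F", "G"),
            "q2": lin("K", "P", "C", "O", "F", "G2"),
        }
        db = list(truth.values()) * 2
        assignments = [
            asn("q1", lin("K", "P", "C")),
            asn("q2", lin("K", "P", "C", "O", "F", "G2")),
        ]
        counts = synth.evaluate(assignments, truth, db)
        for r in range(6):
            total = (counts.correctly_classified[r] + counts.misclassified[r]
                     + counts.falsely_unclassified[r])
            assert total == 2

    def test_tallies_invariant_to_assignment_order(self):
        truth = {
            "q1": lin("K", "P", "C", "O", "F", "G"),
            "q2": lin("K", "P", "C", "O", "F", "G2"),
        }
        db = list(truth.values())
        assignments = [
            asn("q1", lin("K", "P", "C", "O", "F", "G")),
            asn("q2", lin("K", "P")),
        ]
        fwd = synth.evaluate(assignments, truth, db)
        rev = synth.evaluate(list(reversed(assignments)), truth, db)
        assert fwd == rev

    def test_unknown_query_rejected(self):
        with pytest.raises(ValidationError):
            synth.evaluate([asn("qX", lin("K"))], self.truth, [])


class TestLeaveOneOut:
    def test_harness_runs_and_tallies_every_query(self, small_reference):
        assignments, counts = synth.run_leave_one_out(
            small_reference, mode=synth.LEAVE_ONE_SEQUENCE_OUT
        )
        n = len(small_reference.sequences)
        assert len(assignments) == n
        for r in range(len(RANKS)):
            assert (counts.correctly_classified[r] + counts.misclassified[r]
                    + counts.falsely_unclassified[r]) == n

    def test_genus_out_mode_never_sees_own_genus(self, small_reference):
        assignments, _ = synth.run_leave_one_out(
            small_reference, mode=synth.LEAVE_ONE_GENUS_OUT
        )
        for a in assignments:
            if a.depth == 6:
                true_genus = small_reference.taxonomy[a.query_id].ranks[-1]
                assert a.lineage.ranks[-1] != true_genus

    def test_frame_export_indexes_ranks(self, small_reference):
        _, counts = synth.run_leave_one_out(small_reference)
        frame = counts.as_frame()
        assert list(frame.index) == list(RANKS)
        assert frame.to_numpy().sum() == 6 * len(small_reference.sequences)
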