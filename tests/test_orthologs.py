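"""Score-margin family assignment, reciprocal best hits, co-occurrence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetraco.orthologs import (
    ScoreTable,
    assign_family,
    cooccurrence_table,
    count_present_without,
    reciprocal_best_hit,
)

FAMILIES = {"D1": "DMC1", "D2": "DMC1", "R1": "RAD51", "R2": "RAD51"}


def table(rows):
    return ScoreTable(
        pd.DataFrame(rows, columns=["query", "reference", "score"]), FAMILIES
    )


class TestAssignFamily:
    def test_margin_boundary_is_inclusive(self):
        t = table([("q", "D1", 110.0), ("q", "R1", 100.0)])
        call = assign_family("q", t)
        assert call.assigned_family == "DMC1"
        assert call.margin == pytest.approx(0.10)

    def test_below_margin_unassigned(self):
        call = assign_family("q", table([("q", "D1", 105.0), ("q", "R1", 100.0)]))
        assert call.assigned_family == "unassigned"
        assert call.margin == pytest.approx(0.05)

    def test_cross_family_tie_unassigned(self):
        call = assign_family("q", table([("q", "D1", 100.0), ("q", "R1", 100.0)]))
        assert call.assigned_family == "unassigned"
        assert call.margin == 0.0

    def test_second_best_is_best_other_family_hit(self):
        # the literal second-best hit is another DMC1 gene; the margin must
        # be computed against the best RAD51 hit instead
        t = table([("q", "D1", 200.0), ("q", "D2", 195.0), ("q", "R1", 100.0)])
        call = assign_family("q", t)
        assert call.second_best_hit == "R1"
        assert call.assigned_family == "DMC1"

    def test_all_zero_scores_unassigned(self):
        call = assign_family("q", table([("q", "D1", 0.0), ("q", "R1", 0.0)]))
        assert call.assigned_family == "unassigned"

    def test_single_family_rejected(self):
        with pytest.raises(ValueError, match="cross-family"):
            assign_family("q", table([("q", "D1", 10.0), ("q", "D2", 5.0)]))

    @given(scale=st.floats(min_value=0.01, max_value=1e6))
    @settings(derandomize=True, max_examples=30)
    def test_invariant_under_positive_rescaling(self, scale):
        rows = [("q", "D1", 132.0), ("q", "D2", 50.0), ("q", "R1", 117.0)]
        base = assign_family("q", table(rows))
        scaled = assign_family(
            "q", table([(q, r, s * scale) for q, r, s in rows])
        )
        assert scaled.assigned_family == base.assigned_family
        assert scaled.best_hit == base.best_hit

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            table([("q", "D1", -1.0)])


class TestReciprocalBestHit:
    def test_symmetric_pair_confirmed(self):
        fwd = table([("q", "D1", 50.0), ("q", "R1", 10.0)])
        rev = ScoreTable(
            pd.DataFrame(
                [("D1", "q", 60.0), ("D1", "p", 20.0)],
                columns=["query", "reference", "score"],
            ),
            {"q": "X", "p": "X"},
        )
        assert reciprocal_best_hit("q", fwd, rev).confirmed

    def test_paralog_reverse_hit_unconfirmed(self):
        fwd = table([("q", "D1", 50.0), ("q", "R1", 10.0)])
        rev = ScoreTable(
            pd.DataFrame(
                [("D1", "q", 20.0), ("D1", "paralog", 60.0)],
                columns=["query", "reference", "score"],
            ),
            {"q": "X", "paralog": "X"},
        )
        assert not reciprocal_best_hit("q", fwd, rev).confirmed

    def test_missing_reverse_scores_rejected(self):
        fwd = table([("q", "D1", 50.0), ("q", "R1", 10.0)])
        rev = ScoreTable(
            pd.DataFrame([("R1", "q", 5.0)], columns=["query", "reference", "score"]),
            {"q": "X"},
        )
        with pytest.raises(ValueError, match="reverse"):
            reciprocal_best_hit("q", fwd, rev)

    def test_five_gene_matrix_matches_exhaustive_pairs(self):
        """RBH confirmations equal the hand-enumerable mutual-best pairs."""
        genes = ["g1", "g2", "g3", "g4", "g5"]
        rng = np.random.default_rng(17)
        scores = rng.integers(1, 100, size=(5, 5)).astype(float)
        np.fill_diagonal(scores, 0.0)
        rows = [
            (genes[i], genes[j], scores[i, j])
            for i in range(5)
            for j in range(5)
            if i != j
        ]
        st_ = ScoreTable(
            pd.DataFrame(rows, columns=["query", "reference", "score"]),
            {g: "F" for g in genes},
        )
        # brute force: mutual argmax over the raw matrix
        expected = {
            genes[i]
            for i in range(5)
            for j in range(5)
            if i != j
            and scores[i].argmax() == j
            and scores[j].argmax() == i
        }
        confirmed = {
            g for g in genes if reciprocal_best_hit(g, st_, st_).confirmed
        }
        assert confirmed == expected


def _brute_force_call(query, frame, families):
    """Literal restatement of the margin rule, for oracle comparison."""
    hits = sorted(
        frame[frame["query"] == query].itertuples(),
        key=lambda h: (-h.score, h.reference),
    )
    best = hits[0]
    if best.score <= 0:
        return "unassigned"
    others = [h for h in hits if families[h.reference] != families[best.reference]]
    second = others[0]
    if second.score == 0 or (best.score - second.score) / second.score >= 0.10:
        return families[best.reference]
    return "unassigned"


def test_random_matrices_match_brute_force_oracle():
    rng = np.random.default_rng(23)
    refs = [f"D{i}" for i in range(6)] + [f"R{i}" for i in range(6)]
    families = {r: ("DMC1" if r.startswith("D") else "RAD51") for r in refs}
    for trial in range(20):
        scores = rng.integers(0, 40, size=(20, 12)).astype(float)
        rows = [
            (f"q{i}", refs[j], scores[i, j])
            for i in range(20)
            for j in range(12)
        ]
        frame = pd.DataFrame(rows, columns=["query", "reference", "score"])
        st_ = ScoreTable(frame, families)
        for i in range(20):
            call = assign_family(f"q{i}", st_)
            assert call.assigned_family == _brute_force_call(f"q{i}", frame, families)


class TestCooccurrence:
    def test_empty_input(self):
        assert cooccurrence_table({}).empty

    def test_flip_never_without_figl1_on_toy_calls(self):
        from tetraco.orthologs import OrthologCall

        def call(family):
            return OrthologCall("q", family, "r", 1.0, "s", 0.5, 1.0)

        calls = {
            "sp1": [call("FLIP"), call("FIGL1")],
            "sp2": [call("FIGL1")],
            "sp3": [call("unassigned")],
        }
        matrix = cooccurrence_table(calls)
        assert count_present_without(matrix, "FLIP", "FIGL1") == 0
        assert count_present_without(matrix, "FIGL1", "FLIP") == 1

    def test_sums_invariant_under_species_relabelling(self):
        from tetraco.orthologs import OrthologCall

        def call(family):
            return OrthologCall("q", family, "r", 1.0, "s", 0.5, 1.0)

        calls = {"a": [call("X")], "b": [call("Y"), call("X")], "c": []}
        m1 = cooccurrence_table(calls)
        m2 = cooccurrence_table(dict(reversed(list(calls.items()))))
        assert sorted(m1.sum(axis=0)) == sorted(m2.sum(axis=0))
        assert sorted(m1.sum(axis=1)) == sorted(m2.sum(axis=1))
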