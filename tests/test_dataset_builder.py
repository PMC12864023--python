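"""Grouping, splitting, balancing, reporting, and SFT export."""

import json
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stigma_screen import (
    Category,
    Note,
    TermLexicon,
    ValidationError,
    build_groups,
    downsample_balanced,
    export_sft_dataset,
    percent_half_up,
    prevalence_from_counts,
    prevalence_report,
    stratified_group_split,
    term_frequency_table,
)
from stigma_screen.dataset_builder import SFT_TRAINING_CONFIG


def note(nid, enc="", pat="", care="", category=Category.CLEAN):
    return Note(note_id=nid, text="t", encounter_id=enc, patient_id=pat,
                caregiver_id=care, gold_category=category)


class TestBuildGroups:
    def test_shared_patient_links(self):
        notes = [note("a", pat="p1"), note("b", pat="p1"), note("c", pat="p2")]
        groups = build_groups(notes)
        assert groups["a"] == groups["b"] != groups["c"]

    def test_all_distinct_ids_singletons(self):
        notes = [note(f"n{i}", enc=f"e{i}", pat=f"p{i}") for i in range(10)]
        groups = build_groups(notes)
        assert len(set(groups.values())) == 10

    def test_empty_ids_create_no_links(self):
        notes = [note("a"), note("b"), note("c")]
        assert len(set(build_groups(notes).values())) == 3

    def test_transitive_linkage_through_caregiver(self):
        notes = [note("a", enc="e1"), note("b", enc="e1", care="c1"),
                 note("c", care="c1")]
        assert len(set(build_groups(notes).values())) == 1

    @given(st.integers(0, 2**32 - 1))
    def test_components_match_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        notes = [
            note(
                f"n{i}",
                enc=f"e{rng.integers(0, 15)}" if rng.random() < 0.5 else "",
                pat=f"p{rng.integers(0, 10)}" if rng.random() < 0.5 else "",
                care=f"c{rng.integers(0, 8)}" if rng.random() < 0.3 else "",
            )
            for i in range(n)
        ]
        groups = build_groups(notes)
        graph = nx.Graph()
        graph.add_nodes_from(m.note_id for m in notes)
        for kind in ("encounter_id", "patient_id", "caregiver_id"):
            owners = {}
            for m in notes:
                value = getattr(m, kind)
                if value:
                    owners.setdefault(value, []).append(m.note_id)
            for members in owners.values():
                for other in members[1:]:
                    graph.add_edge(members[0], other)
        expected = {
            nid: frozenset(component)
            for component in nx.connected_components(graph)
            for nid in component
        }
        ours = {}
        for nid, gid in groups.items():
            ours.setdefault(gid, set()).add(nid)
        assert {nid: frozenset(ours[gid]) for nid, gid in groups.items()} == expected


class TestStratifiedGroupSplit:
    def test_singleton_balanced_fractions(self):
        notes = [note(f"n{i}", category=list(Category)[i % 3]) for i in range(100)]
        assignment = stratified_group_split(notes, seed=0)
        counts = assignment.counts()
        assert counts["train"] == pytest.approx(70, abs=2)
        assert counts["validation"] == pytest.approx(15, abs=2)
        assert counts["test"] == pytest.approx(15, abs=2)
        assert sum(counts.values()) == 100

    def test_single_giant_group_warns_and_stays_together(self):
        notes = [note(f"n{i}", pat="p0", category=Category.CLEAN) for i in range(30)]
        assignment = stratified_group_split(notes, seed=1)
        assert len(set(assignment.assignment.values())) == 1
        assert assignment.warnings

    @given(st.integers(0, 500))
    def test_no_group_ever_spans_splits(self, seed):
        rng = np.random.default_rng(seed)
        notes = [
            note(
                f"n{i}",
                pat=f"p{rng.integers(0, 25)}",
                category=list(Category)[int(rng.integers(0, 3))],
            )
            for i in range(80)
        ]
        groups = build_groups(notes)
        assignment = stratified_group_split(notes, groups, seed=seed)
        by_group = {}
        for nid, split in assignment.assignment.items():
            by_group.setdefault(groups[nid], set()).add(split)
        assert all(len(splits) == 1 for splits in by_group.values())
        assert set(assignment.assignment) == {m.note_id for m in notes}

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError):
            stratified_group_split([note("a")], fractions=(0.5, 0.3, 0.3))

    def test_deterministic_under_seed(self):
        notes = [note(f"n{i}", pat=f"p{i % 9}") for i in range(40)]
        first = stratified_group_split(notes, seed=5)
        second = stratified_group_split(notes, seed=5)
        assert first.assignment == second.assignment


class TestDownsampleBalanced:
    def make(self, n_pos, n_neg):
        pos = [note(f"p{i}", category=Category.STIGMATIZING) for i in range(n_pos)]
        neg = [note(f"n{i}", category=Category.CLEAN) for i in range(n_neg)]
        return pos + neg

    @given(st.integers(0, 200))
    def test_counting_oracle(self, seed):
        subset = downsample_balanced(self.make(10, 50), seed=seed)
        assert len(subset) == 20
        assert sum(m.gold_binary for m in subset) == 10

    def test_already_balanced_identity(self):
        notes = self.make(5, 5)
        assert downsample_balanced(notes, seed=0) == notes

    def test_minority_may_be_negative_class(self):
        subset = downsample_balanced(self.make(50, 10), seed=0)
        labels = [m.gold_binary for m in subset]
        assert labels.count(0) == labels.count(1) == 10

    def test_empty_minority_rejected(self):
        with pytest.raises(ValidationError):
            downsample_balanced(self.make(0, 10), seed=0)


class TestPrevalence:
    def test_printed_counts(self):
        report = prevalence_from_counts(2072, 288130)
        assert report["percent"] == 0.72

    def test_zero_positives(self):
        assert prevalence_from_counts(0, 100)["percent"] == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            prevalence_from_counts(0, 0)

    @given(st.integers(0, 10_000), st.integers(1, 10_000))
    def test_matches_rational_arithmetic_oracle(self, positives, total):
        positives = min(positives, total)
        result = prevalence_from_counts(positives, total)["percent"]
        exact = Fraction(positives * 100, total)
        # round half-up at 2 decimals in exact rational arithmetic
        scaled = exact * 100
        floor = scaled.numerator // scaled.denominator
        remainder = scaled - floor
        rounded = floor + (1 if remainder >= Fraction(1, 2) else 0)
        assert result == pytest.approx(rounded / 100, abs=1e-9)

    def test_report_from_notes(self):
        notes = [note("a", category=Category.STIGMATIZING),
                 note("b", category=Category.CLEAN),
                 note("c", category=Category.CONTEXTUAL_NONSTIGMA)]
        report = prevalence_report(notes)
        assert (report["positives"], report["total"]) == (1, 3)
        assert report["percent"] == 33.33


class TestTermFrequencyTable:
    LEX = TermLexicon(terms=["etoh abuse", "abuse", "drunk"])

    def test_counts_match_membership_oracle(self):
        notes = [
            Note("a", "etoh abuse and more etoh abuse"),   # 1 note, term once
            Note("b", "drunk and etoh abuse"),
            Note("c", "spousal abuse noted"),
            Note("d", "nothing relevant"),
        ]
        table = term_frequency_table(notes, self.LEX)
        counts = dict(zip(table["term"], table["note_count"]))
        assert counts == {"etoh abuse": 2, "abuse": 1, "drunk": 1}
        percents = dict(zip(table["term"], table["percent"]))
        assert percents["etoh abuse"] == percent_half_up(2, 4) == 50.0

    def test_longest_match_suppression_in_counts(self):
        table = term_frequency_table([Note("a", "etoh abuse")], self.LEX)
        assert list(table["term"]) == ["etoh abuse"]

    def test_sorted_desc_count_then_term(self):
        notes = [Note("a", "drunk and abuse"), Note("b", "abuse and drunk")]
        table = term_frequency_table(notes, self.LEX)
        assert list(table["term"]) == ["abuse", "drunk"]

    def test_empty_corpus(self):
        assert term_frequency_table([], self.LEX).empty

    def test_each_percent_recomputes_from_count(self):
        notes = [Note(f"n{i}", "etoh abuse" if i % 3 else "clean text")
                 for i in range(20)]
        table = term_frequency_table(notes, self.LEX)
        for _, row in table.iterrows():
            assert row["percent"] == percent_half_up(int(row["note_count"]), 20)


class TestSftExport:
    def test_round_trip_and_label_mapping(self, tmp_path):
        notes = [
            note("a", category=Category.STIGMATIZING),
            note("b", category=Category.CLEAN),
            Note("c", "unlabeled text"),
        ]
        notes[0].text = "chronic etoh abuse"
        notes[1].text = "stable overnight"
        path = tmp_path / "sft.json"
        count = export_sft_dataset(notes, path)
        assert count == 2  # the unlabeled note is skipped
        records = json.loads(path.read_text())
        assert [r["output"] for r in records] == ["yes", "no"]
        assert [r["input"] for r in records] == [notes[0].text, notes[1].text]
        config = json.loads(
            (tmp_path / "sft.json.train_config.json").read_text()
        )
        assert config == SFT_TRAINING_CONFIG
        assert (config["lora_rank"], config["lora_alpha"]) == (8, 8)
        assert config["epochs"] == 3 and config["effective_batch_size"] == 64
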