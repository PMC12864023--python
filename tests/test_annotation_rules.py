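"""Contextual annotation rules: quotes, attribution, benign senses."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from stigma_screen import (
    Category,
    RationaleCode,
    RulesConfig,
    TermLexicon,
    ValidationError,
    annotate_corpus,
    contextual_label,
    detect_quoted_spans,
    is_attributed,
    is_benign_sense,
    keyword_classify,
    labeling_summary,
    match_terms,
    review_queue,
)
from stigma_screen.annotation_rules import LabelingSummary
from stigma_screen.corpus_model import Note


class TestDetectQuotedSpans:
    def test_curly_single_quote_span(self):
        text = "he feels ‘stinking drunk’ after"
        scan = detect_quoted_spans(text)
        (span,) = scan.spans
        assert text[span.start_char:span.end_char] == "stinking drunk"
        assert not scan.dangling

    def test_no_quote_characters(self):
        scan = detect_quoted_spans("plain clinical text without quotes")
        assert scan.spans == [] and not scan.dangling

    def test_apostrophe_is_not_dangling(self):
        scan = detect_quoted_spans("the patient’s family visited")
        assert scan.spans == [] and not scan.dangling

    def test_unpaired_quote_sets_dangling(self):
        assert detect_quoted_spans('he said "never mind').dangling
        assert detect_quoted_spans("a stray ” closer").dangling

    def test_straight_double_quotes_pair(self):
        text = 'described as "difficult" today'
        (span,) = detect_quoted_spans(text).spans
        assert text[span.start_char:span.end_char] == "difficult"

    @staticmethod
    def reference_parser(text):
        """Stack-based reference: innermost pairs, then non-overlap filter."""
        openers = {"“": "curly", "‘": "single"}
        closers = {"”": "curly", "’": "single"}
        stack, pairs = [], []
        for i, ch in enumerate(text):
            if ch == '"':
                if stack and stack[-1][0] == "double":
                    pairs.append((stack.pop()[1] + 1, i))
                else:
                    stack.append(("double", i))
            elif ch in openers:
                stack.append((openers[ch], i))
            elif ch in closers:
                style = closers[ch]
                if any(s == style for s, _ in stack):
                    while stack[-1][0] != style:
                        stack.pop()
                    pairs.append((stack.pop()[1] + 1, i))
        pairs = [p for p in pairs if p[1] > p[0]]
        kept = []
        for s, e in pairs:
            if all(e <= ks or s >= ke for ks, ke in kept):
                kept.append((s, e))
        return sorted(kept)

    @given(st.lists(
        st.sampled_from(["“", "”", "‘", "’", '"', "word", "note", " "]),
        min_size=0, max_size=25,
    ).map(" ".join))
    def test_agrees_with_stack_reference(self, text):
        scan = detect_quoted_spans(text)
        assert [(s.start_char, s.end_char) for s in scan.spans] == \
            self.reference_parser(text)

    def test_spans_sorted_and_non_overlapping(self):
        scan = detect_quoted_spans("a ‘one’ and “two” and ‘three’ end")
        spans = scan.spans
        assert spans == sorted(spans, key=lambda s: s.start_char)
        for left, right in zip(spans, spans[1:]):
            assert left.end_char <= right.start_char


class TestIsAttributed:
    CUES = ["he feels", "patient states"]

    def test_cue_directly_before_quote(self):
        text = "he feels ‘stinking drunk’ tonight"
        (span,) = detect_quoted_spans(text).spans
        assert is_attributed(text, span, self.CUES, window_k=10)

    def test_no_cue_in_text(self):
        text = "charted as ‘stinking drunk’ tonight"
        (span,) = detect_quoted_spans(text).spans
        assert not is_attributed(text, span, self.CUES, window_k=10)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_window_boundary_by_construction(self, k):
        """A cue ending exactly k tokens before the quote is attributed;
        one ending k+1 tokens before is not."""
        filler_in = " ".join(["pad"] * (k - 1))
        inside = f"patient states {filler_in} ‘drunk’ again".replace("  ", " ")
        (span,) = detect_quoted_spans(inside).spans
        assert is_attributed(inside, span, self.CUES, window_k=k)

        filler_out = " ".join(["pad"] * k)
        outside = f"patient states {filler_out} ‘drunk’ again".replace("  ", " ")
        (span,) = detect_quoted_spans(outside).spans
        assert not is_attributed(outside, span, self.CUES, window_k=k)


class TestIsBenignSense:
    def test_junky_cough(self, lexicon):
        text = "patient has a junky cough this morning"
        (match,) = match_terms(text, lexicon)
        assert is_benign_sense(match, text, lexicon)

    def test_term_without_patterns(self, lexicon):
        text = "chronic drunk behavior noted"
        (match,) = match_terms(text, lexicon)
        assert not is_benign_sense(match, text, lexicon)

    def test_wrong_neighbor_word(self, lexicon):
        text = "described as junky throughout"
        (match,) = match_terms(text, lexicon)
        assert not is_benign_sense(match, text, lexicon)


class TestContextualLabel:
    def test_attributed_quote_is_contextual(self, lexicon):
        result = contextual_label("he feels ‘stinking drunk’ after dinner", lexicon)
        assert result.category is Category.CONTEXTUAL_NONSTIGMA
        assert result.rationale_codes == [RationaleCode.QUOTED_ATTRIBUTED]
        assert not result.needs_review

    def test_provider_voice_is_stigmatizing(self, lexicon):
        result = contextual_label("chronic etoh abuse, noncompliant", lexicon)
        assert result.category is Category.STIGMATIZING
        assert result.rationale_codes == [RationaleCode.PROVIDER_VOICE]

    def test_no_term_is_clean(self, lexicon):
        result = contextual_label("routine follow-up, no concerns", lexicon)
        assert result.category is Category.CLEAN
        assert result.rationale_codes == [RationaleCode.NO_TERM]
        assert result.matches == []

    def test_benign_sense_is_contextual(self, lexicon):
        result = contextual_label("noted a junky cough overnight", lexicon)
        assert result.category is Category.CONTEXTUAL_NONSTIGMA
        assert result.rationale_codes == [RationaleCode.BENIGN_SENSE]

    def test_unattributed_quote_needs_review(self, lexicon):
        result = contextual_label("overheard ‘drunk’ during rounds", lexicon)
        assert result.needs_review
        assert result.category is Category.STIGMATIZING

    def test_dangling_quote_with_match_needs_review(self, lexicon):
        result = contextual_label("he feels ‘stinking drunk after dinner", lexicon)
        assert result.needs_review and result.dangling_quote

    def test_mixed_matches_escalate_to_stigmatizing(self, lexicon):
        text = "he feels ‘drunk’ tonight; chronic etoh abuse documented"
        result = contextual_label(text, lexicon)
        assert result.category is Category.STIGMATIZING
        assert set(result.rationale_codes) == {
            RationaleCode.QUOTED_ATTRIBUTED, RationaleCode.PROVIDER_VOICE,
        }

    def test_deterministic(self, lexicon):
        text = "he feels ‘drunk’ and has a junky cough"
        first = contextual_label(text, lexicon)
        second = contextual_label(text, lexicon)
        assert first == second

    @pytest.mark.parametrize("text", [
        "he feels ‘stinking drunk’ after dinner",
        "chronic etoh abuse, noncompliant",
        "routine follow-up, no concerns",
        "noted a junky cough overnight",
    ])
    def test_partition_clean_iff_keyword_negative(self, lexicon, text):
        result = contextual_label(text, lexicon)
        assert (result.category is Category.CLEAN) == (
            keyword_classify(text, lexicon) == 0
        )


class TestReviewQueue:
    def make_corpus(self):
        return [
            Note("q1", "overheard ‘drunk’ during rounds"),       # unattributed
            Note("q2", "chronic etoh abuse documented"),          # provider voice
            Note("q3", "routine follow-up, no concerns"),         # clean
            Note("q4", "he said \"never mind about the etoh abuse"),  # dangling
        ]

    def test_queue_contents_and_order(self, lexicon):
        assert review_queue(self.make_corpus(), lexicon) == ["q1", "q4"]

    def test_no_quotes_no_queue(self, lexicon):
        notes = [Note("a", "stable overnight"), Note("b", "chronic etoh abuse")]
        assert review_queue(notes, lexicon) == []

    def test_queue_and_auto_labels_partition_matched_notes(self, lexicon):
        notes = self.make_corpus()
        results = annotate_corpus(notes, lexicon)
        queued = set(review_queue(notes, lexicon))
        auto = {nid for nid, r in results.items()
                if r.matches and not r.needs_review}
        matched = {nid for nid, r in results.items() if r.matches}
        assert queued | auto == matched
        assert queued & auto == set()


class TestLabelingSummary:
    def test_identity_from_results(self, lexicon):
        notes = [
            Note("a", "chronic etoh abuse documented"),
            Note("b", "he feels ‘drunk’ at times"),
            Note("c", "routine follow-up, no concerns"),
        ]
        summary = labeling_summary(annotate_corpus(notes, lexicon).values())
        assert summary.n_keyword_extracted == 2
        assert summary.n_contextual_nonstigma == 1
        assert summary.n_stigmatizing == 1

    def test_contextual_cannot_exceed_extracted(self):
        with pytest.raises(ValidationError):
            LabelingSummary(n_keyword_extracted=5, n_contextual_nonstigma=6)
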