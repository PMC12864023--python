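"""Rule-based contextual annotation of keyword hits.

This module codifies the semi-manual labeling criteria as an explicit,
deterministic rule system over three context cues:

1. quotation marks — a matched term inside a quoted span,
2. speaker attribution — a cue phrase ("patient states", "he feels", ...)
   ending within a small token window before the quote, and
3. linguistic context — benign-sense patterns on adjacent tokens
   (a "junky" cough is a cough quality, not a judgment).

A note with no lexicon hit is CLEAN.  A note whose every hit is either
quoted-and-attributed or benign-sense is CONTEXTUAL_NONSTIGMA.  Everything
else is STIGMATIZING (provider voice).  Hits that no rule covers — a term
inside an unattributed quote, or any hit in a note with unpaired quote
characters — are additionally flagged ``needs_review`` and surfaced through
the review queue rather than silently decided.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

from .corpus_model import Category, Note, TermLexicon
from .errors import ValidationError
from .keyword_engine import TermMatch, Token, match_terms, normalize_tokens


class QuoteStyle(str, Enum):
    SINGLE = "single"   # curly single quotes
    DOUBLE = "double"   # straight double quotes
    CURLY = "curly"     # curly double quotes


class RationaleCode(str, Enum):
    NO_TERM = "NO_TERM"
    QUOTED_ATTRIBUTED = "QUOTED_ATTRIBUTED"
    BENIGN_SENSE = "BENIGN_SENSE"
    PROVIDER_VOICE = "PROVIDER_VOICE"


@dataclass(frozen=True)
class QuoteSpan:
    """Character span of quoted content (quote characters excluded)."""

    start_char: int
    end_char: int
    quote_style: QuoteStyle

    def __post_init__(self) -> None:
        assert self.end_char > self.start_char

    def contains(self, match: TermMatch) -> bool:
        return self.start_char <= match.start_char and match.end_char <= self.end_char


@dataclass
class QuoteScan:
    """Result of quotation detection: paired spans plus a dangling flag for
    unpaired quote characters."""

    spans: list[QuoteSpan]
    dangling: bool


@dataclass
class RulesConfig:
    """Knobs of the annotation rule system.

    ``window_k`` is the attribution window: a cue phrase must end within
    this many normalized tokens before a quote span for the quote to count
    as patient-attributed.  ``cues`` overrides the lexicon's cue list when
    set.
    """

    window_k: int = 10
    cues: Optional[Sequence[str]] = None
    split_hyphens: bool = False

    def __post_init__(self) -> None:
        if self.window_k < 1:
            raise ValidationError("window_k must be >= 1")


@dataclass
class AnnotationResult:
    category: Category
    matches: list[TermMatch]
    rationale_codes: list[RationaleCode]
    needs_review: bool
    dangling_quote: bool = False


def detect_quoted_spans(text: str) -> QuoteScan:
    """Pair quote characters into spans of quoted content.

    Straight double quotes toggle open/close; curly double and curly single
    quotes pair an opener with the nearest subsequent closer of the same
    style.  A closing curly single quote with no pending opener is treated
    as an apostrophe and ignored.  Any other unpaired quote character sets
    the dangling flag.  When quotes nest, the innermost span is kept so the
    reported spans are non-overlapping and sorted.
    """
    emitted: list[QuoteSpan] = []
    dangling = False
    stack: list[tuple[QuoteStyle, int]] = []

    def close(style: QuoteStyle, index: int) -> None:
        nonlocal dangling
        while stack and stack[-1][0] is not style:
            stack.pop()
            dangling = True
        _, open_index = stack.pop()
        if index > open_index + 1:
            emitted.append(QuoteSpan(open_index + 1, index, style))

    for index, char in enumerate(text):
        if char == '"':
            if stack and stack[-1][0] is QuoteStyle.DOUBLE:
                close(QuoteStyle.DOUBLE, index)
            else:
                stack.append((QuoteStyle.DOUBLE, index))
        elif char == "“":  # curly double open
            stack.append((QuoteStyle.CURLY, index))
        elif char == "”":  # curly double close
            if any(style is QuoteStyle.CURLY for style, _ in stack):
                close(QuoteStyle.CURLY, index)
            else:
                dangling = True
        elif char == "‘":  # curly single open
            stack.append((QuoteStyle.SINGLE, index))
        elif char == "’":  # curly single close / apostrophe
            if any(style is QuoteStyle.SINGLE for style, _ in stack):
                close(QuoteStyle.SINGLE, index)
            # a lone right single quote is an apostrophe, not dangling
    if stack:
        dangling = True

    # innermost pairs close (and are emitted) first; keep the earliest
    # non-overlapping set in emission order
    kept: list[QuoteSpan] = []
    for span in emitted:
        if all(span.end_char <= other.start_char or span.start_char >= other.end_char
               for other in kept):
            kept.append(span)
    kept.sort(key=lambda s: (s.start_char, s.end_char))
    return QuoteScan(spans=kept, dangling=dangling)


def _cue_tuples(cues: Iterable[str]) -> list[tuple[str, ...]]:
    out = []
    for cue in cues:
        words = tuple(t.text for t in normalize_tokens(cue))
        if words:
            out.append(words)
    return out


def is_attributed(
    text: str,
    span: QuoteSpan,
    cues: Iterable[str],
    window_k: int = 10,
    tokens: Optional[Sequence[Token]] = None,
) -> bool:
    """True iff a cue phrase ends within ``window_k`` normalized tokens
    before the quote span's start."""
    if window_k < 1:
        raise ValidationError("window_k must be >= 1")
    if tokens is None:
        tokens = normalize_tokens(text)
    pre = [t for t in tokens if t.end <= span.start_char]
    words = [t.text for t in pre]
    for cue in _cue_tuples(cues):
        clen = len(cue)
        for j in range(len(words) - clen + 1):
            if tuple(words[j:j + clen]) == cue:
                distance = len(words) - (j + clen) + 1  # 1 = immediately before
                if distance <= window_k:
                    return True
    return False


def is_benign_sense(
    match: TermMatch,
    note: Union[Note, str],
    lexicon: TermLexicon,
    tokens: Optional[Sequence[Token]] = None,
) -> bool:
    """True iff a benign-sense pattern for the matched term is satisfied by
    the adjacent normalized tokens (checked literally)."""
    text = note.text if isinstance(note, Note) else note
    if tokens is None:
        tokens = normalize_tokens(text)
    for pattern in lexicon.patterns_for(match.term):
        if pattern.position == "next":
            index = match.end_token
            if index < len(tokens) and tokens[index].text in pattern.words:
                return True
        else:
            index = match.start_token - 1
            if index >= 0 and tokens[index].text in pattern.words:
                return True
    return False


def contextual_label(
    note: Union[Note, str],
    lexicon: TermLexicon,
    config: Optional[RulesConfig] = None,
) -> AnnotationResult:
    """Apply the full rule cascade to one note.

    CLEAN when no lexicon term matches; CONTEXTUAL_NONSTIGMA when every
    match is inside an attributed quote span or benign-sense; otherwise
    STIGMATIZING.  ``needs_review`` is set when a match sits inside an
    unattributed quote, or when the note has unpaired quote characters —
    the cases the published criteria leave to a human.
    """
    config = config or RulesConfig()
    text = note.text if isinstance(note, Note) else note
    tokens = normalize_tokens(text, split_hyphens=config.split_hyphens)
    matches = match_terms(text, lexicon, tokens=tokens)
    if not matches:
        return AnnotationResult(
            category=Category.CLEAN,
            matches=[],
            rationale_codes=[RationaleCode.NO_TERM],
            needs_review=False,
        )

    scan = detect_quoted_spans(text)
    cues = config.cues if config.cues is not None else lexicon.attribution_cues
    attributed: list[QuoteSpan] = []
    unattributed: list[QuoteSpan] = []
    for span in scan.spans:
        if is_attributed(text, span, cues, window_k=config.window_k, tokens=tokens):
            attributed.append(span)
        else:
            unattributed.append(span)

    codes: list[RationaleCode] = []
    all_covered_nonstigma = True
    uncovered = False
    for match in matches:
        if is_benign_sense(match, text, lexicon, tokens=tokens):
            code = RationaleCode.BENIGN_SENSE
        elif any(span.contains(match) for span in attributed):
            code = RationaleCode.QUOTED_ATTRIBUTED
        else:
            code = RationaleCode.PROVIDER_VOICE
            all_covered_nonstigma = False
            if any(span.contains(match) for span in unattributed):
                uncovered = True  # quoted but not attributed: no rule decides
        if code not in codes:
            codes.append(code)

    category = (Category.CONTEXTUAL_NONSTIGMA if all_covered_nonstigma
                else Category.STIGMATIZING)
    needs_review = uncovered or scan.dangling
    return AnnotationResult(
        category=category,
        matches=matches,
        rationale_codes=codes,
        needs_review=needs_review,
        dangling_quote=scan.dangling,
    )


def annotate_corpus(
    notes: Sequence[Note],
    lexicon: TermLexicon,
    config: Optional[RulesConfig] = None,
) -> dict[str, AnnotationResult]:
    """Label every note, keyed by note_id, in input order."""
    return {note.note_id: contextual_label(note, lexicon, config) for note in notes}


def review_queue(
    notes: Sequence[Note],
    lexicon: TermLexicon,
    config: Optional[RulesConfig] = None,
) -> list[str]:
    """note_ids whose annotation needs human review, in stable input order."""
    results = annotate_corpus(notes, lexicon, config)
    return [note.note_id for note in notes if results[note.note_id].needs_review]


@dataclass(frozen=True)
class LabelingSummary:
    """Accounting of the semi-manual labeling pipeline.

    ``n_keyword_extracted`` notes contain at least one potentially
    stigmatizing term; ``n_contextual_nonstigma`` of those are judged
    non-stigmatizing in context; the remainder are stigmatizing.
    """

    n_keyword_extracted: int
    n_contextual_nonstigma: int

    def __post_init__(self) -> None:
        if self.n_contextual_nonstigma > self.n_keyword_extracted:
            raise ValidationError(
                "contextually non-stigmatizing count cannot exceed the "
                "keyword-extracted count"
            )

    @property
    def n_stigmatizing(self) -> int:
        return self.n_keyword_extracted - self.n_contextual_nonstigma


def labeling_summary(results: Iterable[AnnotationResult]) -> LabelingSummary:
    """Summarize annotation results into the pipeline accounting."""
    extracted = 0
    contextual = 0
    for result in results:
        if result.category is Category.CLEAN:
            continue
        extracted += 1
        if result.category is Category.CONTEXTUAL_NONSTIGMA:
            contextual += 1
    return LabelingSummary(extracted, contextual)
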