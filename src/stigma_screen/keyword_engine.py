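"""Dictionary-matching keyword baseline.

The baseline is context-blind by design: notes are whitespace-tokenized,
tokens are lowercased with edge punctuation stripped, and any n-gram that
appears in the stigmatizing-term lexicon flags the whole note as
stigmatizing — regardless of quotation, attribution, or word sense.
Matching is leftmost-longest: at a shared start position the longest
lexicon entry wins, so "abuse" is not double-counted inside
"alcohol abuse".
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

from .corpus_model import Note, TermLexicon

_WS_RUN = re.compile(r"\S+")
_HYPHEN_SLASH = re.compile(r"[-/]")


class Token(NamedTuple):
    """A normalized token with its character span in the original text."""

    text: str
    start: int
    end: int


@dataclass(frozen=True)
class TermMatch:
    """One lexicon hit over the normalized token stream.

    Token offsets are 0-based half-open; ``surface`` is the raw text slice
    covered by the match.
    """

    term: str
    start_token: int
    end_token: int
    surface: str
    start_char: int
    end_char: int

    def __post_init__(self) -> None:
        assert self.end_token > self.start_token


def _is_punct(char: str) -> bool:
    return unicodedata.category(char).startswith("P")


def normalize_tokens(text: str, split_hyphens: bool = False) -> list[Token]:
    """Whitespace-tokenize ``text`` into lowercased tokens with spans.

    Leading and trailing punctuation (including straight and curly quotes)
    is stripped from every token; internal hyphens and slashes are kept
    unless ``split_hyphens`` is set, in which case tokens are additionally
    split at ``-`` and ``/`` so that "drug-seeking" matches the bigram
    "drug seeking".  Tokens that are empty after stripping are dropped.
    """
    tokens: list[Token] = []
    for match in _WS_RUN.finditer(text):
        start, end = match.span()
        while start < end and _is_punct(text[start]):
            start += 1
        while end > start and _is_punct(text[end - 1]):
            end -= 1
        if start >= end:
            continue
        if split_hyphens:
            piece_start = start
            for sub in _HYPHEN_SLASH.split(text[start:end]):
                if sub:
                    tokens.append(Token(sub.lower(), piece_start, piece_start + len(sub)))
                piece_start += len(sub) + 1
        else:
            tokens.append(Token(text[start:end].lower(), start, end))
    return tokens


def match_terms(
    note: Union[Note, str],
    lexicon: TermLexicon,
    split_hyphens: bool = False,
    tokens: Optional[Sequence[Token]] = None,
) -> list[TermMatch]:
    """All leftmost-longest lexicon n-gram matches over the token stream.

    A longer match starting at (or spanning) a position suppresses shorter
    matches contained in it: the scan emits the longest entry matching at
    the current position and resumes after its last token.

    ``tokens`` may carry a precomputed token stream to avoid re-tokenizing
    when several analyses run over the same note.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon must be non-empty")
    text = note.text if isinstance(note, Note) else note
    if tokens is None:
        tokens = normalize_tokens(text, split_hyphens=split_hyphens)
    term_set = {t: " ".join(t) for t in (tuple(s.split()) for s in lexicon.terms)}
    max_len = lexicon.max_term_length
    words = [t.text for t in tokens]
    matches: list[TermMatch] = []
    i = 0
    n = len(words)
    while i < n:
        hit_len = 0
        for length in range(min(max_len, n - i), 0, -1):
            candidate = tuple(words[i:i + length])
            if candidate in term_set:
                hit_len = length
                break
        if hit_len:
            start_char = tokens[i].start
            end_char = tokens[i + hit_len - 1].end
            matches.append(TermMatch(
                term=" ".join(words[i:i + hit_len]),
                start_token=i,
                end_token=i + hit_len,
                surface=text[start_char:end_char],
                start_char=start_char,
                end_char=end_char,
            ))
            i += hit_len
        else:
            i += 1
    return matches


def keyword_classify(
    note: Union[Note, str],
    lexicon: TermLexicon,
    split_hyphens: bool = False,
) -> int:
    """1 iff the note contains at least one lexicon term; no context logic."""
    return 1 if match_terms(note, lexicon, split_hyphens=split_hyphens) else 0
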