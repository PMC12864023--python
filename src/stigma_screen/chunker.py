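"""Sliding-window segmentation of long notes and note-level aggregation.

Long clinical notes exceed the input window of transformer backends, so a
note is divided into overlapping segments of N tokens with an overlap of M
tokens between adjacent chunks (step N−M).  The last chunk is truncated,
never padded.  A note is stigmatizing if any of its chunks is (label
aggregation is max).  The token unit is pluggable; the default is
whitespace tokens so the core stays dependency-free, and a model
tokenizer's counting can be injected through the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

from .corpus_model import Note
from .errors import ValidationError

Tokenizer = Callable[[str], list[str]]


def whitespace_tokenizer(text: str) -> list[str]:
    """Default token unit: maximal non-whitespace runs."""
    return text.split()


@dataclass(frozen=True)
class ChunkingConfig:
    """Chunk size N and overlap M, in tokens.  ``None`` for either means
    whole-note processing."""

    chunk_size: Optional[int] = None
    chunk_overlap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.chunk_size is None:
            return
        if self.chunk_size <= 0:
            raise ValidationError("chunk_size must be positive")
        overlap = self.chunk_overlap or 0
        if overlap < 0:
            raise ValidationError("chunk_overlap must be non-negative")
        if overlap >= self.chunk_size:
            raise ValidationError(
                f"chunk_overlap ({overlap}) must be smaller than chunk_size "
                f"({self.chunk_size})"
            )

    @property
    def whole_note(self) -> bool:
        return self.chunk_size is None

    @property
    def step(self) -> int:
        assert self.chunk_size is not None
        return self.chunk_size - (self.chunk_overlap or 0)


def chunk_note(
    note: Union[Note, str],
    config: ChunkingConfig,
    tokenizer: Tokenizer = whitespace_tokenizer,
) -> list[str]:
    """Split a note into overlapping chunk texts.

    Chunk i covers tokens [i*(N−M), i*(N−M)+N); every token is covered by
    at least one chunk and adjacent chunks share exactly M tokens except
    possibly the final, truncated pair.  A note that fits in one chunk (or
    a whole-note config) is returned unsegmented.
    """
    text = note.text if isinstance(note, Note) else note
    if config.whole_note:
        return [text]
    tokens = tokenizer(text)
    n = config.chunk_size
    assert n is not None
    if len(tokens) <= n:
        return [text]
    chunks: list[str] = []
    start = 0
    while True:
        chunks.append(" ".join(tokens[start:start + n]))
        if start + n >= len(tokens):
            break
        start += config.step
    return chunks


def aggregate_chunk_labels(labels: Sequence[int]) -> int:
    """Note label from chunk labels: 1 iff any chunk is positive."""
    if not labels:
        raise ValidationError("cannot aggregate an empty chunk label list")
    if any(label not in (0, 1) for label in labels):
        raise ValidationError("chunk labels must be 0/1")
    return max(labels)
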