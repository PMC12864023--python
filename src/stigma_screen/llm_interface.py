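"""Prompt construction, backend contract, response parsing, embeddings,
and guideline retrieval.

A prompt bundle has four blocks serialized in a fixed order — system,
optional numbered context, note, question — and the serialization is
versioned and frozen (golden-file tested) because downstream labels depend
on the exact prompt bytes.  Mode invariants: zero-shot bundles carry no
context; in-context bundles carry the full configured guideline source;
retrieval bundles carry the top-n most similar entries.

Backends satisfy a two-function contract (``complete`` over bundles,
``embed`` over strings).  The shipped deterministic stub backend answers
from lexicon hits in the note block and embeds via a seeded hash, letting
every pipeline path run offline; any conforming implementation (e.g. a
hosted chat model) can be dropped in through the same contract.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Protocol, Sequence, Union

import numpy as np

from .corpus_model import GuidelineEntry, Note, TermLexicon
from .errors import BackendError, ValidationError
from .keyword_engine import keyword_classify

PROMPT_VERSION = "stigma-screen-prompt/1"

SYSTEM_CLASSIFY = (
    "You are reviewing clinical documentation for substance use-related "
    "stigmatizing language. Read the clinical note and answer the question "
    "with a single word: yes or no."
)
SYSTEM_EXPLAIN = (
    "You are reviewing clinical documentation for substance use-related "
    "stigmatizing language. You previously classified the clinical note "
    "below. Explain the reasoning behind your classification, then restate "
    "your final answer as a single word: yes or no."
)
CLASSIFY_QUESTION = (
    "Does this note contain stigmatizing language in a substance use context?"
)


class PromptMode(str, Enum):
    ZERO_SHOT = "ZERO_SHOT"
    IN_CONTEXT = "IN_CONTEXT"
    RAG = "RAG"
    EXPLANATION = "EXPLANATION"


@dataclass(frozen=True)
class PromptBundle:
    """A fully assembled prompt: system text, optional ordered context
    entries, the note text, and the question."""

    system_text: str
    note_text: str
    question_text: str
    mode: PromptMode
    context_entries: tuple[GuidelineEntry, ...] = ()

    def serialize(self) -> str:
        """Deterministic, versioned flat-text serialization."""
        parts = [f"[system]\n{self.system_text}\n"]
        if self.context_entries:
            lines = [
                f"{index}. {entry.category_text} Examples: {entry.examples_text}"
                for index, entry in enumerate(self.context_entries, start=1)
            ]
            parts.append("[context]\n" + "\n".join(lines) + "\n")
        parts.append(f"[note]\n{self.note_text}\n")
        parts.append(f"[question]\n{self.question_text}\n")
        return "\n".join(parts)


def build_prompt(
    text: str,
    mode: PromptMode,
    context_entries: Sequence[GuidelineEntry] = (),
    question: str = CLASSIFY_QUESTION,
) -> PromptBundle:
    """Assemble a classification prompt, enforcing per-mode context rules."""
    if mode is PromptMode.ZERO_SHOT and context_entries:
        raise ValidationError("zero-shot prompts carry no context entries")
    if mode is PromptMode.RAG and not context_entries:
        raise ValidationError("retrieval prompts require at least one context entry")
    if mode is PromptMode.IN_CONTEXT and not context_entries:
        raise ValidationError("in-context prompts require the full guideline source")
    if mode is PromptMode.EXPLANATION:
        raise ValidationError("use build_explanation_prompt for explanation bundles")
    return PromptBundle(
        system_text=SYSTEM_CLASSIFY,
        note_text=text,
        question_text=question,
        mode=mode,
        context_entries=tuple(context_entries),
    )


def build_explanation_prompt(
    note: Union[Note, str],
    original_label: int,
    context_entries: Sequence[GuidelineEntry] = (),
) -> PromptBundle:
    """Second-pass prompt asking the model to justify a previous call and
    restate its yes/no answer.

    Configurations that classified with context (in-context, retrieval)
    pass the same entries used during the initial classification; zero-shot
    and fine-tuned configurations pass none.
    """
    if original_label not in (0, 1):
        raise ValidationError("original_label must be 0 or 1")
    answer = "yes" if original_label else "no"
    question = (
        f"You answered {answer!r} when asked: {CLASSIFY_QUESTION} "
        "Explain your reasoning, then restate your final answer (yes or no)."
    )
    text = note.text if isinstance(note, Note) else note
    return PromptBundle(
        system_text=SYSTEM_EXPLAIN,
        note_text=text,
        question_text=question,
        mode=PromptMode.EXPLANATION,
        context_entries=tuple(context_entries),
    )


# ---------------------------------------------------------------------------
# Response parsing
# ---------------------------------------------------------------------------

class ParseFailure:
    """Sentinel value: the response contained no standalone yes/no token.

    Returned (never raised) so callers can tally unreadable responses.
    """

    _instance: Optional["ParseFailure"] = None

    def __new__(cls) -> "ParseFailure":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ParseFailure"


PARSE_FAILURE = ParseFailure()

_YES_NO = re.compile(r"\b(yes|no)\b", re.IGNORECASE)


def parse_response(response_text: str) -> Union[int, ParseFailure]:
    """Map a model response to a binary label.

    Case-insensitive scan for the first standalone "yes"/"no" token; when a
    response contains both, the first occurrence wins (a left-to-right
    read).  Returns :data:`PARSE_FAILURE` if neither occurs.
    """
    match = _YES_NO.search(response_text)
    if match is None:
        return PARSE_FAILURE
    return 1 if match.group(1).lower() == "yes" else 0


# ---------------------------------------------------------------------------
# Embedding similarity and retrieval
# ---------------------------------------------------------------------------

def similarity(u: Sequence[float], v: Sequence[float], metric: str = "cosine") -> float:
    """Similarity score between two vectors.

    cosine = u.v / (|u||v|); dot = u.v.  A zero-norm vector under cosine is
    a validation error.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError(f"dimension mismatch: {u.shape} vs {v.shape}")
    if metric == "dot":
        return float(u @ v)
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            raise ValidationError("cosine similarity undefined for zero-norm vector")
        return float((u @ v) / (nu * nv))
    raise ValidationError(f"unknown metric {metric!r} (expected cosine or dot)")


def select_context(
    note_vec: Sequence[float],
    entries: Sequence[GuidelineEntry],
    n: int,
    metric: str = "cosine",
) -> list[GuidelineEntry]:
    """Top-n guideline entries most similar to the note embedding.

    Entries are ranked by descending score with ties broken by ascending
    entry_id; the first min(n, len(entries)) are returned.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    for entry in entries:
        if entry.embedding is None:
            raise ValidationError(f"entry {entry.entry_id!r} has no embedding")
    scored = [
        (similarity(note_vec, entry.embedding, metric=metric), entry)
        for entry in entries
    ]
    scored.sort(key=lambda pair: (-pair[0], pair[1].entry_id))
    return [entry for _, entry in scored[:n]]


# ---------------------------------------------------------------------------
# Backend contract and deterministic stub
# ---------------------------------------------------------------------------

class Backend(Protocol):
    """Minimal contract a language-model backend must satisfy."""

    def complete(self, bundle: PromptBundle) -> str: ...

    def embed(self, text: str) -> np.ndarray: ...


@dataclass(frozen=True)
class StubRules:
    """Behavior specification for the deterministic stub backend.

    ``positive_terms`` defines the lexicon whose hits in the note block
    trigger a "yes" classification.  ``explanation_style`` shapes
    second-pass responses: ``restate`` repeats the classification with a
    canned justification, ``switch`` always answers the opposite of a
    positive call, ``gibberish`` produces an unparseable response.
    """

    positive_terms: tuple[str, ...]
    explanation_style: str = "restate"
    embed_dim: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.positive_terms:
            raise ValidationError("stub rules require at least one positive term")
        if self.explanation_style not in ("restate", "switch", "gibberish"):
            raise ValidationError(
                f"unknown explanation_style {self.explanation_style!r}"
            )
        if self.embed_dim < 1:
            raise ValidationError("embed_dim must be >= 1")


class StubBackend:
    """Deterministic rule-driven backend: classification answers come from
    n-gram lexicon matching on the bundle's note block, embeddings from a
    seeded content hash.  Identical (rules, seed) always reproduce
    identical responses and vectors."""

    def __init__(self, rules: StubRules):
        self.rules = rules
        self._lexicon = TermLexicon(
            terms=list(dict.fromkeys(rules.positive_terms)),
            source_label="stub-rules",
        )

    def _hit(self, bundle: PromptBundle) -> bool:
        return keyword_classify(bundle.note_text, self._lexicon) == 1

    def complete(self, bundle: PromptBundle) -> str:
        if bundle.mode is PromptMode.EXPLANATION:
            return self._explain(bundle)
        if self._hit(bundle):
            return "Yes, the note contains stigmatizing language in a substance use context."
        return "No, the note does not contain stigmatizing language."

    def _explain(self, bundle: PromptBundle) -> str:
        style = self.rules.explanation_style
        if style == "gibberish":
            return "lorem ipsum dolor sit amet, consectetur adipiscing elit"
        if style == "switch":
            return ("No, on reflection the flagged language is attributed to "
                    "the patient and is not stigmatizing.")
        if self._hit(bundle):
            return ("Yes, the note uses a term from established guidance on "
                    "stigmatizing language; my answer stands: yes.")
        return ("No, I found no stigmatizing terminology in the note; my "
                "answer stands: no.")

    def embed(self, text: str) -> np.ndarray:
        digest = hashlib.sha256(
            f"{self.rules.seed}:{text}".encode("utf-8")
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "big"))
        return rng.standard_normal(self.rules.embed_dim)


def stub_backend(rules: StubRules) -> StubBackend:
    """Construct the deterministic stub backend from a rule spec."""
    return StubBackend(rules)


#: Backend plug-in registry.  Only the offline deterministic stub is
#: shipped; the :class:`Backend` protocol is the extension point for
#: hosted or local chat models.
BACKENDS = {"stub": stub_backend}


def make_backend(name: str, rules: StubRules) -> Backend:
    if name not in BACKENDS:
        raise BackendError(
            f"unknown backend {name!r}; available: {sorted(BACKENDS)}"
        )
    return BACKENDS[name](rules)


def embed_entries(
    entries: Sequence[GuidelineEntry], backend: Backend
) -> list[GuidelineEntry]:
    """Return copies of the entries with embeddings filled in."""
    out = []
    for entry in entries:
        out.append(GuidelineEntry(
            entry_id=entry.entry_id,
            source=entry.source,
            category_text=entry.category_text,
            examples_text=entry.examples_text,
            embedding=backend.embed(
                f"{entry.category_text} Examples: {entry.examples_text}"
            ),
        ))
    return out
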