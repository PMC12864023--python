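"""Domain types and readers/writers for notes, lexicons, guideline entries,
predictions, and evaluation artifacts.

The canonical on-disk formats are deliberately plain text:

* ``notes.jsonl`` — one JSON object per line:
  ``{"note_id", "encounter_id", "patient_id", "caregiver_id", "text",
  "gold_category"?}``.  CSV with a mandatory header is also accepted, but
  JSON-lines is preferred because clinical notes contain newlines and quote
  characters.
* ``lexicon.tsv`` — ``term<TAB>benign_pattern?<TAB>category?``.  Rows whose
  category column is ``cue`` declare speaker-attribution cue phrases rather
  than stigmatizing terms.  Benign-sense patterns use the micro-syntax
  ``next:word1|word2`` / ``prev:word1|word2``: the pattern fires when the
  token adjacent to a term match is one of the listed words.
* ``guidelines.json`` — a JSON array of
  ``{"entry_id", "source", "category_text", "examples_text"}``.
* ``predictions.csv`` — ``note_id,approach,label,raw_response,chunk_labels``.

Unicode text is normalized to NFC on read and otherwise left untouched;
curly and straight quote characters are preserved because downstream
quotation detection depends on them.
"""

from __future__ import annotations

import csv
import io
import json
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import FormatError, ValidationError

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Category(str, Enum):
    """Three-way gold category of a note.

    STIGMATIZING
        contains stigmatizing terms used in a stigmatizing (provider-voice)
        context.
    CONTEXTUAL_NONSTIGMA
        contains potentially stigmatizing terms that are not used
        stigmatically (quoted/attributed patient speech, or a benign word
        sense such as a "junky" cough).
    CLEAN
        contains no stigmatizing terms at all.
    """

    STIGMATIZING = "STIGMATIZING"
    CONTEXTUAL_NONSTIGMA = "CONTEXTUAL_NONSTIGMA"
    CLEAN = "CLEAN"


class Approach(str, Enum):
    """Detection strategy that produced a prediction."""

    KEYWORD = "KEYWORD"
    ZERO_SHOT = "ZERO_SHOT"
    IN_CONTEXT = "IN_CONTEXT"
    RAG = "RAG"
    SFT_BACKEND = "SFT_BACKEND"


class GuidelineSource(str, Enum):
    """Origin of a guideline context table.

    NIDA_14 is a 14-entry substance-use-specific guideline table;
    REVIEW_30 is a broader 30-entry table from a systematic review of
    stigmatizing language in healthcare.
    """

    NIDA_14 = "NIDA_14"
    REVIEW_30 = "REVIEW_30"

    @property
    def expected_count(self) -> int:
        return 14 if self is GuidelineSource.NIDA_14 else 30


def category_to_binary(category: Optional[Category]) -> Optional[int]:
    """Binary label derived from a three-way category (STIGMATIZING -> 1)."""
    if category is None:
        return None
    return 1 if category is Category.STIGMATIZING else 0


# ---------------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------------

@dataclass
class Note:
    """One clinical document.

    Identifier fields are opaque strings and may be empty (external corpora
    may lack encounter or caregiver identifiers); the grouping layer treats
    an empty identifier as "no link".
    """

    note_id: str
    text: str
    encounter_id: str = ""
    patient_id: str = ""
    caregiver_id: str = ""
    gold_category: Optional[Category] = None

    @property
    def gold_binary(self) -> Optional[int]:
        return category_to_binary(self.gold_category)


@dataclass(frozen=True)
class BenignPattern:
    """A literal adjacent-context pattern giving a term a benign sense.

    ``position`` is ``"next"`` or ``"prev"``: the token immediately after
    (or before) the matched term must be one of ``words``.
    """

    term: str
    position: str
    words: frozenset[str]

    def __post_init__(self) -> None:
        if self.position not in ("next", "prev"):
            raise ValidationError(
                f"benign pattern position must be 'next' or 'prev', got {self.position!r}"
            )
        if not self.words:
            raise ValidationError("benign pattern requires at least one word")

    def spec_string(self) -> str:
        return f"{self.position}:{'|'.join(sorted(self.words))}"

    @classmethod
    def parse(cls, term: str, spec: str) -> "BenignPattern":
        if ":" not in spec:
            raise FormatError(f"bad benign pattern spec {spec!r} (expected 'next:w1|w2')")
        position, _, words = spec.partition(":")
        wordset = frozenset(w.strip().lower() for w in words.split("|") if w.strip())
        return cls(term=term, position=position.strip(), words=wordset)


def _normalize_term(raw: str) -> str:
    """Lowercase and collapse internal whitespace of a lexicon entry."""
    return " ".join(raw.lower().split())


@dataclass
class TermLexicon:
    """A stigmatizing-term list with optional benign-sense patterns and
    speaker-attribution cue phrases.

    ``terms`` are normalized (lowercase, single-spaced) word sequences in
    first-occurrence order; multi-word entries such as ``"etoh abuse"`` are
    first-class.
    """

    terms: list[str] = field(default_factory=list)
    benign_patterns: list[BenignPattern] = field(default_factory=list)
    attribution_cues: list[str] = field(default_factory=list)
    source_label: str = ""
    term_categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValidationError("lexicon terms contain duplicates")
        term_set = set(self.terms)
        for pattern in self.benign_patterns:
            if pattern.term not in term_set:
                raise ValidationError(
                    f"benign pattern references unknown term {pattern.term!r}"
                )

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def term_tuples(self) -> list[tuple[str, ...]]:
        return [tuple(t.split()) for t in self.terms]

    @property
    def max_term_length(self) -> int:
        return max((len(t.split()) for t in self.terms), default=0)

    def patterns_for(self, term: str) -> list[BenignPattern]:
        return [p for p in self.benign_patterns if p.term == term]


@dataclass
class GuidelineEntry:
    """One row of a guideline context table, with an optional embedding
    slot filled by a backend's ``embed`` function."""

    entry_id: str
    source: GuidelineSource
    category_text: str
    examples_text: str
    embedding: Optional[Sequence[float]] = None


@dataclass
class PredictionRecord:
    """A binary detector output for one note.

    When a note was processed in chunks, ``chunk_labels`` holds the per-chunk
    decisions and ``label`` must equal their maximum (any-chunk-positive
    aggregation).
    """

    note_id: str
    approach: Approach
    label: int
    raw_response: Optional[str] = None
    chunk_labels: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label!r}")
        if self.chunk_labels is not None:
            if not self.chunk_labels:
                raise ValidationError("chunk_labels, when set, must be non-empty")
            if any(l not in (0, 1) for l in self.chunk_labels):
                raise ValidationError("chunk_labels must be 0/1")
            if self.label != max(self.chunk_labels):
                raise ValidationError(
                    "note label must equal max(chunk_labels) "
                    f"({self.label} != max({self.chunk_labels}))"
                )


# ---------------------------------------------------------------------------
# Notes I/O
# ---------------------------------------------------------------------------

_NOTE_FIELDS = ("note_id", "encounter_id", "patient_id", "caregiver_id",
                "text", "gold_category")


def _note_from_record(record: Mapping[str, object], index: int) -> Note:
    for required in ("note_id", "text"):
        if required not in record or record[required] in (None, ""):
            raise FormatError(f"record {index}: missing required field {required!r}")
    raw_category = record.get("gold_category") or None
    category = Category(raw_category) if raw_category else None
    return Note(
        note_id=str(record["note_id"]),
        text=unicodedata.normalize("NFC", str(record["text"])),
        encounter_id=str(record.get("encounter_id") or ""),
        patient_id=str(record.get("patient_id") or ""),
        caregiver_id=str(record.get("caregiver_id") or ""),
        gold_category=category,
    )


def read_notes(path: PathLike, dialect: str = "jsonl") -> list[Note]:
    """Read a note collection from a JSON-lines or CSV file.

    Identifiers are preserved verbatim; text is normalized to NFC unicode
    and otherwise untouched.  A missing ``note_id``/``text`` raises
    :class:`FormatError` naming the offending record index; a duplicate
    ``note_id`` raises :class:`ValidationError`.
    """
    path = Path(path)
    if dialect not in ("jsonl", "csv"):
        raise ValidationError(f"unknown dialect {dialect!r} (expected jsonl or csv)")
    notes: list[Note] = []
    if dialect == "jsonl":
        with path.open(encoding="utf-8") as handle:
            for index, line in enumerate(handle):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"record {index}: invalid JSON ({exc})") from exc
                notes.append(_note_from_record(record, index))
    else:
        with path.open(encoding="utf-8", newline="") as handle:
            reader = csv.DictReader(handle)
            if reader.fieldnames is None or "note_id" not in reader.fieldnames:
                raise FormatError("CSV notes file requires a header with note_id")
            for index, record in enumerate(reader):
                notes.append(_note_from_record(record, index))
    seen: set[str] = set()
    for note in notes:
        if note.note_id in seen:
            raise ValidationError(f"duplicate note_id {note.note_id!r}")
        seen.add(note.note_id)
    return notes


def write_notes(notes: Iterable[Note], path: PathLike, dialect: str = "jsonl") -> None:
    """Write notes in the canonical record layout (inverse of read_notes)."""
    path = Path(path)
    rows = []
    for note in notes:
        rows.append({
            "note_id": note.note_id,
            "encounter_id": note.encounter_id,
            "patient_id": note.patient_id,
            "caregiver_id": note.caregiver_id,
            "text": note.text,
            "gold_category": note.gold_category.value if note.gold_category else None,
        })
    if dialect == "jsonl":
        with path.open("w", encoding="utf-8") as handle:
            for row in rows:
                handle.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif dialect == "csv":
        with path.open("w", encoding="utf-8", newline="") as handle:
            writer = csv.DictWriter(handle, fieldnames=list(_NOTE_FIELDS))
            writer.writeheader()
            for row in rows:
                row = dict(row)
                row["gold_category"] = row["gold_category"] or ""
                writer.writerow(row)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Lexicon I/O
# ---------------------------------------------------------------------------

_CUE_CATEGORY = "cue"


def load_lexicon(path: PathLike, source_label: str = "") -> TermLexicon:
    """Load a term lexicon from a TSV file.

    Terms are lowercased, whitespace-collapsed, and de-duplicated preserving
    first-occurrence order.  Rows whose category column equals ``cue``
    contribute attribution cue phrases instead of terms.
    """
    path = Path(path)
    terms: list[str] = []
    seen: set[str] = set()
    patterns: list[BenignPattern] = []
    cues: list[str] = []
    categories: dict[str, str] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            raw_term = cells[0]
            pattern_spec = cells[1].strip() if len(cells) > 1 else ""
            category = cells[2].strip().lower() if len(cells) > 2 else ""
            term = _normalize_term(raw_term)
            if not term:
                raise ValidationError(f"line {lineno}: zero-length term")
            if category == _CUE_CATEGORY:
                if term not in cues:
                    cues.append(term)
                continue
            if term not in seen:
                seen.add(term)
                terms.append(term)
            if category:
                categories.setdefault(term, category)
            if pattern_spec:
                pattern = BenignPattern.parse(term, pattern_spec)
                if pattern not in patterns:
                    patterns.append(pattern)
    if not terms:
        raise ValidationError(f"lexicon file {path} contains no terms")
    return TermLexicon(
        terms=terms,
        benign_patterns=patterns,
        attribution_cues=cues,
        source_label=source_label or path.name,
        term_categories=categories,
    )


def write_lexicon(lexicon: TermLexicon, path: PathLike) -> None:
    """Serialize a lexicon back to the TSV layout accepted by load_lexicon."""
    path = Path(path)
    by_term: dict[str, list[BenignPattern]] = {t: [] for t in lexicon.terms}
    for pattern in lexicon.benign_patterns:
        by_term[pattern.term].append(pattern)
    with path.open("w", encoding="utf-8") as handle:
        for term in lexicon.terms:
            category = lexicon.term_categories.get(term, "")
            patterns = by_term[term]
            first = patterns[0].spec_string() if patterns else ""
            handle.write(f"{term}\t{first}\t{category}\n")
            for extra in patterns[1:]:
                handle.write(f"{term}\t{extra.spec_string()}\t{category}\n")
        for cue in lexicon.attribution_cues:
            handle.write(f"{cue}\t\t{_CUE_CATEGORY}\n")


#: Documented placeholder lexicon.  The guideline literature's exact term
#: inventory is not published in machine-readable form, so this built-in
#: list covers the substance-use terms the field's style guidance warns
#: against; production runs should supply their own lexicon.tsv.
_DEFAULT_LEXICON_TSV = """\
etoh abuse\t\tsubstance
alcohol abuse\t\tsubstance
tobacco abuse\t\tsubstance
polysubstance abuse\t\tsubstance
substance abuse\t\tsubstance
drug abuse\t\tsubstance
abuse\t\tsubstance
abuser\t\tsubstance
substance abuser\t\tsubstance
addict\t\tsubstance
addicted\t\tsubstance
junkie\t\tsubstance
junky\tnext:cough\tsubstance
alcoholic\t\tsubstance
alcoholism\t\tsubstance
drunk\t\tsubstance
drug seeking\t\tsubstance
dirty\tnext:dressing|linens\tsubstance
patient states\t\tcue
he feels\t\tcue
she feels\t\tcue
reports\t\tcue
per patient\t\tcue
describes\t\tcue
"""


def default_lexicon() -> TermLexicon:
    """Built-in placeholder lexicon with benign-sense patterns and cues."""
    buffer = io.StringIO(_DEFAULT_LEXICON_TSV)
    terms: list[str] = []
    patterns: list[BenignPattern] = []
    cues: list[str] = []
    categories: dict[str, str] = {}
    for line in buffer:
        if not line.strip():
            continue
        term, spec, category = (line.rstrip("\n").split("\t") + ["", ""])[:3]
        term = _normalize_term(term)
        if category == _CUE_CATEGORY:
            cues.append(term)
            continue
        terms.append(term)
        categories[term] = category
        if spec:
            patterns.append(BenignPattern.parse(term, spec))
    return TermLexicon(
        terms=terms,
        benign_patterns=patterns,
        attribution_cues=cues,
        source_label="builtin-placeholder",
        term_categories=categories,
    )


# ---------------------------------------------------------------------------
# Guidelines I/O
# ---------------------------------------------------------------------------

def load_guidelines(
    path: PathLike,
    source: GuidelineSource,
    strict: bool = True,
) -> list[GuidelineEntry]:
    """Load guideline context entries from a JSON array.

    In strict mode the entry count must match the source's published table
    size (14 for NIDA_14, 30 for REVIEW_30); otherwise any non-empty count
    is accepted.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        try:
            raw = json.load(handle)
        except json.JSONDecodeError as exc:
            raise FormatError(f"guidelines file is not valid JSON: {exc}") from exc
    if not isinstance(raw, list):
        raise FormatError("guidelines file must be a JSON array of entries")
    entries: list[GuidelineEntry] = []
    for index, record in enumerate(raw):
        for required in ("entry_id", "category_text"):
            if required not in record:
                raise FormatError(f"entry {index}: missing field {required!r}")
        record_source = GuidelineSource(record.get("source", source.value))
        if record_source is not source:
            raise ValidationError(
                f"entry {index}: tagged {record_source.value}, expected {source.value}"
            )
        entries.append(GuidelineEntry(
            entry_id=str(record["entry_id"]),
            source=source,
            category_text=str(record["category_text"]),
            examples_text=str(record.get("examples_text", "")),
            embedding=record.get("embedding"),
        ))
    if not entries:
        raise ValidationError("guidelines file contains no entries")
    if strict and len(entries) != source.expected_count:
        raise ValidationError(
            f"{source.value} requires exactly {source.expected_count} entries, "
            f"found {len(entries)}"
        )
    return entries


def write_guidelines(entries: Sequence[GuidelineEntry], path: PathLike) -> None:
    rows = [
        {
            "entry_id": e.entry_id,
            "source": e.source.value,
            "category_text": e.category_text,
            "examples_text": e.examples_text,
        }
        for e in entries
    ]
    Path(path).write_text(
        json.dumps(rows, ensure_ascii=False, indent=2) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Predictions I/O
# ---------------------------------------------------------------------------

def read_predictions(path: PathLike) -> list[PredictionRecord]:
    path = Path(path)
    records: list[PredictionRecord] = []
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "note_id" not in reader.fieldnames:
            raise FormatError("predictions file requires a header with note_id")
        for index, row in enumerate(reader):
            try:
                label = int(row["label"])
            except (KeyError, ValueError) as exc:
                raise FormatError(f"record {index}: bad or missing label") from exc
            chunk_raw = (row.get("chunk_labels") or "").strip()
            chunk_labels = (
                [int(c) for c in chunk_raw.split(";")] if chunk_raw else None
            )
            records.append(PredictionRecord(
                note_id=row["note_id"],
                approach=Approach(row["approach"]),
                label=label,
                raw_response=row.get("raw_response") or None,
                chunk_labels=chunk_labels,
            ))
    return records


def write_predictions(records: Iterable[PredictionRecord], path: PathLike) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["note_id", "approach", "label", "raw_response", "chunk_labels"])
        for record in records:
            writer.writerow([
                record.note_id,
                record.approach.value,
                record.label,
                record.raw_response or "",
                ";".join(str(l) for l in record.chunk_labels)
                if record.chunk_labels else "",
            ])
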