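"""Synthetic clinical-note corpora with planted labels.

The generator emulates the three note categories the detection task is
defined over — provider-voice stigmatizing, contextually non-stigmatizing
(quoted/attributed or benign-sense term use), and clean — together with
the group structure (notes clustered per patient) that makes leakage-safe
splitting non-trivial.  Filler text is template-based clinical-register
sentences, validated at generation time to contain no lexicon term words,
no quote characters, and no attribution-cue words, so planted structure is
the *only* structure: clean notes can never match the lexicon and
contextual notes are contextual purely through the planted quote/benign
patterns.

All randomness flows through one ``numpy`` generator seeded from the spec,
so a fixed seed reproduces a corpus byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus_model import (
    Category,
    GuidelineEntry,
    GuidelineSource,
    Note,
    TermLexicon,
    default_lexicon,
)
from .errors import ValidationError
from .keyword_engine import normalize_tokens

# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

#: Clinical-register filler sentences.  Deliberately free of lexicon term
#: words, quote characters, and attribution-cue words (validated below).
FILLER_SENTENCES = (
    "Vital signs remained stable overnight.",
    "Plan to continue current antibiotic course.",
    "Lungs clear to auscultation bilaterally.",
    "Electrolytes within normal limits this morning.",
    "Tolerating a regular diet without difficulty.",
    "Ambulating in the hallway with minimal assistance.",
    "Follow-up chest radiograph ordered for tomorrow.",
    "Pain well controlled on the current regimen.",
    "No acute events during the preceding shift.",
    "Wound edges approximated without erythema.",
    "Renal function trending toward baseline.",
    "Physical therapy consulted for mobility assessment.",
    "Telemetry shows normal sinus rhythm throughout.",
    "Awaiting final culture results from the laboratory.",
    "Blood pressure responding to the adjusted dose.",
    "Family meeting scheduled with the care team.",
    "Oxygen weaned to room air this afternoon.",
    "Repeat basic metabolic panel in the morning.",
    "Discharge planning discussed with case management.",
    "Neurologic examination unchanged from admission.",
    "Incentive spirometry encouraged every hour while awake.",
    "Home medications reconciled on transfer.",
    "Afebrile for the past twenty-four hours.",
    "Diuresis continues with good urine output.",
)

#: Provider-voice sentences planting a stigmatizing term.  No quotes, no
#: benign adjacency, no cue phrases.
STIGMA_TEMPLATES = (
    "Longstanding {term} documented in prior admissions.",
    "History of {term} complicating the current management plan.",
    "Ongoing {term} despite repeated counseling sessions.",
    "Chart review notable for {term} and poor adherence.",
    "Admitted again in the setting of chronic {term}.",
)

#: Attributed-quotation sentences: a cue phrase immediately precedes a
#: quoted term (curly single quotes, as dictation transcripts render them).
QUOTED_TEMPLATES = (
    "{cue} ‘{term}’ when asked about recent use.",
    "{cue} being ‘{term}’ most evenings at home.",
    "{cue} feeling ‘{term}’ since the last admission.",
)

#: Benign-sense sentences: the term is immediately followed by a word from
#: one of its benign patterns (e.g. a junky cough).
BENIGN_TEMPLATES = (
    "Overnight exam notable for a {term} {benign} at intervals.",
    "Persistent {term} {benign} documented on morning rounds.",
)

#: Adversarial sentences: a quoted term with no attribution cue anywhere
#: nearby.  The rule system cannot decide these; they must surface in the
#: review queue.
ADVERSARIAL_TEMPLATES = (
    "Overheard ‘{term}’ during bedside rounds.",
    "The phrase ‘{term}’ appears in an outside record.",
)


# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoteLengthSpec:
    """Note length in whitespace tokens, drawn from a clipped normal.

    The default mean mirrors the average progress-note length of the ICU
    corpora this generator emulates (~1250 tokens)."""

    mean: float = 1250.0
    sd: float = 400.0
    minimum: int = 20

    def draw(self, rng: np.random.Generator) -> int:
        return max(self.minimum, int(round(rng.normal(self.mean, self.sd))))


@dataclass(frozen=True)
class GroupSizeSpec:
    """Distribution of notes-per-patient group sizes."""

    sizes: tuple[int, ...] = (1, 2, 3)
    probs: tuple[float, ...] = (0.7, 0.2, 0.1)

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.probs):
            raise ValidationError("sizes and probs must have equal length")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValidationError("group size probabilities must sum to 1")
        if any(s < 1 for s in self.sizes):
            raise ValidationError("group sizes must be >= 1")

    def draw(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.sizes, p=self.probs))


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Conditions a generated corpus is drawn under.

    The default category mix (50% stigmatizing, 5% contextually
    non-stigmatizing, 45% clean) mirrors the balanced annotated corpus the
    detection study design calls for: roughly half stigmatizing notes, a
    small contextual stratum among the term-containing notes, and clean
    notes filling the negative class.
    """

    n_notes: int = 100
    category_mix: tuple[float, float, float] = (0.50, 0.05, 0.45)
    quote_prob: float = 0.7
    benign_prob: float = 0.3
    adversarial_prob: float = 0.0
    group_sizes: GroupSizeSpec = field(default_factory=GroupSizeSpec)
    note_length: NoteLengthSpec = field(default_factory=NoteLengthSpec)
    lexicon: Optional[TermLexicon] = None
    filler_sentences: tuple[str, ...] = FILLER_SENTENCES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes < 1:
            raise ValidationError("n_notes must be >= 1")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValidationError("category_mix must sum to 1")
        for p in (*self.category_mix, self.quote_prob, self.benign_prob,
                  self.adversarial_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.quote_prob + self.benign_prob <= 0.0:
            raise ValidationError("quote_prob + benign_prob must be positive")

    def resolved_lexicon(self) -> TermLexicon:
        return self.lexicon if self.lexicon is not None else default_lexicon()


# ---------------------------------------------------------------------------
# Validation of building blocks
# ---------------------------------------------------------------------------

def _lexicon_word_set(lexicon: TermLexicon) -> set[str]:
    words: set[str] = set()
    for term in lexicon.terms:
        words.update(term.split())
    return words


def _cue_word_set(lexicon: TermLexicon) -> set[str]:
    words: set[str] = set()
    for cue in lexicon.attribution_cues:
        words.update(cue.split())
    return words


def _validate_filler(spec: SyntheticCorpusSpec, lexicon: TermLexicon) -> list[str]:
    """Filler sentences safe w.r.t. this lexicon: no term words (so clean
    notes can never match, even across sentence boundaries), no quote
    characters, no cue words (so attribution is only ever planted)."""
    forbidden = _lexicon_word_set(lexicon) | _cue_word_set(lexicon)
    safe = []
    for sentence in spec.filler_sentences:
        if any(ch in sentence for ch in "\"“”‘’"):
            continue
        tokens = {t.text for t in normalize_tokens(sentence)}
        if tokens & forbidden:
            continue
        safe.append(sentence)
    if not safe:
        raise ValidationError(
            "no filler sentence is safe with respect to the lexicon; "
            "supply a compatible filler vocabulary"
        )
    return safe


def _capitalize(cue: str) -> str:
    return cue[0].upper() + cue[1:] if cue else cue


# ---------------------------------------------------------------------------
# Note generation
# ---------------------------------------------------------------------------

@dataclass
class PlantedNote:
    """A generated note plus the generator's ground truth about it."""

    note: Note
    category: Category
    adversarial: bool
    planted_terms: list[str]


def _planted_sentences(
    category: Category,
    spec: SyntheticCorpusSpec,
    lexicon: TermLexicon,
    rng: np.random.Generator,
) -> tuple[list[str], bool, list[str]]:
    """Sentences planting the category's term pattern.

    Returns (sentences, adversarial, planted_terms).
    """
    if category is Category.CLEAN:
        return [], False, []

    if len(lexicon) == 0:
        raise ValidationError("lexicon is empty")

    n_plants = int(rng.integers(1, 3))  # 1 or 2 planted term uses
    sentences: list[str] = []
    terms: list[str] = []

    if category is Category.STIGMATIZING:
        for _ in range(n_plants):
            term = lexicon.terms[int(rng.integers(len(lexicon.terms)))]
            template = STIGMA_TEMPLATES[int(rng.integers(len(STIGMA_TEMPLATES)))]
            sentences.append(template.format(term=term))
            terms.append(term)
        return sentences, False, terms

    # CONTEXTUAL_NONSTIGMA
    adversarial = spec.adversarial_prob > 0 and rng.random() < spec.adversarial_prob
    if adversarial:
        term = lexicon.terms[int(rng.integers(len(lexicon.terms)))]
        template = ADVERSARIAL_TEMPLATES[int(rng.integers(len(ADVERSARIAL_TEMPLATES)))]
        return [template.format(term=term)], True, [term]

    next_patterns = [p for p in lexicon.benign_patterns if p.position == "next"]
    p_quote = spec.quote_prob / (spec.quote_prob + spec.benign_prob)
    for _ in range(n_plants):
        use_quote = rng.random() < p_quote or not next_patterns
        if use_quote:
            if not lexicon.attribution_cues:
                raise ValidationError(
                    "contextual quote path requires attribution cues in the lexicon"
                )
            term = lexicon.terms[int(rng.integers(len(lexicon.terms)))]
            cue = lexicon.attribution_cues[
                int(rng.integers(len(lexicon.attribution_cues)))
            ]
            template = QUOTED_TEMPLATES[int(rng.integers(len(QUOTED_TEMPLATES)))]
            sentences.append(template.format(cue=_capitalize(cue), term=term))
        else:
            pattern = next_patterns[int(rng.integers(len(next_patterns)))]
            benign = sorted(pattern.words)[int(rng.integers(len(pattern.words)))]
            template = BENIGN_TEMPLATES[int(rng.integers(len(BENIGN_TEMPLATES)))]
            term = pattern.term
            sentences.append(template.format(term=term, benign=benign))
        terms.append(term)
    return sentences, False, terms


def generate_note(
    category: Category,
    spec: SyntheticCorpusSpec,
    rng: np.random.Generator,
    note_id: str = "",
) -> Note:
    """Generate a single note of the requested category (ids unset)."""
    return _generate_planted(category, spec, rng, note_id).note


def _generate_planted(
    category: Category,
    spec: SyntheticCorpusSpec,
    rng: np.random.Generator,
    note_id: str,
) -> PlantedNote:
    lexicon = spec.resolved_lexicon()
    filler = _validate_filler(spec, lexicon)
    planted, adversarial, terms = _planted_sentences(category, spec, lexicon, rng)

    target = spec.note_length.draw(rng)
    sentences: list[str] = []
    token_count = sum(len(s.split()) for s in planted)
    while token_count < target:
        sentence = filler[int(rng.integers(len(filler)))]
        sentences.append(sentence)
        token_count += len(sentence.split())
    for sentence in planted:
        position = int(rng.integers(len(sentences) + 1))
        sentences.insert(position, sentence)

    note = Note(
        note_id=note_id,
        text=" ".join(sentences),
        gold_category=category,
    )
    return PlantedNote(note=note, category=category,
                       adversarial=adversarial, planted_terms=terms)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def _assemble_corpus(
    categories: Sequence[Category],
    spec: SyntheticCorpusSpec,
    rng: np.random.Generator,
) -> list[PlantedNote]:
    planted: list[PlantedNote] = []
    index = 0
    group = 0
    n = len(categories)
    while index < n:
        size = min(spec.group_sizes.draw(rng), n - index)
        patient = f"P{group:05d}"
        for offset in range(size):
            item = _generate_planted(
                categories[index + offset], spec, rng, f"N{index + offset:06d}"
            )
            item.note.patient_id = patient
            item.note.encounter_id = f"E{index + offset:06d}"
            planted.append(item)
        index += size
        group += 1
    return planted


def generate_corpus(
    spec: SyntheticCorpusSpec,
    return_manifest: bool = False,
):
    """Generate a full corpus: categories drawn from the category mix,
    notes partitioned into patient-sharing groups.

    With ``return_manifest=True`` also returns the per-note ground truth
    (:class:`PlantedNote` list) for oracle-style tests.
    """
    rng = np.random.default_rng(spec.seed)
    draws = rng.choice(3, size=spec.n_notes, p=list(spec.category_mix))
    order = [Category.STIGMATIZING, Category.CONTEXTUAL_NONSTIGMA, Category.CLEAN]
    categories = [order[d] for d in draws]
    planted = _assemble_corpus(categories, spec, rng)
    notes = [p.note for p in planted]
    if return_manifest:
        return notes, planted
    return notes


def generate_imbalanced_eval(
    spec: SyntheticCorpusSpec,
    prevalence: float,
    return_manifest: bool = False,
):
    """Corpus whose positive fraction is exactly round(prevalence*n)/n.

    The positive count is forced, not sampled, so low-prevalence regimes
    (fractions of a percent) are reproduced exactly.  Negatives are split
    between contextual and clean notes per the spec's relative mix.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValidationError("prevalence must lie strictly in (0, 1)")
    n = spec.n_notes
    n_pos = int(round(prevalence * n))
    if n_pos == 0 or n_pos == n:
        raise ValidationError(
            f"prevalence {prevalence} infeasible at n={n}: forced positive "
            f"count is {n_pos}"
        )
    rng = np.random.default_rng(spec.seed)
    _, p_ctx, p_clean = spec.category_mix
    neg_total = p_ctx + p_clean
    p_ctx_given_neg = p_ctx / neg_total if neg_total > 0 else 0.0
    categories = [Category.STIGMATIZING] * n_pos
    for _ in range(n - n_pos):
        categories.append(
            Category.CONTEXTUAL_NONSTIGMA
            if rng.random() < p_ctx_given_neg else Category.CLEAN
        )
    perm = rng.permutation(n)
    categories = [categories[i] for i in perm]
    planted = _assemble_corpus(categories, spec, rng)
    notes = [p.note for p in planted]
    if return_manifest:
        return notes, planted
    return notes


# ---------------------------------------------------------------------------
# Synthetic guideline tables
# ---------------------------------------------------------------------------

_GUIDELINE_TOPICS = (
    ("person-first language", "say person with a substance use disorder"),
    ("morally loaded descriptors", "avoid labels that imply blame"),
    ("test result language", "describe results as positive or negative"),
    ("medication treatment", "name the medication rather than a slang term"),
    ("recovery framing", "describe remission in clinical terms"),
    ("attribution of behavior", "separate the person from the condition"),
    ("alcohol-related terms", "prefer alcohol use disorder"),
    ("opioid-related terms", "prefer opioid use disorder"),
    ("tobacco-related terms", "prefer tobacco use disorder"),
    ("pejorative shorthand", "avoid judgmental chart abbreviations"),
    ("adherence language", "describe specific behavior, not character"),
    ("withdrawal descriptions", "use physiologic terminology"),
    ("newborn exposure", "avoid labels applied to infants"),
    ("general stigma", "use neutral, specific, observable descriptions"),
    ("mental health comorbidity", "avoid diagnosis-as-identity phrasing"),
)


def synthetic_guidelines(source: GuidelineSource) -> list[GuidelineEntry]:
    """A synthetic stand-in guideline table with the published table's
    entry count (14 or 30).

    The real guideline tables are not redistributable in machine-readable
    form; these placeholder entries carry the same structure (category text
    plus examples) so retrieval and prompting paths are fully exercisable.
    """
    count = source.expected_count
    entries = []
    for index in range(count):
        topic, advice = _GUIDELINE_TOPICS[index % len(_GUIDELINE_TOPICS)]
        entries.append(GuidelineEntry(
            entry_id=f"{source.value}-{index + 1:02d}",
            source=source,
            category_text=f"Guidance on {topic} (entry {index + 1}).",
            examples_text=f"Preferred usage: {advice}.",
        ))
    return entries
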