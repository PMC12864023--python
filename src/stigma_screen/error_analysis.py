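"""False-positive explanation workflow and four-category adjudication tally.

For every false positive (predicted stigmatizing, annotated
non-stigmatizing) the backend is prompted a second time to explain its
reasoning and restate its answer.  The machine can decide two outcomes on
its own: UNREADABLE (no coherent yes/no in the explanation) and
DECISION_SWITCH (the restated answer contradicts the original positive
call).  Everything else needs a human adjudicator, who assigns either
TOO_SENSITIVE_OR_UNRELATED (stigmatizing reading was over-sensitive or not
about substance use) or VALID (the note really is stigmatizing and the
original annotation missed it).  Machine and human judgments are stored
separately and merged at tally time, so the automated pipeline never
impersonates the expert.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .corpus_model import Note, PathLike, PredictionRecord
from .errors import BackendError, ValidationError
from .evaluator import LabelMap, _as_label_map
from .llm_interface import (
    PARSE_FAILURE,
    Backend,
    GuidelineEntry,
    ParseFailure,
    build_explanation_prompt,
    parse_response,
)

logger = logging.getLogger(__name__)


class MachineCategory(str, Enum):
    UNREADABLE = "UNREADABLE"
    DECISION_SWITCH = "DECISION_SWITCH"
    NEEDS_ADJUDICATION = "NEEDS_ADJUDICATION"


class HumanCategory(str, Enum):
    UNREADABLE = "UNREADABLE"
    DECISION_SWITCH = "DECISION_SWITCH"
    TOO_SENSITIVE_OR_UNRELATED = "TOO_SENSITIVE_OR_UNRELATED"
    VALID = "VALID"


CATEGORY_COLUMNS = [c.value for c in HumanCategory]


@dataclass
class ErrorAnalysisRecord:
    note_id: str
    approach: str
    explanation_text: str
    second_label: Union[int, ParseFailure]
    machine_category: MachineCategory
    human_category: Optional[HumanCategory] = None

    @property
    def final_category(self) -> Optional[HumanCategory]:
        """Human judgment overrides the machine pre-categorization."""
        if self.human_category is not None:
            return self.human_category
        if self.machine_category is MachineCategory.UNREADABLE:
            return HumanCategory.UNREADABLE
        if self.machine_category is MachineCategory.DECISION_SWITCH:
            return HumanCategory.DECISION_SWITCH
        return None


def collect_false_positives(
    predictions: Union[LabelMap, Sequence[PredictionRecord]],
    gold: Union[LabelMap, Sequence[Note]],
) -> list[str]:
    """note_ids predicted 1 but gold-labeled 0, in stable prediction order."""
    pred_map = _as_label_map(predictions)
    gold_map = _as_label_map(gold)
    missing = set(pred_map) - set(gold_map)
    if missing:
        raise ValidationError(f"gold labels missing for ids: {sorted(missing)[:5]}")
    return [nid for nid, label in pred_map.items()
            if label == 1 and gold_map[nid] == 0]


def _precategorize(
    explanation: str, second_label: Union[int, ParseFailure]
) -> MachineCategory:
    if isinstance(second_label, ParseFailure) or not explanation.strip():
        return MachineCategory.UNREADABLE
    if second_label == 0:
        return MachineCategory.DECISION_SWITCH
    return MachineCategory.NEEDS_ADJUDICATION


def explain_and_precategorize(
    notes_by_id: Mapping[str, Note],
    note_ids: Sequence[str],
    backend: Backend,
    approach: str = "",
    context_entries: Sequence[GuidelineEntry] = (),
) -> list[ErrorAnalysisRecord]:
    """Prompt the backend for explanations of its false positives.

    ``context_entries`` mirrors the original classification mode: the same
    context the classifier saw (full set for in-context, retrieved set for
    retrieval, none for zero-shot/fine-tuned).  A backend failure yields an
    UNREADABLE record with the cause logged, never an aborted run.
    """
    records: list[ErrorAnalysisRecord] = []
    for nid in note_ids:
        note = notes_by_id.get(nid)
        if note is None:
            raise ValidationError(f"unknown note_id {nid!r}")
        bundle = build_explanation_prompt(note, original_label=1,
                                          context_entries=context_entries)
        try:
            explanation = backend.complete(bundle)
        except BackendError as exc:
            logger.warning("backend failed on note %s: %s", nid, exc)
            records.append(ErrorAnalysisRecord(
                note_id=nid, approach=approach, explanation_text="",
                second_label=PARSE_FAILURE,
                machine_category=MachineCategory.UNREADABLE,
            ))
            continue
        second_label = parse_response(explanation)
        records.append(ErrorAnalysisRecord(
            note_id=nid,
            approach=approach,
            explanation_text=explanation,
            second_label=second_label,
            machine_category=_precategorize(explanation, second_label),
        ))
    return records


def apply_adjudications(
    records: Sequence[ErrorAnalysisRecord],
    adjudications: Mapping[str, HumanCategory],
) -> list[ErrorAnalysisRecord]:
    """Merge the human adjudication sidecar into the records (non-mutating)."""
    out = []
    for record in records:
        human = adjudications.get(record.note_id, record.human_category)
        out.append(ErrorAnalysisRecord(
            note_id=record.note_id,
            approach=record.approach,
            explanation_text=record.explanation_text,
            second_label=record.second_label,
            machine_category=record.machine_category,
            human_category=human,
        ))
    return out


def tally(records: Sequence[ErrorAnalysisRecord]) -> pd.DataFrame:
    """Per-approach counts of the four final categories plus row totals.

    Every record must carry a final category (machine-decided or human
    adjudicated); records still awaiting adjudication are a validation
    error listing their ids.
    """
    pending = [r.note_id for r in records if r.final_category is None]
    if pending:
        raise ValidationError(
            f"records lacking a final category (need adjudication): {pending}"
        )
    rows: dict[str, dict[str, int]] = {}
    for record in records:
        row = rows.setdefault(
            record.approach, {c: 0 for c in CATEGORY_COLUMNS}
        )
        row[record.final_category.value] += 1  # type: ignore[union-attr]
    table = pd.DataFrame(
        [
            {"approach": approach, **counts,
             "total": sum(counts.values())}
            for approach, counts in rows.items()
        ],
        columns=["approach", *CATEGORY_COLUMNS, "total"],
    )
    return table


def read_adjudications(path: PathLike) -> dict[str, HumanCategory]:
    """Read the editable adjudication sidecar (note_id,category CSV)."""
    out: dict[str, HumanCategory] = {}
    with Path(path).open(encoding="utf-8", newline="") as handle:
        for row in csv.DictReader(handle):
            out[row["note_id"]] = HumanCategory(row["category"])
    return out


def write_adjudications(
    adjudications: Mapping[str, HumanCategory], path: PathLike
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["note_id", "category"])
        for nid, category in adjudications.items():
            writer.writerow([nid, category.value])
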