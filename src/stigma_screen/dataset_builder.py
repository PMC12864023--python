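"""Leakage-safe grouped splitting, balancing, corpus reporting, and
instruction-tuning export.

Clinical notes cluster: iterative versions of one note share an encounter,
several notes share a patient or a caregiver.  To keep such linked notes
out of opposing splits, notes are grouped as connected components over the
relation "shares a non-empty encounter, patient, or caregiver identifier"
(the strictest anti-leakage reading), and whole groups are assigned to
train/validation/test with a stratified greedy filler.  Reported
percentages are rounded half-up at two decimals, the printed precision of
the field's tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .corpus_model import Category, Note, PathLike, TermLexicon
from .errors import ValidationError
from .keyword_engine import match_terms
from .llm_interface import CLASSIFY_QUESTION

logger = logging.getLogger(__name__)

SPLITS = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


def percent_half_up(count: int, total: int) -> float:
    """count/total as a percentage, rounded half-up to 2 decimal places."""
    if total <= 0:
        raise ValidationError("total must be positive")
    exact = Decimal(count) * 100 / Decimal(total)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Grouping and splitting
# ---------------------------------------------------------------------------

def build_groups(notes: Sequence[Note]) -> dict[str, str]:
    """Map note_id -> group_id via connected components over shared ids.

    Two notes are linked when they share a non-empty encounter_id,
    patient_id, or caregiver_id; linkage is transitive.  Empty identifiers
    create no links, so fully anonymous notes form singleton groups.  The
    group_id is the note_id of the group's first member in input order.
    """
    parent: dict[int, int] = {}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            # keep the smaller input index as root for determinism
            if ri > rj:
                ri, rj = rj, ri
            parent[rj] = ri

    id_owner: dict[str, int] = {}
    for index, note in enumerate(notes):
        parent[index] = index
        for prefix, value in (("enc", note.encounter_id),
                              ("pat", note.patient_id),
                              ("care", note.caregiver_id)):
            if not value:
                continue
            key = f"{prefix}:{value}"
            if key in id_owner:
                union(id_owner[key], index)
            else:
                id_owner[key] = index
    return {note.note_id: notes[find(index)].note_id
            for index, note in enumerate(notes)}


@dataclass
class SplitAssignment:
    """A leakage-safe train/validation/test partition.

    Every note is assigned exactly once and no group spans two splits;
    realized fractions track the targets as closely as whole groups allow.
    """

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int
    warnings: list[str] = field(default_factory=list)

    def notes_in(self, split: str) -> list[str]:
        return [nid for nid, s in self.assignment.items() if s == split]

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in SPLITS}
        for split in self.assignment.values():
            out[split] += 1
        return out


def _group_stratum(members: Sequence[Note]) -> str:
    """Stratum of a group: its majority gold category (ties broken by the
    category enum order; unlabeled notes form their own stratum)."""
    counts: dict[str, int] = {}
    for note in members:
        key = note.gold_category.value if note.gold_category else "UNLABELED"
        counts[key] = counts.get(key, 0) + 1
    order = [c.value for c in Category] + ["UNLABELED"]
    return max(counts, key=lambda k: (counts[k], -order.index(k)))


def stratified_group_split(
    notes: Sequence[Note],
    groups: Optional[Mapping[str, str]] = None,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole groups to splits, stratified by group category.

    Groups are shuffled with ``seed`` and greedily assigned to the most
    under-filled split within their stratum.  A group larger than its best
    split's remaining target is still assigned there (with a warning):
    leakage safety dominates fraction fidelity.
    """
    if len(fractions) != 3:
        raise ValidationError("fractions must have three components")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must sum to 1")
    if groups is None:
        groups = build_groups(notes)
    by_id = {note.note_id: note for note in notes}
    members: dict[str, list[Note]] = {}
    for nid, gid in groups.items():
        members.setdefault(gid, []).append(by_id[nid])

    group_ids = sorted(members)
    rng = np.random.default_rng(seed)
    rng.shuffle(group_ids)

    strata: dict[str, list[str]] = {}
    for gid in group_ids:
        strata.setdefault(_group_stratum(members[gid]), []).append(gid)

    assignment: dict[str, str] = {}
    warnings: list[str] = []
    for stratum, gids in strata.items():
        total = sum(len(members[g]) for g in gids)
        targets = {s: f * total for s, f in zip(SPLITS, fractions)}
        filled = {s: 0 for s in SPLITS}
        for gid in gids:
            size = len(members[gid])
            best = max(SPLITS, key=lambda s: targets[s] - filled[s])
            if size > targets[best]:
                message = (
                    f"group {gid} ({size} notes) exceeds remaining capacity of "
                    f"split {best!r}; assigned anyway to prevent leakage"
                )
                warnings.append(message)
                logger.warning(message)
            filled[best] += size
            for note in members[gid]:
                assignment[note.note_id] = best

    result = SplitAssignment(
        assignment=assignment,
        fractions=tuple(fractions),  # type: ignore[arg-type]
        seed=seed,
        warnings=warnings,
    )
    _assert_no_leakage(result, groups)
    return result


def _assert_no_leakage(result: SplitAssignment, groups: Mapping[str, str]) -> None:
    """Invariant, checked on every build: no group spans two splits."""
    seen: dict[str, str] = {}
    for nid, split in result.assignment.items():
        gid = groups[nid]
        if gid in seen and seen[gid] != split:
            raise ValidationError(
                f"leakage: group {gid} spans splits {seen[gid]} and {split}"
            )
        seen[gid] = split


# ---------------------------------------------------------------------------
# Balancing and prevalence
# ---------------------------------------------------------------------------

def downsample_balanced(notes: Sequence[Note], seed: int = 0) -> list[Note]:
    """Balanced subset: all minority-class notes plus an equal-sized seeded
    random sample of the majority class, in original corpus order."""
    labeled = [n for n in notes if n.gold_binary is not None]
    if len(labeled) != len(notes):
        raise ValidationError("downsampling requires gold labels on every note")
    positives = [n for n in notes if n.gold_binary == 1]
    negatives = [n for n in notes if n.gold_binary == 0]
    minority, majority = sorted((positives, negatives), key=len)
    if not minority:
        raise ValidationError("cannot balance: minority class is empty")
    if len(minority) == len(majority):
        return list(notes)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(majority), size=len(minority), replace=False)
    keep = {majority[i].note_id for i in chosen} | {n.note_id for n in minority}
    return [n for n in notes if n.note_id in keep]


def prevalence_from_counts(positives: int, total: int) -> dict[str, object]:
    """Prevalence report from raw counts (percent half-up at 2 d.p.)."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= positives <= total:
        raise ValidationError("positives must lie in [0, total]")
    return {
        "positives": positives,
        "total": total,
        "percent": percent_half_up(positives, total),
    }


def prevalence_report(notes: Sequence[Note]) -> dict[str, object]:
    """Positive-label prevalence of a gold-labeled corpus."""
    labels = [n.gold_binary for n in notes]
    if any(l is None for l in labels):
        raise ValidationError("prevalence requires gold labels on every note")
    return prevalence_from_counts(sum(labels), len(labels))  # type: ignore[arg-type]


def term_frequency_table(
    notes: Sequence[Note],
    lexicon: TermLexicon,
    top_k: Optional[int] = None,
) -> pd.DataFrame:
    """Per-term note frequency: how many distinct notes each term was
    identified in (longest-match suppression applies), with percentages
    over the whole collection.

    Rows are sorted by descending note count, ties by term.  Several terms
    can be counted in the same note, so percentages need not sum to 100.
    """
    counts: dict[str, int] = {}
    for note in notes:
        for term in {m.term for m in match_terms(note, lexicon)}:
            counts[term] = counts.get(term, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        rows = rows[:top_k]
    total = len(notes)
    return pd.DataFrame(
        [
            {
                "term": term,
                "note_count": count,
                "percent": percent_half_up(count, total) if total else 0.0,
            }
            for term, count in rows
        ],
        columns=["term", "note_count", "percent"],
    )


# ---------------------------------------------------------------------------
# Instruction-tuning export
# ---------------------------------------------------------------------------

#: Fine-tuning configuration exported alongside the training data: LoRA on
#: all target modules, rank 8 / alpha 8, 3 epochs at lr 1e-4 with a cosine
#: schedule, effective batch 64 (8 per device x 8 devices).  The package
#: exports this configuration; it does not execute training.
SFT_TRAINING_CONFIG = {
    "method": "lora",
    "lora_rank": 8,
    "lora_alpha": 8,
    "target_modules": "all",
    "epochs": 3,
    "optimizer": "adamw",
    "lr_scheduler": "cosine",
    "learning_rate": 1e-4,
    "gradient_accumulation_steps": 1,
    "per_device_batch_size": 8,
    "num_devices": 8,
    "effective_batch_size": 64,
}


def export_sft_dataset(
    notes: Iterable[Note],
    path: PathLike,
    assignment: Optional[SplitAssignment] = None,
    split: Optional[str] = None,
) -> int:
    """Export labeled notes as alpaca-style instruction-tuning records.

    Each record is ``{"instruction", "input", "output"}`` with the binary
    question as the instruction and "yes"/"no" as the output.  Unlabeled
    notes are skipped (and counted in the log).  A companion
    ``<path>.train_config.json`` mirrors :data:`SFT_TRAINING_CONFIG`.
    Returns the number of exported records.
    """
    path = Path(path)
    if (assignment is None) != (split is None):
        raise ValidationError("assignment and split must be given together")
    records = []
    skipped = 0
    for note in notes:
        if assignment is not None and assignment.assignment.get(note.note_id) != split:
            continue
        if note.gold_binary is None:
            skipped += 1
            continue
        records.append({
            "instruction": CLASSIFY_QUESTION,
            "input": note.text,
            "output": "yes" if note.gold_binary else "no",
        })
    if skipped:
        logger.info("sft export skipped %d unlabeled notes", skipped)
    path.write_text(
        json.dumps(records, ensure_ascii=False, indent=1) + "\n", encoding="utf-8"
    )
    config_path = path.with_suffix(path.suffix + ".train_config.json")
    config_path.write_text(
        json.dumps(SFT_TRAINING_CONFIG, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return len(records)
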