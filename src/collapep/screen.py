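"""Candidate screening cascade.

Released peptides pass through four stages in fixed order:

1. novelty      - drop peptides already known for the activity (exact DB match)
2. safety       - keep only predicted non-toxic AND non-allergenic peptides
3. activity     - keep peptides called "high" by at least one of three
                  activity classifiers (logistic regression, SVM, MLP votes)
4. docking      - keep peptides whose -CDOCKER energy (-CE) and -CDOCKER
                  interaction energy (-CIE) both exceed a reference ligand's
                  (strictly), sorted by -CIE descending

The toxicity/allergenicity/activity/docking annotations are external tool
exports ingested as TSVs; nothing here re-predicts them. Every candidate
carries a stage log recording each decision and its reason, and a rejected
candidate receives no decisions for later stages, so the report is a
complete audit trail.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .bioprofile import ReferenceDB

STAGES = ("novelty", "safety", "activity", "docking")

#: Controlled vocabularies for ingested annotations; external tool phrasings
#: are mapped through LABEL_MAP (configurable, not hard-coded per tool).
TOX_LABELS = {"toxic", "non-toxic"}
ALLERGEN_LABELS = {"allergenic", "non-allergenic"}
VOTE_LABELS = {"high", "low_non"}
LABEL_MAP = {
    "high activity": "high",
    "low & non-activity": "low_non",
    "non toxic": "non-toxic",
    "nontoxic": "non-toxic",
    "no evidence": "non-allergenic",
}


class ScreenError(ValueError):
    """Raised for malformed screening input."""


@dataclass(frozen=True)
class ReferenceLigand:
    """Positive-control docking result (both energies in kcal/mol, negated)."""

    name: str
    cdocker_energy: float
    cdocker_interaction: float


# -CE/-CIE of the positive-control ACE inhibitor docked alongside the
# bundled candidate panel.
LISINOPRIL = ReferenceLigand("lisinopril", 93.7579, 103.348)


@dataclass
class CandidateRecord:
    """One peptide's audit trail through the cascade."""

    sequence: str
    origins: list[tuple[str, int, int, str]] = field(default_factory=list)
    is_novel: bool | None = None
    toxicity: str = "unannotated"
    allergenicity: str = "unannotated"
    activity_votes: dict[str, str] = field(default_factory=dict)
    cdocker_energy: float | None = None
    cdocker_interaction: float | None = None
    stage_log: list[tuple[str, str, str]] = field(default_factory=list)

    def log(self, stage: str, decision: str, reason: str) -> None:
        self.stage_log.append((stage, decision, reason))

    @property
    def rejected_at(self) -> str | None:
        for stage, decision, _ in self.stage_log:
            if decision == "reject":
                return stage
        return None


def make_candidates(
    fragments: Iterable[str],
    origins: Mapping[str, list[tuple[str, int, int, str]]] | None = None,
    min_length: int = 2,
) -> list[CandidateRecord]:
    """Candidate records from peptide sequences, duplicates collapsed.

    Length-1 fragments (free amino acids) are excluded from screening.
    """
    origins = origins or {}
    out: list[CandidateRecord] = []
    seen: set[str] = set()
    for seq in fragments:
        if len(seq) < min_length or seq in seen:
            continue
        seen.add(seq)
        out.append(CandidateRecord(sequence=seq, origins=list(origins.get(seq, []))))
    return out


def _normalize(label: str, vocabulary: set[str], row: str) -> str:
    lab = LABEL_MAP.get(label.strip().lower(), label.strip().lower())
    if lab not in vocabulary:
        raise ScreenError(f"unknown label {label!r} in row {row!r}; expected one of {sorted(vocabulary)}")
    return lab


def ingest_annotations(
    candidates: Sequence[CandidateRecord],
    table: str | Path | Sequence[Mapping[str, str]],
    kind: str,
) -> list[str]:
    """Attach one kind of external annotation to matching candidates.

    ``kind`` is one of toxicity / allergenicity / activity / docking; the
    table is a TSV path (or pre-parsed rows) keyed by ``sequence`` with
    kind-specific columns (toxicity: label; allergenicity: label; activity:
    lr, svm, mlp; docking: cdocker_energy, cdocker_interaction). Returns the
    table sequences that matched no candidate (reported, not fatal).
    """
    if kind not in {"toxicity", "allergenicity", "activity", "docking"}:
        raise ScreenError(f"unknown annotation kind {kind!r}")
    if isinstance(table, (str, Path)):
        with open(table) as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    else:
        rows = list(table)
    by_seq = {c.sequence: c for c in candidates}
    unmatched = []
    for row in rows:
        seq = row["sequence"].strip().upper()
        rec = by_seq.get(seq)
        if rec is None:
            unmatched.append(seq)
            continue
        if kind == "toxicity":
            rec.toxicity = _normalize(row["label"], TOX_LABELS, seq)
        elif kind == "allergenicity":
            rec.allergenicity = _normalize(row["label"], ALLERGEN_LABELS, seq)
        elif kind == "activity":
            rec.activity_votes = {
                clf.upper(): _normalize(row[clf], VOTE_LABELS, seq)
                for clf in ("lr", "svm", "mlp")
            }
        else:  # docking
            rec.cdocker_energy = float(row["cdocker_energy"])
            rec.cdocker_interaction = float(row["cdocker_interaction"])
    return unmatched


def novelty_filter(
    candidates: Sequence[CandidateRecord], db: ReferenceDB, activity: str
) -> list[CandidateRecord]:
    """Keep peptides not already catalogued for the activity."""
    refs = db.sequences(activity)
    kept = []
    for rec in candidates:
        rec.is_novel = rec.sequence not in refs
        if rec.is_novel:
            rec.log("novelty", "keep", "not in reference database")
            kept.append(rec)
        else:
            rec.log("novelty", "reject", f"known {activity}")
    return kept


def safety_filter(
    candidates: Sequence[CandidateRecord], strict: bool = True
) -> list[CandidateRecord]:
    """Keep predicted non-toxic AND non-allergenic peptides.

    ``strict`` rejects unannotated candidates; the permissive mode treats
    missing annotations as passing (useful when only a subset was submitted
    to the external predictors).
    """
    kept = []
    for rec in candidates:
        tox, alg = rec.toxicity, rec.allergenicity
        if not strict:
            tox = "non-toxic" if tox == "unannotated" else tox
            alg = "non-allergenic" if alg == "unannotated" else alg
        if tox == "toxic":
            rec.log("safety", "reject", "toxicity")
        elif alg == "allergenic":
            rec.log("safety", "reject", "allergenicity")
        elif tox == "unannotated" or alg == "unannotated":
            rec.log("safety", "reject", "unannotated")
        else:
            rec.log("safety", "keep", "non-toxic, non-allergenic")
            kept.append(rec)
    return kept


def activity_select(candidates: Sequence[CandidateRecord]) -> list[CandidateRecord]:
    """Keep peptides with at least one 'high' classifier vote."""
    kept = []
    for rec in candidates:
        if not rec.activity_votes:
            rec.log("activity", "reject", "unscored")
        elif "high" in rec.activity_votes.values():
            voters = sorted(k for k, v in rec.activity_votes.items() if v == "high")
            rec.log("activity", "keep", f"high activity by {', '.join(voters)}")
            kept.append(rec)
        else:
            rec.log("activity", "reject", "no classifier predicted high activity")
    return kept


def docking_select(
    candidates: Sequence[CandidateRecord], reference: ReferenceLigand
) -> list[CandidateRecord]:
    """Keep peptides with both -CE and -CIE strictly above the reference.

    Output is sorted by -CIE descending (stronger predicted binding first).
    """
    if reference is None:
        raise ScreenError("reference ligand required for docking selection")
    kept = []
    for rec in candidates:
        if rec.cdocker_energy is None or rec.cdocker_interaction is None:
            raise ScreenError(f"candidate {rec.sequence}: docking energies missing")
        if (
            rec.cdocker_energy > reference.cdocker_energy
            and rec.cdocker_interaction > reference.cdocker_interaction
        ):
            rec.log("docking", "keep", f"-CE and -CIE above {reference.name}")
            kept.append(rec)
        else:
            rec.log("docking", "reject", f"energy not above {reference.name}")
    kept.sort(key=lambda r: -r.cdocker_interaction)
    return kept


@dataclass
class CascadeReport:
    """Per-stage counts plus the full audit trail."""

    stage_counts: list[dict]
    records: list[CandidateRecord]
    final: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": self.stage_counts,
                "final": self.final,
                "records": [
                    {
                        "sequence": r.sequence,
                        "rejected_at": r.rejected_at,
                        "stage_log": [list(e) for e in r.stage_log],
                    }
                    for r in self.records
                ],
            },
            indent=2,
        )


def run_cascade(
    candidates: Sequence[CandidateRecord],
    db: ReferenceDB,
    activity: str,
    reference: ReferenceLigand,
    strict_safety: bool = True,
    skip_novelty: bool = False,
) -> CascadeReport:
    """Run novelty -> safety -> activity -> docking and report counts.

    Annotations must already be ingested. ``skip_novelty`` starts the
    cascade from pre-screened novel candidates (e.g. a published panel).
    """
    records = list(candidates)
    current: list[CandidateRecord] = records
    counts = []
    for stage in STAGES:
        n_in = len(current)
        if stage == "novelty":
            if skip_novelty:
                continue
            current = novelty_filter(current, db, activity)
        elif stage == "safety":
            current = safety_filter(current, strict=strict_safety)
        elif stage == "activity":
            current = activity_select(current)
        else:
            current = docking_select(current, reference)
        counts.append({"stage": stage, "in": n_in, "out": len(current)})
    return CascadeReport(
        stage_counts=counts,
        records=records,
        final=[r.sequence for r in current],
    )


def bundled_candidate_panel() -> list[CandidateRecord]:
    """The shipped 27-peptide collagen-derived panel with classifier votes
    and CDOCKER energies (positive control: :data:`LISINOPRIL`)."""
    from importlib.resources import files

    text = files("collapep.data").joinpath("candidate_panel.tsv").read_text()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    records = [CandidateRecord(sequence=row["sequence"]) for row in rows]
    ingest_annotations(records, rows, "activity")
    ingest_annotations(records, rows, "docking")
    return records


def write_cascade_tsv(report: CascadeReport, path: str | Path) -> None:
    """Human-readable audit table: one row per candidate."""
    with open(path, "w") as fh:
        fh.write("sequence\tterminal_state\tlog\n")
        for r in report.records:
            state = f"rejected:{r.rejected_at}" if r.rejected_at else "selected"
            log = "; ".join(f"{s}={d}({why})" for s, d, why in r.stage_log)
            fh.write(f"{r.sequence}\t{state}\t{log}\n")
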