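"""Bioactive-fragment profiling against a reference peptide database.

The central statistic is the occurrence frequency of bioactive fragments,

    A = a / N

where N is the residue count of the (mature) chain and ``a`` counts either
all positional substring occurrences of reference peptides in the chain
(precursor profiling, overlaps allowed) or the released fragments of a
digest whose sequence is a reference peptide (release frequency, counted
with positional multiplicity). A is a per-residue frequency and is not
clamped at 1.

Matching uses an Aho-Corasick automaton over the reference sequences of one
activity class, so profiling a chain is a single linear pass regardless of
database size; the automaton is required to find exactly the occurrence set
a naive quadratic scan finds. 'X' residues match nothing.
"""

from __future__ import annotations

import csv
import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .digestion import DigestResult
from .seqmodel import AMINO_ACIDS, ProteinChain

logger = logging.getLogger(__name__)


class ReferenceDBError(ValueError):
    """Raised for malformed reference-database input."""


@dataclass(frozen=True)
class ReferencePeptide:
    """One activity-annotated reference peptide (e.g. a known ACE inhibitor)."""

    sequence: str
    activity: str
    ic50_um: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ReferenceDBError(f"reference peptide too short: {self.sequence!r}")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ReferenceDBError(
                f"reference peptide {self.sequence!r}: invalid residues {sorted(bad)}"
            )
        if self.ic50_um is not None and self.ic50_um <= 0:
            raise ReferenceDBError(f"{self.sequence!r}: IC50 must be positive")


class _AhoCorasick:
    """Multi-pattern matcher: yields (pattern, 0-based end index) per hit."""

    def __init__(self, patterns: Iterable[str]):
        # goto is a list of dicts (state -> residue -> state); out collects
        # every pattern ending at a state, including via suffix links.
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[str]] = [[]]
        self._fail: list[int] = [0]
        for pat in patterns:
            state = 0
            for ch in pat:
                nxt = self._goto[state].get(ch)
                if nxt is None:
                    self._goto.append({})
                    self._out.append([])
                    self._fail.append(0)
                    nxt = len(self._goto) - 1
                    self._goto[state][ch] = nxt
                state = nxt
            self._out[state].append(pat)
        # BFS to set failure links and merge outputs.
        queue = deque(self._goto[0].values())
        while queue:
            state = queue.popleft()
            for ch, nxt in self._goto[state].items():
                queue.append(nxt)
                f = self._fail[state]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[nxt] = self._goto[f].get(ch, 0) if self._goto[f].get(ch, 0) != nxt else 0
                self._out[nxt].extend(self._out[self._fail[nxt]])

    def occurrences(self, text: str) -> list[tuple[str, int]]:
        """All (pattern, start) occurrences in ``text``, overlaps included."""
        hits: list[tuple[str, int]] = []
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for pat in self._out[state]:
                hits.append((pat, i - len(pat) + 1))
        return hits


class ReferenceDB:
    """Activity-annotated reference peptides with a per-activity matcher."""

    def __init__(self, peptides: Iterable[ReferencePeptide]):
        self.peptides: list[ReferencePeptide] = []
        seen: set[tuple[str, str]] = set()
        for p in peptides:
            key = (p.sequence, p.activity)
            if key in seen:
                logger.warning("duplicate reference peptide dropped: %s [%s]", p.sequence, p.activity)
                continue
            seen.add(key)
            self.peptides.append(p)
        if not self.peptides:
            raise ReferenceDBError("reference database is empty")
        self._indexes: dict[str, _AhoCorasick] = {}

    @property
    def activities(self) -> list[str]:
        return sorted({p.activity for p in self.peptides})

    def sequences(self, activity: str) -> set[str]:
        self._check_activity(activity)
        return {p.sequence for p in self.peptides if p.activity == activity}

    def get(self, sequence: str, activity: str) -> ReferencePeptide | None:
        for p in self.peptides:
            if p.sequence == sequence and p.activity == activity:
                return p
        return None

    def _check_activity(self, activity: str) -> None:
        if activity not in {p.activity for p in self.peptides}:
            raise ReferenceDBError(
                f"unknown activity {activity!r}; available: {self.activities}"
            )

    def index(self, activity: str) -> _AhoCorasick:
        self._check_activity(activity)
        if activity not in self._indexes:
            self._indexes[activity] = _AhoCorasick(sorted(self.sequences(activity)))
        return self._indexes[activity]


def load_refdb(path: str | Path) -> ReferenceDB:
    """Read a reference-peptide TSV (sequence, activity, ic50_um, source)."""
    peptides = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sequence", "activity"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ReferenceDBError(f"{path}: header must include {sorted(required)}")
        for rownum, row in enumerate(reader, start=2):
            ic50 = (row.get("ic50_um") or "").strip()
            try:
                peptides.append(
                    ReferencePeptide(
                        sequence=row["sequence"].strip().upper(),
                        activity=row["activity"].strip(),
                        ic50_um=float(ic50) if ic50 else None,
                        source=(row.get("source") or "").strip(),
                    )
                )
            except ReferenceDBError as exc:
                raise ReferenceDBError(f"{path}: row {rownum}: {exc}") from exc
    if not peptides:
        raise ReferenceDBError(f"{path}: no reference peptides")
    return ReferenceDB(peptides)


def bundled_ace_refdb() -> ReferenceDB:
    """The shipped ACE-inhibitor reference set (collagen-chain dipeptides and
    tripeptides from a database snapshot plus literature-reported peptides)."""
    from importlib.resources import as_file, files

    with as_file(files("collapep.data").joinpath("refdb_ace.tsv")) as p:
        return load_refdb(p)


@dataclass(frozen=True)
class ActivityProfile:
    """Occurrence-frequency result for one chain and one activity class."""

    activity: str
    chain_id: str
    a: int
    N: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.N < 1:
            raise ValueError("require a >= 0 and N >= 1")

    @property
    def A(self) -> float:
        return self.a / self.N


def occurrence_profile(
    chain: ProteinChain,
    db: ReferenceDB,
    activity: str,
    overlapping: bool = True,
) -> ActivityProfile:
    """Precursor profile: how often reference peptides occur in the chain.

    With ``overlapping`` (the default) every positional substring occurrence
    counts; with ``overlapping=False`` each distinct reference sequence
    counts at most once (presence/absence).
    """
    hits = db.index(activity).occurrences(chain.residues)
    a = len(hits) if overlapping else len({pat for pat, _ in hits})
    return ActivityProfile(activity=activity, chain_id=chain.id, a=a, N=len(chain))


def release_frequency(result: DigestResult, db: ReferenceDB, activity: str) -> ActivityProfile:
    """Release frequency: digest fragments matching the reference set.

    Fragments count with positional multiplicity (a peptide released twice
    counts twice); N is the mature chain length (fragment lengths sum to it).
    """
    refs = db.sequences(activity)
    a = sum(1 for seq, _, _ in result.fragments if seq in refs)
    n = sum(len(seq) for seq, _, _ in result.fragments)
    return ActivityProfile(activity=activity, chain_id=result.chain_id, a=a, N=n)


def weighted_profile(
    profiles: Sequence[ActivityProfile],
    stoichiometry: Mapping[str, int] | None = None,
) -> float:
    """Copy-number-weighted mean of per-chain A values (2:1 for type I collagen)."""
    if not profiles:
        raise ValueError("no profiles")
    ids = [p.chain_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate chains in profile list: {ids}")
    stoichiometry = stoichiometry or {}
    if stoichiometry and set(stoichiometry) != set(ids):
        raise ValueError(
            f"stoichiometry chains {sorted(stoichiometry)} do not match profiles {sorted(ids)}"
        )
    num = sum(stoichiometry.get(p.chain_id, 1) * p.A for p in profiles)
    den = sum(stoichiometry.get(p.chain_id, 1) for p in profiles)
    return num / den


def classify_known_novel(
    fragments: Iterable[str], db: ReferenceDB, activity: str
) -> tuple[list[str], list[str]]:
    """Split peptides into (known, novel) by exact full-sequence DB match.

    Known peptides are excluded from novelty screening; the partition is
    exhaustive and disjoint, preserving input order.
    """
    refs = db.sequences(activity)
    known, novel = [], []
    for frag in fragments:
        (known if frag in refs else novel).append(frag)
    return known, novel


def naive_occurrences(text: str, patterns: Iterable[str]) -> list[tuple[str, int]]:
    """Quadratic reference scan used to validate the automaton in tests."""
    hits = []
    for pat in patterns:
        start = text.find(pat)
        while start != -1:
            hits.append((pat, start))
            start = text.find(pat, start + 1)
    return hits


def write_profile_tsv(
    profiles: Sequence[ActivityProfile],
    weighted_a: float,
    path: str | Path,
) -> None:
    """Profile report: activity, chain, a, N, A, weighted A."""
    with open(path, "w") as fh:
        fh.write("activity\tchain_id\ta\tN\tA\tweighted_A\n")
        for p in profiles:
            fh.write(f"{p.activity}\t{p.chain_id}\t{p.a}\t{p.N}\t{p.A:.4f}\t{weighted_a:.4f}\n")
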