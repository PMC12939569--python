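"""Simulated enzymatic proteolysis.

An enzyme's cleavage specificity is expressed over the residues flanking a
peptide bond, in protease nomenclature: for the bond between residues P1 and
P1', positions P2-P1 sit N-terminal of the scissile bond and P1'-P2'
C-terminal. A :class:`CleavageSpec` constrains any subset of the four
positions to a residue set; an :class:`EnzymeRule` is a disjunction of specs
minus a disjunction of exception specs (e.g. trypsin: cleave after K or R,
except before P).

Multi-enzyme digestion is simultaneous: the site set is the union of the
per-enzyme site sets, and fragments are the maximal runs between consecutive
sites. The theoretical degree of hydrolysis is

    DH_T = d / D x 100

with d cleaved bonds and D = length - 1 total bonds; for a multi-chain
protein the pooled DH_T is the copy-number-weighted mean of the per-chain
values (2:1 for the two alpha1 chains and one alpha2 chain of type I
collagen).

Bond indices are 0-based: bond i joins residues i and i+1 of the mature
chain. Bonds adjacent to an 'X' (unknown) residue are never cleaved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .seqmodel import AMINO_ACIDS, ProteinChain

_POSITIONS = ("p2", "p1", "p1prime", "p2prime")


class RuleError(ValueError):
    """Raised for malformed enzyme-rule definitions."""


class DigestError(ValueError):
    """Raised for invalid digestion requests."""


@dataclass(frozen=True)
class CleavageSpec:
    """Residue-set constraints on the P2/P1/P1'/P2' context of a bond.

    ``None`` means the position is unconstrained; an out-of-range context
    position (chain terminus) fails any constraint placed on it.
    """

    p2: frozenset[str] | None = None
    p1: frozenset[str] | None = None
    p1prime: frozenset[str] | None = None
    p2prime: frozenset[str] | None = None

    def __post_init__(self) -> None:
        sets = [self.p2, self.p1, self.p1prime, self.p2prime]
        if all(s is None for s in sets):
            raise RuleError("cleavage spec constrains no position")
        for name, s in zip(_POSITIONS, sets):
            if s is not None:
                if not s:
                    raise RuleError(f"position {name}: empty residue set")
                bad = s - AMINO_ACIDS
                if bad:
                    raise RuleError(f"position {name}: invalid residues {sorted(bad)}")

    def matches(self, residues: str, bond: int) -> bool:
        """Whether this spec matches bond ``bond`` (0-based) of ``residues``."""
        n = len(residues)
        for offset, s in ((-1, self.p2), (0, self.p1), (1, self.p1prime), (2, self.p2prime)):
            if s is None:
                continue
            idx = bond + offset
            if idx < 0 or idx >= n or residues[idx] not in s:
                return False
        return True


@dataclass(frozen=True)
class EnzymeRule:
    """One enzyme's compiled cleavage specificity."""

    name: str
    ec_number: str
    specs: tuple[CleavageSpec, ...]
    exceptions: tuple[CleavageSpec, ...] = ()

    def __post_init__(self) -> None:
        if not self.specs:
            raise RuleError(f"enzyme {self.name!r}: no cleavage specs")

    def cleaves(self, residues: str, bond: int) -> bool:
        # X blocks cleavage on either side of the bond.
        if residues[bond] == "X" or residues[bond + 1] == "X":
            return False
        if not any(s.matches(residues, bond) for s in self.specs):
            return False
        return not any(e.matches(residues, bond) for e in self.exceptions)


def _parse_residue_set(val, enzyme: str, position: str) -> frozenset[str] | None:
    if val is None:
        return None
    if isinstance(val, str):
        letters = val.replace(",", " ").split()
        letters = [l for chunk in letters for l in chunk]
    else:
        letters = [str(v) for v in val]
    try:
        return frozenset(l.upper() for l in letters)
    except Exception as exc:  # pragma: no cover
        raise RuleError(f"enzyme {enzyme!r}, position {position}: bad residue set {val!r}") from exc


def _parse_spec(d: Mapping, enzyme: str) -> CleavageSpec:
    unknown = set(d) - set(_POSITIONS)
    if unknown:
        raise RuleError(f"enzyme {enzyme!r}: unknown spec keys {sorted(unknown)}")
    try:
        return CleavageSpec(
            **{pos: _parse_residue_set(d.get(pos), enzyme, pos) for pos in _POSITIONS}
        )
    except RuleError as exc:
        raise RuleError(f"enzyme {enzyme!r}: {exc}") from exc


def compile_rules(source: str | Path | Mapping) -> dict[str, EnzymeRule]:
    """Compile an enzyme-rule table from YAML (path, text, or mapping).

    The YAML maps enzyme name -> {ec, specs: [spec...], exceptions: [...]}
    where each spec constrains a subset of p2/p1/p1prime/p2prime to a
    residue string or list. Names must be unique (YAML enforces key
    uniqueness only per document, so an explicit check guards merged
    tables).
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or not doc:
        raise RuleError("rule table must be a non-empty mapping of enzyme -> definition")
    table: dict[str, EnzymeRule] = {}
    for name, entry in doc.items():
        if name in table:
            raise RuleError(f"duplicate enzyme name {name!r}")
        if not isinstance(entry, Mapping):
            raise RuleError(f"enzyme {name!r}: definition must be a mapping")
        specs = entry.get("specs") or []
        if not specs:
            raise RuleError(f"enzyme {name!r}: empty spec list")
        table[name] = EnzymeRule(
            name=name,
            ec_number=str(entry.get("ec", "")),
            specs=tuple(_parse_spec(s, name) for s in specs),
            exceptions=tuple(_parse_spec(s, name) for s in entry.get("exceptions") or []),
        )
    return table


def default_rules() -> dict[str, EnzymeRule]:
    """The bundled enzyme table (user-editable YAML shipped with the package)."""
    from importlib.resources import files

    return compile_rules(files("collapep.data").joinpath("enzymes.yaml").read_text())


@dataclass(frozen=True)
class DigestResult:
    """Outcome of digesting one mature chain.

    ``sites`` are 0-based bond indices (d = len(sites)); ``fragments`` carry
    1-based inclusive coordinates on the mature chain; concatenating the
    fragment sequences in order reproduces the chain.
    """

    chain_id: str
    sites: tuple[int, ...]
    total_bonds: int
    fragments: tuple[tuple[str, int, int], ...]
    enzymes: tuple[str, ...]

    @property
    def d(self) -> int:
        return len(self.sites)

    @property
    def D(self) -> int:
        return self.total_bonds

    def distinct_sequences(self) -> list[str]:
        """Distinct fragment sequences, first-occurrence order."""
        return list(dict.fromkeys(seq for seq, _, _ in self.fragments))

    def distinct_peptides(self, min_length: int = 2) -> list[str]:
        """Distinct fragments of at least ``min_length`` residues.

        Free amino acids (length-1 fragments) are hydrolysis products but
        not peptides; screening excludes them by default.
        """
        return [s for s in self.distinct_sequences() if len(s) >= min_length]


def cleavage_sites(chain: ProteinChain, rule: EnzymeRule) -> list[int]:
    """All bonds of the mature chain cleaved by ``rule``, sorted ascending."""
    if chain.signal_end is not None:
        raise DigestError(
            f"chain {chain.id!r} still carries a signal-peptide annotation; trim first"
        )
    seq = chain.residues
    return [b for b in range(len(seq) - 1) if rule.cleaves(seq, b)]


def digest(chain: ProteinChain, rules: Sequence[EnzymeRule]) -> DigestResult:
    """Digest a mature chain with one or more enzymes acting simultaneously."""
    if not rules:
        raise DigestError("no enzymes given")
    sites: set[int] = set()
    for r in rules:
        sites.update(cleavage_sites(chain, r))
    ordered = tuple(sorted(sites))
    seq = chain.residues
    bounds = [0, *[s + 1 for s in ordered], len(seq)]
    fragments = tuple(
        (seq[a:b], a + 1, b) for a, b in zip(bounds[:-1], bounds[1:])
    )
    return DigestResult(
        chain_id=chain.id,
        sites=ordered,
        total_bonds=len(seq) - 1,
        fragments=fragments,
        enzymes=tuple(r.name for r in rules),
    )


def degree_of_hydrolysis(
    results: Sequence[DigestResult],
    stoichiometry: Mapping[str, int] | None = None,
) -> float:
    """Pooled theoretical degree of hydrolysis, in percent.

    Per chain DH_T = d/D x 100; the pooled value is the copy-number-weighted
    mean across chains (weights default to 1).
    """
    if not results:
        raise DigestError("no digest results")
    stoichiometry = stoichiometry or {}
    num = den = 0.0
    for r in results:
        if r.total_bonds == 0:
            raise DigestError(f"chain {r.chain_id!r}: single residue, DH undefined")
        w = stoichiometry.get(r.chain_id, 1)
        num += w * (r.d / r.total_bonds * 100.0)
        den += w
    return num / den


#: Fragment length classes used in hydrolysate summaries.
LENGTH_CLASSES = ("1", "2", "3", "4", "5", ">=6")


def length_distribution(result: DigestResult) -> dict[str, int]:
    """Distinct-fragment counts per length class {1, 2, 3, 4, 5, >=6}.

    Distinctness is by fragment sequence (positional duplicates collapse);
    only non-empty classes appear, and counts sum to the number of distinct
    fragments.
    """
    counts: dict[str, int] = {}
    for seq in result.distinct_sequences():
        cls = str(len(seq)) if len(seq) < 6 else ">=6"
        counts[cls] = counts.get(cls, 0) + 1
    return counts


def rank_enzyme_combinations(
    chains: Sequence[ProteinChain],
    rules: Mapping[str, EnzymeRule],
    score: "callable",
    sizes: Iterable[int] = (2, 3),
) -> list[tuple[tuple[str, ...], float, float]]:
    """Enumerate enzyme combinations and rank them by a release score.

    ``score`` maps a list of per-chain :class:`DigestResult` to a number
    (typically the stoichiometry-weighted ACE-inhibitor release frequency
    from :mod:`collapep.bioprofile`). Returns (names, score, DH_T) triples
    sorted by score descending, ties broken by higher DH_T then by
    lexicographic enzyme names.
    """
    stoich = {c.id: c.copy_number for c in chains}
    ranked = []
    names = sorted(rules)
    for k in sizes:
        for combo in itertools.combinations(names, k):
            rs = [rules[n] for n in combo]
            results = [digest(c, rs) for c in chains]
            a = score(results)
            dh = degree_of_hydrolysis(results, stoich)
            ranked.append((combo, a, dh))
    ranked.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return ranked


def write_digest_tsv(results: Sequence[DigestResult], path: str | Path) -> None:
    """Fragment table: chain_id, start, end, sequence, length, enzymes."""
    with open(path, "w") as fh:
        fh.write("chain_id\tstart\tend\tsequence\tlength\tenzymes\n")
        for r in results:
            enz = "+".join(r.enzymes)
            for seq, start, end in r.fragments:
                fh.write(f"{r.chain_id}\t{start}\t{end}\t{seq}\t{len(seq)}\t{enz}\n")
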