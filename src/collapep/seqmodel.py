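"""Protein-chain containers and preprocessing.

Collagen α-chains arrive as FASTA records (typically fetched from UniProt by
the user). Before any downstream analysis the N-terminal signal peptide must
be removed: bioactivity profiling and simulated proteolysis are defined on
the mature chain. Signal-peptide boundaries are supplied as annotations (a
two-column TSV matching a SignalP result export); prediction itself is out
of scope.

Coordinate conventions: user-facing coordinates are 1-based inclusive;
internal peptide-bond indices (see :mod:`collapep.digestion`) are 0-based,
bond ``i`` sitting between residues ``i`` and ``i+1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

#: The 20 standard amino acids plus 'X' for an unknown residue.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AMINO_ACIDS | {"X"}


class SequenceError(ValueError):
    """Raised for malformed or inconsistent sequence input."""


@dataclass(frozen=True)
class ProteinChain:
    """One protein chain with optional signal-peptide annotation.

    Parameters
    ----------
    id : str
        Record identifier, e.g. a UniProt accession.
    residues : str
        Uppercase residue string over the 20-letter alphabet plus ``X``.
    signal_end : int or None
        1-based position of the last signal-peptide residue, if annotated.
    copy_number : int
        Stoichiometric multiplicity of the chain in the assembled protein
        (type I collagen carries two α1 chains per α2 chain).
    """

    id: str
    residues: str
    signal_end: int | None = None
    copy_number: int = 1

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("chain id must be non-empty")
        if not self.residues:
            raise SequenceError(f"chain {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in ALPHABET:
                raise SequenceError(
                    f"chain {self.id!r}: invalid residue {aa!r} at position {pos}"
                )
        if self.signal_end is not None and not (0 < self.signal_end < len(self.residues)):
            raise SequenceError(
                f"chain {self.id!r}: signal_end {self.signal_end} outside (0, {len(self.residues)})"
            )
        if self.copy_number < 1:
            raise SequenceError(f"chain {self.id!r}: copy_number must be >= 1")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_unknown(self) -> bool:
        """Whether the chain contains any 'X' residue (flagged, not rejected)."""
        return "X" in self.residues


@dataclass(frozen=True)
class ChainSet:
    """Ordered collection of chains with unique ids."""

    chains: tuple[ProteinChain, ...]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SequenceError(f"duplicate chain ids: {sorted(dupes)}")
        if sum(len(c) * c.copy_number for c in self.chains) == 0:
            raise SequenceError("chain set has no residues")

    def __iter__(self):
        return iter(self.chains)

    def __len__(self) -> int:
        return len(self.chains)

    def __getitem__(self, chain_id: str) -> ProteinChain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(chain_id)


def load_fasta(path: str | Path) -> ChainSet:
    """Read a FASTA file into a :class:`ChainSet`.

    Record ids are the FASTA header up to the first whitespace; lowercase
    residues are uppercased; every residue must be in the amino-acid
    alphabet (plus ``X``). copy_number defaults to 1 and is adjusted by the
    caller (e.g. via a stoichiometry mapping).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    chains = tuple(
        ProteinChain(id=rec.id, residues=str(rec.seq).upper()) for rec in records
    )
    return ChainSet(chains=chains)


def write_fasta(chains: ChainSet | Iterable[ProteinChain], path: str | Path) -> None:
    """Write chains as plain FASTA (60-column wrapped)."""
    with open(path, "w") as fh:
        for c in chains:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.residues), 60):
                fh.write(c.residues[i : i + 60] + "\n")


def trim_signal(chain: ProteinChain, signal_end: int | None = None) -> ProteinChain:
    """Return the mature chain with the signal peptide removed.

    ``signal_end`` is the 1-based position of the last signal residue; the
    mature chain is residues ``signal_end+1 .. length``. If omitted, the
    chain's own annotation is used. The returned chain carries no
    ``signal_end`` annotation.
    """
    if signal_end is None:
        signal_end = chain.signal_end
    if signal_end is None:
        return chain
    if not (1 <= signal_end < len(chain)):
        raise SequenceError(
            f"chain {chain.id!r}: signal_end {signal_end} must lie in [1, {len(chain) - 1}]"
        )
    return replace(chain, residues=chain.residues[signal_end:], signal_end=None)


def load_signal_annotations(path: str | Path) -> dict[str, int]:
    """Read a signal-peptide annotation TSV (columns: chain_id, signal_end).

    The format matches a minimal SignalP cleavage-site export: one row per
    chain, tab-separated, optional header line.
    """
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SequenceError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            cid, end = parts
            if lineno == 1 and not end.isdigit():  # header
                continue
            try:
                out[cid] = int(end)
            except ValueError as exc:
                raise SequenceError(f"{path}:{lineno}: signal_end not an integer: {end!r}") from exc
    return out


def apply_annotations(
    chains: ChainSet,
    signals: dict[str, int] | None = None,
    stoichiometry: dict[str, int] | None = None,
) -> ChainSet:
    """Attach signal annotations / copy numbers, then trim to mature chains."""
    signals = signals or {}
    stoichiometry = stoichiometry or {}
    mature = []
    for c in chains:
        if c.id in stoichiometry:
            c = replace(c, copy_number=stoichiometry[c.id])
        if c.id in signals:
            c = trim_signal(c, signals[c.id])
        elif c.signal_end is not None:
            c = trim_signal(c)
        mature.append(c)
    return ChainSet(chains=tuple(mature))


def chain_summary(original: ChainSet, mature: ChainSet) -> str:
    """JSON summary of per-chain lengths before/after signal trimming."""
    rows = []
    for c in original:
        m = mature[c.id]
        rows.append(
            {
                "id": c.id,
                "length": len(c),
                "trimmed_length": len(m),
                "copy_number": m.copy_number,
            }
        )
    return json.dumps(rows, indent=2)
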