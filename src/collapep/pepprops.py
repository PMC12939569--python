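"""Physicochemical property panel for candidate peptides.

Conventions chosen for the panel:

* Molecular weight sums standard average residue masses plus one water
  (18.02 Da); monoisotopic masses are available behind a flag.
* Net charge is the side-chain charge at neutral pH counted as
  (#K + #R) - (#D + #E); histidine (pKa ~6) is treated as neutral and
  termini are ignored.
* The isoelectric point solves Henderson-Hasselbalch net charge = 0 over
  termini and the ionizable side chains (D, E, C, Y, H, K, R) by bisection
  on pH in [0, 14]; the pKa table is configurable (default: EMBOSS values).
* Hydrophobicity is reported against a named residue scale
  (Kyte-Doolittle sum and mean ship as defaults); values are only
  comparable within one scale, and the scale label travels with the value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .seqmodel import AMINO_ACIDS


class PropertyError(ValueError):
    """Raised for sequences a property cannot be computed for."""


# Standard average (and monoisotopic) residue masses, Da.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_AVERAGE = 18.02
WATER_MONOISOTOPIC = 18.01056

# EMBOSS pKa set; positive groups gain a proton below their pKa, negative
# groups lose one above. Override with any {group: pKa} mapping.
DEFAULT_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
}
_POSITIVE_GROUPS = {"Nterm", "H", "K", "R"}

#: Registered hydrophobicity scales: name -> (per-residue values, aggregate).
HYDROPHOBICITY_SCALES: dict[str, tuple[Mapping[str, float], str]] = {
    "kyte-doolittle-sum": (_KYTE_DOOLITTLE, "sum"),
    "kyte-doolittle-mean": (_KYTE_DOOLITTLE, "mean"),
}


def _check_sequence(sequence: str, allow_x: bool = False) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise PropertyError("empty sequence")
    allowed = AMINO_ACIDS | ({"X"} if allow_x else set())
    bad = set(seq) - allowed
    if bad:
        raise PropertyError(f"{sequence!r}: invalid residues {sorted(bad)}")
    return seq


def molecular_weight(sequence: str, monoisotopic: bool = False) -> float:
    """Peptide mass in Da: residue masses plus one water, 2 decimals."""
    seq = _check_sequence(sequence)
    table = MONOISOTOPIC_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    water = WATER_MONOISOTOPIC if monoisotopic else WATER_AVERAGE
    return round(sum(table[aa] for aa in seq) + water, 2)


def net_charge(sequence: str) -> int:
    """Side-chain charge at neutral pH: (#K + #R) - (#D + #E)."""
    seq = _check_sequence(sequence, allow_x=True)
    return (seq.count("K") + seq.count("R")) - (seq.count("D") + seq.count("E"))


def charge_at_ph(sequence: str, ph: float, pka: Mapping[str, float] | None = None) -> float:
    """Henderson-Hasselbalch net charge of the peptide at a given pH."""
    seq = _check_sequence(sequence)
    pka = dict(DEFAULT_PKA, **(pka or {}))
    groups: list[str] = ["Nterm", "Cterm"]
    groups += [aa for aa in seq if aa in pka]
    q = 0.0
    for g in groups:
        if g in _POSITIVE_GROUPS:
            q += 1.0 / (1.0 + 10 ** (ph - pka[g]))
        else:
            q -= 1.0 / (1.0 + 10 ** (pka[g] - ph))
    return q


def isoelectric_point(
    sequence: str,
    pka: Mapping[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the peptide's Henderson-Hasselbalch net charge is zero.

    Found by bisection on [0, 14]. With termini always ionizable the charge
    is strictly decreasing in pH, so the root is unique; if the charge does
    not change sign on [0, 14] (an extreme custom pKa table) a
    :class:`PropertyError` is raised.
    """
    lo, hi = 0.0, 14.0
    qlo, qhi = charge_at_ph(sequence, lo, pka), charge_at_ph(sequence, hi, pka)
    if qlo < 0 or qhi > 0:
        raise PropertyError(f"{sequence!r}: net charge does not cross zero on pH [0, 14]")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if charge_at_ph(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2, 4)


def hydrophobicity(sequence: str, scale: str = "kyte-doolittle-sum") -> float:
    """Aggregate hydrophobicity under a registered residue scale."""
    seq = _check_sequence(sequence)
    if scale not in HYDROPHOBICITY_SCALES:
        raise PropertyError(
            f"unknown hydrophobicity scale {scale!r}; available: {sorted(HYDROPHOBICITY_SCALES)}"
        )
    values, agg = HYDROPHOBICITY_SCALES[scale]
    total = sum(values[aa] for aa in seq)
    return total / len(seq) if agg == "mean" else total


def register_scale(name: str, values: Mapping[str, float], aggregate: str = "sum") -> None:
    """Register a custom hydrophobicity scale (aggregate: 'sum' or 'mean')."""
    if aggregate not in {"sum", "mean"}:
        raise PropertyError("aggregate must be 'sum' or 'mean'")
    missing = AMINO_ACIDS - set(values)
    if missing:
        raise PropertyError(f"scale {name!r} missing residues {sorted(missing)}")
    HYDROPHOBICITY_SCALES[name] = (dict(values), aggregate)


@dataclass(frozen=True)
class PropertyPanel:
    """Computed property row for one peptide."""

    sequence: str
    molecular_weight: float
    net_charge: int
    isoelectric_point: float
    hydrophobicity: float
    hydrophobicity_scale: str
    length: int


def property_panel(
    sequence: str,
    scale: str = "kyte-doolittle-sum",
    pka: Mapping[str, float] | None = None,
) -> PropertyPanel:
    """Full panel for one peptide."""
    seq = _check_sequence(sequence)
    return PropertyPanel(
        sequence=seq,
        molecular_weight=molecular_weight(seq),
        net_charge=net_charge(seq),
        isoelectric_point=isoelectric_point(seq, pka),
        hydrophobicity=hydrophobicity(seq, scale),
        hydrophobicity_scale=scale,
        length=len(seq),
    )


def write_panel_tsv(panels, path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tlength\tmolecular_weight\tnet_charge\tisoelectric_point\thydrophobicity\tscale\n")
        for p in panels:
            fh.write(
                f"{p.sequence}\t{p.length}\t{p.molecular_weight:.2f}\t{p.net_charge}\t"
                f"{p.isoelectric_point:.2f}\t{p.hydrophobicity:.3f}\t{p.hydrophobicity_scale}\n"
            )
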