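"""Protein length, average molecular weight and isoelectric point.

Mirrors the Compute pI/Mw approach: molecular weight is the sum of average
isotopic residue masses plus one water, and the isoelectric point is found
by solving net_charge(pH) = 0 with the Bjellqvist pKa set, in which the
N-terminal pKa depends on the first residue and the C-terminal pKa on the
last. Charges follow Henderson–Hasselbalch: a basic group contributes
+1 / (1 + 10^(pH - pKa)) and an acidic group -1 / (1 + 10^(pKa - pH)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .sequence_io import SequenceRecord

#: Average isotopic residue masses (free amino acid minus water), Da.
RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


@dataclass(frozen=True)
class PkaTable:
    """Bjellqvist pKa set (the table behind the ExPASy pI computation)."""

    positive: dict = field(
        default_factory=lambda: {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
    )
    negative: dict = field(
        default_factory=lambda: {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
    )
    # terminal pKa overrides depending on the terminal residue itself
    nterm_by_residue: dict = field(
        default_factory=lambda: {
            "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
        }
    )
    cterm_by_residue: dict = field(default_factory=lambda: {"D": 4.55, "E": 4.75})


DEFAULT_PKA = PkaTable()


@dataclass(frozen=True)
class PhyschemProfile:
    protein_id: str
    length: int
    mw: float  # daltons
    pi: float  # pH units

    def __post_init__(self) -> None:
        if self.mw <= 0 or not 0 < self.pi < 14 or self.length <= 0:
            raise ValueError(f"implausible physicochemical profile: {self}")


def molecular_weight(protein: SequenceRecord, x_mass: Optional[float] = None) -> float:
    """Average molecular weight in Da: residue masses plus one water.

    'X' residues are rejected unless ``x_mass`` supplies an average mass.
    """
    if protein.kind != "protein":
        raise ValueError("molecular_weight expects a protein record")
    total = WATER_MASS
    for aa in protein.seq:
        if aa == "X":
            if x_mass is None:
                raise ValueError(
                    f"{protein.id}: unknown residue 'X' without a fallback mass"
                )
            total += x_mass
        else:
            total += RESIDUE_MASSES[aa]
    return total


def net_charge(
    protein: SequenceRecord, ph: float, pka: PkaTable = DEFAULT_PKA
) -> float:
    """Signed net charge at ``ph`` over termini and D,E,C,Y,H,K,R side chains."""
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {ph}")
    seq = protein.seq
    charge = 0.0
    nterm_pka = pka.nterm_by_residue.get(seq[0], pka.positive["Nterm"])
    charge += 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    cterm_pka = pka.cterm_by_residue.get(seq[-1], pka.negative["Cterm"])
    charge -= 1.0 / (1.0 + 10 ** (cterm_pka - ph))
    for aa in "KRH":
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka.positive[aa]))
    for aa in "DECY":
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka.negative[aa] - ph))
    return charge


def isoelectric_point(
    protein: SequenceRecord,
    pka: PkaTable = DEFAULT_PKA,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    net_charge is strictly decreasing in pH, positive at pH 0 (all basic
    groups protonated) and negative at pH 14 whenever an acidic group or
    the C-terminus is present, so the root is bracketed and unique.
    """
    if not protein.seq:
        raise ValueError("pI undefined for an empty sequence")
    lo, hi = 0.0, 14.0
    c_lo, c_hi = net_charge(protein, lo, pka), net_charge(protein, hi, pka)
    if c_lo <= 0 or c_hi >= 0:
        raise ValueError(f"{protein.id}: pI undefined (no charge sign change)")
    mid = 7.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        c = net_charge(protein, mid, pka)
        if abs(c) < tol:
            break
        if c > 0:
            lo = mid
        else:
            hi = mid
    return mid


def physchem_profile(
    protein: SequenceRecord,
    x_mass: Optional[float] = None,
    pka: PkaTable = DEFAULT_PKA,
) -> PhyschemProfile:
    return PhyschemProfile(
        protein_id=protein.id,
        length=len(protein.seq),
        mw=molecular_weight(protein, x_mass),
        pi=isoelectric_point(protein, pka),
    )


def write_physchem_table(
    profiles: Iterable[PhyschemProfile], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tlength\tmw_Da\tpI\n")
        for p in profiles:
            fh.write(f"{p.protein_id}\t{p.length}\t{p.mw:.2f}\t{p.pi:.2f}\n")
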