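"""Tandem CCCH (TZF) architecture detection and per-protein classification.

Two tandem forms are recognised:

* plant RR-TZF — an arginine-rich (RR) region immediately upstream of a
  C-X7-8-C-X5-C-X3-H finger, a 16-residue linker, and a C-X5-C-X4-C-X3-H
  finger (the pattern C-X7-C-X5-C-X3-H-X16-C-X5-C-X4-C-X3-H);
* animal-type TZF — two identical C-X8-C-X5-C-X3-H fingers separated by
  18 or 19 residues.

Proteins with neither arrangement are non-TZF. The linker is counted as the
residues strictly between the histidine of the first finger and the first
cysteine of the second (motif_b.start - motif_a.end in half-open
coordinates).

The RR region is nowhere quantified in the literature this grammar comes
from; the thresholds here (30-residue upstream window, >= 3 arginines,
arginine fraction >= 0.2) are this module's own calibration and are exposed
as parameters and reported with every call.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

from .motif_scanner import CcchMotif, DEFAULT_BOUNDS, SpacingBounds, scan_ccch
from .sequence_io import SequenceRecord


class ArchClass(str, Enum):
    RR_TZF = "RR_TZF"
    TZF = "TZF"
    NON_TZF = "NON_TZF"


class TandemPair(NamedTuple):
    motif_a: CcchMotif
    motif_b: CcchMotif

    @property
    def linker_len(self) -> int:
        return self.motif_b.start - self.motif_a.end


class RrRegion(NamedTuple):
    start: int
    end: int
    arg_fraction: float


@dataclass
class RrParams:
    """Arginine-rich-region thresholds (window upstream of the first finger)."""

    window: int = 30
    min_fraction: float = 0.2
    min_arg: int = 3


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    call: ArchClass
    tandem_pair: Optional[TandemPair] = None
    rr_region: Optional[RrRegion] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.call == ArchClass.RR_TZF:
            # rr_region may be absent only under the relaxed (require_rr=False)
            # reading; the default classifier always supplies it
            if self.tandem_pair is None:
                raise ValueError("RR_TZF call requires a tandem pair")
            if self.tandem_pair.linker_len != 16:
                raise ValueError("RR_TZF linker must be 16 residues")
        if self.call == ArchClass.TZF:
            if self.tandem_pair is None:
                raise ValueError("TZF call requires a tandem pair")
            if self.tandem_pair.linker_len not in (18, 19):
                raise ValueError("TZF linker must be 18 or 19 residues")


def _check_same_protein(protein: SequenceRecord, motifs: Iterable[CcchMotif]) -> None:
    for m in motifs:
        if m.protein_id != protein.id:
            raise ValueError(
                f"motif from protein {m.protein_id!r} passed with {protein.id!r}"
            )


def detect_plant_rr_tzf(
    protein: SequenceRecord, motifs: list[CcchMotif]
) -> Optional[TandemPair]:
    """First coordinate-ordered pair matching the plant RR-TZF finger grammar.

    motif_a must be C-X7-8-C-X5-C-X3-H, motif_b C-X5-C-X4-C-X3-H, with a
    16-residue linker. Only adjacent motifs can satisfy the linker bound.
    """
    _check_same_protein(protein, motifs)
    for a, b in zip(motifs, motifs[1:]):
        if (
            a.d1 in (7, 8)
            and (a.d2, a.d3) == (5, 3)
            and (b.d1, b.d2, b.d3) == (5, 4, 3)
            and b.start - a.end == 16
        ):
            return TandemPair(a, b)
    return None


def detect_animal_tzf(
    protein: SequenceRecord, motifs: list[CcchMotif]
) -> Optional[TandemPair]:
    """First pair of identical C-X8-C-X5-C-X3-H fingers 18-19 residues apart."""
    _check_same_protein(protein, motifs)
    for a, b in zip(motifs, motifs[1:]):
        if (
            (a.d1, a.d2, a.d3) == (8, 5, 3)
            and (b.d1, b.d2, b.d3) == (8, 5, 3)
            and b.start - a.end in (18, 19)
        ):
            return TandemPair(a, b)
    return None


def arginine_rich_region(
    protein: SequenceRecord,
    anchor: int,
    params: RrParams | None = None,
) -> Optional[RrRegion]:
    """Arginine-rich region in the window immediately upstream of ``anchor``.

    The window is truncated at the sequence start. Reported iff the arginine
    count and fraction both clear their thresholds.
    """
    params = params or RrParams()
    if not 0 <= anchor <= len(protein.seq):
        raise ValueError(f"anchor {anchor} outside sequence {protein.id}")
    start = max(0, anchor - params.window)
    window = protein.seq[start:anchor]
    if not window:
        return None
    n_arg = window.count("R")
    fraction = n_arg / len(window)
    if n_arg >= params.min_arg and fraction >= params.min_fraction:
        return RrRegion(start, anchor, fraction)
    return None


def classify_architecture(
    protein: SequenceRecord,
    motifs: list[CcchMotif] | None = None,
    bounds: SpacingBounds = DEFAULT_BOUNDS,
    greedy: bool = True,
    rr_params: RrParams | None = None,
    require_rr: bool = True,
) -> ArchitectureCall:
    """Classify a protein as plant RR-TZF, animal-type TZF, or non-TZF.

    Rule order: a plant finger pair with an upstream RR region is RR_TZF;
    otherwise an animal-type pair is TZF; otherwise NON_TZF. A plant pair
    lacking its RR region does not qualify as animal-type (the spacings
    differ), so it falls through to NON_TZF with an explanatory note.
    ``require_rr=False`` accepts a plant pair without the RR evidence.
    """
    if motifs is None:
        motifs = scan_ccch(protein, bounds, greedy)
    plant = detect_plant_rr_tzf(protein, motifs)
    if plant is not None:
        rr = arginine_rich_region(protein, plant.motif_a.start, rr_params)
        if rr is not None or not require_rr:
            return ArchitectureCall(protein.id, ArchClass.RR_TZF, plant, rr)
    animal = detect_animal_tzf(protein, motifs)
    if animal is not None:
        return ArchitectureCall(protein.id, ArchClass.TZF, animal)
    note = "tandem without RR region" if plant is not None else ""
    return ArchitectureCall(protein.id, ArchClass.NON_TZF, note=note)


def write_architecture_table(
    calls: Iterable[ArchitectureCall], path: str | Path
) -> None:
    """Architecture calls as TSV; coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tcall\tmotif_a_start\tmotif_a_end\t"
            "motif_b_start\tmotif_b_end\tlinker_len\t"
            "rr_start\trr_end\targ_fraction\tnote\n"
        )
        for c in calls:
            if c.tandem_pair is not None:
                a, b = c.tandem_pair.motif_a, c.tandem_pair.motif_b
                pair = f"{a.start + 1}\t{a.end}\t{b.start + 1}\t{b.end}\t{c.tandem_pair.linker_len}"
            else:
                pair = ".\t.\t.\t.\t."
            if c.rr_region is not None:
                rr = f"{c.rr_region.start + 1}\t{c.rr_region.end}\t{c.rr_region.arg_fraction:.3f}"
            else:
                rr = ".\t.\t."
            fh.write(f"{c.protein_id}\t{c.call.value}\t{pair}\t{rr}\t{c.note}\n")
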