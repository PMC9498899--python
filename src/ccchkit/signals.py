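"""Leucine-rich nuclear export signal (NES) scanning.

Uses the widely adopted NES consensus [LV]-x(2,3)-[LIVFM]-x(2,3)-L-x-[LIMTKD]
(NESbase). A protein carrying at least one consensus match is scored
NES-positive; such proteins are candidate nucleocytoplasmic shuttlers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .sequence_io import SequenceRecord

NES_CONSENSUS = "[LV]-x(2,3)-[LIVFM]-x(2,3)-L-x-[LIMTKD]"
NES_REGEX = re.compile(r"[LV].{2,3}[LIVFM].{2,3}L.[LIMTKD]")

_CLASS_1 = set("LV")
_CLASS_2 = set("LIVFM")
_CLASS_3 = set("LIMTKD")


@dataclass(frozen=True)
class SignalHit:
    """One NES consensus match, 0-based half-open coordinates."""

    protein_id: str
    start: int
    end: int
    matched_seq: str
    signal_kind: str = "NES"

    def validate(self, seq: str) -> None:
        if seq[self.start : self.end] != self.matched_seq:
            raise ValueError(f"{self}: matched_seq does not slice the sequence")
        if not 9 <= self.end - self.start <= 11:
            raise ValueError(f"{self}: span outside consensus bounds")
        s = self.matched_seq
        # anchors: first residue, the mandatory L two before the end, last residue
        if s[0] not in _CLASS_1 or s[-3] != "L" or s[-1] not in _CLASS_3:
            raise ValueError(f"{self}: fixed-offset anchors violate the consensus")


def scan_nes(protein: SequenceRecord, overlapping: bool = False) -> list[SignalHit]:
    """NES consensus matches of a protein, in coordinate order.

    Default is left-to-right non-overlapping greedy matching (as with CCCH
    motifs). ``overlapping`` reports a hit at every matching start position,
    for sensitivity analyses; protein-level presence/absence is unaffected.
    """
    if protein.kind != "protein":
        raise ValueError(f"scan_nes expects a protein record, got {protein.kind}")
    hits = []
    if overlapping:
        for start in range(len(protein.seq)):
            m = NES_REGEX.match(protein.seq, start)
            if m and m.start() == start:
                hits.append(
                    SignalHit(protein.id, m.start(), m.end(), m.group())
                )
    else:
        for m in NES_REGEX.finditer(protein.seq):
            hits.append(SignalHit(protein.id, m.start(), m.end(), m.group()))
    for hit in hits:
        hit.validate(protein.seq)
    return hits


@dataclass
class NesCensus:
    positive_count: int = 0
    hits: dict[str, list[SignalHit]] = field(default_factory=dict)

    @property
    def total_hits(self) -> int:
        return sum(len(h) for h in self.hits.values())

    def positive_fraction(self) -> float:
        return self.positive_count / len(self.hits) if self.hits else 0.0


def nes_census(proteins: Iterable[SequenceRecord]) -> NesCensus:
    """Per-protein NES hit lists and the NES-positive protein count."""
    proteins = list(proteins)
    if not proteins:
        raise ValueError("nes_census requires at least one protein")
    census = NesCensus()
    for protein in proteins:
        hits = scan_nes(protein)
        census.hits[protein.id] = hits
        if hits:
            census.positive_count += 1
    return census


def write_nes_table(census: NesCensus, path: str | Path) -> None:
    """Hits as TSV; coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tmatched_seq\n")
        for pid in census.hits:
            for h in census.hits[pid]:
                fh.write(f"{pid}\t{h.start + 1}\t{h.end}\t{h.matched_seq}\n")
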