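"""CCCH zinc-finger motif detection, subtype classification and family census.

A CCCH zinc finger is written C-Xa-C-Xb-C-Xc-H, where a, b, c count the
residues strictly between the three zinc-coordinating cysteines and the
final histidine. The broad family consensus is C-X4-15-C-X4-6-C-X3-H; the
scanner's default bounds widen this to d2 <= 7 and d3 <= 4 so that rare
variants such as C-X11-C-X7-C-X4-H are countable in the same pass.

Matching is left-to-right and non-overlapping, as a text-editor regex
search behaves: the match starting at the leftmost eligible cysteine is
taken, greedily preferring the lexicographically largest feasible
(d1, d2, d3) at that start, and scanning resumes after the matched
histidine. A lazy mode (smallest spacings) is provided because greediness
can shift counts when cysteines are dense.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable

from .sequence_io import SequenceRecord

AGGREGATE_LABEL = "C-X7-8-C-X5-C-X3-H"


@dataclass(frozen=True)
class SpacingBounds:
    """Inclusive (lo, hi) bounds on the three inter-residue spacings."""

    d1: tuple[int, int] = (4, 15)
    d2: tuple[int, int] = (4, 7)
    d3: tuple[int, int] = (3, 4)

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "d3"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid {name} bounds ({lo}, {hi})")

    def contains(self, d1: int, d2: int, d3: int) -> bool:
        return (
            self.d1[0] <= d1 <= self.d1[1]
            and self.d2[0] <= d2 <= self.d2[1]
            and self.d3[0] <= d3 <= self.d3[1]
        )


DEFAULT_BOUNDS = SpacingBounds()

#: The narrow pattern the family consensus describes (C-X4-15-C-X4-6-C-X3-H).
CONSENSUS_BOUNDS = SpacingBounds(d1=(4, 15), d2=(4, 6), d3=(3, 3))


@dataclass(frozen=True)
class CcchMotif:
    """One detected CCCH motif, 0-based half-open coordinates."""

    protein_id: str
    start: int
    end: int
    c1: int
    c2: int
    c3: int
    h: int

    @property
    def d1(self) -> int:
        return self.c2 - self.c1 - 1

    @property
    def d2(self) -> int:
        return self.c3 - self.c2 - 1

    @property
    def d3(self) -> int:
        return self.h - self.c3 - 1

    @property
    def spacings(self) -> tuple[int, int, int]:
        return (self.d1, self.d2, self.d3)

    def validate(self, seq: str, bounds: SpacingBounds = DEFAULT_BOUNDS) -> None:
        """Re-check anchor residues, spacing bounds and span arithmetic."""
        if not (seq[self.c1] == seq[self.c2] == seq[self.c3] == "C"):
            raise ValueError(f"{self}: anchor cysteines do not match sequence")
        if seq[self.h] != "H":
            raise ValueError(f"{self}: anchor histidine does not match sequence")
        if not bounds.contains(*self.spacings):
            raise ValueError(f"{self}: spacings {self.spacings} outside {bounds}")
        if self.end - self.start != self.d1 + self.d2 + self.d3 + 4:
            raise ValueError(f"{self}: span inconsistent with spacings")
        if self.start != self.c1 or self.end != self.h + 1:
            raise ValueError(f"{self}: start/end do not bracket the anchors")


@lru_cache(maxsize=32)
def _pattern(bounds: SpacingBounds, greedy: bool) -> re.Pattern[str]:
    q = "" if greedy else "?"
    return re.compile(
        f"C(.{{{bounds.d1[0]},{bounds.d1[1]}}}{q})"
        f"C(.{{{bounds.d2[0]},{bounds.d2[1]}}}{q})"
        f"C(.{{{bounds.d3[0]},{bounds.d3[1]}}}{q})H"
    )


def scan_ccch(
    protein: SequenceRecord,
    bounds: SpacingBounds = DEFAULT_BOUNDS,
    greedy: bool = True,
) -> list[CcchMotif]:
    """All non-overlapping CCCH motifs of a protein, in coordinate order."""
    if protein.kind != "protein":
        raise ValueError(f"scan_ccch expects a protein record, got {protein.kind}")
    motifs = []
    for m in _pattern(bounds, greedy).finditer(protein.seq):
        motif = CcchMotif(
            protein_id=protein.id,
            start=m.start(),
            end=m.end(),
            c1=m.start(),
            c2=m.end(1),
            c3=m.end(2),
            h=m.end(3),
        )
        motif.validate(protein.seq, bounds)
        motifs.append(motif)
    return motifs


def classify_motif(m: CcchMotif) -> str:
    """Canonical subtype label, e.g. (7,5,3) -> 'C-X7-C-X5-C-X3-H'."""
    return f"C-X{m.d1}-C-X{m.d2}-C-X{m.d3}-H"


def is_aggregate(m: CcchMotif) -> bool:
    """Membership in the most common plant subtype class C-X7-8-C-X5-C-X3-H."""
    return m.d1 in (7, 8) and m.d2 == 5 and m.d3 == 3


@dataclass
class MotifCensus:
    """Family-wide motif tabulation."""

    subtype_counts: Counter = field(default_factory=Counter)
    per_protein: dict[str, int] = field(default_factory=dict)
    total: int = 0
    aggregate_count: int = 0

    def proteins_with_at_least(self, k: int) -> int:
        return sum(1 for n in self.per_protein.values() if n >= k)

    @property
    def max_copy_number(self) -> int:
        return max(self.per_protein.values(), default=0)

    def validate(self) -> None:
        if sum(self.subtype_counts.values()) != self.total:
            raise ValueError("subtype counts do not sum to total")
        if sum(self.per_protein.values()) != self.total:
            raise ValueError("per-protein copy numbers do not sum to total")

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "aggregate_label": AGGREGATE_LABEL,
            "aggregate_count": self.aggregate_count,
            "subtype_counts": dict(sorted(self.subtype_counts.items())),
            "per_protein": dict(sorted(self.per_protein.items())),
            "max_copy_number": self.max_copy_number,
            "proteins_with_ge2": self.proteins_with_at_least(2),
        }


def motif_census(
    proteins: Iterable[SequenceRecord],
    bounds: SpacingBounds = DEFAULT_BOUNDS,
    greedy: bool = True,
) -> MotifCensus:
    """Aggregate :func:`scan_ccch` over a protein collection."""
    proteins = list(proteins)
    if not proteins:
        raise ValueError("motif_census requires at least one protein")
    census = MotifCensus()
    for protein in proteins:
        motifs = scan_ccch(protein, bounds, greedy)
        census.per_protein[protein.id] = len(motifs)
        census.total += len(motifs)
        for m in motifs:
            census.subtype_counts[classify_motif(m)] += 1
            if is_aggregate(m):
                census.aggregate_count += 1
    census.validate()
    return census


def write_motif_table(
    proteins: Iterable[SequenceRecord],
    path: str | Path,
    bounds: SpacingBounds = DEFAULT_BOUNDS,
    greedy: bool = True,
) -> None:
    """Motif table as TSV; coordinates are 1-based inclusive for readers."""
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tstart\tend\td1\td2\td3\tsubtype\tmatched_seq\n"
        )
        for protein in proteins:
            for m in scan_ccch(protein, bounds, greedy):
                fh.write(
                    f"{m.protein_id}\t{m.start + 1}\t{m.end}\t"
                    f"{m.d1}\t{m.d2}\t{m.d3}\t{classify_motif(m)}\t"
                    f"{protein.seq[m.start:m.end]}\n"
                )


def write_census_json(census: MotifCensus, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(census.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
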