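"""Synthetic protein families with planted motifs and machine-readable truth.

Every pipeline stage is testable without downloads: proteins are random
background sequences into which CCCH motifs, tandem cassettes (plant RR-TZF
and animal-type TZF), arginine-rich regions and NES elements are planted at
non-overlapping positions, with a truth record for every planted element.

The default background alphabet is the 20 canonical residues minus
{C, H, L, V, I, F, M}. Excluding C and H makes spurious CCCH matches
impossible; additionally excluding L (the NES consensus' mandatory anchor),
V (its alternative first-position residue) and I, F, M (the remaining
members of its internal class) makes spurious or shifted NES matches
impossible as well, so planted-element recovery is exact rather than
statistical. A full-alphabet "realistic" background can be requested for
false-positive-rate studies, in which case truth comparison must switch to
superset semantics (all planted elements found; extras counted, not failed).

Planted elements are separated by at least ``min_gap`` background residues
(default 31, one residue more than the widest possible motif span) so that
no scanner match can bridge two elements and the greedy parse of each
element is unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

import numpy as np

from .sequence_io import SequenceRecord

DEFAULT_BACKGROUND = "ADEGKNPQRSTWY"
FULL_BACKGROUND = "ACDEFGHIKLMNPQRSTVWY"

#: widest motif the default spacing bounds admit is 15+7+4+4 = 30 residues
MIN_GAP = 31


class PlacementError(ValueError):
    """Planted elements cannot fit; use longer proteins or fewer elements."""


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted element, 0-based half-open coordinates."""

    protein_id: str
    kind: str
    start: int
    end: int
    params: dict
    seq: str  # the planted residue string, for exact-slice verification


@dataclass
class ElementSpec:
    """One element kind to plant, a fixed number of times or with a probability."""

    kind: str
    params: dict = field(default_factory=dict)
    count: Optional[int] = None
    probability: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.count is None) == (self.probability is None):
            raise ValueError("exactly one of count / probability must be set")


def _default_elements() -> list[ElementSpec]:
    return [
        ElementSpec("ccch_motif", {"d1": 7, "d2": 5, "d3": 3}, probability=0.7),
        ElementSpec("rr_tzf_cassette", {}, probability=0.15),
        ElementSpec("tzf_cassette", {}, probability=0.1),
        ElementSpec("nes", {}, probability=0.4),
    ]


@dataclass
class PlantSpec:
    """Recipe for a synthetic dataset; the seed fully determines the output."""

    n_proteins: int = 200
    length_range: tuple[int, int] = (300, 800)
    background_alphabet: str = DEFAULT_BACKGROUND
    elements: list[ElementSpec] = field(default_factory=_default_elements)
    seed: int = 0
    min_gap: int = MIN_GAP
    id_prefix: str = "SYN"

    def __post_init__(self) -> None:
        if not self.background_alphabet:
            raise ValueError("background alphabet must be non-empty")
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid length range {self.length_range}")


def _bg(rng: np.random.Generator, alphabet: str, n: int) -> str:
    if n == 0:
        return ""
    letters = np.frombuffer(alphabet.encode(), dtype="S1")
    return b"".join(rng.choice(letters, size=n)).decode()


# ---------------------------------------------------------------------------
# element builders: (rng, alphabet, **params) -> (sequence, relative truths)
# relative truths are (kind, start, end, params) tuples local to the element.

def build_ccch_motif(
    rng: np.random.Generator, alphabet: str, d1: int = 7, d2: int = 5, d3: int = 3
) -> tuple[str, list]:
    if min(d1, d2, d3) < 0:
        raise ValueError(f"invalid spacings ({d1}, {d2}, {d3})")
    seq = "C" + _bg(rng, alphabet, d1) + "C" + _bg(rng, alphabet, d2) + "C" + _bg(rng, alphabet, d3) + "H"
    return seq, [("ccch_motif", 0, len(seq), {"d1": d1, "d2": d2, "d3": d3})]


def build_nes(
    rng: np.random.Generator,
    alphabet: str,
    s1: Optional[int] = None,
    s2: Optional[int] = None,
) -> tuple[str, list]:
    s1 = int(rng.integers(2, 4)) if s1 is None else s1
    s2 = int(rng.integers(2, 4)) if s2 is None else s2
    if s1 not in (2, 3) or s2 not in (2, 3):
        raise ValueError("NES spacers must be 2 or 3 residues")
    p1 = "LV"[rng.integers(2)]
    p2 = "LIVFM"[rng.integers(5)]
    p3 = "LIMTKD"[rng.integers(6)]
    seq = p1 + _bg(rng, alphabet, s1) + p2 + _bg(rng, alphabet, s2) + "L" + _bg(rng, alphabet, 1) + p3
    return seq, [("nes", 0, len(seq), {"s1": s1, "s2": s2})]


def build_rr_region(
    rng: np.random.Generator,
    alphabet: str,
    length: int = 30,
    arg_fraction: float = 0.3,
) -> tuple[str, list]:
    n_arg = max(1, round(arg_fraction * length))
    if n_arg > length:
        raise ValueError("arginine fraction above 1")
    chars = list(_bg(rng, alphabet, length))
    for pos in rng.choice(length, size=n_arg, replace=False):
        chars[pos] = "R"
    seq = "".join(chars)
    actual = seq.count("R") / length  # background may add arginines
    return seq, [("rr_region", 0, length, {"length": length, "arg_fraction": actual})]


def plant_rr_tzf_cassette(
    rng: np.random.Generator,
    alphabet: str = DEFAULT_BACKGROUND,
    d1_a: int = 7,
    linker: int = 16,
    rr_length: int = 30,
    rr_arg_fraction: float = 0.3,
) -> tuple[str, list]:
    """Plant RR-TZF cassette: RR region + C-X{7|8}-C-X5-C-X3-H + linker + C-X5-C-X4-C-X3-H.

    The default 16-residue linker is the defining plant-TZF spacing; linker
    overrides exist so detection can be exercised against near-miss spacings.
    """
    if d1_a not in (7, 8):
        raise ValueError("first finger of an RR-TZF cassette has d1 of 7 or 8")
    rr, rr_truth = build_rr_region(rng, alphabet, rr_length, rr_arg_fraction)
    a, a_truth = build_ccch_motif(rng, alphabet, d1_a, 5, 3)
    b, b_truth = build_ccch_motif(rng, alphabet, 5, 4, 3)
    seq = rr + a + _bg(rng, alphabet, linker) + b
    off_a = len(rr)
    off_b = len(rr) + len(a) + linker
    truths = [
        ("rr_tzf_cassette", 0, len(seq), {"d1_a": d1_a, "linker": linker}),
        _shift(rr_truth[0], 0),
        _shift(a_truth[0], off_a),
        _shift(b_truth[0], off_b),
    ]
    return seq, truths


def build_tzf_cassette(
    rng: np.random.Generator, alphabet: str = DEFAULT_BACKGROUND, linker: int = 18
) -> tuple[str, list]:
    """Animal-type TZF cassette: two C-X8-C-X5-C-X3-H fingers, linker 18 or 19."""
    a, a_truth = build_ccch_motif(rng, alphabet, 8, 5, 3)
    b, b_truth = build_ccch_motif(rng, alphabet, 8, 5, 3)
    seq = a + _bg(rng, alphabet, linker) + b
    truths = [
        ("tzf_cassette", 0, len(seq), {"linker": linker}),
        _shift(a_truth[0], 0),
        _shift(b_truth[0], len(a) + linker),
    ]
    return seq, truths


def _shift(rel_truth: tuple, offset: int) -> tuple:
    kind, start, end, params = rel_truth
    return (kind, start + offset, end + offset, params)


BUILDERS: dict[str, Callable] = {
    "ccch_motif": build_ccch_motif,
    "nes": build_nes,
    "rr_region": build_rr_region,
    "rr_tzf_cassette": plant_rr_tzf_cassette,
    "tzf_cassette": build_tzf_cassette,
}

#: conservative per-element length upper bounds, for sizing before building
_MAX_ELEMENT_LEN = {
    "ccch_motif": lambda p: p.get("d1", 7) + p.get("d2", 5) + p.get("d3", 3) + 4,
    "nes": lambda p: 11,
    "rr_region": lambda p: p.get("length", 30),
    "rr_tzf_cassette": lambda p: p.get("rr_length", 30)
    + (p.get("d1_a", 7) + 12)
    + p.get("linker", 16)
    + 16,
    "tzf_cassette": lambda p: 20 + p.get("linker", 18) + 20,
}


def max_element_length(kind: str, params: dict) -> int:
    return _MAX_ELEMENT_LEN[kind](params)


def generate_protein(
    rng: np.random.Generator,
    protein_id: str,
    length: int,
    elements: list[tuple[str, dict]],
    alphabet: str = DEFAULT_BACKGROUND,
    min_gap: int = MIN_GAP,
) -> tuple[SequenceRecord, list[PlantedTruth]]:
    """One background protein with the given elements planted non-overlapping.

    Elements are placed in random order at positions drawn by distributing
    the free residues uniformly (multinomially) into the gaps before,
    between and after the elements, keeping at least ``min_gap`` background
    residues between consecutive elements.
    """
    built = [BUILDERS[kind](rng, alphabet, **params) for kind, params in elements]
    k = len(built)
    total = sum(len(seq) for seq, _ in built)
    need = total + min_gap * max(0, k - 1)
    if length < need:
        raise PlacementError(
            f"{protein_id}: {k} elements need >= {need} residues, "
            f"protein length is {length}; use longer proteins"
        )
    chars = list(_bg(rng, alphabet, length))
    truths: list[PlantedTruth] = []
    if k:
        order = rng.permutation(k)
        gaps = rng.multinomial(length - need, [1.0 / (k + 1)] * (k + 1))
        cursor = int(gaps[0])
        for slot, idx in enumerate(order):
            seq, rel_truths = built[idx]
            chars[cursor : cursor + len(seq)] = seq
            for kind, rstart, rend, params in rel_truths:
                truths.append(
                    PlantedTruth(
                        protein_id, kind, cursor + rstart, cursor + rend,
                        params, seq[rstart:rend],
                    )
                )
            cursor += len(seq)
            if slot < k - 1:
                cursor += min_gap + int(gaps[slot + 1])
    truths.sort(key=lambda t: (t.start, t.end, t.kind))
    return SequenceRecord(protein_id, "".join(chars)), truths


def generate_dataset(spec: PlantSpec) -> tuple[list[SequenceRecord], list[PlantedTruth]]:
    """A dataset of proteins per ``spec`` plus the complete truth table."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[SequenceRecord] = []
    truths: list[PlantedTruth] = []
    for i in range(spec.n_proteins):
        elements: list[tuple[str, dict]] = []
        for es in spec.elements:
            n = es.count if es.count is not None else int(rng.random() < es.probability)
            elements.extend((es.kind, dict(es.params)) for _ in range(n))
        length = int(rng.integers(lo, hi + 1))
        rec, t = generate_protein(
            rng, f"{spec.id_prefix}{i + 1:03d}", length, elements,
            spec.background_alphabet, spec.min_gap,
        )
        records.append(rec)
        truths.extend(t)
    return records, truths


# ---------------------------------------------------------------------------
# study-profile family: a 46-protein set whose planted composition encodes the
# published census of the pine CCCH family (119 motifs of which 100 in the
# C-X7-8-C-X5-C-X3-H class, copy numbers up to 7 in two proteins, 6 plant
# RR-TZF and 3 animal-type TZF members, 22 NES-positive proteins, lengths
# 126-956 aa). See docs/methods.md for the full composition table.

def _study_plans() -> list[list[tuple[str, dict]]]:
    toggle = [0]

    def agg() -> tuple[str, dict]:
        d1 = 7 if toggle[0] % 2 == 0 else 8
        toggle[0] += 1
        return ("ccch_motif", {"d1": d1, "d2": 5, "d3": 3})

    def motif(d1: int, d2: int, d3: int) -> tuple[str, dict]:
        return ("ccch_motif", {"d1": d1, "d2": d2, "d3": d3})

    plans: list[list[tuple[str, dict]]] = []
    for _ in range(2):  # the two 7-copy proteins
        plans.append([agg() for _ in range(7)])
    plans.append([agg() for _ in range(6)])
    for _ in range(3):
        plans.append([agg() for _ in range(5)])
    plans.append([motif(7, 4, 3), motif(7, 4, 3), agg(), agg()])
    for _ in range(4):
        plans.append([agg() for _ in range(4)])
    for _ in range(2):  # RR-TZF members carrying one extra finger
        plans.append([("rr_tzf_cassette", {}), agg()])
    plans.append([motif(7, 6, 3), motif(7, 6, 3), agg()])
    for _ in range(4):
        plans.append([agg() for _ in range(3)])
    for _ in range(4):  # cassette-only RR-TZF members
        plans.append([("rr_tzf_cassette", {})])
    for linker in (18, 19, 18):  # animal-type TZF members
        plans.append([("tzf_cassette", {"linker": linker})])
    plans.append([motif(7, 6, 3), agg()])
    for _ in range(4):
        plans.append([motif(7, 4, 3), agg()])
    for _ in range(2):
        plans.append([motif(5, 4, 3), agg()])
    plans.append([motif(11, 7, 4), agg()])
    plans.append([motif(9, 5, 3)])  # single-copy protein with only this variant
    for _ in range(12):
        plans.append([agg()])
    assert len(plans) == 46
    return plans


def study_family(seed: int = 0) -> tuple[list[SequenceRecord], list[PlantedTruth]]:
    """The default 46-protein study-profile family (see module docstring)."""
    rng = np.random.default_rng(seed)
    plans = _study_plans()
    nes_members = set(rng.choice(len(plans), size=22, replace=False).tolist())
    for i in sorted(nes_members):
        plans[i].append(("nes", {}))

    needs = [
        sum(max_element_length(kind, params) for kind, params in plan)
        + MIN_GAP * (len(plan) - 1)
        for plan in plans
    ]
    lengths = [max(needs[i], int(rng.integers(126, 957))) for i in range(len(plans))]
    # pin the family's length extremes: one minimal single-finger protein
    # and one maximal seven-finger protein
    singles = [
        i for i, plan in enumerate(plans)
        if len(plan) == 1 and plan[0][0] == "ccch_motif"
    ]
    shortest = singles[0] if singles else min(range(len(plans)), key=needs.__getitem__)
    lengths[shortest] = max(126, needs[shortest])
    lengths[0] = 956

    records: list[SequenceRecord] = []
    truths: list[PlantedTruth] = []
    for i, plan in enumerate(plans):
        rec, t = generate_protein(rng, f"ZF{i + 1:02d}", lengths[i], plan)
        records.append(rec)
        truths.extend(t)
    return records, truths


def write_truth_table(truths: Iterable[PlantedTruth], path: str | Path) -> None:
    """Truth as BED-like TSV (1-based inclusive coordinates, params as JSON)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tkind\tparams\n")
        for t in truths:
            params = dict(t.params, seq=t.seq)
            fh.write(
                f"{t.protein_id}\t{t.start + 1}\t{t.end}\t{t.kind}\t"
                f"{json.dumps(params, sort_keys=True)}\n"
            )
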