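"""FASTA I/O, CDS translation, pairwise identity and similarity-based deduplication.

Family-identification pipelines routinely collapse transcript isoforms by
removing sequences that are nearly identical to a longer family member; the
filter here removes any sequence whose global-alignment identity to an
already-retained sequence exceeds a threshold (default 97%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
CDS_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence, either a protein or a coding sequence (CDS)."""

    id: str
    seq: str
    kind: str = "protein"  # "protein" | "cds"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.kind not in ("protein", "cds"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        alphabet = PROTEIN_ALPHABET if self.kind == "protein" else CDS_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains residues outside the "
                f"{self.kind} alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class IdentityResult:
    """Identity of one global alignment: identical columns / alignment length."""

    id_a: str
    id_b: str
    identity: float
    aligned_columns: int


class RemovalRecord(NamedTuple):
    retained_id: str
    identity: float


def read_fasta(path: str | Path, kind: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved.

    The header token before the first whitespace becomes the record id.
    Raises ``ValueError`` for text before the first header (naming the line)
    and for duplicate ids (listing them). An empty file yields an empty list
    with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA — line {lineno} precedes any "
                    f"'>' header: {line.strip()[:40]!r}"
                )
            break
        else:
            warnings.warn(f"{path}: empty FASTA file, no sequences read")
            return []
    records = [
        SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), kind=kind)
        for rec in SeqIO.parse(path, "fasta")
    ]
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"{path}: duplicate FASTA ids: {dups}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA with fixed-width line wrapping (default 60)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def translate_cds(
    record: SequenceRecord,
    force_frame: bool = False,
    truncate_at_stop: bool = False,
) -> SequenceRecord:
    """Translate a CDS with the standard genetic code (table 1).

    A single terminal stop codon is stripped. An internal stop codon raises
    by default; with ``truncate_at_stop`` the protein is truncated there.
    A length not divisible by 3 raises unless ``force_frame`` trims the
    trailing bases. Codons containing N translate to 'X'.
    """
    if record.kind != "cds":
        raise ValueError(f"translate_cds expects a cds record, got {record.kind}")
    seq = record.seq
    if len(seq) % 3:
        if not force_frame:
            raise ValueError(
                f"{record.id}: CDS length {len(seq)} not divisible by 3 "
                "(use force_frame to truncate)"
            )
        seq = seq[: len(seq) - len(seq) % 3]
    aa = str(Seq(seq).translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        codon_idx = aa.index("*") + 1  # 1-based codon number
        if not truncate_at_stop:
            raise ValueError(f"{record.id}: internal stop at codon {codon_idx}")
        aa = aa[: codon_idx - 1]
    if not aa:
        raise ValueError(f"{record.id}: translation is empty")
    return SequenceRecord(id=record.id, seq=aa, kind="protein")


@dataclass
class AlignmentParams:
    """Needleman–Wunsch scoring used for the identity metric."""

    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = -10.0
    gap_extend: float = -0.5


def _aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    params: AlignmentParams | None = None,
) -> IdentityResult:
    """Global-alignment identity between two records of the same kind.

    identity = identical aligned columns / alignment length (gap columns
    count toward the length, never toward the identical count). 'X' never
    counts as an identical column.
    """
    if a.kind != b.kind:
        raise ValueError(f"cannot align {a.kind} ({a.id}) with {b.kind} ({b.id})")
    params = params or AlignmentParams()
    alignment = _aligner(params).align(a.seq, b.seq)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    # ambiguity codes never count as identical: X for proteins, N for CDS
    ambiguous = "X" if a.kind == "protein" else "N"
    identical = sum(
        1
        for x, y in zip(row_a, row_b)
        if x == y and x != "-" and x != ambiguous
    )
    length = len(row_a)
    return IdentityResult(a.id, b.id, identical / length, length)


def deduplicate(
    records: list[SequenceRecord],
    threshold: float = 0.97,
    params: AlignmentParams | None = None,
) -> tuple[list[SequenceRecord], dict[str, RemovalRecord]]:
    """Remove sequences more than ``threshold`` identical to a retained one.

    Greedy longest-first retention: records are considered by decreasing
    length (ties broken by id); a record is kept iff its identity to every
    already-kept record is <= threshold. Returns the kept records in input
    order plus a map removed_id -> (retained_id, identity) naming the kept
    sequence that triggered each removal.
    """
    if not records:
        raise ValueError("deduplicate requires at least one record")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(records, key=lambda r: (-len(r.seq), r.id))
    kept_ids: list[str] = []
    kept_by_id: dict[str, SequenceRecord] = {}
    removed: dict[str, RemovalRecord] = {}
    for rec in order:
        hit = None
        for kid in kept_ids:
            res = pairwise_identity(rec, kept_by_id[kid], params)
            if res.identity > threshold:
                hit = RemovalRecord(kid, res.identity)
                break
        if hit is None:
            kept_ids.append(rec.id)
            kept_by_id[rec.id] = rec
        else:
            removed[rec.id] = hit
    kept = [r for r in records if r.id in kept_by_id]
    if removed:
        logger.info("deduplicate: removed %d of %d records", len(removed), len(records))
    return kept, removed


def write_dedup_report(removed: dict[str, RemovalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("removed_id\tretained_id\tidentity\n")
        for rid in sorted(removed):
            rec = removed[rid]
            fh.write(f"{rid}\t{rec.retained_id}\t{rec.identity:.4f}\n")
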