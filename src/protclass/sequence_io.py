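"""Reading, validating and writing protein sequences in FASTA.

Records are restricted to the 20 canonical amino acids; what happens to
nonstandard letters (``B J O U X Z``, ``*``, gap characters) is controlled
by an explicit policy rather than silently guessed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical residues in alphabetical order; fixes feature ordering everywhere.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL = frozenset(ALPHABET)

#: Residue policies accepted by :func:`read_fasta`.
POLICIES = ("reject", "drop_residue", "map_to_exclusion")


class FastaError(ValueError):
    """Malformed FASTA input or a record violating the residue policy."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence.

    ``id`` is the token after the first ``|`` of the header's first word when
    a ``|`` is present (UniProt-style ``sp|P001|NAME`` headers), otherwise the
    first whitespace-delimited token. ``description`` keeps the remainder of
    the header line.
    """

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("record id must be non-empty")
        if not self.sequence:
            raise FastaError(f"record {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Protein records with one binary label each (1 = positive class)."""

    records: list[ProteinRecord]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.records) != len(self.labels):
            raise ValueError("one label per record required")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in dataset: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset([self.records[i] for i in idx], self.labels[idx])


def parse_header_id(header: str) -> str:
    """Identifier from a FASTA header (the text after ``>``)."""
    token = header.split(None, 1)[0] if header.split() else ""
    if "|" in token:
        return token.split("|")[1]
    return token


def sanitize_sequence(
    raw: str, policy: str = "drop_residue", record_id: str = "?"
) -> str | None:
    """Uppercase ``raw`` and apply the nonstandard-residue policy.

    Returns the cleaned sequence, or ``None`` when the record should be
    excluded (``map_to_exclusion`` with offending characters present).
    Idempotent: sanitizing an already-clean sequence is the identity.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    seq = raw.upper()
    bad = [(pos, ch) for pos, ch in enumerate(seq) if ch not in _CANONICAL]
    if not bad:
        return seq
    if policy == "reject":
        pos, ch = bad[0]
        raise FastaError(
            f"record {record_id!r}: nonstandard residue {ch!r} at position {pos + 1}"
        )
    if policy == "map_to_exclusion":
        logger.warning(
            "record %s: excluded (%d nonstandard residue(s), e.g. %r)",
            record_id, len(bad), bad[0][1],
        )
        return None
    # drop_residue
    logger.warning(
        "record %s: dropped %d nonstandard residue(s): %s",
        record_id, len(bad), "".join(sorted({ch for _, ch in bad})),
    )
    return "".join(ch for ch in seq if ch in _CANONICAL)


def read_fasta(path: str | Path, policy: str = "drop_residue") -> list[ProteinRecord]:
    """Parse a protein FASTA file into :class:`ProteinRecord` objects.

    Multi-line sequences are concatenated, blank lines and trailing
    whitespace are ignored, and lowercase residues are uppercased.
    """
    path = Path(path)
    # tolerate blank lines and trailing whitespace, which the strict
    # Biopython FASTA parser rejects
    lines = [ln.rstrip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FastaError(f"{path}: empty FASTA file")
    if not lines[0].lstrip().startswith(">"):
        raise FastaError(f"{path}: sequence data before any '>' header")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO("\n".join(lines) + "\n"), "fasta"):
        rec_id = parse_header_id(rec.description)
        if not rec_id:
            raise FastaError(f"{path}: record with empty header id")
        if rec_id in seen:
            raise FastaError(f"{path}: duplicate record id {rec_id!r}")
        seen.add(rec_id)
        desc = rec.description.split(None, 1)
        description = desc[1] if len(desc) > 1 else ""
        seq = sanitize_sequence(str(rec.seq).replace(" ", ""), policy, rec_id)
        if seq is None:
            continue
        if not seq:
            raise FastaError(
                f"{path}: record {rec_id!r} empty after residue sanitization"
            )
        records.append(ProteinRecord(rec_id, description, seq))
    if not records and not seen:
        raise FastaError(f"{path}: no records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to ``path``; round-trips exactly through :func:`read_fasta`."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    path = Path(path)
    with path.open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def attach_labels(
    pos: Sequence[ProteinRecord], neg: Sequence[ProteinRecord]
) -> LabeledDataset:
    """Combine per-class record lists into one dataset, positives first."""
    pos_ids = {r.id for r in pos}
    collisions = sorted(pos_ids & {r.id for r in neg})
    if collisions:
        raise ValueError(f"record ids present in both classes: {collisions}")
    records = list(pos) + list(neg)
    labels = np.array([1] * len(pos) + [0] * len(neg), dtype=int)
    return LabeledDataset(records, labels)


def read_label_table(path: str | Path) -> dict[str, int]:
    """Two-column TSV ``id<TAB>label`` with labels in {0,1}."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label'")
        rec_id, value = parts[0].strip(), parts[1].strip()
        if value not in {"0", "1"}:
            raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {value!r}")
        if rec_id in labels:
            raise ValueError(f"{path}:{lineno}: duplicate id {rec_id!r}")
        labels[rec_id] = int(value)
    if not labels:
        raise ValueError(f"{path}: no labels found")
    return labels


def dataset_from_label_table(
    records: Sequence[ProteinRecord], labels: dict[str, int]
) -> LabeledDataset:
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise ValueError(f"records without labels: {missing[:5]}")
    return LabeledDataset(list(records), np.array([labels[r.id] for r in records]))
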