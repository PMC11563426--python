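"""Peptide dataset I/O: FASTA and CSV reading/writing, residue validation.

The canonical residue alphabet is the 20 standard amino acids in alphabetical
single-letter order (A,C,D,...,Y). That ordering fixes feature-column identity
for every encoder downstream. Labels are binary: 1 = positive class (e.g.
IL-10-inducing), 0 = negative. Labels travel beside sequences (a CSV column or
a per-file flag), never inside FASTA headers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical 20-letter amino-acid alphabet, alphabetical single-letter order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHASET = frozenset(ALPHABET)

ValidationPolicy = Literal["strict", "drop-record", "strip-nonstandard"]


class PeptideValidationError(ValueError):
    """A residue string violates the canonical-alphabet invariant."""


class FastaParseError(ValueError):
    """Malformed or empty FASTA input."""


class _DropRecord(Exception):
    """Internal signal: record flagged for removal under drop-record policy."""


def validate_sequence(residues: str, policy: ValidationPolicy = "strict") -> str:
    """Normalise and validate a residue string against the canonical alphabet.

    Input is uppercased first. Under ``strict`` any non-canonical letter is an
    error; under ``drop-record`` the record is flagged for removal (raises
    :class:`_DropRecord`, handled by dataset readers); under
    ``strip-nonstandard`` non-canonical letters are removed, erroring only if
    nothing remains. Idempotent under every policy.
    """
    if not residues:
        raise PeptideValidationError("empty residue string")
    seq = residues.upper()
    bad = sorted({c for c in seq if c not in _ALPHASET})
    if not bad:
        return seq
    if policy == "strict":
        raise PeptideValidationError(
            f"non-canonical residue(s) {','.join(bad)} in sequence {residues!r}"
        )
    if policy == "drop-record":
        raise _DropRecord(bad)
    if policy == "strip-nonstandard":
        kept = "".join(c for c in seq if c in _ALPHASET)
        if not kept:
            raise PeptideValidationError(
                f"sequence {residues!r} empty after stripping non-standard residues"
            )
        return kept
    raise ValueError(f"unknown validation policy: {policy!r}")


@dataclass(frozen=True)
class PeptideSequence:
    """An identifier plus a validated residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise PeptideValidationError(f"peptide {self.id!r}: empty residues")
        bad = sorted({c for c in self.residues if c not in _ALPHASET})
        if bad:
            raise PeptideValidationError(
                f"peptide {self.id!r}: non-canonical residue(s) {','.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """An ordered peptide collection with a parallel binary label vector."""

    sequences: list[PeptideSequence]
    labels: np.ndarray  # shape (n,), values in {0, 1}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary {0,1}")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sequences)

    def deduplicate(self) -> "LabeledDataset":
        """Drop peptides whose residue string repeats, keeping first occurrence.

        Off by default everywhere; offered because benchmark curation practice
        varies on this point.
        """
        seen: set[str] = set()
        keep = []
        for i, s in enumerate(self.sequences):
            if s.residues not in seen:
                seen.add(s.residues)
                keep.append(i)
        return LabeledDataset(
            [self.sequences[i] for i in keep], self.labels[keep]
        )


def read_fasta(
    path: str | Path,
    label: int | None = None,
    policy: ValidationPolicy = "strict",
) -> LabeledDataset:
    """Read peptides from a FASTA file, optionally assigning one label to all.

    Records appear in file order. Duplicate ids are rejected. When ``label``
    is None the dataset carries label 0 for every record (callers combining
    per-class files should pass the class label explicitly).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: list[PeptideSequence] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as e:  # Biopython parse failure
        raise FastaParseError(f"{path}: {e}") from e
    if not records:
        # distinguish empty file from file with no valid records
        raise FastaParseError(f"{path}: no FASTA records found")
    for rec in records:
        try:
            residues = validate_sequence(str(rec.seq), policy)
        except _DropRecord:
            continue
        sequences.append(PeptideSequence(rec.id, residues))
    lab = 0 if label is None else int(label)
    return LabeledDataset(sequences, np.full(len(sequences), lab, dtype=int))


def write_fasta(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a dataset's sequences to FASTA, preserving id and order."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="")
        for s in dataset.sequences
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_label_csv(
    path: str | Path, policy: ValidationPolicy = "strict"
) -> LabeledDataset:
    """Read a two-column CSV (sequence,label) or three-column (id,sequence,label).

    A header row is detected by non-numeric content in the label column of the
    first line. Ids are synthesised (``pep_0001`` ...) when absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[str, str, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for ln, row in enumerate(reader):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) == 2:
                rid, seq, lab = None, row[0].strip(), row[1].strip()
            elif len(row) >= 3:
                rid, seq, lab = row[0].strip(), row[1].strip(), row[2].strip()
            else:
                raise ValueError(f"{path}:{ln + 1}: expected 2 or 3 columns")
            if ln == 0 and not lab.lstrip("-").isdigit():
                continue  # header
            if lab not in ("0", "1"):
                raise ValueError(f"{path}:{ln + 1}: label must be 0 or 1, got {lab!r}")
            rows.append((rid, seq, int(lab)))
    sequences, labels = [], []
    for i, (rid, seq, lab) in enumerate(rows):
        try:
            residues = validate_sequence(seq, policy)
        except _DropRecord:
            continue
        sequences.append(PeptideSequence(rid or f"pep_{i + 1:04d}", residues))
        labels.append(lab)
    return LabeledDataset(sequences, np.array(labels, dtype=int))


def write_feature_csv(
    matrix: "FeatureMatrix",  # noqa: F821 — forward ref, avoids import cycle
    labels: Sequence[int] | np.ndarray,
    path: str | Path,
) -> None:
    """Serialise a feature matrix plus labels to CSV at full float precision.

    Header is the feature names followed by ``label``; one row per peptide,
    indexed by peptide id. ``repr``-level float formatting guarantees a
    bit-for-bit round-trip through :func:`read_feature_csv`.
    """
    labels = np.asarray(labels, dtype=int)
    if matrix.values.shape[0] != labels.shape[0]:
        raise ValueError(
            f"matrix has {matrix.values.shape[0]} rows but {labels.shape[0]} labels"
        )
    df = pd.DataFrame(matrix.values, index=matrix.row_ids, columns=matrix.col_names)
    df["label"] = labels
    df.index.name = "id"
    # shortest round-trip repr so read_feature_csv restores values bit-for-bit
    df.to_csv(path, float_format=lambda v: repr(float(v)))


def read_feature_csv(path: str | Path) -> tuple["FeatureMatrix", np.ndarray]:  # noqa: F821
    """Inverse of :func:`write_feature_csv`."""
    from pepstack.encoders import FeatureMatrix

    df = pd.read_csv(path, index_col="id", float_precision="round_trip")
    labels = df.pop("label").to_numpy(dtype=int)
    return (
        FeatureMatrix(
            row_ids=[str(i) for i in df.index],
            col_names=list(df.columns),
            values=df.to_numpy(dtype=float),
        ),
        labels,
    )
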