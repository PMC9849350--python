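"""Readers and writers for all on-disk artifacts.

Formats handled here:

* FASTA protein sequences (via Biopython);
* per-residue label files — for each protein an id line (``>id``) followed by
  a 0/1 string with one character per residue;
* PSI-BLAST ASCII PSSM profiles (the ``-out_ascii_pssm`` layout; the first
  20-column score block is read);
* per-residue embedding containers — either a single ``.npz`` keyed by
  protein id, or a directory of whitespace-delimited text matrices named
  ``<id>.emb``;
* the prediction table written by ``capsite predict`` (TSV, one row per
  residue, 1-based residue indices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .features import ALPHABET, PssmProfile

logger = logging.getLogger("capsite")

_VALID = set(ALPHABET) | {"X"}


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


@dataclass
class ProteinRecord:
    """One protein: id, sequence, and (optionally) per-residue labels."""

    id: str
    sequence: str
    labels: np.ndarray | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"{self.id}: invalid residue letters {bad}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.sequence),):
                raise ValueError(
                    f"{self.id}: {self.labels.size} labels for "
                    f"{len(self.sequence)} residues"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError(f"{self.id}: labels must be 0/1")

    def __len__(self) -> int:
        return len(self.sequence)


# -- FASTA ---------------------------------------------------------------------


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; letters outside the 20-residue alphabet are
    mapped to ``X`` with a logged warning.  Duplicate ids are an error.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in _VALID else "X" for c in seq)
        if cleaned != seq:
            bad = sorted(set(seq) - _VALID)
            logger.warning(
                "%s: mapped non-standard residue(s) %s to X", rec.id, bad
            )
        records.append(ProteinRecord(rec.id, cleaned))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# -- label files ---------------------------------------------------------------


def read_labels(path, records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Attach per-residue 0/1 labels to ``records`` (matched by id)."""
    by_id = {rec.id: rec for rec in records}
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}: expected an id line, got {lines[i]!r}")
        pid = lines[i][1:].split()[0]
        if i + 1 >= len(lines):
            raise FormatError(f"{path}: missing label string for {pid!r}")
        labels = lines[i + 1]
        if pid not in by_id:
            raise FormatError(f"{path}: unknown protein id {pid!r}")
        if set(labels) - {"0", "1"}:
            raise FormatError(
                f"{path}: non-binary symbol in labels for {pid!r}"
            )
        rec = by_id[pid]
        if len(labels) != len(rec.sequence):
            raise FormatError(
                f"{pid!r}: {len(labels)} labels for "
                f"{len(rec.sequence)}-residue sequence"
            )
        rec.labels = np.frombuffer(labels.encode(), dtype=np.uint8) - ord("0")
        i += 2
    return records


def write_labels(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.labels is None:
                raise ValueError(f"{rec.id}: no labels to write")
            fh.write(f">{rec.id}\n{''.join(map(str, rec.labels))}\n")


# -- PSI-BLAST ASCII PSSM ------------------------------------------------------


def read_pssm_ascii(path) -> PssmProfile:
    """Parse the first 20-column score block of a PSI-BLAST ASCII PSSM."""
    rows: list[np.ndarray] = []
    letters: list[str] = []
    order: list[int] | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        tokens = line.split()
        if order is None:
            # header line listing the 20 residue letters (possibly twice)
            if len(tokens) >= 20 and all(
                t in ALPHABET and len(t) == 1 for t in tokens[:20]
            ):
                order = [ALPHABET.index(t) for t in tokens[:20]]
            continue
        if not tokens:
            if rows:
                break  # blank line after the matrix: trailing statistics
            continue
        if not tokens[0].isdigit():
            if rows:
                break
            continue
        if len(tokens) < 22:
            raise FormatError(
                f"{path}:{lineno}: truncated PSSM row "
                f"({len(tokens)} fields, need >= 22)"
            )
        try:
            values = np.array([float(t) for t in tokens[2:22]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        scores = np.empty(20)
        scores[order] = values  # reorder file columns into ALPHABET order
        rows.append(scores)
        letters.append(tokens[1])
    if order is None or not rows:
        raise FormatError(f"{path}: no PSSM score block found")
    return PssmProfile(np.stack(rows), residues="".join(letters))


def write_pssm_ascii(profile: PssmProfile, path) -> None:
    """Serialize a profile in the PSI-BLAST ASCII layout (read back exactly
    when scores are integers, as PSI-BLAST prints them)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write("           " + "  ".join(ALPHABET) + "\n")
        residues = profile.residues or "X" * len(profile)
        for i, row in enumerate(profile.log_odds, 1):
            vals = " ".join(f"{int(round(v)):3d}" for v in row)
            fh.write(f"{i:5d} {residues[i - 1]}  {vals}\n")
        fh.write("\n")


# -- embedding containers ------------------------------------------------------


def read_embeddings(path, protein_id: str, expected_length: int | None = None):
    """Load the per-residue embedding matrix for one protein.

    ``path`` is either a ``.npz`` container keyed by id, or a directory of
    ``<id>.emb`` whitespace-delimited text matrices.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as container:
            if protein_id not in container.files:
                raise KeyError(
                    f"protein {protein_id!r} not in container {path}"
                )
            matrix = np.asarray(container[protein_id], dtype=float)
    else:
        f = path / f"{protein_id}.emb"
        if not f.exists():
            raise KeyError(f"protein {protein_id!r}: {f} does not exist")
        matrix = np.loadtxt(f, ndmin=2)
    if matrix.ndim != 2:
        raise FormatError(f"{protein_id!r}: embedding must be a 2-D matrix")
    if expected_length is not None and matrix.shape[0] != expected_length:
        raise FormatError(
            f"{protein_id!r}: embedding has {matrix.shape[0]} rows for a "
            f"{expected_length}-residue sequence"
        )
    return matrix


def write_embeddings(matrices: dict[str, np.ndarray], path) -> None:
    """Write an embedding container (dialect chosen by extension)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, **{k: np.asarray(v) for k, v in matrices.items()})
    else:
        path.mkdir(parents=True, exist_ok=True)
        for pid, matrix in matrices.items():
            np.savetxt(path / f"{pid}.emb", np.asarray(matrix), fmt="%.8g")


# -- prediction tables ---------------------------------------------------------


@dataclass
class PredictionTable:
    """Per-residue positive-class scores and binary calls for many proteins."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["protein_id", "residue_index", "amino_acid", "score", "call"]
        )
    )

    def __post_init__(self):
        if len(self.frame):
            scores = self.frame["score"].to_numpy(dtype=float)
            if np.any((scores < 0) | (scores > 1)):
                raise ValueError("scores must lie in [0, 1]")


def make_prediction_table(
    records, scores_per_protein, threshold: float = 0.5
) -> PredictionTable:
    """Assemble the output table (1-based residue indices; a score exactly at
    the threshold is called positive)."""
    rows = []
    for rec, scores in zip(records, scores_per_protein):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(rec.sequence),):
            raise ValueError(f"{rec.id}: score/sequence length mismatch")
        for i, (aa, s) in enumerate(zip(rec.sequence, scores), 1):
            rows.append((rec.id, i, aa, float(s), int(s >= threshold)))
    frame = pd.DataFrame(
        rows, columns=["protein_id", "residue_index", "amino_acid", "score", "call"]
    )
    return PredictionTable(frame)


def write_predictions(table: PredictionTable, path) -> None:
    frame = table.frame.copy()
    frame["score"] = frame["score"].map(lambda s: f"{s:.6f}")
    frame.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> PredictionTable:
    frame = pd.read_csv(path, sep="\t")
    return PredictionTable(frame)
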