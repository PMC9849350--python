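"""Per-residue feature construction.

Each protein is encoded into two channels that the network consumes side by
side:

* **MBF** (multi-source biological features): for every residue, its 20 PSSM
  log-odds values plus 10 tabulated descriptors (7 physical, 3
  physicochemical), stacked over a sliding window of ``n`` residues centred on
  the target residue, giving an ``L x (30 n)`` matrix.  Positions beyond the
  sequence ends contribute zero vectors.
* **Embedding**: an opaque ``L x D`` per-residue matrix from a protein
  language model (D = 1024 for ProtT5), consumed as-is — never windowed.

The PSSM log-odds convention is ``score(a, b) = log10(M(a, b) / (p_a p_b))``
with ``M`` a substitution probability matrix and ``p`` background residue
frequencies; real profiles are parsed from PSI-BLAST output, and this formula
is used only to score synthetic profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Names of the shipped descriptors, in column order.
DESCRIPTOR_NAMES: tuple[str, ...] = ()
_DESCRIPTOR_TABLE: dict[str, np.ndarray] = {}

#: Registry of extra per-residue descriptor functions (letter -> vector);
#: registered descriptors are appended after the shipped 10 columns.
EXTRA_DESCRIPTORS: dict[str, Callable[[str], np.ndarray]] = {}


def _load_table() -> None:
    global DESCRIPTOR_NAMES
    text = (
        resources.files("capsite.data")
        .joinpath("residue_descriptors.tsv")
        .read_text()
    )
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line and not line.startswith("#")
    ]
    header, body = rows[0], rows[1:]
    DESCRIPTOR_NAMES = tuple(header[1:])
    for row in body:
        _DESCRIPTOR_TABLE[row[0]] = np.array([float(v) for v in row[1:]])
    missing = set(ALPHABET) - set(_DESCRIPTOR_TABLE)
    if missing:  # pragma: no cover - shipped table is complete
        raise RuntimeError(f"descriptor table missing residues: {missing}")


_load_table()


def residue_descriptors(aa: str) -> np.ndarray:
    """Return the 10 tabulated descriptor values for one residue letter.

    ``X`` (unknown residue) maps to the all-zero vector so matrix shapes stay
    stable for non-standard residues.
    """
    if aa == "X":
        base = np.zeros(len(DESCRIPTOR_NAMES))
    else:
        try:
            base = _DESCRIPTOR_TABLE[aa]
        except KeyError:
            raise ValueError(f"unknown residue letter {aa!r}") from None
    if EXTRA_DESCRIPTORS:
        extras = [np.atleast_1d(fn(aa)) for fn in EXTRA_DESCRIPTORS.values()]
        return np.concatenate([base, *extras])
    return base


def pssm_log_odds(M: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Score a 20x20 substitution-probability matrix against background.

    ``score(a, b) = log10(M(a, b) / (p_a p_b))``.  Used by the synthetic
    profile generator; real PSSMs are parsed, not computed.
    """
    M = np.asarray(M, dtype=float)
    p = np.asarray(p, dtype=float)
    if M.shape != (20, 20) or p.shape != (20,):
        raise ValueError("expected M of shape (20, 20) and p of shape (20,)")
    if np.any(M <= 0) or np.any(p <= 0):
        raise ValueError("substitution probabilities and background must be > 0")
    return np.log10(M / np.outer(p, p))


@dataclass(frozen=True)
class PssmProfile:
    """Positional log-odds profile for one protein.

    ``log_odds`` has one row per residue, 20 columns in :data:`ALPHABET`
    order; ``background`` is the residue background distribution the scores
    are relative to; ``residues`` keeps the letters from the profile file for
    consistency checks against the FASTA sequence.
    """

    log_odds: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05)
    )
    residues: str = ""

    def __post_init__(self):
        lo = np.asarray(self.log_odds, dtype=float)
        object.__setattr__(self, "log_odds", lo)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if lo.ndim != 2 or lo.shape[1] != 20:
            raise ValueError("log_odds must be L x 20")
        if not np.all(np.isfinite(lo)):
            raise ValueError("log_odds must be finite")
        if np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be positive and sum to 1")

    def __len__(self) -> int:
        return self.log_odds.shape[0]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry for the MBF channel.

    ``n`` is the (odd) window size — the centre residue is the prediction
    target and the step is one residue; the published sweep selects 25.
    Out-of-sequence positions are zero-padded.
    """

    n: int = 25
    pad_policy: str = "zero"
    step: int = 1

    def __post_init__(self):
        if self.n < 1 or self.n % 2 == 0:
            raise ValueError("window size must be odd and >= 1")
        if self.pad_policy != "zero":
            raise ValueError("only zero padding is supported")
        if self.step != 1:
            raise ValueError("sliding step must be 1")


@dataclass
class FeatureBundle:
    """Both model channels for one protein, plus optional labels."""

    protein_id: str
    mbf: np.ndarray | None
    embedding: np.ndarray | None
    labels: np.ndarray | None = None

    def __post_init__(self):
        lengths = {
            name: arr.shape[0]
            for name, arr in (
                ("mbf", self.mbf),
                ("embedding", self.embedding),
                ("labels", self.labels),
            )
            if arr is not None
        }
        if not lengths:
            raise ValueError(f"{self.protein_id}: bundle has no channels")
        if len(set(lengths.values())) > 1:
            raise ValueError(
                f"{self.protein_id}: channel length mismatch {lengths}"
            )

    def __len__(self) -> int:
        for arr in (self.mbf, self.embedding, self.labels):
            if arr is not None:
                return arr.shape[0]
        raise AssertionError


def base_feature_matrix(sequence: str, pssm: PssmProfile) -> np.ndarray:
    """Per-residue base vectors: [20 PSSM log-odds, 10 descriptors]."""
    if len(pssm) != len(sequence):
        raise ValueError(
            f"sequence length {len(sequence)} != profile length {len(pssm)}"
        )
    desc = np.stack([residue_descriptors(aa) for aa in sequence])
    return np.concatenate([pssm.log_odds, desc], axis=1)


def encode_mbf(
    record, pssm: PssmProfile, cfg: WindowConfig | None = None
) -> np.ndarray:
    """Window-stack the base features into the ``L x (30 n)`` MBF matrix.

    Row ``i`` concatenates the base vectors of residues
    ``i - (n-1)/2 ... i + (n-1)/2``; positions past either end contribute
    zeros.
    """
    cfg = cfg or WindowConfig()
    base = base_feature_matrix(record.sequence, pssm)
    L, F = base.shape
    half = (cfg.n - 1) // 2
    padded = np.zeros((L + 2 * half, F))
    padded[half : half + L] = base
    # stride view: row i -> padded[i : i + n] flattened
    out = np.empty((L, cfg.n * F))
    for offset in range(cfg.n):
        out[:, offset * F : (offset + 1) * F] = padded[offset : offset + L]
    return out


def assemble_bundle(
    record,
    pssm: PssmProfile | None = None,
    embedding: np.ndarray | None = None,
    cfg: WindowConfig | None = None,
    channels: tuple[str, ...] = ("mbf", "embedding"),
) -> FeatureBundle:
    """Build the :class:`FeatureBundle` for one protein.

    The two channels stay separate here — fusion happens inside the network,
    after the per-channel encoders.
    """
    mbf = emb = None
    if "mbf" in channels:
        if pssm is None:
            raise ValueError(
                f"{record.id}: MBF channel enabled but no PSSM profile given"
            )
        mbf = encode_mbf(record, pssm, cfg)
    if "embedding" in channels:
        if embedding is None:
            raise ValueError(
                f"{record.id}: embedding channel enabled but no embedding given"
            )
        embedding = np.asarray(embedding, dtype=float)
        if embedding.shape[0] != len(record.sequence):
            raise ValueError(
                f"{record.id}: embedding has {embedding.shape[0]} rows for a "
                f"{len(record.sequence)}-residue sequence"
            )
        emb = embedding
    labels = getattr(record, "labels", None)
    if labels is not None:
        labels = np.asarray(labels, dtype=int)
    return FeatureBundle(record.id, mbf, emb, labels)
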