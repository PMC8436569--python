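"""Protein sequence input, fixed-length windowing, and synthetic fixtures.

A protein sequence is turned into a transaction database by cutting it into
consecutive, non-overlapping windows of a nominal length (default 10
residues).  Each window is treated as a market-basket transaction whose items
are amino-acid letters; both the residue multiset (with multiplicity) and the
distinct-letter set of every window are kept, because the two downstream
counting modes need one each.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, single-letter code, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Nominal window length used throughout.
DEFAULT_WINDOW_LEN = 10


@dataclass(frozen=True)
class ProteinSequence:
    """An identifier plus an ordered residue string over the 20-letter alphabet."""

    id: str
    residues: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Window:
    """One fixed-length transaction: a contiguous substring of the sequence."""

    index: int
    residues: str
    multiset: Counter = field(compare=False)
    letter_set: frozenset = field(compare=False)

    @staticmethod
    def from_residues(index: int, residues: str) -> "Window":
        counts = Counter(residues)
        return Window(index, residues, counts, frozenset(counts))


@dataclass(frozen=True)
class TransactionDB:
    """The ordered list of windows cut from one protein sequence."""

    windows: tuple
    window_len: int
    source_id: str

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def occurrences(self) -> Counter:
        """Total occurrence count of each letter across all windows."""
        total: Counter = Counter()
        for w in self.windows:
            total.update(w.multiset)
        return total

    def concatenated(self) -> str:
        return "".join(w.residues for w in self.windows)


def validate_residues(residues: str, *, record_id: str = "", strict: bool = True) -> str:
    """Upper-case and validate a residue string against the standard alphabet.

    Strict mode raises on the first non-standard character (B, J, O, U, X, Z,
    ``*`` and anything else outside the 20 letters) with its 1-based position;
    lenient mode drops such characters and logs a warning.
    """
    residues = residues.upper()
    if strict:
        for pos, ch in enumerate(residues, start=1):
            if ch not in _AA_SET:
                raise ValidationError(
                    f"record {record_id!r}: non-standard residue {ch!r} at position {pos}"
                )
        return residues
    kept = [ch for ch in residues if ch in _AA_SET]
    dropped = len(residues) - len(kept)
    if dropped:
        logger.warning(
            "record %r: dropped %d non-standard residue(s)", record_id, dropped
        )
    return "".join(kept)


def read_fasta(path, *, strict: bool = True) -> list:
    """Read all records of a FASTA file as :class:`ProteinSequence` objects.

    The id is the header token up to the first whitespace; the remainder is
    kept as a description.  Wrapped sequence lines are joined and upper-cased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    sequences = []
    for record in SeqIO.parse(str(path), "fasta"):
        raw = str(record.seq).replace(" ", "")
        if not raw:
            raise ValidationError(f"record {record.id!r}: empty sequence")
        residues = validate_residues(raw, record_id=record.id, strict=strict)
        if not residues:
            raise ValidationError(
                f"record {record.id!r}: no standard residues after validation"
            )
        sequences.append(
            ProteinSequence(record.id, residues, record.description)
        )
    return sequences


def partition(seq: ProteinSequence, window_len: int = DEFAULT_WINDOW_LEN) -> TransactionDB:
    """Cut a sequence into consecutive non-overlapping windows.

    The trailing partial window is retained as a transaction, so the number of
    windows is ``ceil(length / window_len)``.
    """
    if window_len < 1:
        raise ValidationError(f"window_len must be >= 1, got {window_len}")
    if seq.length < 1:
        raise ValidationError("cannot partition an empty sequence")
    windows = tuple(
        Window.from_residues(i // window_len, seq.residues[i : i + window_len])
        for i in range(0, seq.length, window_len)
    )
    assert len(windows) == math.ceil(seq.length / window_len)
    return TransactionDB(windows, window_len, seq.id)


def generate_random_protein(length: int, seed: int, freqs: dict | None = None) -> ProteinSequence:
    """Generate a random protein sequence, i.i.d. over the 20-letter alphabet.

    ``freqs`` maps letters to nonnegative weights (missing letters get weight
    0); omitted means uniform.  Deterministic for a fixed seed.
    """
    if length < 1:
        raise ValidationError(f"length must be >= 1, got {length}")
    if freqs is None:
        probs = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    else:
        bad = set(freqs) - _AA_SET
        if bad:
            raise ValidationError(f"unknown letters in freqs: {sorted(bad)}")
        weights = np.array([float(freqs.get(a, 0.0)) for a in AMINO_ACIDS])
        if (weights < 0).any():
            raise ValidationError("weights must be nonnegative")
        if weights.sum() == 0:
            raise ValidationError("weights must not all be zero")
        probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(AMINO_ACIDS), size=length, p=probs)
    return ProteinSequence(f"random-{seed}", "".join(letters))


def hbb_fixture_path() -> Path:
    """Path to the bundled 147-residue human hemoglobin subunit beta FASTA."""
    return Path(resources.files("aarules.data") / "hbb_p68871.fasta")
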