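"""Amino-acid alignments with optional per-column confidence scores.

Residue alphabet is the 20 standard amino acids plus ``-`` (gap) and
``X`` (masked / unknown).  Both gap and ``X`` are treated as missing
data by the likelihood machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._jtt import AMINO_ACIDS

GAP = "-"
MASK = "X"
VALID_CHARS = set(AMINO_ACIDS) | {GAP, MASK}


@dataclass
class Alignment:
    """A rectangular amino-acid alignment.

    Parameters
    ----------
    ids
        Unique sequence identifiers, one per row.
    rows
        Aligned residue strings (equal length) over the 20 amino acids
        plus ``-`` and ``X``.
    confidence
        Optional per-column confidence scores in ``[0, 1]``.
    """

    ids: list[str]
    rows: list[str]
    confidence: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have the same length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence identifiers must be unique")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise ValueError("all alignment rows must have equal length")
        for r in self.rows:
            bad = set(r) - VALID_CHARS
            if bad:
                raise ValueError(f"invalid residue characters: {sorted(bad)}")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.rows and self.confidence.shape != (len(self.rows[0]),):
                raise ValueError("confidence vector needs one entry per column")
            if np.any((self.confidence < 0) | (self.confidence > 1)):
                raise ValueError("confidence scores must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"no sequence with id {seq_id!r}") from None

    def to_array(self) -> np.ndarray:
        """Return the alignment as a (rows, cols) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    @classmethod
    def from_array(
        cls,
        ids: list[str],
        arr: np.ndarray,
        confidence: np.ndarray | None = None,
    ) -> "Alignment":
        return cls(list(ids), ["".join(r) for r in arr], confidence)

    @classmethod
    def from_fasta(cls, path, confidence: np.ndarray | None = None) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return cls(
            [r.id for r in records],
            [str(r.seq).upper() for r in records],
            confidence,
        )

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(row), id=sid, description="")
            for sid, row in zip(self.ids, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")


def mask_low_confidence(aln: Alignment, threshold: float) -> Alignment:
    """Mask every residue in columns whose confidence is below ``threshold``.

    Residues in a column with confidence strictly less than ``threshold``
    are replaced by ``X``; gap characters are left untouched and all other
    columns are returned unchanged.

    Raises
    ------
    ValueError
        If the alignment carries no confidence vector or the threshold is
        outside ``[0, 1]``.
    """
    if aln.confidence is None:
        raise ValueError("alignment has no per-column confidence scores")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    arr = aln.to_array()
    low = aln.confidence < threshold
    sub = arr[:, low]
    sub[sub != GAP] = MASK
    arr[:, low] = sub
    return Alignment.from_array(aln.ids, arr, aln.confidence.copy())


def strip_gappy_columns(
    aln: Alignment, max_gap_fraction: float
) -> tuple[Alignment, np.ndarray]:
    """Drop columns whose gap fraction is ``>= max_gap_fraction``.

    Retains exactly the columns with gap fraction strictly below the
    cutoff (a 95% cutoff keeps columns with *less than* 95% gaps).

    Returns
    -------
    (alignment, column_map)
        The stripped alignment and an integer array mapping each new
        column index to its original column index.
    """
    if not 0.0 < max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in (0, 1]")
    if aln.n_rows == 0 or aln.n_cols == 0:
        raise ValueError("cannot strip columns of an empty alignment")
    arr = aln.to_array()
    gap_frac = (arr == GAP).mean(axis=0)
    keep = np.flatnonzero(gap_frac < max_gap_fraction)
    conf = aln.confidence[keep] if aln.confidence is not None else None
    return Alignment.from_array(aln.ids, arr[:, keep], conf), keep
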