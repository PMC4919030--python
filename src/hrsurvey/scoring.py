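"""Substitution-matrix scoring for protein alignment.

Matrices are the NCBI integer tables shipped with biopython (``BLOSUM50`` by
default, matching the survey's pairwise-search settings together with the
affine gap penalties open −10 / extend −2); custom matrices can be read from
files in the same NCBI text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 standard amino acids, in the conventional NCBI-matrix order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Internal alphabet: 20 standard residues plus ``X`` (unknown, scores 0).
ALPHABET = AMINO_ACIDS + "X"

_CODE = {aa: i for i, aa in enumerate(ALPHABET)}
X_CODE = _CODE["X"]


class SequenceFormatError(ValueError):
    """Raised when a sequence contains characters outside the protein alphabet."""


def encode(seq: str) -> np.ndarray:
    """Encode a protein string into integer codes (X and rare ambiguity
    codes B/Z/U/O/* are mapped to the neutral ``X`` code)."""
    seq = seq.upper()
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        code = _CODE.get(ch)
        if code is None:
            if ch in "BZUO*J":
                code = X_CODE
            else:
                raise SequenceFormatError(f"illegal residue {ch!r} at position {i}")
        out[i] = code
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclass
class ScoringScheme:
    """Integer substitution scores plus affine gap penalties.

    A gap of length *k* is charged ``gap_open + k * gap_extend`` (the
    FASTA-suite convention, so a length-1 gap under the defaults costs −12).
    """

    matrix_name: str = "BLOSUM50"
    gap_open: int = -10
    gap_extend: int = -2
    matrix: np.ndarray = field(default=None, repr=False)  # 21x21 incl. X

    def __post_init__(self):
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap_open and gap_extend must be negative")
        if self.matrix is None:
            self.matrix = _load_matrix(self.matrix_name)
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (21, 21):
            raise ValueError("matrix must be 21x21 (20 residues + X)")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> int:
        """Substitution score of two single residues."""
        return int(self.matrix[_CODE[a.upper()], _CODE[b.upper()]])

    @classmethod
    def from_file(cls, path, gap_open: int = -10, gap_extend: int = -2) -> "ScoringScheme":
        """Load a custom matrix from an NCBI-format text file."""
        arr = substitution_matrices.read(str(path))
        return cls(matrix_name=str(path), gap_open=gap_open, gap_extend=gap_extend,
                   matrix=_to_internal(arr))


def _to_internal(arr) -> np.ndarray:
    """Re-index a biopython substitution Array onto ALPHABET; X scores 0."""
    m = np.zeros((21, 21), dtype=np.int64)
    letters = arr.alphabet
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if a in letters and b in letters:
                m[i, j] = int(arr[a, b])
    # X row/column forced to 0 regardless of the file's convention.
    m[X_CODE, :] = 0
    m[:, X_CODE] = 0
    return m


def _load_matrix(name: str) -> np.ndarray:
    return _to_internal(substitution_matrices.load(name))
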