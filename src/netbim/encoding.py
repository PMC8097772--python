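"""BLOSUM50 encoding of sanitized 9-mer peptides.

Each peptide becomes a 9 x 21 matrix: row i is the BLOSUM50 substitution row
of residue i restricted to a fixed 21-letter alphabet (the 20 canonical amino
acids in alphabetical order plus 'Z', the Glu/Gln ambiguity code used as the
catch-all for non-canonical residues), divided by 10.  Entries therefore lie
in [-0.5, 1.5].  Euclidean distance between flattened matrices is the
peptide-peptide distance used for nearest-neighbour imputation of network
features.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

#: Fixed column (and row-lookup) order of the encoding.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWYZ"

#: Division applied to raw BLOSUM50 scores to ease model training.
SCALE: float = 10.0


@lru_cache(maxsize=1)
def blosum50_matrix() -> np.ndarray:
    """The 21 x 21 BLOSUM50 submatrix over ``ALPHABET``, scaled by 1/SCALE.

    Loaded from Biopython's copy of the standard NCBI matrix, which includes
    the ambiguity codes (Z = Glu/Gln).
    """
    m = substitution_matrices.load("BLOSUM50")
    out = np.empty((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a][b]
    return out / SCALE


@dataclass(frozen=True)
class EncodedPeptide:
    peptide: str
    matrix: np.ndarray  # shape (9, 21)

    def flat(self) -> np.ndarray:
        return self.matrix.ravel()


def encode_peptide(peptide: str) -> EncodedPeptide:
    """Encode a sanitized 9-mer as its scaled BLOSUM50 row matrix."""
    if len(peptide) != 9:
        raise ValueError(f"peptide must be a 9-mer, got {peptide!r}")
    table = blosum50_matrix()
    try:
        idx = [ALPHABET.index(c) for c in peptide]
    except ValueError as exc:
        raise ValueError(f"residue outside alphabet in {peptide!r}") from exc
    return EncodedPeptide(peptide=peptide, matrix=table[idx, :].copy())


def encode_batch(peptides) -> np.ndarray:
    """Stack encodings into an (n, 9, 21) array (order preserved)."""
    return np.stack([encode_peptide(p).matrix for p in peptides])


def peptide_distance(a: EncodedPeptide, b: EncodedPeptide) -> float:
    """Euclidean distance between the two flattened 189-element encodings."""
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("shape mismatch between encoded peptides")
    return float(np.linalg.norm(a.flat() - b.flat()))


def read_fasta_peptides(path) -> dict[str, str]:
    """Read peptides from FASTA; record IDs become keys (values sanitized upstream)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
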