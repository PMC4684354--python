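"""Standard genetic code constants shared across the package.

All codon-indexed arrays in :mod:`ribowave` are ordered by :data:`SENSE_CODONS`
(the 61 non-stop codons of the standard nuclear code, lexicographic order).
"""

from __future__ import annotations

from itertools import product

import numpy as np
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = ("A", "C", "G", "T")

ALL_CODONS: tuple[str, ...] = tuple("".join(c) for c in product(NUCLEOTIDES, repeat=3))

STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

N_SENSE = len(SENSE_CODONS)  # 61

#: codon string -> dense index in [0, 61)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in _COMPLEMENT for b in codon)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def codons_to_indices(codons) -> np.ndarray:
    """Encode an iterable of sense codons as an int array over [0, 61).

    Raises ``KeyError`` for stop codons or invalid triplets.
    """
    return np.fromiter((CODON_INDEX[c] for c in codons), dtype=np.int64)
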