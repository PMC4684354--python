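"""Coding-sequence containers and FASTA round-tripping.

A :class:`CodingSequenceSet` holds in-frame coding sequences, one record per
gene, each consisting of at least one sense codon followed by exactly one stop
codon.  It is the coordinate substrate for every downstream computation:
footprint positions are nucleotide offsets into these sequences, and all
codon-level statistics are indexed against them.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterator
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .genetic_code import STOP_CODONS, codons_to_indices, is_valid_codon


@dataclass(frozen=True)
class CodingSequence:
    """One in-frame CDS: ``gene_id``, sense codons, and the terminal stop."""

    gene_id: str
    sense_codons: tuple[str, ...]
    stop_codon: str

    def __post_init__(self) -> None:
        if not self.sense_codons:
            raise ValueError(f"{self.gene_id}: needs at least one sense codon")
        if self.stop_codon not in STOP_CODONS:
            raise ValueError(f"{self.gene_id}: {self.stop_codon!r} is not a stop codon")
        for c in self.sense_codons:
            if not is_valid_codon(c):
                raise ValueError(f"{self.gene_id}: invalid codon {c!r}")
            if c in STOP_CODONS:
                raise ValueError(f"{self.gene_id}: internal stop codon {c}")

    @property
    def sense_length(self) -> int:
        """Number of sense codons (stop excluded)."""
        return len(self.sense_codons)

    @property
    def nt_length(self) -> int:
        """Nucleotide length including the stop codon."""
        return 3 * (len(self.sense_codons) + 1)

    @property
    def sequence(self) -> str:
        return "".join(self.sense_codons) + self.stop_codon

    def codon_indices(self) -> np.ndarray:
        return codons_to_indices(self.sense_codons)


@dataclass
class CodingSequenceSet:
    """Ordered collection of :class:`CodingSequence` with unique gene ids."""

    records: list[CodingSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_ids in CodingSequenceSet")
        self._by_id = {r.gene_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CodingSequence]:
        return iter(self.records)

    def __getitem__(self, gene_id: str) -> CodingSequence:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def sense_lengths(self) -> dict[str, int]:
        return {r.gene_id: r.sense_length for r in self.records}


def cds_from_sequence(
    gene_id: str, seq: str, on_internal_stop: str = "raise"
) -> CodingSequence | None:
    """Split a nucleotide string into an in-frame :class:`CodingSequence`.

    The sequence must be a multiple of 3 nt, over ACGT, and end in a stop
    codon.  ``on_internal_stop`` selects what happens to records with a stop
    before the terminal codon: ``"raise"`` aborts, ``"warn"`` emits a warning
    and returns ``None`` (the record is skipped by :func:`read_cds_fasta`).
    """
    if on_internal_stop not in ("raise", "warn"):
        raise ValueError("on_internal_stop must be 'raise' or 'warn'")
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise FormatError(f"{gene_id}: length {len(seq)} is not a multiple of 3")
    if len(seq) < 6:
        raise FormatError(f"{gene_id}: too short for one sense codon plus stop")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for c in codons:
        if not is_valid_codon(c):
            raise FormatError(f"{gene_id}: non-ACGT codon {c!r}")
    if codons[-1] not in STOP_CODONS:
        raise FormatError(f"{gene_id}: does not end in a stop codon")
    internal = [i for i, c in enumerate(codons[:-1]) if c in STOP_CODONS]
    if internal:
        msg = f"{gene_id}: internal stop codon at codon {internal[0]}"
        if on_internal_stop == "raise":
            raise FormatError(msg)
        warnings.warn(msg + "; record skipped", stacklevel=2)
        return None
    return CodingSequence(gene_id, tuple(codons[:-1]), codons[-1])


def read_cds_fasta(path, on_internal_stop: str = "raise") -> CodingSequenceSet:
    """Read a CDS FASTA (one in-frame record per gene) into a set."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parsed = cds_from_sequence(rec.id, str(rec.seq), on_internal_stop)
        if parsed is not None:
            records.append(parsed)
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return CodingSequenceSet(records)


def write_cds_fasta(cds: CodingSequenceSet, path) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in cds]
    SeqIO.write(recs, str(path), "fasta")
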