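"""From CDS-mapped footprint reads to A-site counts and relative enrichments.

The A-site assignment rule: reads of length 28 or 29 are assigned to the
in-frame codon closest to the nucleotide at (0-based) offset +15 from the
5' end of the read; reads of length 30 use offset +16.  "Closest in-frame
codon" is formalized as the nearest codon start: a nucleotide at distance 0
or 1 past a codon start belongs to that codon, distance 2 rounds up to the
next codon.  Distances over a 3-nt period are 0/1/2, so no ties exist.

Per-gene normalization divides each position's count by the mean count over
the *included* (edge-trimmed) interior, so the included-position mean of the
relative enrichment is exactly 1 for every retained gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .sequences import CodingSequenceSet

ACCEPTED_LENGTHS = (28, 29, 30)

#: 5' -> A-site nucleotide offset per accepted read length
A_SITE_NT_OFFSET = {28: 15, 29: 15, 30: 16}

READS_COLUMNS = ["gene_id", "five_prime_pos", "length_nt", "count"]


# ---------------------------------------------------------------------------
# read-set container & IO


def make_read_set(gene_id, five_prime_pos, length_nt, count) -> pd.DataFrame:
    """Assemble a footprint read set table from columns."""
    df = pd.DataFrame(
        {
            "gene_id": pd.Series(gene_id, dtype=str),
            "five_prime_pos": pd.Series(five_prime_pos, dtype=np.int64),
            "length_nt": pd.Series(length_nt, dtype=np.int64),
            "count": pd.Series(count, dtype=np.int64),
        }
    )
    validate_read_set(df)
    return df


def validate_read_set(reads: pd.DataFrame) -> None:
    missing = set(READS_COLUMNS) - set(reads.columns)
    if missing:
        raise FormatError(f"read set missing columns {sorted(missing)}")
    if len(reads) and int(reads["five_prime_pos"].min()) < 0:
        raise FormatError("negative five_prime_pos in read set")
    if len(reads) and int(reads["count"].min()) < 1:
        raise FormatError("read counts must be >= 1")


def read_footprints_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # surface parser failures with file context
        raise FormatError(f"{path}: {exc}") from exc
    validate_read_set(df)
    return df[READS_COLUMNS].astype(
        {"five_prime_pos": np.int64, "length_nt": np.int64, "count": np.int64}
    )


def write_footprints_tsv(reads: pd.DataFrame, path, header: str | None = None) -> None:
    validate_read_set(reads)
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        reads.to_csv(fh, sep="\t", index=False)


def read_footprints_sam(path, cds: CodingSequenceSet) -> pd.DataFrame:
    """Convert a SAM alignment against the CDS FASTA into a read set.

    Only primary, mapped, forward-strand alignments with fully matched
    (soft-clip-free) CIGARs are kept; everything else is dropped.
    """
    import pysam

    rows: dict[tuple[str, int, int], int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_reverse:
                continue
            if aln.cigartuples is None or any(op != 0 for op, _ in aln.cigartuples):
                continue  # require pure match: no soft clips or indels
            gene = aln.reference_name
            if gene not in cds:
                raise FormatError(f"{path}: alignment to unknown gene {gene!r}")
            key = (gene, aln.reference_start, aln.query_length)
            rows[key] = rows.get(key, 0) + 1
    if not rows:
        return make_read_set([], [], [], [])
    keys = sorted(rows)
    return make_read_set(
        [k[0] for k in keys],
        [k[1] for k in keys],
        [k[2] for k in keys],
        [rows[k] for k in keys],
    )


# ---------------------------------------------------------------------------
# A-site assignment


def assign_a_site(five_prime_pos: int, length_nt: int) -> tuple[int | None, str | None]:
    """Assign one read to its A-site codon index.

    Returns ``(codon_index, None)`` on success or ``(None, reason)`` where
    ``reason`` is ``"length"`` for an unaccepted read length.  Bounds against
    a particular gene are checked in :func:`counts_from_reads` (this function
    has no gene context), except that a negative position is an error.
    """
    if five_prime_pos < 0:
        raise ParameterError("five_prime_pos must be >= 0")
    if length_nt not in A_SITE_NT_OFFSET:
        return None, "length"
    nt = five_prime_pos + A_SITE_NT_OFFSET[length_nt]
    codon, frame = divmod(nt, 3)
    if frame == 2:  # distance 2 past a codon start rounds up to the next codon
        codon += 1
    return codon, None


def _assign_vectorized(five_prime_pos: np.ndarray, length_nt: np.ndarray) -> np.ndarray:
    """Vectorized assignment; unaccepted lengths yield -1."""
    offsets = np.full(length_nt.shape, -1, dtype=np.int64)
    for ln, off in A_SITE_NT_OFFSET.items():
        offsets[length_nt == ln] = off
    nt = five_prime_pos + offsets
    codon = nt // 3 + (nt % 3 == 2)
    codon[offsets < 0] = -1
    return codon


# ---------------------------------------------------------------------------
# counts & enrichment containers


@dataclass
class PositionCounts:
    """Per-gene vectors of A-site read counts over sense codon positions."""

    counts: dict[str, np.ndarray]
    rejections: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    def __getitem__(self, gene_id: str) -> np.ndarray:
        return self.counts[gene_id]

    def to_frame(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame({"gene_id": g, "codon_index": np.arange(v.size), "count": v})
            for g, v in self.counts.items()
        ]
        return pd.concat(parts, ignore_index=True)


@dataclass
class RelativeEnrichment:
    """Edge-masked, gene-mean-normalized enrichment vectors.

    ``values[g]`` has the gene's full sense length with NaN outside the
    inclusion mask; over included positions the mean is exactly 1.
    """

    values: dict[str, np.ndarray]
    edge_exclusion: int
    dropped_genes: list[str] = field(default_factory=list)

    def __getitem__(self, gene_id: str) -> np.ndarray:
        return self.values[gene_id]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for g, v in self.values.items():
            idx = np.flatnonzero(np.isfinite(v))
            parts.append(
                pd.DataFrame({"gene_id": g, "codon_index": idx, "enrichment": v[idx]})
            )
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=["gene_id", "codon_index", "enrichment"]
        )


# ---------------------------------------------------------------------------
# operations


def counts_from_reads(reads: pd.DataFrame, cds: CodingSequenceSet) -> PositionCounts:
    """Tally A-site assignments into per-gene position count vectors.

    Reads with unaccepted lengths are tallied under ``"length"``; assignments
    falling outside the sense codon range are tallied under ``"bounds"``.
    Retained + rejected counts always reconcile with the input total.
    """
    validate_read_set(reads)
    reads = reads.reset_index(drop=True)
    unknown = set(reads["gene_id"].unique()) - set(cds.gene_ids)
    if unknown:
        raise FormatError(f"reads reference unknown gene_ids: {sorted(unknown)[:5]}")

    counts = {r.gene_id: np.zeros(r.sense_length, dtype=np.int64) for r in cds}
    rejections = {"length": 0, "bounds": 0}
    if not len(reads):
        return PositionCounts(counts, rejections)

    pos = reads["five_prime_pos"].to_numpy(np.int64)
    if pos.min() < 0:
        raise ParameterError("negative five_prime_pos")
    assigned = _assign_vectorized(pos, reads["length_nt"].to_numpy(np.int64))
    n = reads["count"].to_numpy(np.int64)
    bad_len = assigned < 0
    rejections["length"] = int(n[bad_len].sum())

    lengths = cds.sense_lengths()
    for gene_id, sub in reads.loc[~bad_len].groupby(
        reads.loc[~bad_len, "gene_id"], sort=False
    ):
        a = assigned[sub.index.to_numpy()]
        c = sub["count"].to_numpy(np.int64)
        ok = (a >= 0) & (a < lengths[gene_id])
        rejections["bounds"] += int(c[~ok].sum())
        np.add.at(counts[gene_id], a[ok], c[ok])
    return PositionCounts(counts, rejections)


def relative_enrichment(
    counts: PositionCounts, edge_exclusion: int, min_included_reads: int = 1
) -> RelativeEnrichment:
    """Normalize counts to per-gene relative enrichments over the interior.

    ``edge_exclusion`` codons are masked at both ends of every gene.  Genes
    whose interior is empty, or whose interior read total falls below
    ``min_included_reads``, are dropped (recorded in ``dropped_genes``).
    """
    if edge_exclusion < 0:
        raise ParameterError("edge_exclusion must be >= 0")
    values: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for gene_id, c in counts.counts.items():
        lo, hi = edge_exclusion, c.size - edge_exclusion
        if hi - lo <= 0:
            dropped.append(gene_id)
            continue
        interior = c[lo:hi]
        total = int(interior.sum())
        if total < min_included_reads or total == 0:
            dropped.append(gene_id)
            continue
        mean = interior.mean()
        e = np.full(c.size, np.nan)
        e[lo:hi] = interior / mean
        values[gene_id] = e
    return RelativeEnrichment(values, edge_exclusion, dropped)


def gene_rpkm(counts: PositionCounts, cds: CodingSequenceSet) -> pd.Series:
    """Reads per kilobase of sense sequence per million mapped reads."""
    total = counts.total()
    if total <= 0:
        raise ParameterError("no mapped reads: RPKM undefined")
    out = {}
    for gene_id, c in counts.counts.items():
        kb = 3 * cds[gene_id].sense_length / 1000.0
        out[gene_id] = (int(c.sum()) / kb) / (total / 1e6)
    return pd.Series(out, name="rpkm")
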