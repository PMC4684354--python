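"""Codon-specific elongation rates.

:class:`ElongationRates` maps each of the 61 sense codons to its mean dwell
time — the mean of the exponential waiting time a ribosome spends with that
codon in its A-site before translocating.  Dwell times are relative units;
normalizing the mean dwell to 1 over codon usage makes the simulation clock
read in "mean elongation cycles".  The stepping rate of codon ``c`` is
``1 / dwell[c]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genetic_code import CODON_INDEX, N_SENSE, SENSE_CODONS


@dataclass(frozen=True)
class ElongationRates:
    """Per-codon mean dwell times covering all 61 sense codons."""

    dwell: pd.Series  # index: codon string, value: mean dwell time

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.dwell.index)
        if missing:
            raise ParameterError(f"dwell table missing {len(missing)} sense codons")
        vals = self.dwell.loc[list(SENSE_CODONS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ParameterError("dwell times must be strictly positive and finite")
        # canonical codon order, immutable backing vector
        object.__setattr__(self, "dwell", pd.Series(vals, index=list(SENSE_CODONS), name="dwell"))

    @classmethod
    def from_mapping(cls, mapping) -> "ElongationRates":
        return cls(pd.Series(mapping, dtype=float))

    @classmethod
    def uniform(cls, value: float = 1.0) -> "ElongationRates":
        return cls(pd.Series(value, index=list(SENSE_CODONS), dtype=float))

    @classmethod
    def from_vector(cls, vector: np.ndarray) -> "ElongationRates":
        """Build from a length-61 vector in :data:`SENSE_CODONS` order."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (N_SENSE,):
            raise ParameterError(f"expected a length-{N_SENSE} vector")
        return cls(pd.Series(vector, index=list(SENSE_CODONS)))

    def vector(self) -> np.ndarray:
        """Dwell times as a length-61 array in :data:`SENSE_CODONS` order."""
        return self.dwell.to_numpy(copy=True)

    def __getitem__(self, codon: str) -> float:
        return float(self.dwell[codon])

    def normalized(self, weights: np.ndarray | None = None) -> "ElongationRates":
        """Rescale so the (weighted) mean dwell over codons equals 1."""
        v = self.vector()
        if weights is None:
            mean = v.mean()
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != v.shape or w.sum() <= 0:
                raise ParameterError("weights must be a nonnegative length-61 vector")
            mean = float(np.dot(v, w) / w.sum())
        return ElongationRates.from_vector(v / mean)

    def per_position(self, codon_indices: np.ndarray) -> np.ndarray:
        """Dwell time of each position given its codon index."""
        return self.vector()[codon_indices]


def read_rates_tsv(path) -> ElongationRates:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"codon", "dwell"} <= set(df.columns):
        from .errors import FormatError

        raise FormatError(f"{path}: expected columns 'codon' and 'dwell'")
    return ElongationRates(df.set_index("codon")["dwell"])


def write_rates_tsv(rates: ElongationRates, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        rates.dwell.rename_axis("codon").reset_index().to_csv(fh, sep="\t", index=False)


def codon_index_or_raise(codon: str) -> int:
    try:
        return CODON_INDEX[codon]
    except KeyError:
        raise ParameterError(f"{codon!r} is not a sense codon") from None
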