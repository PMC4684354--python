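import numpy as np
import pandas as pd
import pytest

import ribowave as rw
from ribowave.genetic_code import SENSE_CODONS


@pytest.fixture
def toy_cds() -> rw.CodingSequenceSet:
    """Two tiny genes with hand-checkable codon content."""
    return rw.CodingSequenceSet(
        [
            rw.CodingSequence(
                "gene1",
                ("ATG", "GCT", "CGA", "GCT", "AAA", "CGA", "GCT", "TTG",
                 "AAA", "GCT", "CGA", "ATG"),
                "TAA",
            ),
            rw.CodingSequence(
                "gene2",
                ("ATG", "AAA", "GCT", "CGA", "TTG", "TTG", "GCT", "AAA"),
                "TGA",
            ),
        ]
    )


@pytest.fixture
def uniform_rates() -> rw.ElongationRates:
    return rw.ElongationRates.uniform(1.0)


@pytest.fixture
def slow_cga_rates() -> rw.ElongationRates:
    dwell = pd.Series(1.0, index=list(SENSE_CODONS))
    dwell["CGA"] = 4.0
    return rw.ElongationRates(dwell)


def brute_force_offset_profile(enrichment, cds, offsets):
    """O(genes x positions x offsets) reference implementation of E[X, d]."""
    sums = {(x, d): 0.0 for x in SENSE_CODONS for d in offsets}
    counts = {(x, d): 0 for x in SENSE_CODONS for d in offsets}
    for gene_id, e in enrichment.values.items():
        codons = cds[gene_id].sense_codons
        n = len(codons)
        for p in range(n):
            if not np.isfinite(e[p]):
                continue
            for d in offsets:
                anchor = p - d
                if 0 <= anchor < n and np.isfinite(e[anchor]):
                    x = codons[anchor]
                    sums[(x, d)] += e[p]
                    counts[(x, d)] += 1
    E = pd.DataFrame(np.nan, index=list(SENSE_CODONS), columns=list(offsets))
    N = pd.DataFrame(0, index=list(SENSE_CODONS), columns=list(offsets))
    for (x, d), c in counts.items():
        N.loc[x, d] = c
        if c:
            E.loc[x, d] = sums[(x, d)] / c
    return E, N
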