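"""Synthetic transcriptomes, dwell-time schemes, and matched experiments.

This module manufactures data with the statistical structure the analysis
assumes, so every downstream stage can be exercised and validated without
external sequencing data:

- a transcriptome of in-frame coding sequences with controlled codon usage;
- a pair of codon dwell-time schemes: "pre" dwell times that increase with
  1/tAI (non-optimal codons decode slowly, as measured without the drug) and
  "post" dwell times whose rank order is tunably anticorrelated with the pre
  scheme (the disrupted dynamics during cycloheximide exposure);
- a matched pair of footprint experiments: one sampled from the
  pre-treatment steady state, one sampled after switching every codon's
  dwell time and letting elongation continue for a bounded duration.

All footprint reads are rendered at 28 nt with the 5' end exactly 15 nt
upstream of the A-site codon start, so the assignment rule recovers the
simulated ribosome positions exactly; read-length heterogeneity is exercised
separately in the assignment unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genetic_code import N_SENSE, SENSE_CODONS, STOP_CODONS
from .rates import ElongationRates
from .sequences import CodingSequence, CodingSequenceSet
from .simulate import _advance, _FlatCDS
from .stats import TAITable


@dataclass(frozen=True)
class RateScheme:
    """Paired pre/post dwell-time tables over all 61 sense codons."""

    pre: ElongationRates
    post: ElongationRates
    label: str = ""


# ---------------------------------------------------------------------------
# codon frequency and tAI helpers


def uniform_codon_frequencies() -> pd.Series:
    return pd.Series(1.0 / N_SENSE, index=list(SENSE_CODONS), name="frequency")


def dirichlet_codon_frequencies(alpha: float = 5.0, seed: int = 0) -> pd.Series:
    """Non-uniform synthetic codon usage drawn from a symmetric Dirichlet.

    ``alpha ~ 5`` gives usage heterogeneity of the magnitude seen in real
    transcriptomes (a few-fold spread between common and rare codons).
    """
    rng = np.random.default_rng(seed)
    return pd.Series(
        rng.dirichlet(np.full(N_SENSE, float(alpha))), index=list(SENSE_CODONS),
        name="frequency",
    )


def synthetic_tai_table(seed: int = 0, log_range: float = 3.0) -> TAITable:
    """A synthetic tRNA adaptation index table spanning a realistic range.

    Values are log-uniform over ``exp(-log_range)..1`` and renormalized so
    the best codon has tAI exactly 1, mimicking the wide dynamic range of
    genomic tRNA availabilities without bundling any genome's tRNA counts.
    """
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.uniform(-float(log_range), 0.0, size=N_SENSE))
    tai = pd.Series(raw / raw.max(), index=list(SENSE_CODONS), name="tai")
    return TAITable(tai=tai, weights=tai.copy(), tgcn={}, penalties={})


# ---------------------------------------------------------------------------
# operations


def generate_transcriptome(
    n_genes: int,
    length_distribution: tuple[int, int] = (450, 550),
    codon_frequencies: pd.Series | None = None,
    seed: int = 0,
) -> CodingSequenceSet:
    """Random in-frame coding sequences with iid codon usage.

    ``length_distribution`` is an inclusive (min, max) range of sense-codon
    counts, drawn uniformly; a stop codon is appended to every gene.  The
    default 450-550 leaves a usable interior even under wide edge exclusion.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    lo, hi = int(length_distribution[0]), int(length_distribution[1])
    if lo < 1:
        raise ParameterError("minimum sense length must be >= 1")
    if hi < lo:
        raise ParameterError("max length < min length")
    freq = uniform_codon_frequencies() if codon_frequencies is None else pd.Series(
        codon_frequencies, dtype=float
    )
    if set(freq.index) != set(SENSE_CODONS):
        raise ParameterError("codon_frequencies must cover exactly the 61 sense codons")
    p = freq.loc[list(SENSE_CODONS)].to_numpy(dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ParameterError("codon frequencies must be nonnegative and sum to 1 (tol 1e-9)")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    records = []
    for g in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        codons = tuple(SENSE_CODONS[i] for i in rng.choice(N_SENSE, size=length, p=p))
        stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
        records.append(CodingSequence(f"g{g + 1:0{width}d}", codons, stop))
    return CodingSequenceSet(records)


def generate_rate_scheme(
    tai_table: TAITable,
    anticorrelation: float = -1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    codon_frequencies: pd.Series | None = None,
    label: str = "",
) -> RateScheme:
    """Build pre/post dwell-time schemes anchored to 1/tAI.

    Pre dwell times are ``(1/tAI) * exp(noise_sd * N(0,1))`` — a positive
    monotone transform of 1/tAI with lognormal noise, so at ``noise_sd=0``
    the pre scheme ranks exactly like 1/tAI.  Post dwell times share the
    dynamic range of the pre scheme but their log-scale codon scores are the
    Gaussian blend ``a*z + sqrt(1-a^2)*g`` with ``a = anticorrelation``, so
    their rank correlation with the pre scheme has the sign (and roughly the
    magnitude) of ``a``; at ``a = -1`` it is exactly -1.  Both schemes are
    normalized to mean dwell 1 over codon usage (uniform by default).
    """
    if not -1.0 <= anticorrelation <= 1.0:
        raise ParameterError("anticorrelation must be in [-1, 1]")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    tai = tai_table.tai.loc[list(SENSE_CODONS)].to_numpy(dtype=float)
    if np.any(tai <= 0):
        raise ParameterError("tAI values must be positive")
    rng = np.random.default_rng(seed)
    log_pre = np.log(1.0 / tai) + noise_sd * rng.standard_normal(N_SENSE)
    mu, sd = log_pre.mean(), log_pre.std()
    z = (log_pre - mu) / sd if sd > 0 else np.zeros(N_SENSE)
    a = float(anticorrelation)
    blend = a * z + np.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal(N_SENSE)
    log_post = mu + sd * blend

    weights = None
    if codon_frequencies is not None:
        weights = pd.Series(codon_frequencies, dtype=float).loc[list(SENSE_CODONS)].to_numpy()
    pre = ElongationRates.from_vector(np.exp(log_pre)).normalized(weights)
    post = ElongationRates.from_vector(np.exp(log_post)).normalized(weights)
    return RateScheme(pre=pre, post=post, label=label)


def generate_experiment_pair(
    cds: CodingSequenceSet,
    scheme: RateScheme,
    n_footprints: int,
    chx_duration: float,
    seed: int = 0,
    initiation_weights: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched no-drug / drug footprint experiments from one transcriptome.

    The first read set samples the steady state under ``scheme.pre``; the
    second samples ribosome positions ``chx_duration`` mean-dwell units after
    a global switch to ``scheme.post`` (including ribosomes that initiated
    inside the window).  Both are rendered as 28-nt reads; sampling continues
    until exactly ``n_footprints`` renderable footprints per condition.
    """
    if n_footprints < 1:
        raise ParameterError("n_footprints must be >= 1")
    if chx_duration < 0:
        raise ParameterError("chx_duration must be >= 0")
    flat = _FlatCDS(cds)
    if initiation_weights is None:
        gene_w = np.ones(len(flat.gene_ids))
    else:
        gene_w = pd.Series(initiation_weights, dtype=float).loc[list(flat.gene_ids)].to_numpy()
        if np.any(gene_w <= 0):
            raise ParameterError("initiation weights must be positive")
    rng = np.random.default_rng(seed)

    dwell_pre = flat.dwell_flat(scheme.pre)
    dwell_post = flat.dwell_flat(scheme.post)
    w_pos = dwell_pre * np.repeat(gene_w, flat.lengths)
    p_pos = w_pos / w_pos.sum()

    no_chx = _sample_steady_reads(flat, p_pos, n_footprints, rng)
    chx = _sample_switched_reads(
        flat, p_pos, gene_w, dwell_pre, dwell_post, chx_duration, n_footprints, rng
    )
    return no_chx, chx


def _renderable(flat: _FlatCDS, gene: np.ndarray, a: np.ndarray) -> np.ndarray:
    # 28-nt read spanning [3a-15, 3a+13) must fit inside the CDS (stop included)
    return (a >= 5) & (3 * a + 13 <= 3 * (flat.lengths[gene] + 1))


def _reads_from_positions(flat: _FlatCDS, gene: np.ndarray, a: np.ndarray) -> pd.DataFrame:
    from .footprints import make_read_set

    five_prime = 3 * a - 15
    order = np.lexsort((five_prime, gene))
    gene, five_prime = gene[order], five_prime[order]
    boundary = np.flatnonzero(
        np.concatenate([[True], (np.diff(gene) != 0) | (np.diff(five_prime) != 0)])
    )
    counts = np.diff(np.concatenate([boundary, [gene.size]]))
    return make_read_set(
        [flat.gene_ids[g] for g in gene[boundary]],
        five_prime[boundary],
        np.full(boundary.shape, 28, dtype=np.int64),
        counts,
    )


def _sample_steady_reads(flat, p_pos, n, rng) -> pd.DataFrame:
    genes_out, a_out, have = [], [], 0
    while have < n:
        batch = max(int((n - have) * 1.2) + 100, 1000)
        pos = rng.choice(flat.n_positions, size=batch, p=p_pos)
        gene = np.searchsorted(flat.offsets, pos, side="right") - 1
        a = pos - flat.offsets[gene]
        ok = _renderable(flat, gene, a)
        genes_out.append(gene[ok])
        a_out.append(a[ok])
        have += int(ok.sum())
    gene = np.concatenate(genes_out)[:n]
    a = np.concatenate(a_out)[:n]
    return _reads_from_positions(flat, gene, a)


def _sample_switched_reads(
    flat, p_pos, gene_w, dwell_pre, dwell_post, duration, n, rng
) -> pd.DataFrame:
    """Sample renderable positions from the post-switch snapshot.

    The snapshot mixes survivors of the old steady state with ribosomes that
    initiated inside the window.  Per unit initiation rate, a gene's
    stationary mass is ``w_g * T_g`` (``T_g`` = summed pre dwell over the
    gene) and its window-initiation mass is ``w_g * duration``; a sampled
    ribosome is a window initiation with the corresponding probability.
    Terminated ribosomes are discarded, matching instantaneous termination.
    """
    ends = flat.offsets + flat.lengths
    T = np.array([dwell_pre[s:e].sum() for s, e in zip(flat.offsets, ends)])
    mass_existing = float(np.dot(gene_w, T))
    mass_new = float(duration * gene_w.sum())
    frac_new = mass_new / (mass_existing + mass_new)
    p_gene = gene_w / gene_w.sum()

    genes_out, a_out, have = [], [], 0
    while have < n:
        batch = max(int((n - have) * 1.4) + 100, 1000)
        n_new = int(rng.binomial(batch, frac_new))
        n_old = batch - n_new
        pos = rng.choice(flat.n_positions, size=n_old, p=p_pos)
        gene_old = np.searchsorted(flat.offsets, pos, side="right") - 1
        a_old = pos - flat.offsets[gene_old]
        dur_old = np.full(n_old, float(duration))
        gene_new = rng.choice(len(flat.gene_ids), size=n_new, p=p_gene)
        a_new = np.zeros(n_new, dtype=np.int64)
        dur_new = rng.uniform(0.0, duration, size=n_new) if duration > 0 else np.zeros(n_new)

        gene = np.concatenate([gene_old, gene_new])
        a = np.concatenate([a_old, a_new])
        dur = np.concatenate([dur_old, dur_new])
        a_fin, terminated, _ = _advance(flat, gene, a, dur, dwell_post, rng)
        ok = ~terminated & _renderable(flat, gene, a_fin)
        genes_out.append(gene[ok])
        a_out.append(a_fin[ok])
        have += int(ok.sum())
    gene = np.concatenate(genes_out)[:n]
    a = np.concatenate(a_out)[:n]
    return _reads_from_positions(flat, gene, a)
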