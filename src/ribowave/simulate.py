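"""Stochastic simulation of translation elongation.

Ribosomes traverse coding sequences codon by codon, waiting an exponentially
distributed time at each position with mean equal to the dwell time of the
codon in the A-site.  Initiation is a Poisson process per gene; termination is
instantaneous at the stop codon.

With steric exclusion disabled (the default), ribosomes are independent
particles and the model is a network of M/M/inf queues: the stationary
occupancy of position ``i`` is Poisson with mean
``initiation_rate * dwell(codon_i)``, independent across positions.  The
simulator exploits this product form to draw exact stationary snapshots
without burn-in, and propagates each ribosome forward independently after a
rate switch.  With exclusion enabled, an exact event-driven (Gillespie)
simulation is used instead; it is intended for small robustness studies, not
for transcriptome-scale sampling.

The CHX experiment is modeled by :func:`simulate_rate_switch`: equilibrate
under pre-treatment dwell times, switch every codon's dwell time, let
elongation continue for a bounded duration, then photograph all ribosomes.
The rejected null model (:func:`simulate_exponential_arrest`) instead freezes
each ribosome after its own exponential waiting time with *unchanged* rates,
which by memorylessness reproduces the stationary snapshot and hence predicts
no downstream waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .rates import ElongationRates
from .sequences import CodingSequenceSet


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation parameters.

    ``initiation_rate`` is per gene per unit time (mean-dwell units);
    ``exclusion_footprint`` in codons, 0 disables steric exclusion;
    ``n_cells`` independent replicate systems; ``burn_in`` only matters for
    the event-driven path (the product-form sampler is exact).
    """

    initiation_rate: float = 0.05
    exclusion_footprint: int = 0
    n_cells: int = 1
    burn_in: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initiation_rate <= 0:
            raise ParameterError("initiation_rate must be > 0")
        if self.exclusion_footprint < 0:
            raise ParameterError("exclusion_footprint must be >= 0")
        if self.burn_in < 0:
            raise ParameterError("burn_in must be >= 0")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")


@dataclass
class RibosomeSnapshot:
    """Positions of all ribosomes at one instant.

    ``gene_index`` indexes into ``gene_ids``; ``a_site`` is the 0-based sense
    codon index under the A-site.  ``n_elongation_events`` counts elongation
    steps taken during a finite simulated window (None for instantaneous
    stationary draws).
    """

    gene_ids: tuple[str, ...]
    gene_index: np.ndarray
    a_site: np.ndarray
    n_elongation_events: int | None = None
    n_tracked: int | None = None

    def __len__(self) -> int:
        return int(self.a_site.size)

    def occupancies(self):
        for g, a in zip(self.gene_index, self.a_site):
            yield self.gene_ids[g], int(a)


class _FlatCDS:
    """Concatenated per-position codon indices for vectorized simulation."""

    def __init__(self, cds: CodingSequenceSet):
        self.gene_ids = tuple(cds.gene_ids)
        self.lengths = np.array([r.sense_length for r in cds], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)[:-1]])
        self.codon_idx = np.concatenate([r.codon_indices() for r in cds])
        self.n_positions = int(self.lengths.sum())

    def dwell_flat(self, rates: ElongationRates) -> np.ndarray:
        return rates.per_position(self.codon_idx)


def _stationary_position_weights(flat: _FlatCDS, rates: ElongationRates,
                                 gene_rates: np.ndarray) -> np.ndarray:
    """Unnormalized stationary occupancy mass per flat position."""
    dwell = flat.dwell_flat(rates)
    return dwell * np.repeat(gene_rates, flat.lengths)


def _gene_initiation_rates(flat: _FlatCDS, config: SimulationConfig) -> np.ndarray:
    return np.full(len(flat.gene_ids), config.initiation_rate * config.n_cells)


def _positions_to_snapshot(flat: _FlatCDS, flat_pos: np.ndarray, **kw) -> RibosomeSnapshot:
    gene = np.searchsorted(flat.offsets, flat_pos, side="right") - 1
    a = flat_pos - flat.offsets[gene]
    return RibosomeSnapshot(flat.gene_ids, gene, a, **kw)


def _advance(
    flat: _FlatCDS,
    gene: np.ndarray,
    a: np.ndarray,
    durations: np.ndarray,
    dwell_flat: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Propagate independent ribosomes forward for per-ribosome durations.

    Returns (final a_site, terminated mask, elongation event count).  A
    ribosome stepping past its last sense codon terminates instantly.
    """
    a = a.astype(np.int64).copy()
    t = durations.astype(float).copy()
    end = flat.lengths[gene]
    off = flat.offsets[gene]
    events = 0
    active = np.flatnonzero((t > 0) & (a < end))
    while active.size:
        w = rng.exponential(dwell_flat[off[active] + a[active]])
        move = w < t[active]
        movers = active[move]
        t[movers] -= w[move]
        t[active[~move]] = 0.0
        a[movers] += 1
        events += movers.size
        still = movers[(a[movers] < end[movers]) & (t[movers] > 0)]
        active = still
    terminated = a >= end
    return a, terminated, events


# ---------------------------------------------------------------------------
# public operations (independent-particle fast path + Gillespie)


def simulate_steady_state(
    cds: CodingSequenceSet,
    rates: ElongationRates,
    config: SimulationConfig,
    sample_time: float | None = None,
) -> RibosomeSnapshot:
    """Draw one snapshot from the stationary law of the elongation process."""
    if sample_time is not None and sample_time < config.burn_in:
        raise ParameterError("sample_time must be >= burn_in")
    if config.exclusion_footprint > 0:
        t = config.burn_in if sample_time is None else sample_time
        return _gillespie(cds, rates, rates, config, max(t, config.burn_in), 0.0)
    flat = _FlatCDS(cds)
    rng = np.random.default_rng(config.seed)
    lam = _stationary_position_weights(flat, rates, _gene_initiation_rates(flat, config))
    counts = rng.poisson(lam)
    flat_pos = np.repeat(np.arange(flat.n_positions), counts)
    return _positions_to_snapshot(flat, flat_pos)


def simulate_rate_switch(
    cds: CodingSequenceSet,
    rates_pre: ElongationRates,
    rates_post: ElongationRates,
    config: SimulationConfig,
    switch_duration: float,
) -> RibosomeSnapshot:
    """Equilibrate under ``rates_pre``, switch, elongate for a bounded time.

    ``switch_duration == 0`` reduces exactly to
    :func:`simulate_steady_state` under ``rates_pre``.
    """
    if switch_duration < 0:
        raise ParameterError("switch_duration must be >= 0")
    if config.exclusion_footprint > 0:
        return _gillespie(cds, rates_pre, rates_post, config, config.burn_in, switch_duration)
    flat = _FlatCDS(cds)
    rng = np.random.default_rng(config.seed)
    gene_rates = _gene_initiation_rates(flat, config)

    lam = _stationary_position_weights(flat, rates_pre, gene_rates)
    counts = rng.poisson(lam)
    flat_pos = np.repeat(np.arange(flat.n_positions), counts)
    gene0 = np.searchsorted(flat.offsets, flat_pos, side="right") - 1
    a0 = flat_pos - flat.offsets[gene0]
    dur0 = np.full(a0.shape, switch_duration)

    # ribosomes initiating inside the window elongate only for the time left
    n_new = rng.poisson(gene_rates * switch_duration)
    gene1 = np.repeat(np.arange(len(flat.gene_ids)), n_new)
    a1 = np.zeros(gene1.shape, dtype=np.int64)
    dur1 = rng.uniform(0.0, switch_duration, size=gene1.shape)

    gene = np.concatenate([gene0, gene1])
    a = np.concatenate([a0, a1])
    dur = np.concatenate([dur0, dur1])
    dwell_post = flat.dwell_flat(rates_post)
    a_final, terminated, events = _advance(flat, gene, a, dur, dwell_post, rng)
    keep = ~terminated
    return RibosomeSnapshot(
        flat.gene_ids,
        gene[keep],
        a_final[keep],
        n_elongation_events=events,
        n_tracked=int(a.size),
    )


def simulate_exponential_arrest(
    cds: CodingSequenceSet,
    rates: ElongationRates,
    arrest_rate: float,
    config: SimulationConfig,
) -> RibosomeSnapshot:
    """Freeze each ribosome after its own exponential arrest time.

    Rates are unchanged while waiting for arrest, so by memorylessness the
    frozen interior positions sample the same stationary law as an
    instantaneous snapshot: the null model predicting no downstream waves.
    Ribosomes reaching the stop codon before arrest terminate and are lost.
    """
    if arrest_rate <= 0:
        raise ParameterError("arrest_rate must be > 0")
    if config.exclusion_footprint > 0:
        raise ParameterError("exponential arrest is implemented for exclusion_footprint=0")
    flat = _FlatCDS(cds)
    rng = np.random.default_rng(config.seed)
    lam = _stationary_position_weights(flat, rates, _gene_initiation_rates(flat, config))
    counts = rng.poisson(lam)
    flat_pos = np.repeat(np.arange(flat.n_positions), counts)
    gene = np.searchsorted(flat.offsets, flat_pos, side="right") - 1
    a = flat_pos - flat.offsets[gene]
    durations = rng.exponential(1.0 / arrest_rate, size=a.shape)
    dwell = flat.dwell_flat(rates)
    a_final, terminated, events = _advance(flat, gene, a, durations, dwell, rng)
    keep = ~terminated
    return RibosomeSnapshot(
        flat.gene_ids,
        gene[keep],
        a_final[keep],
        n_elongation_events=events,
        n_tracked=int(a.size),
    )


def snapshot_to_reads(snapshot: RibosomeSnapshot, cds: CodingSequenceSet,
                      read_length: int = 28):
    """Render ribosome positions as footprint reads.

    The 5' end is placed ``3*a - 15`` nt into the CDS, which makes the
    length-specific A-site assignment rule (+15 for 28/29 nt, +16 for 30 nt)
    recover the simulated codon exactly.  Positions too close to either CDS
    edge for a full read are dropped and counted.

    Returns ``(reads, n_dropped)``.
    """
    from .footprints import A_SITE_NT_OFFSET, make_read_set

    if read_length not in A_SITE_NT_OFFSET:
        raise ParameterError(f"unsupported read length {read_length}")
    nt_lengths = np.array(
        [3 * (cds[g].sense_length + 1) for g in snapshot.gene_ids], dtype=np.int64
    )
    five_prime = 3 * snapshot.a_site.astype(np.int64) - 15
    ok = (five_prime >= 0) & (
        five_prime + read_length <= nt_lengths[snapshot.gene_index]
    )
    n_dropped = int((~ok).sum())
    gene = snapshot.gene_index[ok]
    pos = five_prime[ok]
    # aggregate identical (gene, pos) into counted records
    order = np.lexsort((pos, gene))
    gene, pos = gene[order], pos[order]
    if gene.size:
        boundary = np.flatnonzero(
            np.concatenate([[True], (np.diff(gene) != 0) | (np.diff(pos) != 0)])
        )
        counts = np.diff(np.concatenate([boundary, [gene.size]]))
        gene_u, pos_u = gene[boundary], pos[boundary]
    else:
        counts = np.array([], dtype=np.int64)
        gene_u = pos_u = np.array([], dtype=np.int64)
    reads = make_read_set(
        [snapshot.gene_ids[g] for g in gene_u],
        pos_u,
        np.full(pos_u.shape, read_length, dtype=np.int64),
        counts,
    )
    return reads, n_dropped


# ---------------------------------------------------------------------------
# event-driven simulation with steric exclusion


def _gillespie(
    cds: CodingSequenceSet,
    rates_pre: ElongationRates,
    rates_post: ElongationRates,
    config: SimulationConfig,
    burn_in: float,
    switch_duration: float,
) -> RibosomeSnapshot:
    """Exact SSA with steric exclusion; genes and cells are independent.

    The snapshot is taken at ``burn_in + switch_duration``; rates switch from
    pre to post at ``burn_in``.  Quadratic-ish per-event cost — intended for
    toy problems, not transcriptome scale.
    """
    flat = _FlatCDS(cds)
    ex = config.exclusion_footprint
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_cells)
    all_gene: list[int] = []
    all_a: list[int] = []
    events = 0
    for cell_seed in seeds:
        rng = np.random.default_rng(cell_seed)
        for g, rec in enumerate(cds):
            dwell_pre = rates_pre.per_position(rec.codon_indices())
            dwell_post = rates_post.per_position(rec.codon_indices())
            ribs: list[int] = []  # ascending codon positions
            t = 0.0
            t_end = burn_in + switch_duration
            L = rec.sense_length
            while True:
                dwell = dwell_pre if t < burn_in else dwell_post
                # candidate events: initiation + unblocked elongations
                rates_list = []
                moves = []
                can_initiate = (not ribs) or (ribs[0] >= max(ex, 1))
                if can_initiate:
                    rates_list.append(config.initiation_rate)
                    moves.append(-1)
                for i, p in enumerate(ribs):
                    ahead = ribs[i + 1] if i + 1 < len(ribs) else None
                    if ahead is None or ahead - p > ex:
                        rates_list.append(1.0 / dwell[p])
                        moves.append(i)
                total = float(np.sum(rates_list))
                if total <= 0:
                    break
                wait = rng.exponential(1.0 / total)
                if t < burn_in <= t + wait:
                    t = burn_in  # rates change mid-flight: restart clocks
                    continue
                if t + wait >= t_end:
                    break
                t += wait
                k = rng.choice(len(rates_list), p=np.asarray(rates_list) / total)
                if moves[k] == -1:
                    ribs.insert(0, 0)
                else:
                    i = moves[k]
                    ribs[i] += 1
                    events += 1
                    if ribs[i] >= L:
                        ribs.pop(i)
            all_gene.extend([g] * len(ribs))
            all_a.extend(ribs)
    return RibosomeSnapshot(
        flat.gene_ids,
        np.asarray(all_gene, dtype=np.int64),
        np.asarray(all_a, dtype=np.int64),
        n_elongation_events=events,
        n_tracked=None,
    )
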