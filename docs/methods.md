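# Methods

## Model

Translation elongation is modeled as a continuous-time Markov jump process:
a ribosome with codon `c` in its A-site waits `Exp(tau_c)` (mean dwell time
`tau_c`, relative units) before advancing one codon. Initiation is Poisson
with rate `lambda` per gene; termination is instantaneous at the stop codon.
The simulation clock is in mean-dwell units (mean dwell normalized to 1 over
codon usage), so durations read as "average elongation cycles"; absolute
time enters only when interpreting durations against the ~0.1–0.3 aa/s pace
of drug-disrupted elongation (natural elongation in yeast runs at 7–9 aa/s).

With steric exclusion disabled (the default), ribosomes are independent and
the system is an open network of M/M/∞ queues: stationary occupancies are
independent Poisson variables with mean `lambda * tau_i`. Two consequences
are exploited throughout:

- **Exact stationary sampling.** Steady-state snapshots are drawn directly
  from the product-form law (Poisson counts per position, or multinomial
  positions conditioned on a footprint total) rather than by burning in an
  event-driven simulation. This is not an approximation in this regime; it
  removes burn-in bias and makes transcriptome-scale sampling (10^6
  footprints) take seconds.
- **Independent forward propagation.** After a global dwell-time switch,
  each ribosome's residual dwell is memoryless, so the post-switch snapshot
  is obtained by advancing every ribosome independently under the new rates
  for the switch duration, plus Poisson-distributed initiations inside the
  window (entry times uniform). Ribosomes reaching the stop codon are
  removed.

An exact event-driven (Gillespie) path exists for `exclusion_footprint > 0`
(entry requires the first `exclusion_footprint` codons free; a ribosome may
step only if the gap ahead exceeds the footprint). It is intended for small
robustness checks; the analytic statements below hold in the no-exclusion
regime, which is also where "density proportional to dwell time" is exact.

The **exponential-arrest null** draws a stationary snapshot and advances
each ribosome under *unchanged* rates for its own `Exp(arrest_rate)` waiting
time before freezing it. By memorylessness the frozen interior positions
sample the stationary law again, so this model predicts no downstream waves
and unchanged occupancies — the property the acceptance suite verifies.
Only ribosomes present at drug addition are tracked; the resulting 5'-end
deficit extends ~`1/arrest_rate` codons (10 codons at the default 0.1) and
lies entirely inside the 90-codon edge exclusion.

## Analytic wave model

Expected density obeys `d rho_i/dt = k_{i-1} rho_{i-1} - k_i rho_i` with
`k = 1/tau_new`, inflow `J` at position 0, free outflow at the end, and
initial condition `rho(0) = J * tau_old`. The integrator is LSODA at
relative tolerance 1e-9 (stiff-safe; the default geometry is 201 positions
with the perturbed codon at index 100, leaving room for waves to travel
without boundary effects). For a perturbed codon in a uniform background of
rate `k_f`, the excess relaxes as a Poisson(`k_f t`) displacement kernel:
centroid `k_f t`, width `sqrt(k_f t)` — the signature used to cross-check
the stochastic simulator (centroids agree within 5% at 6000 replicate
cells). Wave summaries locate the origin at the position of largest dwell
change and report |excess|-weighted centroid/width and the signed net area
over downstream positions; the degenerate no-perturbation case is flagged
undefined rather than reported as a spurious center.

## Footprint processing

A-site assignment follows the length-specific rule: reads of 28 or 29 nt
target the nucleotide at 0-based offset +15 from the 5' end, 30-nt reads
offset +16; the target is assigned to the nearest codon start, with
distance 2 rounding up (distances over a 3-nt period are 0/1/2, so ties
cannot occur). A 28-nt read starting at CDS position 0 therefore reports
the sixth codon (1-based). Accepted lengths are fixed to {28, 29, 30}: the
library preps behind this protocol size-select ~27–29 nt, but no assignment
offset is defined for 27-nt reads, so they are rejected and tallied rather
than guessed at. Rejections are tallied by reason ("length", "bounds") and
retained + rejected always reconciles with the input total.

Relative enrichment divides each position's count by the mean over the
gene's *included* interior (edge exclusion of 90 codons by default, 200
whenever downstream wave areas are computed, matching the wider trim that
suppresses start-proximal codon-composition bias). Whether the original
normalization used the full CDS or the trimmed interior is ambiguous;
interior-only is implemented so that the included-position mean is exactly 1
for every retained gene, which downstream statistics rely on. Genes with an
empty interior or fewer than `min_included_reads` (default 1) interior reads
are dropped and logged.

Offset profiles `E[X, d]` average enrichments over all included positions
`p` with codon `X` at `p - d`, requiring both `p` and `p - d` inside the
inclusion mask; empty strata carry `n = 0` and undefined mean. Per-stratum
standard deviations are tracked so flatness tests can use proper standard
errors. The implementation concatenates genes with sentinel gaps and
accumulates each offset with one vectorized pass; a brute-force
triple-loop oracle in the test suite pins its output exactly.

## Wave analysis and CAE

For a window `[d_lo, d_hi]` (presets: 6–65 for matched-pair conservation,
7–90 for aggregate/corrected enrichment; `d_lo >= 3` enforced so the window
clears the tRNA binding sites), per codon:

- `delta_binding = sum_{d in {0,1,2}} (E_test - E_ref)`
- `wave_area = sum_{d in window} (E_test - E_ref)`
- `corrected_aggregate = sum_{d in {0,1,2}} E_test + wave_area`

The regression of `wave_area` on `delta_binding` across codons is OLS with
intercept. `E_ref` may be a matched control profile or the flat unit
baseline. A caveat discovered while validating the unit baseline: per-gene
normalization couples a codon's own dwell into its stratum baseline — genes
containing a slow codon have an elevated interior mean, depressing that
codon's stratum enrichments by roughly `(tau_X - 1)(1/61 + 1/M)` per offset
(`M` = included interior length). Summed over an 80-offset window this is
O(1) for interiors of ~100 codons and cancels about half the recovered
signal. With a matched reference the bias is identical in both profiles and
cancels exactly, so matched-pair mode is preferred whenever a control
exists; unit-baseline CAE is reliable only when `M` is large (hundreds of
codons of usable interior). The recovery analysis in the acceptance suite
uses the matched reference for this reason.

tAI is computed as `W_X = sum_a (1 - s_pairing) * tGCN_a` over the decoding
anticodons (cognate plus one wobble per codon third base, anticodon-34
against codon-3, genomic A34 read as inosine), normalized to max 1; built-in
default penalties follow the classic parameterization (`s_I:U = 0`,
`s_I:C = 0.28`, `s_I:A = 0.9999`, `s_G:U = 0.41`, `s_U:G = 0.68`), and any
codon with no positive-weight anticodon is an error rather than a silent
zero. Rank correlations against `1/tAI` are one-tailed for positive
association. Cross-experiment comparison uses Pearson correlations of
per-codon occupancies and UPGMA (average linkage on Euclidean row
distances), with rows pre-sorted lexicographically so distance ties resolve
identically everywhere; dendrograms serialize to ultrametric newick.

## Synthetic data: what it emulates, what it does not

The generator draws iid codons per gene (uniform frequencies by default; a
Dirichlet helper provides realistic few-fold usage heterogeneity), gene
lengths uniform on 450–550 sense codons — long enough to keep a usable
interior under the 200-codon trim without yeast-scale data — and a stop
codon per gene. Dwell schemes anchor pre-switch dwell times to `1/tAI` of a
synthetic tAI table (log-uniform over e^-3..1, spanning the realistic
dynamic range) with lognormal noise (`noise_sd = 0.1` default), and build
post-switch dwell times as a Gaussian blend in log space whose rank
correlation with the pre scheme has the sign and approximate magnitude of
the `anticorrelation` parameter (−1 default, reproducing the observed
inversion of occupancy ranks under the drug). Both schemes are normalized
to mean dwell 1. Footprints are rendered as 28-nt reads with the 5' end 15
nt upstream of the A-site codon start, so assignment recovers simulated
positions exactly; length heterogeneity is exercised separately in unit
tests. Initiation is uniform across genes by default (per-gene weights
configurable) since per-gene normalization removes expression differences.

Not emulated: UTRs, uneven nuclease digestion, ligation bias, multi-mapped
reads, ribosome drop-off, frameshifting, or collision-dependent kinetics.
Passing tests therefore demonstrate correctness of the inference machinery
under the model's own assumptions, not robustness to library-prep artifacts
of real data.

## Study scales and numerical choices

The acceptance-level analyses run at 200 genes × 450–550 codons and 10^6
footprints per condition — the scale at which every stage (including the
10^6-ribosome arrest and steady-state ensembles, via the product-form
sampler) completes in seconds. At this scale the per-codon wave-area noise
is dominated by codon-composition variance of the per-position dwell change
(strata of ~330 positions per codon-offset after the 200-codon trim), which
places the conservation fit's r^2 near 0.85 with slope scattering a few
percent around −1; the corresponding real-data analyses, with ~25× more
usable positions, sit at 0.85–0.93. Pretreatment durations for the
duration-proportionality analysis are 24 and 54 mean-dwell units (4 and 9
minutes at ~6 codons/min of disrupted elongation), placing peak centers at
~25 and ~55 codons — inside the 7–50-codon range observed across published
datasets — where the window truncation at offset 6 biases the nearer center
by well under a codon.

Other numerics: exact footprint totals are achieved by rejection-sampling
renderable positions (positions within 5 codons of the start or 3 of the
stop cannot carry a full 28-nt read and are redrawn); identical reads are
aggregated into counted records; all randomness flows from explicit integer
seeds through `numpy` Generators (per-cell substreams for the event-driven
path), making every output bit-reproducible; TSV outputs carry version,
seed, and a parameter hash in a comment header.

## Known limitations

- Unit-baseline CAE bias at short interiors (above); use matched controls
  at desk scale.
- The arrest null supports only the no-exclusion regime, where the
  memorylessness argument is exact.
- The event-driven exclusion path is quadratic-ish per event and meant for
  toy geometries, not transcriptome-scale ensembles.
- Peak centroids computed with |excess| weighting acquire an upward bias
  from sampling noise far from the peak; comparisons against the analytic
  model in the test suite use signed weighting over a bounded window for
  this reason.
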