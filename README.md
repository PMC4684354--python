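# ribowave

Codon-level analysis of ribosome profiling data, built around a specific
artifact of the standard yeast protocol: pretreatment with cycloheximide
(CHX) does not freeze ribosomes in place. Elongation continues for many
cycles under drug-disrupted, codon-specific rates, which rewrites the
apparent A/P/E-site occupancies and launches transient **waves** of ribosome
density downstream of every codon whose dwell time changed. `ribowave`
computes the profiles that expose these waves, quantifies them, tests the
conservation relation that identifies them as transport transients, and uses
them to recover pre-disruption decode times.

Intended users: computational biologists analyzing CDS-mapped ribosome
footprint data, and anyone who wants a self-contained, simulation-backed
test bed for codon dwell-time inference artifacts.

## The model in brief

Ribosomes wait an exponentially distributed time at each codon position,
with mean dwell time `tau_c` depending only on the A-site codon `c`. With
initiation flux `J` and no steric exclusion, the stationary density at
position `i` is

    rho_i = J * tau_i,

so footprint counts measure dwell times. Relative enrichment divides each
position's A-site count by its gene's (edge-trimmed) mean; the offset
profile `E[X, d]` averages enrichments at all positions exactly `d` codons
downstream of occurrences of codon `X` (offsets 0/+1/+2 are the A/P/E
sites). If at `t = 0` the dwell times switch from `tau_pre` to `tau_post`
and elongation continues for a time `t`, the master equation

    d rho_i / dt = k_{i-1} rho_{i-1} - k_i rho_i,   k_i = 1 / tau_post_i

relaxes each codon's stationary excess `J (tau_pre - tau_post)` into a wave
that advances at the local stepping rate and spreads like a Poisson kernel
(centroid `k t`, width `sqrt(k t)`). Mass conservation then predicts, per
codon identity,

    sum_{d in {0,1,2}} dE[X, d]  +  sum_{d in window} dE[X, d]  =  0,

i.e. an ordinary least-squares fit of downstream wave area on summed
binding-site change across the 61 codons has slope −1. Adding each codon's
wave area back onto its remaining binding-site enrichment (the *corrected
aggregate enrichment*, CAE) estimates its total pre-disruption decode time;
CAE restores the positive rank correlation with `1/tAI` (tRNA adaptation
index) that raw CHX occupancies lack. The rejected null model — each
ribosome elongating unchanged until an exponential arrest event — merely
resamples the stationary law and predicts no waves at all.

## Worked example

```python
import ribowave as rw

cds = rw.generate_transcriptome(200, (450, 550), seed=0)
tai = rw.synthetic_tai_table(seed=100)
scheme = rw.generate_rate_scheme(tai, anticorrelation=-1.0, noise_sd=0.1, seed=200)
no_chx, chx = rw.generate_experiment_pair(cds, scheme, 1_000_000, 15.0, seed=300)

profiles = {}
for label, reads in (("no_chx", no_chx), ("chx", chx)):
    counts = rw.counts_from_reads(reads, cds)
    enr = rw.relative_enrichment(counts, edge_exclusion=200)
    profiles[label] = rw.offset_profile(enr, cds, range(0, 91))

fit = rw.wave_analysis(profiles["chx"], profiles["no_chx"], window=(6, 65))
print(f"slope={fit.slope:.3f} r2={fit.r_squared:.3f}")

occ = rw.site_occupancies(profiles["chx"])["A"]
print("raw  rho=%.3f" % rw.spearman_vs_inverse_tai(occ, tai)[0])
cae = rw.wave_analysis(profiles["chx"], profiles["no_chx"], (7, 90)).per_codon
rho, p = rw.spearman_vs_inverse_tai(cae["corrected_aggregate"], tai)
print("CAE  rho=%.3f p=%.2g" % (rho, p))
```

prints

```
slope=-1.019 r2=0.872
raw  rho=-0.979
CAE  rho=0.536 p=4.2e-06
```

Reading: per codon, the enrichment lost (or gained) at the tRNA binding
sites after the dwell-time switch reappears as a downstream wave of equal
area (slope ≈ −1, tight fit); the drug sample's raw A-site occupancies rank
*opposite* to `1/tAI` even though the pre-switch dwell times were built to
rank with it, and adding wave areas back (CAE) recovers the true positive
correlation.

The same stages are exposed as a CLI (`ribowave simulate | assign | enrich |
profile | occupancy | wave | cluster | tai | analytic-wave | make-synthetic |
run`), reading CDS FASTA, footprint TSV/SAM, and rates/tGCN TSV files.

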