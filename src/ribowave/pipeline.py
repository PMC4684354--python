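"""Run configuration, provenance headers, and end-to-end pipeline modes."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import MissingInputError, ParameterError
from .footprints import (
    counts_from_reads,
    read_footprints_sam,
    read_footprints_tsv,
    relative_enrichment,
    write_footprints_tsv,
)
from .rates import read_rates_tsv, write_rates_tsv
from .sequences import read_cds_fasta, write_cds_fasta
from .simulate import (
    SimulationConfig,
    simulate_rate_switch,
    simulate_steady_state,
    snapshot_to_reads,
)
from .stats import offset_profile, site_occupancies, wave_analysis
from .wavemodel import evolve_density, single_perturbation_dwells, wave_summary
from .synthetic import (
    generate_experiment_pair,
    generate_rate_scheme,
    generate_transcriptome,
    synthetic_tai_table,
)

log = logging.getLogger("ribowave")


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run; flags override file values."""

    out_dir: str = "ribowave_out"
    cds_fasta: str | None = None
    reads: str | None = None  # TSV, or SAM against the CDS FASTA
    rates_pre: str | None = None
    rates_post: str | None = None
    edge_exclusion: int = 90
    wave_edge_exclusion: int = 200
    window: tuple[int, int] = (7, 90)
    min_included_reads: int = 1
    # synthetic-pair parameters
    n_genes: int = 200
    length_range: tuple[int, int] = (450, 550)
    n_footprints: int = 1_000_000
    chx_duration: float = 15.0
    anticorrelation: float = -1.0
    noise_sd: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("window", "length_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def params_hash(self) -> str:
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def header(self) -> str:
        return (
            f"# ribowave {__version__} seed={self.seed} "
            f"params={self.params_hash()}\n"
        )


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise MissingInputError(f"{what} is required for this mode")
    p = Path(path)
    if not p.exists():
        raise MissingInputError(f"{what}: {path} does not exist")
    return p


def _load_reads(path: Path, cds):
    if path.suffix.lower() == ".sam":
        return read_footprints_sam(path, cds)
    return read_footprints_tsv(path)


def run_pipeline(config: RunConfig, mode: str) -> dict[str, Path]:
    """Execute one end-to-end mode; returns the files written.

    Modes: ``synthetic-pair`` generates a transcriptome, an anticorrelated
    dwell scheme and a matched experiment pair, then runs the wave-area
    conservation analysis on them; ``analyze`` computes counts, enrichments,
    offset profiles and occupancies for one real read set against a CDS set.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header()
    written: dict[str, Path] = {}

    def save_df(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index)
        written[name] = path
        log.info("wrote %s", path)

    if mode == "synthetic-pair":
        log.info("generating transcriptome: %d genes, lengths %s, seed %d",
                 config.n_genes, config.length_range, config.seed)
        cds = generate_transcriptome(
            config.n_genes, config.length_range, seed=config.seed
        )
        write_cds_fasta(cds, out / "cds.fa")
        written["cds.fa"] = out / "cds.fa"
        tai = synthetic_tai_table(seed=config.seed + 1)
        scheme = generate_rate_scheme(
            tai,
            anticorrelation=config.anticorrelation,
            noise_sd=config.noise_sd,
            seed=config.seed + 2,
            label="synthetic-pair",
        )
        write_rates_tsv(scheme.pre, out / "rates_pre.tsv", header)
        write_rates_tsv(scheme.post, out / "rates_post.tsv", header)
        written["rates_pre.tsv"] = out / "rates_pre.tsv"
        written["rates_post.tsv"] = out / "rates_post.tsv"
        log.info("sampling %d footprints per condition, switch duration %.3g",
                 config.n_footprints, config.chx_duration)
        no_chx, chx = generate_experiment_pair(
            cds, scheme, config.n_footprints, config.chx_duration, seed=config.seed + 3
        )
        write_footprints_tsv(no_chx, out / "reads_no_chx.tsv", header)
        write_footprints_tsv(chx, out / "reads_chx.tsv", header)
        written["reads_no_chx.tsv"] = out / "reads_no_chx.tsv"
        written["reads_chx.tsv"] = out / "reads_chx.tsv"

        profiles = {}
        for label, reads in (("no_chx", no_chx), ("chx", chx)):
            counts = counts_from_reads(reads, cds)
            enr = relative_enrichment(
                counts, config.wave_edge_exclusion, config.min_included_reads
            )
            lo, hi = config.window
            profiles[label] = offset_profile(enr, cds, range(0, hi + 1))
        result = wave_analysis(profiles["chx"], profiles["no_chx"], config.window)
        save_df(result.per_codon.rename_axis("codon"), "wave_analysis.tsv", index=True)
        summary = pd.DataFrame(
            [{"slope": result.slope, "intercept": result.intercept,
              "r_squared": result.r_squared, "window_lo": result.window[0],
              "window_hi": result.window[1]}]
        )
        save_df(summary, "wave_regression.tsv")
        return written

    if mode == "analyze":
        cds = read_cds_fasta(_require(config.cds_fasta, "cds_fasta"))
        reads = _load_reads(_require(config.reads, "reads"), cds)
        counts = counts_from_reads(reads, cds)
        save_df(counts.to_frame(), "counts.tsv")
        enr = relative_enrichment(counts, config.edge_exclusion, config.min_included_reads)
        save_df(enr.to_frame(), "enrichment.tsv")
        log.info("rejections: %s; dropped genes: %d", counts.rejections, len(enr.dropped_genes))
        profile = offset_profile(enr, cds)
        path = out / "offset_profile.tsv"
        profile.to_tsv(path, header)
        written["offset_profile.tsv"] = path
        save_df(site_occupancies(profile).rename_axis("codon"), "occupancy.tsv", index=True)
        return written

    if mode == "simulate":
        cds = read_cds_fasta(_require(config.cds_fasta, "cds_fasta"))
        rates_pre = read_rates_tsv(_require(config.rates_pre, "rates_pre"))
        sim_cfg = SimulationConfig(seed=config.seed)
        if config.rates_post is not None:
            rates_post = read_rates_tsv(_require(config.rates_post, "rates_post"))
            snap = simulate_rate_switch(
                cds, rates_pre, rates_post, sim_cfg, config.chx_duration
            )
        else:
            snap = simulate_steady_state(cds, rates_pre, sim_cfg)
        reads, dropped = snapshot_to_reads(snap, cds)
        log.info("%d ribosomes, %d dropped at edges", len(snap), dropped)
        write_footprints_tsv(reads, out / "reads_simulated.tsv", header)
        written["reads_simulated.tsv"] = out / "reads_simulated.tsv"
        return written

    if mode == "analytic":
        old, new = single_perturbation_dwells()
        times = [0.0, 5.0, 10.0, 20.0, 40.0]
        traj = evolve_density(old, new, 1.0, times)
        dens = pd.DataFrame(traj.density, index=pd.Index(times, name="time"),
                            columns=traj.positions)
        save_df(dens, "analytic_density.tsv", index=True)
        save_df(wave_summary(traj), "analytic_wave_summary.tsv")
        return written

    raise ParameterError(f"unknown pipeline mode {mode!r}")
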