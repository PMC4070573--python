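"""End-to-end pipeline: configuration, seeding and stage orchestration.

A run goes synthetic-data (or real-mode file loading) -> per-sample CNV
discovery -> region genotyping -> population genetics (He, VST) ->
breakpoint architecture -> enrichment/QC -> report. Every stochastic stage
receives a sub-seed derived deterministically from the master seed and the
stage name, so reruns with the same config and seed are byte-identical and
individual stages are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import breakpoints as bp
from . import discovery, enrichment_validation as ev, genotyping, popgen
from . import synthetic_data as sd
from .io_formats import (
    IntervalSet,
    SampleSheet,
    read_bed,
    read_fasta,
    read_probe_track,
    read_sample_sheet,
    write_report,
)


class ConfigError(ValueError):
    pass


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic 31-bit sub-seed from (master seed, stage name)."""
    return (zlib.crc32(f"{master_seed}:{stage}".encode()) ^ master_seed) % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters, with defaults at the study's stated values."""

    mode: str = "synthetic"
    seed: int = 0
    # real-mode inputs
    genome_fasta: str | None = None
    probe_dir: str | None = None
    sample_sheet: str | None = None
    repeats_bed: str | None = None
    gaps_bed: str | None = None
    genes_bed: str | None = None
    # synthetic-mode generator settings (forwarded to SimulationConfig)
    simulation: dict = field(default_factory=dict)
    # stage parameters
    hmm_means: tuple[float, float, float] = (-0.6, 0.0, 0.45)
    hmm_self_transition: float = 0.999
    caller2_k_sd: float = 2.0
    caller2_min_probes: int = 30
    merge_max_gap: int = 3_000
    merge_repeat_fraction: float = 0.80
    genotype_k_sd: float = 1.5
    breakpoint_window: int = 400
    gc_peak_window: int = 500
    gc_background_window: int = 10_000
    gc_rel_increase: float = 0.5
    n_resamples: int = 1000
    top_k: int = 25
    he_group_size: int = 5
    he_draws: int = 1000

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for name in ("breakpoint_window", "gc_peak_window", "gc_background_window",
                     "n_resamples", "he_draws"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.mode == "real":
            for name in ("genome_fasta", "probe_dir", "sample_sheet"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"real mode requires {name}")
                if not Path(path).exists():
                    raise ConfigError(f"{name} does not exist: {path}")


def validate_config(raw: dict | None) -> PipelineConfig:
    """Normalize a parsed YAML mapping into a PipelineConfig.

    Unknown keys are an error (listed); missing keys take defaults.
    """
    raw = dict(raw or {})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "hmm_means" in raw:
        raw["hmm_means"] = tuple(raw["hmm_means"])
    return PipelineConfig(**raw)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    samples: SampleSheet
    regions: list
    genotypes: genotyping.GenotypeMatrix
    sharing: pd.DataFrame
    sharing_counts: dict
    polarization: pd.DataFrame
    per_sample: pd.DataFrame
    vst_ranking: pd.DataFrame
    he_comparison: popgen.HeComparison
    gc_peaks: list
    homology: tuple[float, float, float]
    repeat_enrichment: dict
    control_fdr: tuple[int, int, float]
    self_self_count: int
    truth: sd.TruthSet | None = None


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage and (optionally) write the report directory."""
    if config.mode == "synthetic":
        sim_kwargs = dict(config.simulation)
        sim_kwargs["seed"] = stage_seed(config.seed, "synthetic")
        sim = sd.SimulationConfig(**sim_kwargs)
        genome, repeats, gaps, genes = sd.generate_genome(sim)
        samples = sd.default_sample_sheet()
        truth = sd.draw_truth_genotypes(sim, samples)
        regions_iv, controls_iv = sd.tiled_regions(truth, sim)
        footprint = IntervalSet(
            pd.concat([regions_iv.df, controls_iv.df], ignore_index=True)
        ).sorted()
        tracks = sd.simulate_acgh(truth, sim, samples, footprint)
    else:
        genome = read_fasta(config.genome_fasta)
        samples = read_sample_sheet(config.sample_sheet)
        repeats = read_bed(config.repeats_bed) if config.repeats_bed else _empty_ivs()
        gaps = read_bed(config.gaps_bed) if config.gaps_bed else _empty_ivs()
        genes = read_bed(config.genes_bed) if config.genes_bed else _empty_ivs()
        tracks = {
            s: read_probe_track(Path(config.probe_dir) / f"{s}.tsv", s)
            for s in samples.samples
        }
        regions_iv = controls_iv = None
        truth = None

    hmm_params = discovery.HMMParams(
        means=config.hmm_means, self_transition=config.hmm_self_transition
    )
    caller2 = discovery.SecondCallerParams(
        k_sd=config.caller2_k_sd, min_probes=config.caller2_min_probes
    )
    merge = discovery.MergeParams(
        max_gap=config.merge_max_gap, repeat_gap_fraction=config.merge_repeat_fraction
    )
    all_segments = []
    for sample in samples.samples:
        all_segments.extend(
            discovery.discover_sample(
                tracks[sample], repeats, gaps,
                hmm_params=hmm_params, caller2_params=caller2, merge_params=merge,
            )
        )
    regions = discovery.define_regions(all_segments) if all_segments else []

    gm = genotyping.genotype_all(regions, tracks, samples, config.genotype_k_sd)
    sharing = genotyping.classify_sharing(gm)
    counts = genotyping.sharing_counts(sharing)
    polarization = genotyping.polarize_events(gm)
    per_sample = genotyping.per_sample_summary(gm)

    vst_results = popgen.vst_by_region(gm, tracks)
    polymorphic = [v for v in vst_results if v.vt > 0]
    vst_ranking = popgen.rank_vst(polymorphic, min(config.top_k, len(polymorphic)))
    he_cmp = popgen.wolf_subsample_he_test(
        gm, config.he_group_size, config.he_draws, stage_seed(config.seed, "he")
    )

    cnv_iv = IntervalSet.from_records(
        (r.chrom, r.start, r.end, r.region_id) for r in regions
    ) if regions else _empty_ivs()
    pairs = bp.make_breakpoint_pairs(cnv_iv, genome, config.breakpoint_window)
    gc_peaks = bp.detect_gc_peaks(
        genome, config.gc_peak_window, config.gc_background_window,
        rel_increase=config.gc_rel_increase,
    )
    homology = (
        bp.homology_permutation_test(
            pairs, genome, n_permutations=max(1, config.n_resamples // 100),
            seed=stage_seed(config.seed, "homology"), window=config.breakpoint_window,
        )
        if len(pairs) >= 2
        else (float("nan"), float("nan"), float("nan"))
    )
    rep_enrich = (
        bp.repeat_enrichment(
            pairs, repeats, genome,
            n_resamples=config.n_resamples,
            seed=stage_seed(config.seed, "repeats"),
            window_sizes=[config.breakpoint_window],
        )
        if len(pairs) >= 1 and len(repeats)
        else {}
    )

    # QC: genotype the control regions and count non-equal calls
    if controls_iv is not None and len(controls_iv):
        control_regions = [
            discovery.CNVRegion(rec.label, rec.chrom, rec.start, rec.end)
            for rec in controls_iv
        ]
        control_gm = genotyping.genotype_all(
            control_regions, tracks, samples, config.genotype_k_sd
        )
        control_fdr = ev.control_calls_from_matrix(control_gm.calls)
    else:
        control_fdr = (0, 0, float("nan")) if controls_iv is None else (0, 0, 0.0)
    self_count = ev.self_self_calls(
        tracks[samples.reference], repeats, gaps,
        hmm_params=hmm_params, caller2_params=caller2, merge_params=merge,
    )

    result = PipelineResult(
        samples=samples, regions=regions, genotypes=gm, sharing=sharing,
        sharing_counts=counts, polarization=polarization, per_sample=per_sample,
        vst_ranking=vst_ranking, he_comparison=he_cmp, gc_peaks=gc_peaks,
        homology=homology, repeat_enrichment=rep_enrich,
        control_fdr=control_fdr, self_self_count=self_count, truth=truth,
    )
    if outdir is not None:
        write_report(
            {
                "genotypes": gm.calls,
                "per_sample": per_sample.reset_index(),
                "vst": vst_ranking,
                "seed": config.seed,
                "config": {
                    k: v for k, v in dataclasses.asdict(config).items()
                    if not isinstance(v, dict)
                },
                "counts": {
                    "regions": len(regions),
                    "cnv_calls": int((gm.calls.values != "equal").sum()),
                    **counts,
                    "self_self_calls": self_count,
                },
            },
            outdir,
        )
    return result


def _empty_ivs() -> IntervalSet:
    return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "label"]))
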