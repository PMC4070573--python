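"""Synthetic genomes, annotations, truth CNVs and multi-sample aCGH tracks.

The generator emulates a two-colour tiling-array experiment on wolf-like
canids: a panel of dogs (including a dingo), gray wolves and outgroup canids
hybridized against a single reference dog. Copy-number alleles are drawn
per group under Hardy-Weinberg equilibrium with three haplotype states
(L = 0 copies, N = 1, G = 2), giving diploid copy numbers 0-4, and each
probe reports log2(copy/2) plus homoscedastic Gaussian noise. Probes tile
the CNV loci (plus flanks) and single-copy control regions at the spacing
the array design prescribes for a region's size: 50 bp below 100 kb,
150 bp for 100-300 kb, 1 kb above 300 kb.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, IntervalSet, ProbeTrack, SampleSheet

L1_AGE_CLASSES = ("CanisFamiliaris", "Canis", "Canidae", "Carnivora", "OlderMammalia")

#: log2 ratio reported for a homozygous deletion (copy 0); clamps -inf while
#: staying far below any loss-calling threshold.
ZERO_COPY_LOG2 = -3.0


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass
class GCPeakSpec:
    chrom: str
    position: int  # left edge of the peak
    width: int  # >= 500 bp
    gc: float


@dataclass
class CNVLocusSpec:
    """One implanted CNV locus with per-group allele frequencies.

    ``freqs`` maps group -> (loss, normal, gain) haplotype frequencies;
    ``gain_copies`` is the per-haplotype copy count of the gain allele
    (2 by default, so NG = 3 and GG = 4 total copies).
    """

    chrom: str
    start: int
    end: int
    freqs: dict[str, tuple[float, float, float]]
    gain_copies: int = 2

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ConfigError(f"CNV locus {self.chrom}:{self.start}-{self.end} empty")
        for group, (l, n, g) in self.freqs.items():
            if abs(l + n + g - 1.0) > 1e-9:
                raise ConfigError(
                    f"allele frequencies for group {group!r} sum to {l+n+g}, not 1"
                )
            if min(l, n, g) < 0:
                raise ConfigError(f"negative allele frequency for group {group!r}")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic aCGH experiment.

    Defaults mirror the real study's scale where the analysis depends on it
    (23-sample panel, 42 control regions, 50 bp probe spacing, 0.15 noise
    SD) on a desk-sized two-chromosome genome.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_500_000}
    )
    base_gc: float = 0.41
    gc_peaks: list[GCPeakSpec] = field(default_factory=list)
    # repeat density: expected repeats per Mb per family label
    repeat_density: dict[str, float] = field(
        default_factory=lambda: {
            "SimpleRepeat": 30.0,
            "SINE": 60.0,
            **{f"L1:{age}": 12.0 for age in L1_AGE_CLASSES},
        }
    )
    repeat_length: tuple[int, int] = (150, 900)
    n_gaps_per_chrom: int = 1
    gap_length: int = 5_000
    n_genes: int = 60
    gene_length: tuple[int, int] = (2_000, 30_000)
    cnv_loci: list[CNVLocusSpec] = field(default_factory=list)
    n_cnv_loci: int = 30
    cnv_length: tuple[int, int] = (3_000, 20_000)
    locus_flank: int = 10_000
    n_control_regions: int = 42
    control_length: int = 10_000
    probe_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_noise_sd <= 0:
            raise ConfigError("probe noise SD must be > 0")
        for peak in self.gc_peaks:
            if peak.width < 500:
                raise ConfigError("GC peak width must be >= 500 bp")
            if peak.chrom not in self.chrom_lengths:
                raise ConfigError(f"GC peak on unknown chromosome {peak.chrom!r}")
            if peak.width > self.chrom_lengths[peak.chrom]:
                raise ConfigError("GC peak wider than its chromosome")


@dataclass
class TruthSet:
    """Ground truth: loci, per-sample diploid genotypes, copies and expected log2."""

    loci: list[CNVLocusSpec]
    # genotypes[sample][locus index] = (allele, allele) with alleles in {L,N,G}
    genotypes: dict[str, list[tuple[str, str]]]

    ALLELE_COPIES = {"L": 0, "N": 1}

    def copy_number(self, sample: str, locus_idx: int) -> int:
        locus = self.loci[locus_idx]
        copies = {"L": 0, "N": 1, "G": locus.gain_copies}
        a, b = self.genotypes[sample][locus_idx]
        return copies[a] + copies[b]

    def expected_log2(self, sample: str, locus_idx: int) -> float:
        c = self.copy_number(sample, locus_idx)
        return ZERO_COPY_LOG2 if c == 0 else float(np.log2(c / 2.0))

    def call(self, sample: str, locus_idx: int) -> str:
        c = self.copy_number(sample, locus_idx)
        return "loss" if c < 2 else ("gain" if c > 2 else "equal")

    def intervals(self) -> IntervalSet:
        return IntervalSet.from_records(
            (loc.chrom, loc.start, loc.end, f"cnv_{i}")
            for i, loc in enumerate(self.loci)
        )


def default_sample_sheet() -> SampleSheet:
    """The study panel: 4 purebred dogs + dingo, 15 gray wolves, 3 outgroups.

    The reference is a boxer (self-self semantics for its own track); the
    dingo is grouped with dogs.
    """
    rows = [
        ("Boxer", "dog", "boxer", 1),
        ("Dachshund", "dog", "dachshund", 0),
        ("Beagle", "dog", "beagle", 0),
        ("Basenji", "dog", "basenji", 0),
        ("Dingo", "dog", "dingo", 0),
    ]
    wolf_pops = [
        "Israel", "Israel", "Italy", "Italy", "Portugal", "Iberia",
        "Yellowstone", "GreatLakes", "Iran", "Mexico", "China", "India",
        "Mongolia", "Mongolia", "Sweden",
    ]
    for i, pop in enumerate(wolf_pops, start=1):
        rows.append((f"Wolf{i:02d}", "wolf", pop, 0))
    rows += [
        ("RedWolf", "outgroup", "redwolf", 0),
        ("Coyote", "outgroup", "coyote", 0),
        ("GoldenJackal", "outgroup", "jackal", 0),
    ]
    df = pd.DataFrame(rows, columns=["sample", "group", "population", "is_reference"])
    df["is_reference"] = df["is_reference"].astype(bool)
    return SampleSheet(df)


def default_cnv_loci(
    config: SimulationConfig, rng: np.random.Generator
) -> list[CNVLocusSpec]:
    """Place ``n_cnv_loci`` non-overlapping loci with a frequency mixture.

    Frequency archetypes cover the cases the analysis distinguishes: shared
    polymorphic, dog-specific, wolf-specific, highly differentiated (dog
    gain ~0.9 vs wolf 0) and monomorphic-normal loci.
    """
    archetypes = [
        {"dog": (0.2, 0.8, 0.0), "wolf": (0.2, 0.8, 0.0), "outgroup": (0.2, 0.8, 0.0)},
        {"dog": (0.0, 0.7, 0.3), "wolf": (0.0, 0.7, 0.3), "outgroup": (0.0, 0.7, 0.3)},
        {"dog": (0.0, 0.5, 0.5), "wolf": (0.0, 1.0, 0.0), "outgroup": (0.0, 1.0, 0.0)},
        {"dog": (0.0, 1.0, 0.0), "wolf": (0.4, 0.6, 0.0), "outgroup": (0.0, 1.0, 0.0)},
        {"dog": (0.0, 0.1, 0.9), "wolf": (0.0, 1.0, 0.0), "outgroup": (0.0, 1.0, 0.0)},
        {"dog": (0.0, 1.0, 0.0), "wolf": (0.0, 1.0, 0.0), "outgroup": (0.0, 1.0, 0.0)},
    ]
    chroms = list(config.chrom_lengths)
    loci: list[CNVLocusSpec] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    spacing = 2 * config.locus_flank + 10_000
    for i in range(config.n_cnv_loci):
        length = int(rng.integers(config.cnv_length[0], config.cnv_length[1] + 1))
        for _attempt in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(
                rng.integers(config.locus_flank,
                             config.chrom_lengths[chrom] - length - config.locus_flank)
            )
            end = start + length
            if all(
                end + spacing <= s or start >= e + spacing
                for s, e in occupied[chrom]
            ):
                occupied[chrom].append((start, end))
                loci.append(
                    CNVLocusSpec(chrom, start, end, dict(archetypes[i % len(archetypes)]))
                )
                break
        else:
            raise ConfigError("could not place CNV loci without overlap")
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def generate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, IntervalSet, IntervalSet, IntervalSet]:
    """Generate sequence plus repeat, gap and gene annotations.

    Per-base GC follows ``base_gc`` except inside implanted GC peaks, which
    are placed exactly; gaps are runs of N. Returns (genome, repeats, gaps,
    genes); repeats carry their family (and, for L1, age class) as label.
    """
    rng = np.random.default_rng(config.seed)
    chroms: dict[str, str] = {}
    gap_records = []
    for chrom, length in config.chrom_lengths.items():
        gc_prob = np.full(length, config.base_gc)
        for peak in config.gc_peaks:
            if peak.chrom == chrom:
                gc_prob[peak.position : peak.position + peak.width] = peak.gc
        is_gc = rng.random(length) < gc_prob
        # within GC / AT, both bases equally likely
        second = rng.random(length) < 0.5
        bases = np.where(is_gc, np.where(second, "G", "C"), np.where(second, "A", "T"))
        for _ in range(config.n_gaps_per_chrom):
            gap_start = int(rng.integers(0, length - config.gap_length))
            bases[gap_start : gap_start + config.gap_length] = "N"
            gap_records.append((chrom, gap_start, gap_start + config.gap_length, "gap"))
        chroms[chrom] = "".join(bases)

    repeat_records = []
    for chrom, length in config.chrom_lengths.items():
        for family, per_mb in config.repeat_density.items():
            n = rng.poisson(per_mb * length / 1e6)
            for _ in range(n):
                rep_len = int(rng.integers(*config.repeat_length))
                start = int(rng.integers(0, max(1, length - rep_len)))
                repeat_records.append((chrom, start, start + rep_len, family))

    gene_records = []
    chrom_names = list(config.chrom_lengths)
    for i in range(config.n_genes):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        length = config.chrom_lengths[chrom]
        gene_len = int(rng.integers(*config.gene_length))
        start = int(rng.integers(0, max(1, length - gene_len)))
        gene_records.append((chrom, start, start + gene_len, f"gene_{i}"))

    genome = GenomeSequence(chroms)
    repeats = IntervalSet.from_records(repeat_records).sorted()
    gaps = (
        IntervalSet.from_records(gap_records).sorted()
        if gap_records
        else IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "label"]))
    )
    genes = IntervalSet.from_records(gene_records).sorted()
    return genome, repeats, gaps, genes


# ---------------------------------------------------------------------------
# Truth genotypes
# ---------------------------------------------------------------------------


def draw_truth_genotypes(
    config: SimulationConfig,
    samples: SampleSheet,
    loci: Sequence[CNVLocusSpec] | None = None,
) -> TruthSet:
    """Draw two haplotype alleles per sample per locus from its group's
    frequencies (Hardy-Weinberg sampling)."""
    rng = np.random.default_rng((config.seed, 1))
    if loci is None:
        loci = config.cnv_loci or default_cnv_loci(
            config, np.random.default_rng((config.seed, 2))
        )
    alleles = np.array(["L", "N", "G"])
    genotypes: dict[str, list[tuple[str, str]]] = {}
    for sample in samples.samples:
        group = samples.group_of(sample)
        calls = []
        for locus in loci:
            if group not in locus.freqs:
                raise ConfigError(
                    f"no allele frequencies for group {group!r} at "
                    f"{locus.chrom}:{locus.start}-{locus.end}"
                )
            probs = np.asarray(locus.freqs[group], float)
            pair = rng.choice(alleles, size=2, p=probs)
            calls.append((str(pair[0]), str(pair[1])))
        genotypes[sample] = calls
    return TruthSet(list(loci), genotypes)


# ---------------------------------------------------------------------------
# Probe simulation
# ---------------------------------------------------------------------------


def probe_spacing(region_length: int) -> int:
    """Array-design spacing rule: 50 bp (<100 kb), 150 bp (100-300 kb), 1 kb."""
    if region_length < 100_000:
        return 50
    if region_length <= 300_000:
        return 150
    return 1_000


def tiled_regions(
    truth: TruthSet, config: SimulationConfig
) -> tuple[IntervalSet, IntervalSet]:
    """The array footprint: CNV loci padded by ``locus_flank``, plus
    single-copy control regions placed clear of every locus."""
    rng = np.random.default_rng((config.seed, 3))
    records = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_lengths}
    for i, locus in enumerate(truth.loci):
        start = max(0, locus.start - config.locus_flank)
        end = min(config.chrom_lengths[locus.chrom], locus.end + config.locus_flank)
        records.append((locus.chrom, start, end, f"region_{i}"))
        occupied[locus.chrom].append((start, end))
    control_records = []
    chroms = list(config.chrom_lengths)
    for i in range(config.n_control_regions):
        for _attempt in range(500):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(
                rng.integers(0, config.chrom_lengths[chrom] - config.control_length)
            )
            end = start + config.control_length
            if all(end <= s or start >= e for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                control_records.append((chrom, start, end, f"control_{i}"))
                break
        else:
            raise ConfigError("could not place control regions")
    return (
        IntervalSet.from_records(records).sorted(),
        IntervalSet.from_records(control_records).sorted(),
    )


def probe_positions(regions: IntervalSet) -> dict[str, np.ndarray]:
    """Deterministic probe grid over the tiled regions, spacing by region size."""
    by_chrom: dict[str, list[np.ndarray]] = {}
    for rec in regions:
        step = probe_spacing(rec.end - rec.start)
        pos = np.arange(rec.start + step // 2, rec.end, step)
        by_chrom.setdefault(rec.chrom, []).append(pos)
    return {
        chrom: np.unique(np.concatenate(parts)) for chrom, parts in by_chrom.items()
    }


def simulate_acgh(
    truth: TruthSet,
    config: SimulationConfig,
    samples: SampleSheet,
    regions: IntervalSet | None = None,
) -> dict[str, ProbeTrack]:
    """Per-sample probe tracks: expected log2 of local copy number plus
    Gaussian noise. The reference sample's track is pure noise around zero
    (self-self hybridization semantics)."""
    if regions is None:
        regions, _controls = tiled_regions(truth, config)
    positions = probe_positions(regions)
    rng = np.random.default_rng((config.seed, 4))
    reference = samples.reference
    tracks: dict[str, ProbeTrack] = {}
    for sample in samples.samples:
        frames = []
        for chrom in sorted(positions):
            pos = positions[chrom]
            mu = np.zeros(len(pos))
            if sample != reference:
                for i, locus in enumerate(truth.loci):
                    if locus.chrom != chrom:
                        continue
                    inside = (pos >= locus.start) & (pos < locus.end)
                    if inside.any():
                        mu[inside] = truth.expected_log2(sample, i)
            noise = rng.normal(0.0, config.probe_noise_sd, size=len(pos))
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "position": pos, "log2ratio": mu + noise}
                )
            )
        tracks[sample] = ProbeTrack(sample, pd.concat(frames, ignore_index=True))
    return tracks


# ---------------------------------------------------------------------------
# Breakpoint homology implants
# ---------------------------------------------------------------------------


def implant_breakpoint_homology(
    genome: GenomeSequence,
    truth: TruthSet,
    motif_length: int,
    window: int = 400,
    loci: Sequence[int] | None = None,
    seed: int = 0,
) -> GenomeSequence:
    """Write an identical random motif into both breakpoint windows of the
    chosen CNV loci (all loci by default), creating NAHR-like homology.

    The two windows of a CNV are centred on its start and end coordinates.
    Returns a new genome; the input is not modified.
    """
    if motif_length == 0:
        return genome
    if motif_length >= window:
        raise ConfigError("motif length must be below the breakpoint window size")
    rng = np.random.default_rng(seed)
    chroms = {name: bytearray(seq, "ascii") for name, seq in genome.chroms.items()}
    idx = list(range(len(truth.loci))) if loci is None else list(loci)
    written: dict[str, list[tuple[int, int]]] = {}
    for i in idx:
        locus = truth.loci[i]
        motif = "".join(rng.choice(list("ACGT"), size=motif_length))
        for center in (locus.start, locus.end):
            start = center - motif_length // 2
            end = start + motif_length
            if start < 0 or end > len(chroms[locus.chrom]):
                raise ConfigError(
                    f"motif at {locus.chrom}:{start} outside chromosome"
                )
            for s, e in written.get(locus.chrom, []):
                if start < e and s < end:
                    raise ConfigError(
                        f"overlapping homology implants on {locus.chrom}"
                    )
            written.setdefault(locus.chrom, []).append((start, end))
            chroms[locus.chrom][start:end] = motif.encode("ascii")
    return GenomeSequence({name: bs.decode("ascii") for name, bs in chroms.items()})
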