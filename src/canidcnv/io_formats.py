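"""Readers, writers and core containers for the aCGH CNV pipeline.

All genomic coordinates are 0-based half-open throughout the package, the
same convention BED uses, so BED input and output are bit-compatible with
the in-memory representation.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
GROUPS = ("dog", "wolf", "outgroup")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """Per-chromosome nucleotide strings (A/C/G/T/N, upper case)."""

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains invalid bases: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms


@dataclass
class IntervalSet:
    """A set of labelled genomic intervals, 0-based half-open.

    Backed by a pandas DataFrame with columns chrom/start/end/label; helper
    accessors return per-chromosome numpy arrays sorted by start, which is
    what the overlap and randomization machinery consumes.
    """

    df: pd.DataFrame

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int] | tuple[str, int, int, str]]
    ) -> "IntervalSet":
        rows = []
        for rec in records:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            label = str(rec[3]) if len(rec) > 3 else "."
            if start >= end:
                raise FormatError(
                    f"empty or inverted interval {chrom}:{start}-{end}"
                )
            rows.append((chrom, start, end, label))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False, name="Interval"))

    def subset(self, mask) -> "IntervalSet":
        return IntervalSet(self.df[mask].reset_index(drop=True))

    def with_label(self, label: str) -> "IntervalSet":
        return self.subset(self.df["label"] == label)

    def labels(self) -> list[str]:
        return sorted(self.df["label"].unique())

    def by_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) sorted by start for one chromosome."""
        sub = self.df[self.df["chrom"] == chrom].sort_values("start")
        return sub["start"].to_numpy(int), sub["end"].to_numpy(int)

    def sorted(self) -> "IntervalSet":
        df = self.df.sort_values(["chrom", "start", "end", "label"])
        return IntervalSet(df.reset_index(drop=True))

    def total_length(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def covered_bases(self, chrom: str, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by the union of intervals."""
        starts, ends = self.by_chrom(chrom)
        if len(starts) == 0 or start >= end:
            return 0
        s = np.clip(starts, start, end)
        e = np.clip(ends, start, end)
        covered = 0
        cur_s = cur_e = None
        for a, b in zip(s, e):
            if b <= a:
                continue
            if cur_e is None or a > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = a, b
            else:
                cur_e = max(cur_e, b)
        if cur_e is not None:
            covered += cur_e - cur_s
        return int(covered)

    def check_bounds(self, genome: GenomeSequence) -> None:
        lengths = genome.lengths
        for rec in self:
            if rec.chrom not in lengths:
                raise FormatError(f"interval on unknown chromosome {rec.chrom!r}")
            if rec.start < 0 or rec.end > lengths[rec.chrom]:
                raise FormatError(
                    f"interval {rec.chrom}:{rec.start}-{rec.end} outside chromosome"
                )


@dataclass
class SampleSheet:
    """Sample roster: id, group (dog/wolf/outgroup), population, reference flag."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "group", "population", "is_reference"}
        missing = required - set(self.df.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        bad = set(self.df["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        if self.df["sample"].duplicated().any():
            raise FormatError("duplicate sample ids in sample sheet")
        n_ref = int(self.df["is_reference"].sum())
        if n_ref != 1:
            raise FormatError(f"expected exactly one reference sample, got {n_ref}")

    @property
    def samples(self) -> list[str]:
        return list(self.df["sample"])

    @property
    def reference(self) -> str:
        return str(self.df.loc[self.df["is_reference"], "sample"].iloc[0])

    def group_of(self, sample: str) -> str:
        return str(self.df.set_index("sample").loc[sample, "group"])

    def in_group(self, group: str) -> list[str]:
        return list(self.df.loc[self.df["group"] == group, "sample"])

    @property
    def dogs(self) -> list[str]:
        """Domestic dog group; by convention the dingo carries group 'dog'."""
        return self.in_group("dog")

    @property
    def wolves(self) -> list[str]:
        return self.in_group("wolf")

    @property
    def outgroups(self) -> list[str]:
        return self.in_group("outgroup")


@dataclass
class ProbeTrack:
    """One sample's ordered aCGH probes: chrom, position, log2 test/reference ratio."""

    sample: str
    df: pd.DataFrame  # columns chrom, position, log2ratio

    def __post_init__(self) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False):
            pos = sub["position"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise FormatError(f"probes on {chrom} not sorted by position")
            if np.any(np.diff(pos) == 0):
                raise FormatError(f"duplicate probe positions on {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(self.df["chrom"].unique())

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["position"].to_numpy(int), sub["log2ratio"].to_numpy(float)

    def values(self) -> np.ndarray:
        return self.df["log2ratio"].to_numpy(float)

    def region_mean(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """Mean log2 ratio and probe count over [start, end)."""
        pos, val = self.chrom_arrays(chrom)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        n = int(hi - lo)
        if n == 0:
            return float("nan"), 0
        return float(val[lo:hi].mean()), n


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_probe_track(path: str | Path, sample: str | None = None) -> ProbeTrack:
    """Read a per-sample probe TSV (columns chrom, position, log2ratio).

    Positions must be sorted and unique per chromosome; format errors name
    the offending line.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chrom", "position", "log2ratio"]:
            raise FormatError(
                f"{path}: expected header chrom/position/log2ratio, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            chrom = parts[0]
            try:
                pos = int(parts[1])
                val = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            rows.append((chrom, pos, val))
    df = pd.DataFrame(rows, columns=["chrom", "position", "log2ratio"])
    try:
        return ProbeTrack(sample or path.stem, df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_probe_track(track: ProbeTrack, path: str | Path) -> None:
    track.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED file (0-based half-open; optional 4th column kept as label)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            label = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], start, end, label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    intervals.df.to_csv(path, sep="\t", index=False, header=False)


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-)FASTA genome; sequences are upper-cased and validated."""
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        if rec.id in chroms:
            raise FormatError(f"{path}: duplicate chromosome {rec.id!r}")
        chroms[rec.id] = seq
    if not chroms:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chroms.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    if "is_reference" in df.columns:
        df["is_reference"] = df["is_reference"].astype(int).astype(bool)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.df.copy()
    out["is_reference"] = out["is_reference"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def format_percent(x: float) -> str:
    """Percentages printed to one decimal place."""
    return f"{x:.1f}"


def floor_truncate_percent(x: float) -> float:
    """Floor-truncate a percentage to two decimals (17/966 -> 1.75)."""
    return np.floor(x * 100.0) / 100.0


def write_report(results: Mapping[str, object], outdir: str | Path) -> list[Path]:
    """Write pipeline outputs as TSV tables plus a plain-text run log.

    ``results`` may hold any of: ``genotypes`` (DataFrame region x sample),
    ``per_sample`` (Total/Gains/Losses/Unique summary), ``vst`` (ranked VST
    table), ``config`` (mapping echoed into the log) and ``seed``. Missing
    keys are simply skipped; empty frames yield headers-only tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _emit(key: str, fname: str) -> None:
        obj = results.get(key)
        if obj is None:
            return
        path = outdir / fname
        obj.to_csv(path, sep="\t", index=(key == "genotypes"), float_format="%.6g")
        written.append(path)

    _emit("genotypes", "genotype_matrix.tsv")
    _emit("per_sample", "per_sample_summary.tsv")
    _emit("vst", "vst_ranking.tsv")

    log = outdir / "run_log.txt"
    with open(log, "w") as fh:
        fh.write("canidcnv run log\n")
        fh.write(f"seed: {results.get('seed', 'NA')}\n")
        cfg = results.get("config")
        if cfg is not None:
            fh.write("config:\n")
            for key in sorted(cfg):
                fh.write(f"  {key}: {cfg[key]}\n")
        counts = results.get("counts")
        if counts is not None:
            for key in sorted(counts):
                fh.write(f"count {key}: {counts[key]}\n")
    written.append(log)
    return written
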