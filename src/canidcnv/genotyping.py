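"""Stage 2: genotype every sample at every CNV region and classify events.

A sample is called *gain* at a region when its mean log2 ratio over the
region's probes is at or above the chip median + 1.5 chip SD, *loss* at or
below median - 1.5 SD, and *equal* otherwise; the median and SD are those
of all log2 values of that sample's chip. Sharing classes and the
post-domestication polarization follow the group labels: the dingo counts
as a dog; red wolf, coyote and golden jackal are wild canids for sharing
but are not used in the "absent from all gray wolves" polarization test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discovery import CNVRegion
from .io_formats import ProbeTrack, SampleSheet

CALLS = ("loss", "equal", "gain")


class NoCallError(ValueError):
    """A region with no probes for a sample cannot be genotyped."""


@dataclass
class ChipStats:
    """Median and SD of all probe log2 values of one sample's chip."""

    median: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("chip SD must be > 0")

    @classmethod
    def from_track(cls, track: ProbeTrack) -> "ChipStats":
        vals = track.values()
        return cls(float(np.median(vals)), float(vals.std(ddof=1)))


@dataclass
class GenotypeMatrix:
    """Region x sample calls in {loss, equal, gain} with the sample roster."""

    calls: pd.DataFrame  # index region_id, columns sample ids
    samples: SampleSheet
    regions: dict[str, CNVRegion] | None = None

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.values)) - set(CALLS)
        if bad:
            raise ValueError(f"invalid genotype calls: {sorted(bad)}")
        missing = set(self.samples.samples) - set(self.calls.columns)
        if missing:
            raise ValueError(f"samples missing from matrix: {sorted(missing)}")

    @property
    def region_ids(self) -> list[str]:
        return list(self.calls.index)

    def counts(self, region_id: str, sample_ids: list[str]) -> tuple[int, int, int]:
        """(#loss, #equal, #gain) among the given samples at a region."""
        row = self.calls.loc[region_id, sample_ids]
        return (
            int((row == "loss").sum()),
            int((row == "equal").sum()),
            int((row == "gain").sum()),
        )


def genotype_region(
    region: CNVRegion, track: ProbeTrack, stats: ChipStats, k_sd: float = 1.5
) -> str:
    """3-way call from the region's mean log2 against median +- k SD.

    Values exactly at a threshold are called non-equal.
    """
    mean, n = track.region_mean(region.chrom, region.start, region.end)
    if n == 0:
        raise NoCallError(f"region {region.region_id} has no probes for {track.sample}")
    if mean >= stats.median + k_sd * stats.sd:
        return "gain"
    if mean <= stats.median - k_sd * stats.sd:
        return "loss"
    return "equal"


def genotype_all(
    regions: list[CNVRegion],
    tracks: dict[str, ProbeTrack],
    samples: SampleSheet,
    k_sd: float = 1.5,
) -> GenotypeMatrix:
    stats = {s: ChipStats.from_track(t) for s, t in tracks.items()}
    data = {
        sample: [
            genotype_region(region, tracks[sample], stats[sample], k_sd)
            for region in regions
        ]
        for sample in samples.samples
    }
    calls = pd.DataFrame(data, index=[r.region_id for r in regions])
    return GenotypeMatrix(calls, samples, {r.region_id: r for r in regions})


# ---------------------------------------------------------------------------
# Sharing classes and polarization
# ---------------------------------------------------------------------------


def classify_sharing(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-region sharing class between dogs (incl. dingo) and wild canids.

    dog_specific: >=1 non-equal dog call, none in any wild canid (gray
    wolves and outgroup species); wild_specific symmetric; shared: non-equal
    calls on both sides; monomorphic: no non-equal call anywhere.
    """
    dogs = gm.samples.dogs
    wild = gm.samples.wolves + gm.samples.outgroups
    rows = []
    for rid in gm.region_ids:
        row = gm.calls.loc[rid]
        dog_var = bool((row[dogs] != "equal").any()) if dogs else False
        wild_var = bool((row[wild] != "equal").any()) if wild else False
        if dog_var and wild_var:
            cls = "shared"
        elif dog_var:
            cls = "dog_specific"
        elif wild_var:
            cls = "wild_specific"
        else:
            cls = "monomorphic"
        rows.append((rid, cls))
    return pd.DataFrame(rows, columns=["region_id", "class"]).set_index("region_id")


def sharing_counts(classes: pd.DataFrame) -> dict[str, int]:
    counts = classes["class"].value_counts().to_dict()
    return {
        c: int(counts.get(c, 0))
        for c in ("dog_specific", "wild_specific", "shared", "monomorphic")
    }


def polarize_events(gm: GenotypeMatrix) -> pd.DataFrame:
    """Flag post-domestication duplications/deletions per region.

    A gain (resp. loss) present in at least one dog and absent from all
    gray wolves is a candidate post-domestication duplication (resp.
    deletion); both flags can be set for one region. Outgroup species do
    not enter this test.
    """
    dogs = gm.samples.dogs
    wolves = gm.samples.wolves
    if not wolves:
        raise ValueError("polarization requires a non-empty gray wolf group")
    rows = []
    for rid in gm.region_ids:
        row = gm.calls.loc[rid]
        dup = bool((row[dogs] == "gain").any()) and not bool(
            (row[wolves] == "gain").any()
        )
        dele = bool((row[dogs] == "loss").any()) and not bool(
            (row[wolves] == "loss").any()
        )
        rows.append((rid, dup, dele))
    return pd.DataFrame(
        rows, columns=["region_id", "duplication", "deletion"]
    ).set_index("region_id")


def per_sample_summary(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample Total/Gains/Losses plus Unique counts.

    Unique counts a region for a sample when that sample carries the only
    non-equal call at the region; Total = Gains + Losses by construction.
    """
    samples = gm.samples.samples
    nonequal = gm.calls[samples] != "equal"
    carriers = nonequal.sum(axis=1)
    rows = []
    for sample in samples:
        col = gm.calls[sample]
        gains = int((col == "gain").sum())
        losses = int((col == "loss").sum())
        uniq_mask = nonequal[sample] & (carriers == 1)
        uniq_gains = int(((col == "gain") & uniq_mask).sum())
        uniq_losses = int(((col == "loss") & uniq_mask).sum())
        rows.append(
            (sample, gains + losses, gains, losses,
             uniq_gains + uniq_losses, uniq_gains, uniq_losses)
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "total", "gains", "losses",
                 "unique_total", "unique_gains", "unique_losses"],
    ).set_index("sample")
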