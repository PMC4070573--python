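import numpy as np
import pandas as pd
import pytest

from canidcnv.io_formats import IntervalSet, ProbeTrack, SampleSheet
from canidcnv.pipeline import run_pipeline, validate_config


@pytest.fixture
def empty_intervals():
    return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "label"]))


@pytest.fixture
def small_sheet():
    """Minimal roster: 3 dogs (ref Boxer), 6 wolves, 1 outgroup."""
    rows = [("Boxer", "dog", "boxer", True), ("Beagle", "dog", "beagle", False),
            ("Dingo", "dog", "dingo", False)]
    rows += [(f"Wolf{i}", "wolf", f"pop{i}", False) for i in range(6)]
    rows += [("Coyote", "outgroup", "coyote", False)]
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample", "group", "population", "is_reference"])
    )


def make_track(sample, values, chrom="chr1", spacing=50, start=25):
    pos = start + spacing * np.arange(len(values))
    return ProbeTrack(
        sample,
        pd.DataFrame({"chrom": chrom, "position": pos, "log2ratio": values}),
    )


@pytest.fixture
def track_factory():
    return make_track


SMALL_PIPELINE_CONFIG = {
    "seed": 7,
    "simulation": {
        "chrom_lengths": {"chr1": 600_000, "chr2": 600_000},
        "n_cnv_loci": 12,
        "n_control_regions": 10,
        "n_genes": 30,
    },
    "n_resamples": 50,
    "he_draws": 200,
}


@pytest.fixture(scope="session")
def small_pipeline_result():
    """One shared scaled-down end-to-end synthetic run."""
    return run_pipeline(validate_config(dict(SMALL_PIPELINE_CONFIG)))
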