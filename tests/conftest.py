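import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methdx.genome import ReferenceGenome

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_genome() -> ReferenceGenome:
    """Hand-checkable two-sequence genome with one unplaced scaffold."""
    return ReferenceGenome(
        {
            "chr1": "AACGTTACGGTACGCGATCCGGAT" * 3,
            "scaffold1": "TTACGCATGCACGT" * 5,
        },
        {"chr1": "chromosome", "scaffold1": "unplaced"},
    )


def make_site_table(rows, cpg_merged=False) -> pd.DataFrame:
    """rows: (chrom, pos, strand, context, u, c, o)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "context",
            "n_unconverted", "n_converted", "n_other",
        ],
    )
    df.attrs["cpg_merged"] = cpg_merged
    return df
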