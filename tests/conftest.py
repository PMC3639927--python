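import numpy as np
import pandas as pd
import pytest

from lce_cnvpop.io_formats import PROBE_COLUMNS, ProbeTable


def make_probe_table(signals, spacing=10_000, chrom="chr1", comparison_id="T_vs_R", origin=0):
    """Build a ProbeTable from a list of (log2_direct, log2_swap) pairs.

    Probes tile contiguously from ``origin`` at ``spacing`` bp.  ``None``
    stands for a missing label.
    """
    rows = []
    for i, (d, s) in enumerate(signals):
        start = origin + i * spacing
        rows.append(
            (
                chrom,
                start,
                start + spacing,
                f"P{i:04d}",
                np.nan if d is None else float(d),
                np.nan if s is None else float(s),
            )
        )
    df = pd.DataFrame(rows, columns=PROBE_COLUMNS)
    return ProbeTable(probes=df, comparison_id=comparison_id)


def flat_probes(value, n, **kwargs):
    """n probes with direct=value and a perfectly mirrored swap label."""
    return make_probe_table([(value, -value)] * n, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def genotype_frame():
    """Small two-population genotype table with one missing value per locus."""
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(1, 9)],
            "population": ["POPA"] * 5 + ["POPB"] * 3,
            "cnv_genotype": ["+/+", "+/-", "-/-", "+/-", "NA", "+/+", "+/+", "+/-"],
            "snp_genotype": ["AA", "AG", "GG", "AG", "AG", "NA", "AA", "AG"],
        }
    )
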