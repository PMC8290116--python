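import numpy as np
import pandas as pd
import pytest

from cladesv.alignment_io import AlignmentRecord


def make_record(
    query_name="scaf1",
    query_len=6_000,
    query_start=0,
    query_end=1_500,
    strand="+",
    target_name="chr1",
    target_len=5_000_000,
    target_start=100_000,
    target_end=101_500,
    mapq=60,
    tp="P",
    dv=0.10,
):
    tags = {"tp": tp}
    tag_types = {"tp": "A"}
    if dv is not None:
        tags["dv"] = dv
        tag_types["dv"] = "f"
    span = target_end - target_start
    return AlignmentRecord(
        query_name=query_name,
        query_len=query_len,
        query_start=query_start,
        query_end=query_end,
        strand=strand,
        target_name=target_name,
        target_len=target_len,
        target_start=target_start,
        target_end=target_end,
        residue_matches=max(1, span - 10),
        block_len=span,
        mapq=mapq,
        tags=tags,
        tag_types=tag_types,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def site_frame():
    """Builder for tiny site-frequency frames from (p1,p2,p3,p4) tuples."""

    def build(patterns, chrom="chr1", spacing=1000):
        rows = [
            {"chrom": chrom, "pos": (i + 1) * spacing, "p1": p1, "p2": p2, "p3": p3, "p4": p4}
            for i, (p1, p2, p3, p4) in enumerate(patterns)
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "p1", "p2", "p3", "p4"])

    return build
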