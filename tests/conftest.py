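import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from bindsig.genes import _finalize_annotation, promoters_from_annotation
from bindsig.intervals import PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def make_peakset(rows, label=""):
    """rows: iterable of (chrom, start, end) or (chrom, start, end, name)."""
    recs = []
    for row in rows:
        rec = {"chrom": row[0], "start": row[1], "end": row[2]}
        if len(row) > 3:
            rec["name"] = row[3]
        recs.append(rec)
    if not recs:
        return PeakSet(label=label)
    return PeakSet(pd.DataFrame(recs), label=label)


@pytest.fixture
def tiny_annotation():
    """Four genes on two chromosomes with mixed strands.

    chr1: geneA + [10_000, 15_000), geneB - [100_000, 110_000)
    chr2: geneC + [50_000, 55_000), geneD - [200_000, 204_000)
    """
    ann = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "start": [10_000, 100_000, 50_000, 200_000],
            "end": [15_000, 110_000, 55_000, 204_000],
            "strand": ["+", "-", "+", "-"],
            "gene_id": ["geneA", "geneB", "geneC", "geneD"],
        }
    )
    return _finalize_annotation(ann)


@pytest.fixture
def tiny_promoters(tiny_annotation):
    return promoters_from_annotation(tiny_annotation)
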