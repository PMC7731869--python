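import numpy as np
import pandas as pd
import pytest

from exodys.annotation_io import AnnotationModel, ExonInterval
from exodys.samples import SampleSheet


@pytest.fixture
def toy_annotation() -> AnnotationModel:
    """Two genes on one chromosome; gene A has two overlapping transcripts."""
    exons = [
        ExonInterval("chr1", 100, 200, "+", "A.t1.e1", "A.t1", "A"),
        ExonInterval("chr1", 400, 500, "+", "A.t1.e2", "A.t1", "A"),
        ExonInterval("chr1", 800, 900, "+", "A.t1.e3", "A.t1", "A"),
        ExonInterval("chr1", 150, 250, "+", "A.t2.e1", "A.t2", "A"),
        ExonInterval("chr1", 400, 500, "+", "A.t2.e2", "A.t2", "A"),
        ExonInterval("chr1", 5000, 5300, "-", "B.t1.e1", "B.t1", "B"),
        ExonInterval("chr1", 5600, 5700, "-", "B.t1.e2", "B.t1", "B"),
    ]
    return AnnotationModel(exons=exons)


@pytest.fixture
def small_sheet() -> SampleSheet:
    return SampleSheet(
        sample_ids=["c1", "c2", "c3", "p1", "p2", "p3"],
        conditions=["control"] * 3 + ["case"] * 3,
    )


def random_scan_instance(rng: np.random.Generator):
    """A random small count matrix for oracle-equivalence checks.

    Up to 5 transcripts of 2-5 exons, 2-3 controls and 2-3 cases; counts
    are small integers so degenerate paths (zero variance, zero control SD)
    occur naturally.
    """
    n_tx = int(rng.integers(1, 6))
    transcript_of = {}
    exon_ids = []
    for t in range(n_tx):
        for e in range(int(rng.integers(2, 6))):
            eid = f"t{t}.e{e}"
            exon_ids.append(eid)
            transcript_of[eid] = f"t{t}"
    n_ctrl = int(rng.integers(2, 4))
    n_case = int(rng.integers(2, 4))
    samples = [f"c{i}" for i in range(n_ctrl)] + [f"p{i}" for i in range(n_case)]
    counts = pd.DataFrame(
        rng.integers(0, 40, size=(len(exon_ids), len(samples))),
        index=exon_ids, columns=samples,
    )
    sheet = SampleSheet(sample_ids=samples,
                        conditions=["control"] * n_ctrl + ["case"] * n_case)
    return counts, transcript_of, sheet
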