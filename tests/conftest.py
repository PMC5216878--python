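import numpy as np
import pytest

from beanscan.seqdata import (
    Dataset,
    LocusAlignment,
    PopulationLabel,
    RegionAnnotation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_alignment(rng, n=None, L=None, locus_id="rand",
                     alphabet="ACGT", max_n=8, max_L=30):
    """Small random alignment for oracle-equivalence checks."""
    n = n or int(rng.integers(2, max_n + 1))
    L = L or int(rng.integers(1, max_L + 1))
    rows = {
        f"s{i}": "".join(rng.choice(list(alphabet), size=L))
        for i in range(n)
    }
    return LocusAlignment(locus_id, rows)


@pytest.fixture
def two_pop_alignment():
    """4 wild + 4 domesticated rows with shared and private variation."""
    wild = LocusAlignment("toy", {
        "w1": "ACGTACGTAC",
        "w2": "ACGTACGTAC",
        "w3": "ACGAACGTAC",
        "w4": "ACGAACTTAC",
    })
    dom = LocusAlignment("toy", {
        "d1": "ACGTACGTAC",
        "d2": "ACGAACGTAC",
        "d3": "ACGTACGTGC",
        "d4": "ACGTACGTGC",
    })
    return wild, dom


@pytest.fixture
def annotated_dataset():
    """One locus: 6 bp exon + 4 bp intron, MW/MD rows, for region logic."""
    rows = {
        "w1": "ATGAAATTTT",
        "w2": "ATGAAATTTT",
        "w3": "ATGAAACTTT",
        "d1": "ATGAAATTTT",
        "d2": "ATGAAATTTT",
    }
    aln = LocusAlignment("L1", rows)
    ann = RegionAnnotation("L1", ((0, 6, "exon"), (6, 10, "intron")), 0)
    manifest = {"w1": PopulationLabel.MW, "w2": PopulationLabel.MW,
                "w3": PopulationLabel.MW,
                "d1": PopulationLabel.MD, "d2": PopulationLabel.MD}
    return Dataset(loci=[aln], annotations={"L1": ann}, manifest=manifest)
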