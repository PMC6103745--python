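import numpy as np
import pandas as pd
import pytest

from splicescreen import (
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    SpliceEvent,
    simulate_junction_counts,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_screen():
    """A 1000-barcode screen with 10 planted hits at 8x enrichment."""
    return simulate_screen(1000, 10, 8.0, 1e6, n_replicates=2, seed=7)


@pytest.fixture(scope="session")
def small_junctions():
    """200 SE events, 20 with a planted |delta PSI| of 0.4."""
    return simulate_junction_counts(
        200, 3, 100, 0.3, n_delta_events=20, delta_psi=0.4, seed=3
    )


@pytest.fixture()
def toy_expression():
    """Four genes, one sample, strictly decreasing expression."""
    return pd.DataFrame(
        {"s1": [4.0, 3.0, 2.0, 1.0]}, index=pd.Index(["g1", "g2", "g3", "g4"], name="gene")
    )


@pytest.fixture()
def toy_genome():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture()
def se_event():
    return SpliceEvent(
        event_id="ev1",
        gene="FLNB",
        etype="SE",
        chrom="chr3",
        strand="+",
        exon_start=1_000,
        exon_end=1_150,
        upstream_exon=(400, 600),
        downstream_exon=(2_000, 2_200),
    )


def make_peaks(label, triples, **kwargs):
    """Helper: PeakSet from (chrom, start, end) triples."""
    return PeakSet(
        label,
        [GenomicInterval(c, s, e, name=f"{label}{i}", **kwargs) for i, (c, s, e) in enumerate(triples)],
    )


@pytest.fixture()
def peaks_factory():
    return make_peaks
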