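import numpy as np
import pandas as pd
import pytest

from introndelay.models import CellCycleSchedule, GeneModel, SimulationConfig


@pytest.fixture(scope="session")
def default_schedule():
    return CellCycleSchedule.drosophila_default()


@pytest.fixture
def single_exon_gene():
    return GeneModel("gA", "chr2L", "+", ((1000, 6000),), origin="zygotic")


@pytest.fixture
def three_gene_annotation():
    """One isolated gene plus a nested pair sharing exonic space."""
    g_iso = GeneModel("iso", "chr2L", "+", ((100, 600),), origin="maternal")
    g_outer = GeneModel("outer", "chr2L", "+", ((2000, 2500), (3000, 3600)), origin="zygotic")
    g_inner = GeneModel("inner", "chr2L", "-", ((3100, 3400),), origin="zygotic")
    return [g_iso, g_outer, g_inner]


def make_reads(intervals, chrom="chr2L", strand="+"):
    """Helper: build a read table from (start, end) pairs."""
    df = pd.DataFrame(intervals, columns=["start", "end"])
    df.insert(0, "chrom", chrom)
    df["name"] = [f"r{i}" for i in range(len(df))]
    df["score"] = 0
    df["strand"] = strand
    return df


@pytest.fixture
def reads_factory():
    return make_reads
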