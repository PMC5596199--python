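"""Shared fixtures: toy annotations and compact simulation configs."""

import numpy as np
import pandas as pd
import pytest

from regulocate import Gene, GenomeAnnotation, SimulationConfig
from regulocate.motifs import HIT_COLUMNS


@pytest.fixture
def toy_annotation():
    """Seven genes: a 3-gene '+' operon, two singletons, a 2-gene operon.

    Layout (all '+', gaps >= 250):
      op1: g1 1001-1400, g2 1700-2100, g3 2400-2800
      op2: g4 3600-4000   (singleton, motif planted upstream)
      op3: g5 4600-5000   (singleton, no motif)
      op4: g6 5600-6000, g7 6300-6700
    """
    genes = [
        Gene("g1", "chr", 1001, 1400, "+", "op1", 1),
        Gene("g2", "chr", 1700, 2100, "+", "op1", 2),
        Gene("g3", "chr", 2400, 2800, "+", "op1", 3),
        Gene("g4", "chr", 3600, 4000, "+", "op2", 1),
        Gene("g5", "chr", 4600, 5000, "+", "op3", 1),
        Gene("g6", "chr", 5600, 6000, "+", "op4", 1),
        Gene("g7", "chr", 6300, 6700, "+", "op4", 2),
    ]
    return GenomeAnnotation(genes, {"chr": 8000})


@pytest.fixture
def toy_hits():
    """Intergenic hits upstream of op1's first gene and of singleton g4."""
    return pd.DataFrame(
        [("chr", 940, 953, "+", 10.0, 1e-6),     # ends 48 bp before g1
         ("chr", 3550, 3563, "-", 10.0, 1e-6)],  # ends 37 bp before g4
        columns=HIT_COLUMNS)


@pytest.fixture
def small_config():
    """Compact two-replicon dataset: fast to simulate, same effect structure."""
    return SimulationConfig(
        replicon_names=("chrA", "hot"),
        replicon_lengths=(300_000, 260_000),
        n_genes=(140, 120),
        hot_region=(1, 20_000, 160_000),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
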