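import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from dmrcall.dmr import LibraryInfo, MethylationMatrix


def make_matrix(chrom, pos, meth, unmeth, groups=("high", "high", "low", "low")):
    """Build a MethylationMatrix from plain lists (one row per CpG)."""
    rep = {"high": 0, "low": 0}
    libs = []
    for g in groups:
        rep[g] += 1
        libs.append(LibraryInfo(f"{g}_rep{rep[g]}", g, rep[g]))
    return MethylationMatrix(
        np.array(chrom, dtype=object),
        np.array(pos, dtype=np.int64),
        libs,
        np.array(meth, dtype=np.int64),
        np.array(unmeth, dtype=np.int64),
    )


def matrix_from_betas(betas, coverage=100, chrom="chr1", start=1000, spacing=10):
    """Matrix where every library observes the given per-site betas exactly.

    ``betas`` is a list of per-library tuples per site, or a flat list
    applied to all libraries.
    """
    n = len(betas)
    pos = [start + i * spacing for i in range(n)]
    meth, unmeth = [], []
    for b in betas:
        row_b = b if isinstance(b, (tuple, list)) else (b, b, b, b)
        meth.append([round(x * coverage) for x in row_b])
        unmeth.append([coverage - round(x * coverage) for x in row_b])
    return make_matrix([chrom] * n, pos, meth, unmeth)


@pytest.fixture
def simple_matrix():
    """Four libraries, three CpGs, all well covered."""
    return make_matrix(
        ["chr1", "chr1", "chr1"],
        [100, 150, 200],
        [[8, 9, 6, 5], [20, 18, 2, 3], [10, 10, 10, 10]],
        [[2, 1, 4, 5], [0, 2, 18, 17], [10, 10, 10, 10]],
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-parameter simulated dataset, shared across tests."""
    from dmrcall.simulate import SimConfig, simulate_methylome

    return simulate_methylome(SimConfig(seed=7))
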