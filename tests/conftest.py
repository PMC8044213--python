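import numpy as np
import pandas as pd
import pytest

from methdyn.io import SITE_COLUMNS, MethylomeTrack
from methdyn.simulate import default_fixture


def make_track(records, sample_id="test"):
    """Build a track from (chrom, pos, strand, context, meth, total) tuples."""
    return MethylomeTrack(sample_id, pd.DataFrame(records, columns=SITE_COLUMNS))


def uniform_track(positions, level, coverage, chrom="chr1", seed=0, sample_id="u"):
    """Binomial sampling at a constant true level (perfect conversion)."""
    rng = np.random.default_rng(seed)
    total = np.full(len(positions), coverage, dtype=int)
    meth = rng.binomial(total, level)
    return make_track(
        [
            (chrom, int(p), "+", "CpG", int(k), int(n))
            for p, k, n in zip(positions, meth, total)
        ],
        sample_id,
    )


@pytest.fixture(scope="session")
def small_study():
    """Small synthetic two-lineage study for cheap integration tests."""
    arch, truth, config = default_fixture(seed=11, scale=0.2)
    return arch, truth, config


@pytest.fixture(scope="session")
def study():
    """The default-scale synthetic study (two 1 Mb chromosomes)."""
    arch, truth, config = default_fixture(seed=1, scale=1.0)
    return arch, truth, config
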