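import numpy as np
import pandas as pd
import pytest

from pmd_rewire.core import MethylomeTrack


def make_track(m_values, coverage=20, spacing=100, chrom="chr1", sample="toy",
               chrom_len=None, start=100):
    """Deterministic toy track: per-site counts meth = round(m * coverage)."""
    m = np.asarray(m_values, float)
    pos = start + np.arange(m.size) * spacing
    meth = np.round(m * coverage).astype(int)
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "meth": meth, "total": coverage}
    )
    size = chrom_len or int(pos[-1]) + spacing
    return MethylomeTrack(sample, sites, {chrom: size})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_920)
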