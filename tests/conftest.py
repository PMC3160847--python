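import numpy as np
import pytest

import promshape as ps


@pytest.fixture(scope="session")
def sim300():
    """The reference desk-scale simulation: 100 TSSDs per shape class, seed 1."""
    tssds, truth = ps.simulate_tssds((100, 100, 100), seed=1)
    return tssds, truth


@pytest.fixture(scope="session")
def fitted300(sim300):
    """Two-level classifier fitted on the reference simulation (k1=30, k2=3)."""
    tssds, _ = sim300
    est = ps.TSSDShapeClassifier(k1=30, k2=3).fit(tssds)
    return est


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_tssd(rng, width=None, n_tags=50, id_="t", chrom="chr1", strand="+", anchor=1000):
    """A random trimmed TSSD histogram for property tests."""
    w = int(width if width is not None else rng.integers(1, 30))
    counts = rng.multinomial(n_tags - 2 if w > 1 else n_tags, np.full(w, 1.0 / w))
    if w > 1:
        counts[0] += 1
        counts[-1] += 1
    return ps.TSSD(id=id_, chrom=chrom, strand=strand, anchor=anchor, counts=counts)
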