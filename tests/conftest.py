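import numpy as np
import pytest

import rhythmkit as rk


@pytest.fixture(scope="session")
def iso_clean():
    """Jitter-free isochronous series: pulse every 0.2 s, 10 s, 1 kHz."""
    return rk.gen_isochronous(rk.IsochronousSpec(period=0.2, duration=10.0, jitter_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def iso_jittered():
    """Isochronous series with 0.005-s Gaussian jitter on pulse positions."""
    return rk.gen_isochronous(
        rk.IsochronousSpec(period=0.2, duration=10.0, jitter_sd=0.005, seed=11)
    )


@pytest.fixture(scope="session")
def hier_jittered():
    """Triplets-of-double-pulses series with 0.005-s gap jitter."""
    return rk.gen_hierarchical(rk.HierarchicalSpec(duration=10.0, jitter_sd=0.005, seed=12))


@pytest.fixture(scope="session")
def poisson_10s():
    """Random series: homogeneous Poisson, 12 events/s, 10 s."""
    return rk.gen_poisson(rk.PoissonSpec(rate=12.0, duration=10.0, seed=13))


@pytest.fixture(scope="session")
def synthetic_trio_dists(iso_jittered, hier_jittered, poisson_10s):
    """Log-IEI distributions of the three reference series on one shared grid."""
    seqs = [rk.intervals(s) for s in (iso_jittered, hier_jittered, poisson_10s)]
    return rk.log_iei_distribution(seqs, labels=["iso", "hier", "rand"])
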