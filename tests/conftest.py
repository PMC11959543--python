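import pytest

from dualbind.intervals import GenomicRegion, RegionSet
from dualbind.simulate import SimulationConfig, simulate_study


def region(chrom, start, end, **kw):
    return GenomicRegion(chrom, start, end, **kw)


def regionset(*triples, **kw):
    return RegionSet([GenomicRegion(*t) for t in triples], **kw)


@pytest.fixture(scope="session")
def default_study():
    """One shared default-simulation study (seed fixed)."""
    return simulate_study(SimulationConfig(seed=2))


@pytest.fixture(scope="session")
def symmetric_noise_free_study():
    """Deterministic, A/B-symmetric design: exact dominance recovery holds."""
    cfg = SimulationConfig(
        seed=5,
        dispersion=None,
        summit_jitter_sd=0.0,
        n_common_a_dominant=40,
        n_common_similar=40,
        n_common_b_dominant=40,
        n_a_only=50,
        n_b_only=50,
        n_noise_peaks=0,
        n_fallback_sites=0,
        ratio_a_dominant=(2.0, 2.0),
        ratio_similar=(1.0, 1.0),
    )
    return simulate_study(cfg)
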