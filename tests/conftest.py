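import numpy as np
import pytest

from centrospat import DEFAULT_REGION, GeneratorConfig, NucleusRegion, SpotPattern


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def region():
    return DEFAULT_REGION


@pytest.fixture
def small_region():
    return NucleusRegion(center=(0.0, 0.0), radius=10.0)


def random_pattern(rng, n, radius=10.0):
    """Uniform pattern with n spots in a centered disk (test helper)."""
    region = NucleusRegion(center=(0.0, 0.0), radius=radius)
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-radius, radius, (4 * n, 2))
        pts.extend(cand[(cand**2).sum(axis=1) <= radius**2][: n - len(pts)])
    return SpotPattern(region, np.array(pts), "test")


@pytest.fixture
def csr_pattern(rng):
    from centrospat import sample_csr

    return sample_csr(DEFAULT_REGION, 46, rng)


@pytest.fixture
def nine_configs():
    return {m: GeneratorConfig(model=m) for m in
            ("CSR", "PDS", "UTA", "UTHA", "S2DG", "T2DG", "TH2DG", "2DGNB", "T2DGTNB")}
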