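import math

import numpy as np
import pytest

import repliprog as rp


@pytest.fixture(scope="session")
def yeast_growth() -> rp.GrowthRate:
    """Slow-growing budding yeast culture (doubling time 120 min)."""
    return rp.GrowthRate(9.6e-5)


@pytest.fixture(scope="session")
def four_origin_params() -> rp.YeastModelParams:
    """Benchmark chromosome: 300 kb, four well-separated origins.

    Intensities sit in the informative range I*/Lambda ~ 2-15: strong
    enough to leave clear peaks, weak enough that the peak level r/(1+r)
    has not saturated and the intensity remains identifiable.
    """
    origins = rp.PointOriginSet.single_chrom(
        [40e3, 110e3, 180e3, 260e3], [2e-5, 4e-5, 8e-5, 1.5e-4]
    )
    return rp.YeastModelParams(origins=origins, lam_hat=1e-5)


@pytest.fixture(scope="session")
def coli_growth() -> rp.GrowthRate:
    """E. coli-like culture with a 45 min doubling time."""
    return rp.GrowthRate(math.log(2.0) / 2700.0)


@pytest.fixture(scope="session")
def oscillating_truth(coli_growth) -> rp.BacterialParams:
    """Ground truth for the bacterial speed-fluctuation recovery fixture."""
    return rp.BacterialParams(
        L=4641652.0,
        v0=800.0,
        D=1e6,
        growth=coli_growth,
        modulation=rp.SpeedModulation(0.15, 2.0 * math.pi / 2700.0, 1.5),
    )


@pytest.fixture(scope="session")
def random_origin_case():
    """Factory for random point-origin configurations (Fig-2b-style
    intensities, log-uniform on [1e-5, 2e-3] per bp)."""

    def make(rng: np.random.Generator, k_max: int = 10, length: float = 1.6e6):
        k = int(rng.integers(1, k_max + 1))
        pos = np.sort(rng.uniform(0, length, k))
        while len(np.unique(pos)) < k:
            pos = np.sort(rng.uniform(0, length, k))
        iota = 10 ** rng.uniform(-5, np.log10(2e-3), k)
        return rp.YeastModelParams(
            origins=rp.PointOriginSet.single_chrom(pos, iota), lam_hat=9.6e-5 / 27.0
        )

    return make
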