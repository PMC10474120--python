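import numpy as np
import pytest

from ppekinetics import (
    MonomerSpec,
    RateSet,
    SynthConfig,
    conversions,
    default_time_grid,
    generate,
    truncate,
)


def pair_species(names=("A", "B")):
    return tuple(MonomerSpec(n, 100.0) for n in names)


def binary_rates(r1: float) -> RateSet:
    return RateSet.from_ratios(pair_species(), [r1])


def make_series(
    r1: float,
    f0=(0.5, 0.5),
    n_points: int = 60,
    noise_sigma: float = 0.0,
    seed: int = 0,
    final_conversion: float = 0.9,
    x_max: float | None = 0.6,
):
    """Noisy or noiseless binary conversion series from a known true ratio."""
    cfg = SynthConfig(
        rates=binary_rates(r1),
        f0=f0,
        noise_sigma=noise_sigma,
        seed=seed,
        final_conversion=final_conversion,
        time_grid=default_time_grid(n_points, 24 * 60.0),
    )
    series = conversions(generate(cfg))
    if x_max is not None:
        series = truncate(series, x_max)
    return series


def ternary_series(
    k=(4.0, 2.0, 1.0),
    f0=(1 / 3, 1 / 3, 1 / 3),
    n_points: int = 60,
    noise_sigma: float = 0.0,
    seed: int = 0,
    final_conversion: float = 0.9,
    x_max: float | None = 0.6,
):
    species = tuple(MonomerSpec(n, 100.0) for n in ("A", "B", "C"))
    cfg = SynthConfig(
        rates=RateSet(species, tuple(float(v) for v in k)),
        f0=f0,
        noise_sigma=noise_sigma,
        seed=seed,
        final_conversion=final_conversion,
        time_grid=default_time_grid(n_points, 24 * 60.0),
    )
    series = conversions(generate(cfg))
    if x_max is not None:
        series = truncate(series, x_max)
    return series


@pytest.fixture
def p1_noiseless_dataset():
    from ppekinetics import preset

    return generate(preset("P1", noise_sigma=0.0, n_points=60))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
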