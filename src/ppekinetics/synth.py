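"""Synthetic real-time 31P NMR kinetics datasets.

The generator emulates what the spectrometer delivers for a living
statistical ring-opening copolymerization followed in situ: one monomer and
one polymer integral per phosphoester species on a shared time grid.  Under
the nonterminal model each monomer decays first order,

    [M_i](t) = [M_i]0 * exp(-k_i * kappa * t),

with relative rates ``k_i`` and a single global scale ``kappa`` chosen so
the dataset reaches its configured final conversion at the last time point
(absolute time is cosmetic; only ratios are identifiable from composition
data).  Total 31P signal per species is conserved — monomer plus polymer
integral is constant — and integration error is modelled as independent
multiplicative Gaussian noise per integral, since NMR integral error scales
with peak area.

Named presets emulate the ten copolymerizations of the study (P1-P10):
species, printed degrees of polymerization, total conversions, catalysts and
reaction times are taken from the published synthesis table, and the "true"
reactivity ratios are reconstructed from the printed gradient strengths Δr
under the ideal constraint r1·r2 = 1.  The weighed-in feeds are not printed;
they are recovered by inverting the drift model so that the cumulative
composition at the printed total conversion reproduces the printed DP
fractions.  These presets are model-consistent reconstructions, not the
(unavailable) raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .chemistry import INITIATOR_MASSES
from .ingest import KineticsDataset
from .kinetics import (
    MonomerSpec,
    RateSet,
    feed_for_final_composition,
    ratios_from_delta,
)

__all__ = ["SynthConfig", "generate", "preset", "preset_names", "default_time_grid"]

#: measurement conditions of the emulated kinetics protocol (metadata only)
PROTOCOL = {
    "solvent": "DCM",
    "total_monomer_conc_mol_L": 4.0,
    "temperature_C": -10.0,
    "nmr_delay_D1_s": 30.0,
}


def default_time_grid(n_points: int = 40, total_minutes: float = 24 * 60.0) -> np.ndarray:
    """Acquisition time grid in minutes, mimicking a real-time NMR schedule.

    The first ten spectra are 5.7 min apart, spectra 10-20 are 11.3 min
    apart, and the remaining points are spaced geometrically out to
    ``total_minutes`` (slow reactions are sampled ever more sparsely).  If
    ``n_points`` is too small for the head schedule, or ``total_minutes``
    too short, a quadratic grid (dense early) is used instead.
    """
    if n_points < 4:
        raise ValueError("need at least 4 time points")
    head = [0.0]
    for _ in range(9):
        head.append(head[-1] + 5.7)
    for _ in range(10):
        head.append(head[-1] + 11.3)
    if n_points <= len(head) or total_minutes <= head[-1] * 1.5:
        u = np.linspace(0.0, 1.0, n_points)
        return total_minutes * u * u
    tail_n = n_points - len(head)
    ratio = (total_minutes / head[-1]) ** (1.0 / tail_n)
    tail = head[-1] * ratio ** np.arange(1, tail_n + 1)
    return np.concatenate([head, tail])


@dataclass
class SynthConfig:
    """Everything needed to generate one synthetic kinetics dataset."""

    rates: RateSet
    f0: tuple[float, ...]
    total_monomer_conc: float = 4.0          # mol/L, protocol default
    monomer_to_initiator: float = 100.0      # targeted total DP
    time_grid: np.ndarray = field(default_factory=default_time_grid)
    noise_sigma: float = 0.02                # relative sd of integral noise
    seed: int = 0
    final_conversion: float = 0.95
    initiator: str = "2-methoxyethanol"
    rate_scale: float | None = None          # kappa override (1/min); None -> solved
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.time_grid.ndim != 1 or len(self.time_grid) < 4:
            raise ValueError("time_grid must be 1-D with >= 4 points")
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 < self.final_conversion <= 1.0):
            raise ValueError("final_conversion must lie in (0, 1]")
        f0 = np.asarray(self.f0, dtype=float)
        if f0.shape != (self.rates.n,) or abs(f0.sum() - 1.0) > 1e-9:
            raise ValueError("f0 must have one entry per species and sum to 1")
        self.f0 = tuple(float(v) for v in f0 / f0.sum())
        if self.initiator not in INITIATOR_MASSES:
            raise ValueError(f"unknown initiator {self.initiator!r}")


def _solve_rate_scale(config: SynthConfig) -> float:
    """kappa (1/min) such that X(t_end) equals the configured final conversion."""
    k = np.asarray(config.rates.k, dtype=float)
    f0 = np.asarray(config.f0, dtype=float)
    t_end = float(config.time_grid[-1])
    target = min(config.final_conversion, 1.0 - 1e-12)

    def conv(kappa: float) -> float:
        return 1.0 - float(f0 @ np.exp(-k * kappa * t_end)) - target

    hi = 1.0 / t_end
    while conv(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("could not bracket rate scale")
    return brentq(conv, 1e-18, hi, xtol=1e-18, rtol=8.9e-16)


def generate(config: SynthConfig) -> KineticsDataset:
    """Generate the dataset: per species, noisy monomer and polymer integrals.

    Noise draws are ordered deterministically (whole monomer matrix, then
    whole polymer matrix) so an identical config and seed reproduce the
    dataset bit for bit.
    """
    k = np.asarray(config.rates.k, dtype=float)
    f0 = np.asarray(config.f0, dtype=float)
    kappa = config.rate_scale if config.rate_scale is not None else _solve_rate_scale(config)
    t = config.time_grid
    with np.errstate(under="ignore"):
        a = np.exp(-np.outer(t, k) * kappa)  # survival per (time, species)
    conc0 = config.total_monomer_conc * f0
    monomer = conc0 * a
    polymer = conc0 * (1.0 - a)
    rng = np.random.default_rng(config.seed)
    if config.noise_sigma > 0:
        monomer = monomer * (1.0 + rng.normal(0.0, config.noise_sigma, monomer.shape))
        polymer = polymer * (1.0 + rng.normal(0.0, config.noise_sigma, polymer.shape))
    meta = {
        "species": list(config.rates.names),
        "feed": [float(v) for v in f0],
        "initiator": config.initiator,
        "seed": config.seed,
        "noise_sigma": config.noise_sigma,
        "monomer_to_initiator": config.monomer_to_initiator,
        "final_conversion": config.final_conversion,
        "rate_scale_per_min": kappa,
        **PROTOCOL,
        **config.meta,
    }
    return KineticsDataset(
        time=t.copy(),
        species=list(config.rates.names),
        monomer=np.clip(monomer, 0.0, None),
        polymer=np.clip(polymer, 0.0, None),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# preset library (P1-P10 of the published synthesis table)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _PresetRecord:
    name: str
    species: tuple[str, ...]
    dp: tuple[int, ...]                   # printed DP per monomer
    total_conversion: float               # printed total conversion
    delta_r: tuple[float, ...]            # printed Δr per adjacent pair
    catalysts: str
    reaction_time_h: float
    initiator: str


def _initiator_for(species: tuple[str, ...]) -> str:
    # EPP-containing systems were initiated from 2-(benzyloxy)ethanol
    # (their end-group NMR shows benzylic protons); everything else from
    # 2-methoxyethanol.
    return "2-(benzyloxy)ethanol" if "EPP" in species else "2-methoxyethanol"


def _rec(name, species, dp, conv, delta_r, catalysts, hours) -> _PresetRecord:
    return _PresetRecord(
        name, tuple(species), tuple(dp), conv, tuple(delta_r),
        catalysts, hours, _initiator_for(tuple(species)),
    )


PRESETS: Mapping[str, _PresetRecord] = {
    "P1": _rec("P(PhPPn-grad-MePPn)", ("PhPPn", "MePPn"), (48, 41), 0.93, (5,), "DBU", 22),
    "P2": _rec("P(PhPPn-grad-EtPPn)", ("PhPPn", "EtPPn"), (48, 43), 0.83, (24,), "DBU", 24),
    "P3": _rec("P(EtPPn-grad-ETP)", ("EtPPn", "ETP"), (47, 19), 0.83, (16,), "DBU/TU", 26),
    "P4": _rec("P(EtPPn-grad-EEP)", ("EtPPn", "EEP"), (90, 71), 0.97, (3,), "DBU/TU", 19),
    "P5": _rec("P(EEP-grad-ETP)", ("EEP", "ETP"), (47, 33), 0.86, (10,), "DBU/TU", 30),
    "P6": _rec("P(MEP-grad-ETP)", ("MEP", "ETP"), (53, 24), 0.83, (18,), "DBU/TU", 24),
    "P7": _rec("P(EtPPn-grad-EPP)", ("EtPPn", "EPP"), (53, 29), 0.75, (26,), "DBU/TU", 68),
    "P8": _rec("P(ETP-grad-EPP)", ("ETP", "EPP"), (39, 28), 0.72, (5,), "DBU/TU", 122),
    "P9": _rec(
        "P(EtPPn-grad-ETP-grad-EPP)", ("EtPPn", "ETP", "EPP"),
        (51, 29, 13), 0.73, (14, 13), "DBU/TU", 125,
    ),
    # Δr values for P10 are not printed; the P9 pair strengths are reused on
    # the inverted incorporation order (EPP before ETP under DBU/TrisUrea).
    "P10": _rec(
        "P(EtPPn-grad-EPP-grad-ETP)", ("EtPPn", "EPP", "ETP"),
        (50, 32, 25), 0.98, (14, 13), "DBU/TrisUrea", 45,
    ),
}


def preset_names() -> list[str]:
    return list(PRESETS)


def preset(
    name: str,
    *,
    noise_sigma: float = 0.02,
    seed: int = 0,
    n_points: int = 40,
) -> SynthConfig:
    """Fully populated SynthConfig emulating one of the study's runs P1-P10."""
    try:
        rec = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESETS)}"
        ) from None
    species = tuple(MonomerSpec.from_library(s) for s in rec.species)
    ratios = [ratios_from_delta(d)[0] for d in rec.delta_r]
    rates = RateSet.from_ratios(species, ratios)
    dp = np.asarray(rec.dp, dtype=float)
    f0 = feed_for_final_composition(rates, dp / dp.sum(), rec.total_conversion)
    m2i = dp.sum() / rec.total_conversion  # so DP_i = x_i * f0_i * m2i round-trips
    return SynthConfig(
        rates=rates,
        f0=tuple(float(v) for v in f0),
        monomer_to_initiator=float(m2i),
        time_grid=default_time_grid(n_points, rec.reaction_time_h * 60.0),
        noise_sigma=noise_sigma,
        seed=seed,
        final_conversion=rec.total_conversion,
        initiator=rec.initiator,
        meta={
            "preset": name,
            "copolymer": rec.name,
            "catalysts": rec.catalysts,
            "reaction_time_h": rec.reaction_time_h,
            "dp_printed": list(rec.dp),
            "delta_r_printed": list(rec.delta_r),
        },
    )
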