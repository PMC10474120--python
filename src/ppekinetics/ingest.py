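"""Integral time series in, conversion series out.

The pipeline starts from integral tables, not raw spectra: one row per
spectrum, one monomer and one polymer integral column per phosphoester
species.  CSV dialect::

    # species=PhPPn,MePPn
    # feed=0.52,0.48
    # initiator=2-methoxyethanol
    time_min,PhPPn_monomer,PhPPn_polymer,MePPn_monomer,MePPn_polymer
    0,2.08,0,1.92,0
    ...

Leading ``#`` lines carry optional metadata (``key=value``); UTF-8, '.'
decimal separator.  Because monomer plus polymer 31P signal per species is
conserved during a clean living polymerization, the per-species sum is both
the natural normalization for conversions and a quality-control handle.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KineticsDataset",
    "ConversionSeries",
    "read_csv",
    "write_csv",
    "conversions",
    "truncate",
    "qc",
]

log = logging.getLogger(__name__)

#: fewer time points than this cannot support any of the fits
MIN_POINTS = 4

#: relative trend drift of a species' total signal that triggers a QC warning
QC_DRIFT_WARN = 0.05


@dataclass
class KineticsDataset:
    """Time-stamped monomer/polymer integrals per species plus metadata."""

    time: np.ndarray                      # minutes, strictly increasing
    species: list[str]
    monomer: np.ndarray                   # shape (n_time, n_species)
    polymer: np.ndarray                   # shape (n_time, n_species)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.monomer = np.asarray(self.monomer, dtype=float)
        self.polymer = np.asarray(self.polymer, dtype=float)
        nt, ns = len(self.time), len(self.species)
        if nt < MIN_POINTS:
            raise ValueError(f"need >= {MIN_POINTS} time points, got {nt}")
        if np.any(np.diff(self.time) <= 0):
            bad = int(np.argmax(np.diff(self.time) <= 0))
            raise ValueError(f"time not strictly increasing (first violation at row {bad + 1})")
        for name, arr in (("monomer", self.monomer), ("polymer", self.polymer)):
            if arr.shape != (nt, ns):
                raise ValueError(f"{name} integrals must have shape ({nt}, {ns}), got {arr.shape}")
            if np.any(arr < 0):
                raise ValueError(f"negative {name} integrals after cleaning")

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass
class ConversionSeries:
    """Per-monomer conversions x_i(t) and their feed-weighted total X(t)."""

    time: np.ndarray
    species: list[str]
    x: np.ndarray                         # shape (n_time, n_species), in [0, 1]
    X: np.ndarray                         # total conversion, in [0, 1]
    f0: np.ndarray                        # feed fractions used for weighting

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if np.any(self.x < -1e-12) or np.any(self.x > 1 + 1e-12):
            raise ValueError("conversions must lie in [0, 1]")
        if np.max(np.abs(self.X - self.x @ self.f0)) > 1e-9:
            raise ValueError("X must be the f0-weighted mean of per-monomer conversions")

    def index(self, name: str) -> int:
        return self.species.index(name)

    def __len__(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    # shortest decimal that round-trips the double exactly
    return repr(float(v))


def write_csv(ds: KineticsDataset, path) -> None:
    """Write the dataset in the package dialect.

    Floats are written as their shortest exact decimal representation, so
    a write/read cycle is lossless and identical data produce identical
    bytes.
    """
    lines: list[str] = []
    lines.append(f"# species={','.join(ds.species)}")
    feed = ds.meta.get("feed")
    if feed is not None:
        lines.append("# feed=" + ",".join(_fmt(v) for v in feed))
    initiator = ds.meta.get("initiator")
    if initiator is not None:
        lines.append(f"# initiator={initiator}")
    for key in sorted(ds.meta):
        if key in ("species", "feed", "initiator"):
            continue
        val = ds.meta[key]
        if isinstance(val, float):
            val = _fmt(val)
        lines.append(f"# {key}={val}")
    header = ["time_min"]
    for sp in ds.species:
        header += [f"{sp}_monomer", f"{sp}_polymer"]
    lines.append(",".join(header))
    for i, t in enumerate(ds.time):
        row = [_fmt(t)]
        for j in range(ds.n_species):
            row.append(_fmt(ds.monomer[i, j]))
            row.append(_fmt(ds.polymer[i, j]))
        lines.append(",".join(row))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)


def read_csv(path) -> KineticsDataset:
    """Read a kinetics table; negative integrals are clipped to 0 with a warning."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    meta: dict = {}
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, val = stripped.split("=", 1)
                meta[key.strip()] = val.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise ValueError("empty kinetics file")
    df = pd.read_csv(io.StringIO("\n".join(body)), float_precision="round_trip")
    if "time_min" not in df.columns:
        raise ValueError(f"missing required column 'time_min'; found {list(df.columns)}")
    species: list[str] = []
    for col in df.columns:
        if col.endswith("_monomer"):
            sp = col[: -len("_monomer")]
            if f"{sp}_polymer" not in df.columns:
                raise ValueError(f"species {sp!r} has a monomer column but no '{sp}_polymer'")
            species.append(sp)
    if not species:
        raise ValueError("no '<species>_monomer' columns found")
    if "species" in meta:
        declared = [s.strip() for s in meta["species"].split(",")]
        if set(declared) != set(species):
            raise ValueError(
                f"declared species {declared} do not match columns {species}"
            )
        species = declared  # preserve declared order
    if "feed" in meta:
        meta["feed"] = [float(v) for v in meta["feed"].split(",")]
    meta["species"] = species
    monomer = df[[f"{sp}_monomer" for sp in species]].to_numpy(dtype=float)
    polymer = df[[f"{sp}_polymer" for sp in species]].to_numpy(dtype=float)
    for name, arr in (("monomer", monomer), ("polymer", polymer)):
        n_neg = int(np.sum(arr < 0))
        if n_neg:
            log.warning("clipped %d negative %s integrals to 0", n_neg, name)
            warnings.warn(f"clipped {n_neg} negative {name} integrals to 0", stacklevel=2)
            np.clip(arr, 0.0, None, out=arr)
    return KineticsDataset(
        time=df["time_min"].to_numpy(dtype=float),
        species=species,
        monomer=monomer,
        polymer=polymer,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def conversions(
    ds: KineticsDataset, mode: str = "paired", f0=None
) -> ConversionSeries:
    """Per-monomer and total conversions from the integral table.

    ``paired`` (default): x_i = P_i / (M_i + P_i) per time point — invariant
    to any per-spectrum rescaling of all integrals (spectrometer gain).
    ``monomer_only``: x_i = 1 - M_i(t) / M_i(0) — for when a polymer
    resonance overlaps and only monomer decay is usable.

    ``f0`` defaults to the first spectrum's monomer integral fractions
    (the first spectrum precedes measurable conversion); total conversion
    is the f0-weighted mean of the per-monomer conversions.
    """
    if mode not in ("paired", "monomer_only"):
        raise ValueError(f"mode must be 'paired' or 'monomer_only', got {mode!r}")
    M, P = ds.monomer, ds.polymer
    if mode == "paired":
        total = M + P
        if np.any(total <= 0):
            i, j = np.argwhere(total <= 0)[0]
            raise ValueError(
                f"monomer+polymer integral is 0 for species {ds.species[j]!r} at row {i}"
            )
        x = P / total
    else:
        m0 = M[0]
        if np.any(m0 <= 0):
            j = int(np.argwhere(m0 <= 0)[0])
            raise ValueError(
                f"species {ds.species[j]!r} has zero monomer integral at t=0"
            )
        x = np.clip(1.0 - M / m0, 0.0, 1.0)
    if f0 is None:
        f0 = ds.meta.get("feed")
    if f0 is None:
        m0 = M[0]
        if np.any(m0 <= 0):
            j = int(np.argwhere(m0 <= 0)[0])
            raise ValueError(
                f"cannot estimate feed: species {ds.species[j]!r} has zero "
                "monomer integral at t=0; pass f0 explicitly"
            )
        f0 = m0 / m0.sum()
    f0 = np.asarray(f0, dtype=float)
    f0 = f0 / f0.sum()
    return ConversionSeries(
        time=ds.time.copy(), species=list(ds.species), x=x, X=x @ f0, f0=f0
    )


def truncate(series: ConversionSeries, x_max: float = 0.60) -> ConversionSeries:
    """Keep only points with total conversion X <= x_max.

    Reactivity-ratio fits are standardly restricted to data below ~60% total
    conversion, where the nonterminal drift assumptions are cleanest.
    """
    if not (0.0 < x_max <= 1.0):
        raise ValueError(f"x_max must lie in (0, 1], got {x_max}")
    keep = series.X <= x_max
    if int(keep.sum()) < MIN_POINTS:
        raise ValueError(
            f"only {int(keep.sum())} points with X <= {x_max}; "
            "need >= 4 — increase x_max or record more early-time spectra"
        )
    return ConversionSeries(
        time=series.time[keep],
        species=list(series.species),
        x=series.x[keep],
        X=series.X[keep],
        f0=series.f0.copy(),
    )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc(ds: KineticsDataset) -> dict:
    """Report-only QC exploiting total-31P conservation per species.

    For each species the monomer+polymer sum should be constant over time.
    ``trend_drift`` is the fitted linear change over the run relative to the
    mean (systematic loss/gain; warned above 5%); ``scatter`` is the
    relative standard deviation (integration noise level).  Non-monotone
    per-monomer conversion is flagged but never altered.
    """
    report: dict = {"species": {}, "warnings": []}
    t = ds.time
    for j, sp in enumerate(ds.species):
        total = ds.monomer[:, j] + ds.polymer[:, j]
        mean = float(total.mean())
        if mean <= 0:
            report["species"][sp] = {"trend_drift": np.nan, "scatter": np.nan}
            report["warnings"].append(f"{sp}: total signal is zero")
            continue
        slope = float(np.polyfit(t, total, 1)[0])
        trend = slope * (t[-1] - t[0]) / mean
        scatter = float(total.std(ddof=1)) / mean if len(total) > 1 else 0.0
        entry = {"trend_drift": float(trend), "scatter": float(scatter)}
        # monotonicity of the paired conversion estimate
        with np.errstate(invalid="ignore", divide="ignore"):
            x = ds.polymer[:, j] / np.where(total > 0, total, np.nan)
        n_rev = int(np.sum(np.diff(x) < 0))
        entry["n_conversion_reversals"] = n_rev
        report["species"][sp] = entry
        if abs(trend) > QC_DRIFT_WARN:
            msg = (
                f"{sp}: total 31P signal drifts {100 * trend:+.1f}% over the run "
                f"(threshold {100 * QC_DRIFT_WARN:.0f}%)"
            )
            report["warnings"].append(msg)
            log.warning(msg)
    return report


def qc_json(ds: KineticsDataset) -> str:
    """QC report serialized as JSON."""
    return json.dumps(qc(ds), indent=2, sort_keys=True, allow_nan=True)
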