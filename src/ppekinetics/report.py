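"""Polymer-level arithmetic and the Table-style report builder.

Degree of polymerization, number-average molar mass and monomer-ratio
arithmetic as determined by end-group NMR analysis:

    DP_i = round(x_i * feed_dp_i)          per-monomer conversion x feed ratio
    Mn   = Σ DP_i * M_i + M_initiator      exact linear sum
    ratio_i = 100 * DP_i / Σ DP            largest-remainder integer percents

Mn is displayed to 0.1 kg/mol ("13.9k" style).  ``build_report`` ties the
full pipeline together for a set of named presets: generate (or read) a
kinetics dataset, extract conversions, truncate, fit the three nonterminal
models, average, classify gradient strength, and emit one row per polymer
as TSV plus a JSON result bundle with provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chemistry import initiator_mass, monomer_mass
from .fit import MODELS, assess_gradient, average_models, fit_pair, fit_ternary
from .ingest import conversions, truncate
from .synth import PRESETS, generate, preset

__all__ = [
    "PolymerRecord",
    "RunConfig",
    "dp_from_conversion",
    "mn_from_dp",
    "format_mn_k",
    "monomer_ratio",
    "build_report",
]

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_FIT_FAILURE = 3


@dataclass(frozen=True)
class PolymerRecord:
    """One polymer's composition and molar-mass bookkeeping."""

    id: str
    species: tuple[str, ...]
    dp: tuple[int, ...]
    total_conversion: float
    initiator: str
    mn: float                      # g/mol
    monomer_ratio_pct: tuple[int, ...]
    catalysts: str = ""
    reaction_time_h: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.dp):
            raise ValueError("DP values must be >= 0")
        if self.monomer_ratio_pct and abs(sum(self.monomer_ratio_pct) - 100) > 1:
            raise ValueError("monomer ratio must sum to 100 within rounding")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    presets: tuple[str, ...] = tuple(PRESETS)
    noise_sigma: float = 0.0
    seed: int = 0
    n_points: int = 40
    x_max: float = 0.60
    models: tuple[str, ...] = MODELS
    lambda_flags: tuple = ()       # ((A, B), model, reason) exclusions
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        unknown = [p for p in self.presets if p not in PRESETS]
        if unknown:
            raise ValueError(f"unknown presets {unknown}; valid: {list(PRESETS)}")
        bad_models = set(self.models) - set(MODELS)
        if bad_models:
            raise ValueError(f"unknown models {sorted(bad_models)}; valid: {MODELS}")
        if not (0.0 < self.x_max <= 1.0):
            raise ValueError("x_max must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def dp_from_conversion(x, feed_dp) -> np.ndarray:
    """Per-species DP = round(conversion * feed monomer-to-initiator ratio)."""
    x = np.asarray(x, dtype=float)
    feed_dp = np.asarray(feed_dp, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("conversions must lie in [0, 1]")
    if np.any(feed_dp <= 0):
        raise ValueError("feed DP ratios must be > 0")
    return np.rint(x * feed_dp).astype(int)


def mn_from_dp(dp, molar_masses, initiator_mass_g_mol: float) -> float:
    """Number-average molar mass Mn = Σ DP_i·M_i + M_initiator, in g/mol."""
    dp = np.asarray(dp, dtype=float)
    masses = np.asarray(molar_masses, dtype=float)
    if dp.shape != masses.shape:
        raise ValueError(
            f"DP and molar-mass lists differ in length: {dp.shape} vs {masses.shape}"
        )
    if np.any(masses <= 0) or initiator_mass_g_mol <= 0:
        raise ValueError("molar masses must be > 0")
    return float(dp @ masses + initiator_mass_g_mol)


def format_mn_k(mn_g_mol: float) -> str:
    """Mn in the synthesis-table 'k' notation, rounded to 0.1 kg/mol."""
    return f"{mn_g_mol / 1000.0:.1f}k"


def monomer_ratio(dp) -> tuple[int, ...]:
    """Integer composition percentages by the largest-remainder method."""
    dp = np.asarray(dp, dtype=float)
    total = dp.sum()
    if total <= 0:
        raise ValueError("cannot compute a monomer ratio from all-zero DPs")
    raw = 100.0 * dp / total
    base = np.floor(raw).astype(int)
    short = 100 - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return tuple(int(v) for v in base)


def record_for_preset(name: str) -> PolymerRecord:
    """Table-row bookkeeping for a preset from its printed DPs and conversion."""
    rec = PRESETS[name]
    masses = [monomer_mass(s) for s in rec.species]
    mn = mn_from_dp(rec.dp, masses, initiator_mass(rec.initiator))
    return PolymerRecord(
        id=name,
        species=rec.species,
        dp=rec.dp,
        total_conversion=rec.total_conversion,
        initiator=rec.initiator,
        mn=mn,
        monomer_ratio_pct=monomer_ratio(rec.dp),
        catalysts=rec.catalysts,
        reaction_time_h=rec.reaction_time_h,
        metadata={"copolymer": rec.name, "delta_r_printed": list(rec.delta_r)},
    )


# ---------------------------------------------------------------------------
# pipeline report
# ---------------------------------------------------------------------------

def _fit_preset(name: str, config: RunConfig) -> dict:
    """Run synth -> conversions -> truncate -> fit -> classify for one preset."""
    cfg = preset(
        name, noise_sigma=config.noise_sigma, seed=config.seed,
        n_points=config.n_points,
    )
    ds = generate(cfg)
    series = truncate(conversions(ds), config.x_max)
    rec = PRESETS[name]
    out: dict = {"id": name, "species": list(rec.species)}
    if len(rec.species) == 2:
        fits = fit_pair(series, tuple(rec.species), config.models)
        avg = average_models(fits)
        grad = assess_gradient(avg)
        out["pairs"] = {
            "/".join(rec.species): _pair_payload(fits, avg, grad)
        }
        out["delta_r"] = [round(grad.delta_r, 3)]
        out["gradient_class"] = [grad.gradient_class]
    else:
        table = fit_ternary(series, tuple(rec.species), config.models, config.lambda_flags)
        out["pairs"] = {}
        deltas: list[float] = []
        classes: list[str] = []
        for pair, avg in table.averages.items():
            grad = assess_gradient(avg)
            out["pairs"]["/".join(pair)] = _pair_payload(
                table.estimates[pair], avg, grad
            )
        # adjacent pairs define the block-to-block transitions of the terpolymer
        for a, b in zip(rec.species, rec.species[1:]):
            grad = assess_gradient(table.averages[(a, b)])
            deltas.append(round(grad.delta_r, 3))
            classes.append(grad.gradient_class)
        out["delta_r"] = deltas
        out["gradient_class"] = classes
    return out


def _pair_payload(fits, avg, grad) -> dict:
    payload = {
        m: {
            "r1": e.r1, "r2": e.r2, "se1": e.se1, "se2": e.se2,
            "R2": e.R2, "n": e.n_points,
        }
        for m, e in fits.items()
    }
    payload["average"] = {
        "r1": avg.r1_mean, "r1_sd": avg.r1_sd,
        "r2": avg.r2_mean, "r2_sd": avg.r2_sd,
        "models": list(avg.models),
        "excluded": [list(e) for e in avg.excluded],
    }
    payload["delta_r"] = grad.delta_r
    payload["gradient_class"] = grad.gradient_class
    return payload


def build_report(config: RunConfig) -> dict:
    """Synthesis-table-style report for the configured presets.

    Returns a dict with ``rows`` (one per polymer), ``tsv`` (the formatted
    table) and ``provenance``; when ``config.out_dir`` is set, writes
    ``report.tsv``, ``report.json`` and ``run_log.jsonl`` there
    deterministically.
    """
    rows = []
    for name in config.presets:
        record = record_for_preset(name)
        try:
            fitted = _fit_preset(name, config)
        except (ValueError, RuntimeError) as err:
            raise RuntimeError(
                f"fit stage failed for preset {name}: {err}; "
                "run the synth/fit stages individually to diagnose"
            ) from err
        rows.append(
            {
                "id": name,
                "copolymer": record.metadata["copolymer"],
                "species": "/".join(record.species),
                "dp": "/".join(str(d) for d in record.dp),
                "monomer_ratio": "/".join(str(v) for v in record.monomer_ratio_pct),
                "total_conversion_pct": round(100.0 * record.total_conversion, 1),
                "delta_r": "/".join(format(d, "g") for d in fitted["delta_r"]),
                "gradient_class": "/".join(fitted["gradient_class"]),
                "mn_g_mol": round(record.mn, 1),
                "mn_k": format_mn_k(record.mn),
                "catalysts": record.catalysts,
                "reaction_time_h": record.reaction_time_h,
                "fits": fitted["pairs"],
            }
        )
    columns = [
        "id", "copolymer", "species", "dp", "monomer_ratio",
        "total_conversion_pct", "delta_r", "gradient_class", "mn_k",
        "catalysts", "reaction_time_h",
    ]
    tsv_lines = ["\t".join(columns)]
    for row in rows:
        tsv_lines.append("\t".join(str(row[c]) for c in columns))
    tsv = "\n".join(tsv_lines) + "\n"
    provenance = {
        "package": "ppekinetics",
        "version": __version__,
        "config": {
            "presets": list(config.presets),
            "noise_sigma": config.noise_sigma,
            "seed": config.seed,
            "n_points": config.n_points,
            "x_max": config.x_max,
            "models": list(config.models),
            "lambda_flags": [list(map(list, f)) if isinstance(f, tuple) else f
                             for f in config.lambda_flags],
        },
    }
    result = {"rows": rows, "tsv": tsv, "provenance": provenance}
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.tsv").write_text(tsv, encoding="utf-8")
        (out / "report.json").write_text(
            json.dumps({"rows": rows, "provenance": provenance},
                       indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        with open(out / "run_log.jsonl", "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(
                    {"event": "report_row", "id": row["id"],
                     "delta_r": row["delta_r"], "class": row["gradient_class"],
                     "seed": config.seed},
                    sort_keys=True) + "\n")
    return result
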