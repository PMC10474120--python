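"""Reactivity-ratio estimation by three nonterminal models.

All three estimators view the same underlying drift law — under chain-end-
independent propagation the survivals of two comonomers obey
``a_B = a_A ** (1/r1)`` with ``r1 = k_A/k_B`` — through different fitting
coordinates:

* **Jaacks**: through-origin regression of ln(1/(1-x_A)) on ln(1/(1-x_B));
  the slope is r1 directly.  (The drift law has no intercept, so none is
  fitted.)
* **BSL** (conversion-conversion integrated form): least-squares fit of
  x_B = 1 - (1-x_A)^(1/r1) by bounded 1-D minimization on log r.
* **Ideal integrated**: least-squares fit of the instantaneous unreacted
  feed fraction f_A against total conversion, with the model curve obtained
  by inverting the analytic composition relation.

On noiseless data the three agree exactly (they are reparametrizations of
one curve); with noise they respond differently, so their unweighted mean
and sample standard deviation are reported as the cross-model estimate.
r1 and r2 are fitted independently per model — their product is an implicit
diagnostic of the ideal assumption r1·r2 = 1.

Gradient strength is Δr = |r1 - r2| under the ideal constraint, classified
into soft (0, 1.5], medium (1.5, 7.5], hard (7.5, 25] and block-like
(25, ∞) copolymers.  For ternary systems every ordered pair is fitted
separately (valid because the pairwise drift is independent of the third
species), giving six ratios that may be reconciled into a consistent rate
set elsewhere.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .ingest import ConversionSeries
from .kinetics import MonomerSpec, RateSet, survival_from_conversion

__all__ = [
    "MODELS",
    "ReactivityEstimate",
    "ReactivityAverage",
    "GradientAssessment",
    "TernaryRatioTable",
    "fit_jaacks",
    "fit_bsl",
    "fit_ideal_integrated",
    "fit_pair",
    "average_models",
    "assess_gradient",
    "fit_ternary",
]

log = logging.getLogger(__name__)

MODELS = ("jaacks", "bsl", "ideal")

#: search window for the 1-D fits, in log r
_LOG_R_BOUNDS = (math.log(1e-3), math.log(1e3))
_LOG_R_XATOL = 1e-10

#: gradient-strength class boundaries (upper edges, half-open as printed)
GRADIENT_CLASSES = (("soft", 1.5), ("medium", 7.5), ("hard", 25.0), ("block", math.inf))

#: anonymous species pair used when the ideal-integrated objective needs a
#: RateSet but only the ratio matters
_DUMMY_PAIR = (MonomerSpec("ref", 1.0), MonomerSpec("other", 1.0))


@dataclass(frozen=True)
class ReactivityEstimate:
    """One model's reactivity-ratio pair with fit diagnostics."""

    model: str
    pair: tuple[str, str]
    r1: float
    r2: float
    se1: float
    se2: float
    R2: float
    n_points: int
    x_max: float

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and self.r2 > 0):
            raise ValueError(f"ratios must be positive, got ({self.r1}, {self.r2})")
        if self.R2 > 1 + 1e-12:
            raise ValueError(f"R2 cannot exceed 1, got {self.R2}")


@dataclass(frozen=True)
class ReactivityAverage:
    """Cross-model mean ± sample sd of a pair's reactivity ratios."""

    pair: tuple[str, str]
    r1_mean: float
    r1_sd: float
    r2_mean: float
    r2_sd: float
    models: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...] = ()   # (model, reason)


@dataclass(frozen=True)
class GradientAssessment:
    """Gradient strength Δr = max(r1,r2) - min(r1,r2) and its class label."""

    delta_r: float
    gradient_class: str


@dataclass
class TernaryRatioTable:
    """Six pairwise reactivity ratios of a three-monomer system.

    ``averages`` maps each unordered pair (in series order) to its
    cross-model :class:`ReactivityAverage`; ``estimates`` holds every
    per-model fit; ``lambda_flags`` lists (pair, model, reason) entries
    excluded from averaging.
    """

    species: tuple[str, str, str]
    estimates: dict[tuple[str, str], dict[str, ReactivityEstimate]]
    averages: dict[tuple[str, str], ReactivityAverage]
    lambda_flags: tuple[tuple[tuple[str, str], str, str], ...] = ()

    def ratio(self, x: str, y: str) -> float:
        """Averaged r_xy for an ordered species pair."""
        if (x, y) in self.averages:
            return self.averages[(x, y)].r1_mean
        if (y, x) in self.averages:
            return self.averages[(y, x)].r2_mean
        raise KeyError(f"no fitted pair involving {x!r} and {y!r}")

    def ratio_dict(self) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for (a, b), avg in self.averages.items():
            out[(a, b)] = avg.r1_mean
            out[(b, a)] = avg.r2_mean
        return out


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _pair_data(series: ConversionSeries, pair: tuple[str, str]):
    """Extract (x_A, x_B, pair-renormalized f0) with invalid points dropped."""
    ia, ib = series.index(pair[0]), series.index(pair[1])
    xa, xb = series.x[:, ia], series.x[:, ib]
    ok = (xa < 1.0) & (xb < 1.0) & (xa >= 0.0) & (xb >= 0.0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} fully converted points for pair {pair}", stacklevel=3
        )
    xa, xb = xa[ok], xb[ok]
    if len(xa) < 4:
        raise ValueError(f"fewer than 4 usable points for pair {pair}")
    if np.all(xa == 0) and np.all(xb == 0):
        raise ValueError(f"no consumption observed for pair {pair}")
    w = np.array([series.f0[ia], series.f0[ib]], dtype=float)
    return xa, xb, w / w.sum()


def _r2(observed: np.ndarray, residual_ss: float) -> float:
    tss = float(np.sum((observed - observed.mean()) ** 2))
    if tss < 1e-300:
        return 1.0 if residual_ss < 1e-300 else 0.0
    return 1.0 - residual_ss / tss


def _minimize_log_r(objective) -> float:
    """Bounded deterministic 1-D minimization of objective(log r)."""
    res = minimize_scalar(
        objective,
        bounds=_LOG_R_BOUNDS,
        method="bounded",
        options={"xatol": _LOG_R_XATOL},
    )
    lo, hi = _LOG_R_BOUNDS
    if res.x - lo < 1e-6 or hi - res.x < 1e-6:
        raise RuntimeError(
            "optimizer converged at the search bound (r outside [1e-3, 1e3]); "
            "inspect the data for degenerate conversions"
        )
    return float(res.x)


def _curvature_se(objective, log_r_hat: float, n: int) -> float:
    """Standard error of r from the curvature of the SS surface at the optimum.

    var(r̂) ≈ 2 σ̂² / (d²SS/dr²) with σ̂² = SS/(n-1); the second derivative
    is taken numerically in r (not log r).
    """
    r = math.exp(log_r_hat)
    h = 1e-4 * r
    ss0 = objective(log_r_hat)
    ssp = objective(math.log(r + h))
    ssm = objective(math.log(r - h))
    hess = (ssp - 2.0 * ss0 + ssm) / (h * h)
    if hess <= 0 or n < 2:
        return float("nan")
    sigma2 = ss0 / (n - 1)
    return math.sqrt(2.0 * sigma2 / hess)


# ---------------------------------------------------------------------------
# the three estimators
# ---------------------------------------------------------------------------

def fit_jaacks(series: ConversionSeries, pair: tuple[str, str]) -> ReactivityEstimate:
    """Jaacks log-drift regression.

    Under the drift law ln(1/(1-x_A)) = r1 · ln(1/(1-x_B)) exactly, so r1 is
    the through-origin least-squares slope; r2 comes from the swapped
    regression (making the fit antisymmetric under pair swap by
    construction).
    """
    xa, xb, _ = _pair_data(series, pair)
    u = np.log1p(-xa) * -1.0    # ln(1/(1-x_A))
    v = np.log1p(-xb) * -1.0
    if not (np.any(u > 0) or np.any(v > 0)):
        raise ValueError(f"no consumption observed for pair {pair}")
    n = len(u)

    def slope_se(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
        sxx = float(x @ x)
        if sxx == 0.0:
            raise ValueError(f"regressor identically zero for pair {pair}")
        b = float(y @ x) / sxx
        resid = y - b * x
        ss = float(resid @ resid)
        se = math.sqrt(ss / (n - 1) / sxx) if n > 1 else float("nan")
        return b, se, ss

    r1, se1, ss1 = slope_se(u, v)
    r2, se2, ss2 = slope_se(v, u)
    return ReactivityEstimate(
        model="jaacks", pair=pair, r1=r1, r2=r2, se1=se1, se2=se2,
        R2=_r2(u, ss1), n_points=n, x_max=float(series.X.max()),
    )


def fit_bsl(series: ConversionSeries, pair: tuple[str, str]) -> ReactivityEstimate:
    """BSL integrated conversion-conversion fit.

    r1 minimizes Σ [x_B - (1 - (1-x_A)^(1/r))]²; r2 minimizes the swapped
    objective.  Solved on log r by bounded deterministic minimization;
    standard errors from the curvature of the sum of squares at the optimum.
    """
    xa, xb, _ = _pair_data(series, pair)
    n = len(xa)

    def make_objective(x_pred_from: np.ndarray, x_target: np.ndarray):
        lom = np.log1p(-x_pred_from)  # ln(1 - x)

        def objective(log_r: float) -> float:
            model = 1.0 - np.exp(lom / math.exp(log_r))
            d = x_target - model
            return float(d @ d)

        return objective

    obj1 = make_objective(xa, xb)     # parameter is r1 = kA/kB
    obj2 = make_objective(xb, xa)
    lr1 = _minimize_log_r(obj1)
    lr2 = _minimize_log_r(obj2)
    ss1 = obj1(lr1)
    return ReactivityEstimate(
        model="bsl", pair=pair,
        r1=math.exp(lr1), r2=math.exp(lr2),
        se1=_curvature_se(obj1, lr1, n), se2=_curvature_se(obj2, lr2, n),
        R2=_r2(xb, ss1), n_points=n, x_max=float(series.X.max()),
    )


def fit_ideal_integrated(
    series: ConversionSeries, pair: tuple[str, str]
) -> ReactivityEstimate:
    """Ideal integrated composition-versus-total-conversion fit.

    The observation is the instantaneous unreacted feed fraction of A,
    f_A = f0_A(1-x_A) / [f0_A(1-x_A) + f0_B(1-x_B)], plotted against the
    pair's total conversion.  For a candidate r the model curve is the
    analytic composition relation, inverted from X to the reference-species
    survival by bisection.  r1 and r2 come from the two role assignments.
    """
    xa, xb, w = _pair_data(series, pair)
    n = len(xa)

    def make_objective(x_ref, x_other, f0_pair):
        # observed instantaneous feed fraction of the reference species
        unreacted_ref = f0_pair[0] * (1.0 - x_ref)
        unreacted_other = f0_pair[1] * (1.0 - x_other)
        f_obs = unreacted_ref / (unreacted_ref + unreacted_other)
        X_obs = f0_pair[0] * x_ref + f0_pair[1] * x_other

        def objective(log_r: float) -> float:
            r = math.exp(log_r)
            rates = RateSet.from_ratios(_DUMMY_PAIR, [r])
            a_ref = survival_from_conversion(rates, f0_pair, X_obs)
            a_other = np.exp(np.log(np.maximum(a_ref, 1e-300)) / r)
            u_ref = f0_pair[0] * a_ref
            f_model = u_ref / (u_ref + f0_pair[1] * a_other)
            d = f_obs - f_model
            return float(d @ d)

        return objective, f_obs

    obj1, f_obs1 = make_objective(xa, xb, w)
    obj2, _ = make_objective(xb, xa, w[::-1])
    lr1 = _minimize_log_r(obj1)
    lr2 = _minimize_log_r(obj2)
    ss1 = obj1(lr1)
    return ReactivityEstimate(
        model="ideal", pair=pair,
        r1=math.exp(lr1), r2=math.exp(lr2),
        se1=_curvature_se(obj1, lr1, n), se2=_curvature_se(obj2, lr2, n),
        R2=_r2(f_obs1, ss1), n_points=n, x_max=float(series.X.max()),
    )


_FITTERS = {"jaacks": fit_jaacks, "bsl": fit_bsl, "ideal": fit_ideal_integrated}


# ---------------------------------------------------------------------------
# aggregation, classification, ternary extension
# ---------------------------------------------------------------------------

def fit_pair(
    series: ConversionSeries,
    pair: tuple[str, str],
    models: "tuple[str, ...]" = MODELS,
) -> dict[str, ReactivityEstimate]:
    """Run the requested estimators on one species pair."""
    unknown = set(models) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}; valid: {MODELS}")
    return {m: _FITTERS[m](series, pair) for m in models}


def average_models(
    estimates: "list[ReactivityEstimate] | dict[str, ReactivityEstimate]",
    excluded: "tuple[tuple[str, str], ...]" = (),
) -> ReactivityAverage:
    """Unweighted cross-model mean ± sample sd of r1 and r2.

    ``excluded`` lists (model, reason) entries left out of the average but
    recorded on the result.
    """
    if isinstance(estimates, dict):
        estimates = list(estimates.values())
    excluded_models = {m for m, _ in excluded}
    included = [e for e in estimates if e.model not in excluded_models]
    if not included:
        raise ValueError("no estimates left to average after exclusions")
    pairs = {e.pair for e in included}
    if len(pairs) != 1:
        raise ValueError(f"estimates mix species pairs: {pairs}")
    if len(included) == 1:
        warnings.warn(
            "averaging a single model; sd reported as 0", stacklevel=2
        )
    r1 = np.array([e.r1 for e in included])
    r2 = np.array([e.r2 for e in included])
    sd1 = float(r1.std(ddof=1)) if len(r1) > 1 else 0.0
    sd2 = float(r2.std(ddof=1)) if len(r2) > 1 else 0.0
    return ReactivityAverage(
        pair=included[0].pair,
        r1_mean=float(r1.mean()), r1_sd=sd1,
        r2_mean=float(r2.mean()), r2_sd=sd2,
        models=tuple(e.model for e in included),
        excluded=tuple(excluded),
    )


def assess_gradient(avg: "ReactivityAverage | tuple[float, float]") -> GradientAssessment:
    """Classify gradient strength from a pair of averaged reactivity ratios.

    Δr is the difference of the larger and smaller ratio; boundaries are
    half-open at the top: soft (0, 1.5], medium (1.5, 7.5], hard (7.5, 25],
    block-like above 25.  Δr = 0 (a strictly random copolymer) is reported
    as soft.
    """
    if isinstance(avg, ReactivityAverage):
        r1, r2 = avg.r1_mean, avg.r2_mean
    else:
        r1, r2 = avg
    if not (r1 > 0 and r2 > 0):
        raise ValueError(f"ratios must be positive, got ({r1}, {r2})")
    delta = max(r1, r2) - min(r1, r2)
    for label, upper in GRADIENT_CLASSES:
        if delta <= upper:
            return GradientAssessment(delta_r=delta, gradient_class=label)
    raise AssertionError("unreachable")


def fit_ternary(
    series: ConversionSeries,
    triple: "tuple[str, str, str] | None" = None,
    models: "tuple[str, ...]" = MODELS,
    lambda_flags: "tuple[tuple[tuple[str, str], str, str], ...]" = (),
) -> TernaryRatioTable:
    """Pairwise reactivity ratios of a three-monomer system.

    Each unordered pair is fitted with each requested model on that pair's
    conversions; the pairwise drift between two species does not involve the
    third, so binary estimators apply unchanged.  ``lambda_flags`` entries
    ((A, B), model, reason) are excluded from the pair's average, matching
    the practice of flagging unreliable ternary fits.
    """
    if triple is None:
        if len(series.species) != 3:
            raise ValueError("series is not ternary; pass an explicit triple")
        triple = tuple(series.species)  # type: ignore[assignment]
    if len(triple) != 3:
        raise ValueError(f"need exactly 3 species, got {triple}")
    estimates: dict[tuple[str, str], dict[str, ReactivityEstimate]] = {}
    averages: dict[tuple[str, str], ReactivityAverage] = {}
    for i in range(3):
        for j in range(i + 1, 3):
            pair = (triple[i], triple[j])
            try:
                fits = fit_pair(series, pair, models)
            except Exception as err:
                raise RuntimeError(f"fit failed for pair {pair}: {err}") from err
            estimates[pair] = fits
            excl = tuple(
                (model, reason)
                for flagged_pair, model, reason in lambda_flags
                if set(flagged_pair) == set(pair)
            )
            averages[pair] = average_models(fits, excluded=excl)
    return TernaryRatioTable(
        species=triple, estimates=estimates, averages=averages,
        lambda_flags=tuple(lambda_flags),
    )
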