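"""Nonterminal (chain-end-independent) copolymerization model.

In organocatalytic living ring-opening copolymerization the probability of
adding a monomer depends only on the incoming monomer, not on the chain-end
identity.  Each species ``i`` then disappears by first-order kinetics with
its own relative propagation constant ``k_i``::

    d[M_i]/dt = -k_i * kappa(t) * [M_i]

where ``kappa(t)`` collects everything species-independent (catalyst,
active-chain concentration).  Dividing two of these equations removes time
entirely: with survival fractions ``a_i = [M_i]/[M_i]0``,

    a_j = a_i ** (k_j / k_i)                       (the drift law)

so the whole composition history is parametrized by the survival of a single
reference species.  Pairwise reactivity ratios are ``r_ij = k_i / k_j`` and
satisfy ``r_ij * r_ji = 1`` (the "ideal" constraint) and transitivity
``r_ik = r_ij * r_jk`` by construction.

This module holds the analytic machinery shared by every other stage:
survival drift, conversion/composition state, composition-versus-conversion
curves, the Δr ↔ (r1, r2) conversion used for gradient-strength bookkeeping,
and the inversions needed to reconstruct feeds from final compositions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .chemistry import monomer_mass

__all__ = [
    "MonomerSpec",
    "RateSet",
    "FeedState",
    "CompositionCurve",
    "drift",
    "ratios_from_delta",
    "conversion_state",
    "composition_curve",
    "survival_from_conversion",
    "feed_for_final_composition",
    "rateset_from_ratio_table",
]

#: final-conversion cap for composition curves; avoids the 0**0 / log(0)
#: degeneracies of full conversion while being visually indistinguishable
FINAL_CONVERSION_CAP = 0.999


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonomerSpec:
    """One comonomer: a short label, its molar mass, optional 31P shifts."""

    name: str
    molar_mass: float
    shift_monomer: float | None = None
    shift_polymer: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("monomer name must be non-empty")
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass must be > 0, got {self.molar_mass}")

    @classmethod
    def from_library(cls, name: str) -> "MonomerSpec":
        """Look the monomer up in the built-in phosphoester table."""
        from .chemistry import MONOMER_FORMULAS

        _, sm, sp = MONOMER_FORMULAS[name]
        return cls(name, monomer_mass(name), sm, sp)


@dataclass(frozen=True)
class RateSet:
    """Relative propagation rates for a monomer system.

    ``k`` is dimensionless; only ratios matter, and by convention one entry
    is 1 (the constructors enforce this by normalizing to the last species).
    Every pairwise reactivity ratio is ``ratio(i, j) = k[i] / k[j]``.
    """

    species: tuple[MonomerSpec, ...]
    k: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.species) != len(self.k):
            raise ValueError("species and k must have equal length")
        if len(self.species) < 1:
            raise ValueError("need at least one species")
        if any(not (ki > 0 and math.isfinite(ki)) for ki in self.k):
            raise ValueError(f"all k must be positive finite, got {self.k}")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate species names: {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def n(self) -> int:
        return len(self.k)

    def ratio(self, x: int | str, y: int | str) -> float:
        """Reactivity ratio r_xy = k_x / k_y."""
        return self._k(x) / self._k(y)

    def _k(self, key: int | str) -> float:
        if isinstance(key, str):
            key = self.names.index(key)
        return self.k[key]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def from_ratios(
        cls, species: "list[MonomerSpec] | tuple[MonomerSpec, ...]",
        adjacent_ratios: "list[float] | tuple[float, ...]",
    ) -> "RateSet":
        """Build from adjacent-pair ratios r_{i,i+1}; last species gets k = 1.

        For a binary system ``adjacent_ratios = [r1]`` gives k = (r1, 1);
        for a ternary one ``[r12, r23]`` gives k = (r12*r23, r23, 1).
        """
        if len(adjacent_ratios) != len(species) - 1:
            raise ValueError("need one adjacent ratio per species pair")
        k = [1.0]
        for r in reversed(adjacent_ratios):
            if not r > 0:
                raise ValueError(f"ratios must be positive, got {r}")
            k.insert(0, r * k[0])
        return cls(tuple(species), tuple(k))


@dataclass(frozen=True)
class FeedState:
    """A point on the copolymerization trajectory.

    ``f0``: initial mole fractions; ``survival``: a_i = [M_i]/[M_i]0;
    ``f``: instantaneous unreacted-feed fractions; ``F``: cumulative
    incorporated fractions; ``X``: total conversion.
    """

    f0: tuple[float, ...]
    survival: tuple[float, ...]
    f: tuple[float, ...]
    F: tuple[float, ...]
    X: float

    def __post_init__(self) -> None:
        if abs(sum(self.f0) - 1.0) > 1e-12:
            raise ValueError(f"f0 must sum to 1, got {sum(self.f0)}")
        if any(not (0.0 < a <= 1.0) for a in self.survival):
            raise ValueError(f"survivals must lie in (0, 1], got {self.survival}")


@dataclass
class CompositionCurve:
    """Composition as a function of total conversion on a monotone X grid.

    ``f[g, i]`` is the instantaneous unreacted-feed fraction of species i at
    grid point g; ``F[g, i]`` the cumulative incorporated fraction.  Both
    rows sum to 1 everywhere; incorporated amount ``F * X`` is nondecreasing.
    """

    names: tuple[str, ...]
    X: np.ndarray
    f: np.ndarray
    F: np.ndarray
    survival: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# analytic relations
# ---------------------------------------------------------------------------

def drift(r: float, a):
    """Survival of species B given survival ``a`` of A and ratio r = kA/kB.

    Integrating d[A]/d[B] = r [A]/[B] gives b = a ** (1/r).  Accepts scalar
    or ndarray ``a``; every element must lie in (0, 1].
    """
    if not (r > 0 and math.isfinite(r)):
        raise ValueError(f"rate ratio must be positive finite, got {r}")
    arr = np.asarray(a, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError(f"survival must lie in (0, 1], got {a}")
    out = np.exp(np.log(arr) / r)
    return float(out) if np.isscalar(a) or arr.ndim == 0 else out


def ratios_from_delta(delta_r: float) -> tuple[float, float]:
    """Invert the gradient-strength definition Δr = r1 - r2 with r1·r2 = 1.

    Solves r - 1/r = Δr for r ≥ 1: r1 = (Δr + sqrt(Δr² + 4)) / 2, r2 = 1/r1.
    Δr must be nonnegative (order the pair so the faster monomer is first).
    """
    if delta_r < 0:
        raise ValueError(f"delta_r must be >= 0, got {delta_r}")
    r1 = 0.5 * (delta_r + math.sqrt(delta_r * delta_r + 4.0))
    return r1, 1.0 / r1


def _survivals(k: np.ndarray, a_ref, ref: int = 0) -> np.ndarray:
    """All species' survivals from the reference species' survival."""
    a_ref = np.asarray(a_ref, dtype=float)
    expo = k / k[ref]
    # log-space keeps exponents of O(100) well behaved near a_ref -> 1
    with np.errstate(under="ignore"):
        return np.exp(np.multiply.outer(np.log(a_ref), expo))


def conversion_state(rates: RateSet, f0, a_ref: float) -> FeedState:
    """Full trajectory state from the reference (first) species' survival.

    X = 1 - Σ f0_i a_i with a_i = a_ref ** (k_i/k_ref); instantaneous feed
    f_i = f0_i a_i / Σ f0_j a_j; cumulative incorporated
    F_i = f0_i (1 - a_i) / X, defined by its continuous limit f0 at X = 0.
    """
    if not (0.0 < a_ref <= 1.0):
        raise ValueError(f"a_ref must lie in (0, 1], got {a_ref}")
    f0 = np.asarray(f0, dtype=float)
    if f0.shape != (rates.n,):
        raise ValueError(f"f0 must have {rates.n} entries")
    if abs(f0.sum() - 1.0) > 1e-12:
        raise ValueError(f"f0 must sum to 1, got {f0.sum()}")
    k = np.asarray(rates.k, dtype=float)
    a = _survivals(k, a_ref)
    unreacted = f0 * a
    X = 1.0 - unreacted.sum()
    f = unreacted / unreacted.sum()
    if X > 0:
        F = f0 * (1.0 - a) / X
    else:
        F = f0.copy()
    return FeedState(
        f0=tuple(f0), survival=tuple(a), f=tuple(f), F=tuple(F), X=float(X)
    )


def survival_from_conversion(rates: RateSet, f0, X, *, iterations: int = 100):
    """Invert X -> reference-species survival by bisection.

    The bisection runs on the slowest species' survival s (all exponents
    k_i/k_min ≥ 1, so X is well conditioned in s over the whole range) and
    returns the survival of the *first* species.  Vectorized over X.
    """
    f0 = np.asarray(f0, dtype=float)
    k = np.asarray(rates.k, dtype=float)
    X = np.asarray(X, dtype=float)
    scalar = X.ndim == 0
    Xv = np.atleast_1d(X)
    if np.any(Xv < 0) or np.any(Xv >= 1):
        raise ValueError("total conversion must lie in [0, 1)")
    slow = int(np.argmin(k))
    expo = k / k[slow]

    def total_conv(s: np.ndarray) -> np.ndarray:
        with np.errstate(under="ignore"):
            a = np.exp(np.multiply.outer(np.log(np.maximum(s, 1e-300)), expo))
        return 1.0 - (f0 * a).sum(axis=-1)

    lo = np.zeros_like(Xv)          # X -> 1
    hi = np.ones_like(Xv)           # X = 0
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        too_low = total_conv(mid) > Xv   # converted too much -> raise s
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    s = 0.5 * (lo + hi)
    with np.errstate(under="ignore"):
        a_first = np.exp(np.log(np.maximum(s, 1e-300)) * expo[0])
    a_first = np.where(Xv == 0.0, 1.0, a_first)
    return float(a_first[0]) if scalar else a_first


def composition_curve(
    rates: RateSet,
    f0,
    n_grid: int = 201,
    final_conversion: float = FINAL_CONVERSION_CAP,
) -> CompositionCurve:
    """Instantaneous and cumulative composition on a uniform X grid.

    The grid runs from 0 to ``final_conversion`` (capped just below 1 to
    avoid the degenerate fully converted state).
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    if not (0.0 < final_conversion < 1.0):
        raise ValueError("final_conversion must lie in (0, 1)")
    f0 = np.asarray(f0, dtype=float)
    if abs(f0.sum() - 1.0) > 1e-12:
        raise ValueError(f"f0 must sum to 1, got {f0.sum()}")
    k = np.asarray(rates.k, dtype=float)
    X = np.linspace(0.0, final_conversion, n_grid)
    a_ref = survival_from_conversion(rates, f0, X)
    a = _survivals(k, a_ref)
    unreacted = f0 * a
    f = unreacted / unreacted.sum(axis=1, keepdims=True)
    F = np.empty_like(f)
    pos = X > 0
    F[pos] = f0 * (1.0 - a[pos]) / X[pos, None]
    F[~pos] = f0
    # renormalize away bisection residue (components already sum to ~1)
    F /= F.sum(axis=1, keepdims=True)
    return CompositionCurve(names=rates.names, X=X, f=f, F=F, survival=a)


# ---------------------------------------------------------------------------
# inversions used by presets and by ternary reconciliation
# ---------------------------------------------------------------------------

def feed_for_final_composition(rates: RateSet, F_final, X_final: float):
    """Feed fractions that reach cumulative composition ``F_final`` at X_final.

    Mass balance per species reads f0_i (1 - a_i) = F_i X, with all a_i tied
    to the slowest species' survival s by the drift law; Σ f0_i = 1 then is a
    single monotone equation in s, solved with Brent's method.
    Returns the f0 array.
    """
    F_final = np.asarray(F_final, dtype=float)
    if not (0.0 < X_final < 1.0):
        raise ValueError("X_final must lie in (0, 1)")
    if F_final.shape != (rates.n,):
        raise ValueError(f"F_final must have {rates.n} entries")
    if np.any(F_final < 0) or abs(F_final.sum() - 1.0) > 1e-9:
        raise ValueError("F_final must be nonnegative and sum to 1")
    k = np.asarray(rates.k, dtype=float)
    slow = int(np.argmin(k))
    expo = k / k[slow]

    def f0_of(s: float) -> np.ndarray:
        with np.errstate(under="ignore"):
            a = np.exp(math.log(s) * expo) if s > 0 else np.where(expo > 0, 0.0, 1.0)
        return F_final * X_final / (1.0 - a)

    def excess(s: float) -> float:
        return f0_of(s).sum() - 1.0

    # Σ f0 is increasing in s: at s->0 it equals X_final < 1, at s->1 it blows up
    lo, hi = 1e-15, 1.0 - 1e-15
    s = brentq(excess, lo, hi, xtol=1e-15, rtol=8.9e-16)
    f0 = f0_of(s)
    return f0 / f0.sum()


def rateset_from_ratio_table(
    species: "list[MonomerSpec] | tuple[MonomerSpec, ...]",
    ratios: dict[tuple[str, str], float],
) -> RateSet:
    """Project a (possibly inconsistent) table of pairwise ratios onto a RateSet.

    Fitted ternary ratio tables contain six numbers but the nonterminal
    model has only n-1 free parameters, so an observed table need not be
    transitive.  The log-least-squares projection — each log k_x is the mean
    of its implied values ``log r_xy + log k_y`` over all pairs, i.e. the
    geometric mean of the per-pair k estimates — is used, normalized so the
    last species has k = 1.
    """
    names = [s.name for s in species]
    n = len(names)
    logk = np.zeros(n)
    for x, nx in enumerate(names):
        vals = []
        for y, ny in enumerate(names):
            if x == y:
                continue
            if (nx, ny) in ratios:
                vals.append(math.log(ratios[(nx, ny)]))
            elif (ny, nx) in ratios:
                vals.append(-math.log(ratios[(ny, nx)]))
        if not vals:
            raise ValueError(f"no ratio involves species {nx!r}")
        logk[x] = sum(vals) / n  # row mean with log k_x's own 0 term
    # solve the centered log-LS system: logk_x - mean(logk) = row mean of log r
    logk -= logk[-1]
    k = np.exp(logk)
    return RateSet(tuple(species), tuple(float(v) for v in k))
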