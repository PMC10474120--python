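# Methods

## Model and scope

All computations assume the nonterminal (chain-end-independent) model of
living copolymerization: the probability of adding monomer *i* depends only
on *i*, through a relative propagation constant *k*ᵢ, never on the chain
end. This is the accepted idealization for organocatalytic ROP of cyclic
phosphoesters at conditions where transesterification is suppressed
(DCM, −10 °C, DBU-based catalysis — carried as preset metadata, never used
in computation). Consequences used throughout:

* survivals obey the drift law *a*ⱼ = *a*ᵢ^(kⱼ/kᵢ), so trajectories are
  parametrized by one reference survival and absolute time is
  unidentifiable from composition data;
* reactivity ratios satisfy *r*ᵢⱼ·*r*ⱼᵢ = 1 and transitivity exactly;
  fitted ratios need not, which is exploited as a diagnostic;
* the pairwise drift between two species is independent of any third, so
  binary estimators apply unchanged to terpolymer data.

Terminal/penultimate models (Mayo–Lewis with r₁r₂ ≠ 1 as a mechanism),
depropagation and transesterification are out of scope.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `x_max` | 0.60 | fits use data with total conversion X ≤ x_max; the standard truncation for integrated reactivity-ratio fits |
| `noise_sigma` | 0.02 | relative sd of multiplicative integral noise in the generator (dimensionless) |
| `total_monomer_conc` | 4 mol/L | protocol metadata; scales integrals only |
| `monomer_to_initiator` | 100 | targeted total DP; presets use ΣDP/X_final so DP arithmetic round-trips |
| `final_conversion` | preset-specific | conversion reached at the last spectrum |
| MC `n_chains`, `length` | 10, 100 | mirror the conventional 10-chain visualizations; pool = round(n·L/X_final) |
| log-r search bounds | [ln 10⁻³, ln 10³] | 1-D fit window; convergence at a bound is an error, not a result |

## Synthetic-data generator

The generator emulates the measurement, not the spectrometer: per species
one monomer and one polymer integral per time point, with
[Mᵢ](t) = [Mᵢ]₀·exp(−kᵢκt). The global scale κ is solved (Brent) so each
dataset reaches its configured final conversion at its last time point;
reported reaction hours are cosmetic. The acquisition grid mimics a
real-time schedule (10 spectra at 5.7 min, 10 at 11.3 min, geometric
tail). Integration error is multiplicative Gaussian (relative sd
`noise_sigma`, independent per integral) because NMR integral error scales
with peak area; an additive component, baseline/phasing artifacts, peak
overlap and temperature drift are *not* modelled. Passing tests therefore
demonstrate correctness of the estimators under the stated noise model,
not robustness to every artifact of real spectra.

Presets P1–P10 are model-consistent reconstructions of the studied
systems: species, DPs, total conversions, catalysts and times from the
published synthesis table; "true" ratios from the printed Δr via
r₁ = (Δr + √(Δr²+4))/2, r₂ = 1/r₁ (the per-model printed values are not
machine-readable). The weighed-in feeds are not printed; they are
recovered by solving f₀ such that the cumulative composition at the
printed total conversion equals the printed DP fractions (mass balance
f₀ᵢ(1−aᵢ) = FᵢX reduces this to one monotone equation in the slowest
species' survival, solved by Brent). P10's pair strengths are not printed;
the P9 values (Δr₁₂ = 14, Δr₂₃ = 13) are reused on the inverted
EPP-before-ETP incorporation order, which is the documented qualitative
difference between the two catalyst systems.

## Conversion extraction

Default normalization is paired, xᵢ = Pᵢ/(Mᵢ+Pᵢ) per time point, which is
invariant to per-spectrum gain; `monomer_only` mode (1 − Mᵢ(t)/Mᵢ(0)) is
provided for overlapping polymer resonances. f₀ defaults to the first
spectrum's monomer fractions (it precedes measurable conversion at
−10 °C) and can be overridden. Conversions are deliberately not forced
monotone: noise must stay visible to the fits. QC reports, per species,
the linear-trend drift of the conserved monomer+polymer sum (warning above
5 %, a systematic-loss indicator) separately from its relative scatter
(the noise level); the two would confound each other in a single range
statistic.

## Estimators and numerics

Jaacks is a through-origin regression — the drift law has no intercept,
and an intercept would absorb t = 0 normalization error. BSL is fitted in
monomer-vs-monomer conversion coordinates (identical noiseless curve to
the conversion-vs-X form, but avoids using the noisy X on both axes).
The ideal-integrated objective inverts X → reference survival by bisection
on the slowest species' survival (exponents ≥ 1 keep the inversion well
conditioned over the whole range; 100 halvings, far below discretization
error). Both 1-D fits minimize on log r with Brent's bounded method,
xatol 10⁻¹⁰, deterministically (no random starts). Standard errors: exact
regression se for Jaacks; curvature of the SS surface at the optimum
(var ≈ 2σ̂²/H) for BSL and ideal. r₁ and r₂ are fitted independently per
model; their product's deviation from 1 is an ideality diagnostic, and the
reported uncertainty on averages is the across-model sample sd (matching
the magnitude of published ± values), with per-fit se kept separately.

Degenerate inputs: fully converted points (x ≥ 1) are dropped with a
warning; all-zero conversions raise "no consumption"; an optimizer at the
search bound raises rather than returning a boundary value; X = 0 defines
cumulative composition by its continuous limit f₀; composition curves cap
at X = 0.999 to avoid power underflow at full conversion.

Ternary systems are fitted pairwise (six ratios, three models each).
λ-style exclusions are config-driven — a list of (pair, model, reason)
entries removed from the average and recorded — because no objective rule
for the published flags is stated. When a single consistent rate set is
needed (e.g. to drive the Monte Carlo from six fitted ratios), the
log-least-squares projection is used: each log k is the mean of its
implied values over all pairs, i.e. the geometric mean of per-pair k
estimates, normalized to the slowest species.

## Monte Carlo

Round-robin growth (each round, every chain adds one unit from the shared
pool with probability kᵢNᵢ/ΣkⱼNⱼ) enforces dispersity exactly 1 while all
chains compete for one pool; the pool is sized by the experimental final
conversion so chain ends show the terminal composition actually reached.
Integer conservation (pool + chains) is exact and validated on
construction. One named numpy Generator per run; identical (config, seed)
gives byte-identical chain text.

## Problem sizes and verification

Noiseless calibrations use 60-point series truncated at X ≤ 0.6; all
three estimators recover true r ∈ {0.1 … 20} to better than 10⁻³ relative
and agree pairwise to 10⁻⁶. The noisy-recovery calibration uses σ = 0.02,
50 points, 200 seeded replicates at true r = 5 (cross-model bias well
under 1 %, mean r₁r₂ within 0.001 of 1). Monte-Carlo-versus-analytic
checks draw 10⁵ units and compare cumulative composition on a 10-point
conversion grid against 3σ binomial bounds. The composition machinery is
cross-checked against an independent stiff ODE integration of the drift
equations (scipy `solve_ivp`, rtol 10⁻¹²) to 10⁻⁶. These sizes keep the
full suite around half a minute; all are configurable upward.

## Known limitations

* The generator's noise model is the package's own choice; real integral
  error may have additive components and correlated baseline structure.
* Preset feeds and ratios are reconstructions under the ideal model, not
  deposited raw data; recovered quantities validate internal consistency,
  not the original measurements.
* Two synthesis-table rows (P5, P8) print Mₙ values inconsistent with
  their own DPs and any supported end group; the package reports the
  arithmetic result (12.8k, 10.9k) without special-casing.
* Gradient classes use the printed half-open boundaries; values within
  floating-point distance of a boundary classify strictly by ≤.
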