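# ppekinetics

Copolymerization kinetics for polyphosphoesters (PPEs) from real-time
³¹P NMR: reactivity ratios by three nonterminal models, gradient-strength
classification, Monte Carlo chain microstructures, and synthesis-table
polymer reports.

## Who this is for

Polymer chemists following living statistical ring-opening
copolymerizations (ROP) of cyclic phosphoesters — phosphates, side- and
in-chain phosphonates, thiophosphates — in situ by ³¹P NMR. Each species
has resolved monomer and polymer resonances, so every spectrum yields a
per-monomer conversion. This package turns those integral time series into
reactivity ratios, a gradient classification, and simulated chain
microstructures, and ships a seeded synthetic-data generator so the whole
pipeline is testable without spectrometer data.

## The model

Organocatalytic living ROP is well described by the **nonterminal**
(chain-end-independent) model: monomer *i* is consumed first order with
relative rate *k*ᵢ, so with survivals *a*ᵢ = [Mᵢ]/[Mᵢ]₀ the drift law

&nbsp;&nbsp;&nbsp;&nbsp;*a*ⱼ = *a*ᵢ^(kⱼ/kᵢ)

eliminates time entirely. Pairwise reactivity ratios *r*ᵢⱼ = *k*ᵢ/*k*ⱼ
obey *r*ᵢⱼ·*r*ⱼᵢ = 1 and *r*ᵢₖ = *r*ᵢⱼ·*r*ⱼₖ. Three standard estimators
view this one curve in different coordinates, and their spread is an error
estimate:

* **Jaacks** — through-origin slope of ln(1/(1−x_A)) vs ln(1/(1−x_B));
* **BSL** (Beckingham–Sanoja–Lynd) — least squares on
  x_B = 1 − (1−x_A)^(1/r);
* **ideal integrated** — least squares of the instantaneous feed fraction
  f_A against total conversion X, using the analytic composition curve.

Fits use data up to 60 % total conversion (configurable). Gradient
strength is Δr = |r₁ − r₂| (ideal assumption), classified as **soft**
(0 < Δr ≤ 1.5), **medium** (≤ 7.5), **hard** (≤ 25) or **block-like**
(> 25). Monte Carlo chains grow round-robin from a shared depleting pool
with addition probabilities ∝ kᵢNᵢ (dispersity exactly 1), and per-polymer
arithmetic gives DPᵢ = round(xᵢ·feedᵢ), Mₙ = Σ DPᵢMᵢ + M_initiator.

Built-in presets P1–P10 reconstruct the ten studied copolymerizations
(binary pairs of PhPPn/MePPn/EtPPn/MEP/EEP/ETP/EPP and two terpolymers)
from their printed DPs, conversions and Δr values.

## Worked example

```sh
ppekin synth --preset P1 --noise 0 --seed 1 --out p1.csv
ppekin fit --in p1.csv
```

prints (abridged):

```json
{
  "pairs": {
    "PhPPn/MePPn": {
      "average": {"r1": 5.192582400411162, "r1_sd": 2.24e-08,
                  "r2": 0.19258240325476517, "r2_sd": 3.25e-10},
      "delta_r": 4.999999997156396,
      "gradient_class": "medium"
    }
  }
}
```

The noiseless P1 preset encodes true ratios r₁ = (5+√29)/2 ≈ 5.1926 and
r₂ = 1/r₁ (i.e. Δr = 5); all three models recover them to eight digits and
the pair classifies as a medium gradient. With `--noise 0.02` the models
disagree at the percent level and the reported sd becomes meaningful.

Continue the pipeline:

```sh
ppekin classify --r1 4.9 --r2 0.21     # {"delta_r": 4.69, "class": "medium"}
ppekin simulate --delta-r 24 --chains 10 --length 100 --final-x 0.83 \
    --seed 2 --out chains.txt          # block-like chain strings AAAB...BBBB
ppekin report --presets P1,P4,P9 --noise 0 --out-dir results/
```

`report.tsv` contains one row per polymer with DPs, monomer ratio, fitted
Δr, gradient class and Mₙ — e.g. P1: `48/41  54/46  Δr 5  medium  13.9k`.

The same operations are available as library calls
(`ppekinetics.fit_pair`, `simulate`, `build_report`, …).

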