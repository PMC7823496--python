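# saslepr

Analysis of membrane molecular dynamics from nitroxide spin-label EPR
spectra, with the companion membrane-composition calculations used in
temperature-acclimation studies of plant (chloroplast) membranes.

## What it is for

Doxyl stearic acid spin labels report on the ordering and motion of
lipid chains: 5-SASL (nitroxide on carbon 5) probes the region near the
polar head groups, 16-SASL (carbon 16) the hydrophobic core.  An X-band
EPR spectrometer records the first derivative of the absorption; the
shape of that derivative encodes membrane fluidity.  `saslepr` turns
two-column spectra (field in mT, intensity) into the standard dynamic
quantities, across measurement-temperature series and genotypes:

* **Order parameter** from the outer (2A′∥) and inner (2A′⊥) hyperfine
  splittings of anisotropic 5-SASL spectra:

      a₀ = (A′∥ + 2A′⊥)/3,   S = 0.5407 · (A′∥ − A′⊥)/a₀

  S runs from 1 (maximally ordered membrane) to 0 (maximally
  disordered); out-of-range values are flagged, never clamped.

* **Rotational correlation times** from the fast-motion 16-SASL triplet
  (central peak-to-peak linewidth ΔH₀ in gauss; line amplitudes h₊, h₀,
  h₋ low/mid/high field):

      τ₂B = 6.51·10⁻¹⁰ · ΔH₀ · (√(h₀/h₋) − √(h₀/h₊))        [s]
      τ₂C = 6.51·10⁻¹⁰ · ΔH₀ · (√(h₀/h₋) + √(h₀/h₊) − 2)    [s]

  τ₂B reflects rotation about the chain's long axis, τ₂C motion
  perpendicular to it; lower values mean higher local fluidity.

* **Pigment quantification** from 80 %-acetone absorbance triples
  (A663.2, A664.8, A470 → chlorophyll a, b, a+b, carotenoids in µg/mL).

* **Fatty-acid unsaturation summaries** (U/S and 18:3/18:2 ratios) from
  GC-FAME mole-percent tables, with `<LOD` handling.

* **Per-temperature statistics**: technical-within-biological replicate
  aggregation (mean ± SE) and pooled-variance Student t contrasts per
  measurement temperature (p ≤ α, letter groups).

Because raw spectra from such studies are rarely deposited, the package
ships a first-class synthetic-spectrum generator with analytically known
ground truth (three-line fast-motion triplets and axially anisotropic
lineshapes), so the whole chain is testable end to end.

## Worked example

```python
from saslepr import *

grid = FieldGrid.default(4096)          # 12 mT window centred at 335 mT

# polar-head region: anisotropic 5-SASL spectrum -> order parameter
p = AnisotropicParams(A_par=3.0, A_perp=1.5)
feats = extract_anisotropic_features(simulate_anisotropic(p, grid))
op = order_parameter(feats)
print(f"A'par = {feats.A_par_prime:.3f} mT, A'perp = {feats.A_perp_prime:.3f} mT")
print(f"a0 = {op.a0:.3f} mT, S = {op.S:.4f}")

# membrane core: fast-motion 16-SASL triplet -> correlation times
q = FastMotionParams(width_A=0.15, width_B=-0.02, width_C=0.03)
f = extract_fast_motion_features(simulate_fast_motion(q, grid))
ct = correlation_times(f)
print(f"deltaH0 = {f.deltaH0:.4f} mT, h+/h0/h- = {f.h_plus:.2f}/{f.h_zero:.2f}/{f.h_minus:.2f}")
print(f"tau2B = {ct.tau2B:.3e} s, tau2C = {ct.tau2C:.3e} s")

# bundled barley chloroplast fatty-acid table -> fluidity proxies
from saslepr.datasets import load_barley_chloroplast_profiles
prof = load_barley_chloroplast_profiles()["delisa_20C"]
print(f"U/S = {unsaturation_ratio(prof):.2f}, 18:3/18:2 = {trienoic_dienoic_ratio(prof):.2f}")
```

prints

```
A'par = 3.000 mT, A'perp = 1.500 mT
a0 = 2.000 mT, S = 0.4055
deltaH0 = 0.1500 mT, h+/h0/h- = 21.53/24.49/13.77
tau2B = 2.606e-10 s, tau2C = 3.905e-10 s
U/S = 3.11, 18:3/18:2 = 15.06
```

The recovered splittings equal the requested ones, so S reproduces the
closed form 0.5407·1.5/2.0 = 0.4055; the τ values match the analytic
ground truth of the simulated linewidth coefficients (τ₂B = 2.604e-10 s,
τ₂C = 3.906e-10 s) to ~0.1 %; the barley wild-type grown at 20 °C has
~3.1× as much unsaturated as saturated fatty acid.

## Command line

`saslepr` exposes `simulate`, `extract`, `dynamics`, `pigments`,
`lipids`, `compare` and `run-all`.  `run-all` regenerates a complete
synthetic acclimation experiment (2 genotypes × 3 growth temperatures,
protocol temperature grids, 2 biological × 2 technical replicates) and
writes `features.csv`, `dynamics.csv`, `aggregates.csv`,
`comparisons.csv` and an audit `runlog.json`:

```bash
saslepr run-all --out-dir demo_run --seed 7
```

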