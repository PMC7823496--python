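# Methods

## Scope and data model

`saslepr` analyses first-derivative X-band EPR spectra of doxyl stearic
acid spin labels in membranes and the companion composition
measurements (pigments, fatty acids) used in temperature-acclimation
work.  A `Spectrum` is a strictly increasing magnetic-field axis (mT), a
first-derivative intensity vector (arbitrary units) and acquisition
metadata (spin label, genotype, growth and measurement temperature,
replicate id).  Chromatogram processing and raw mass-spectrometry are
out of scope: fatty acids enter as mole-percent tables, hormones as
ready concentration tables.

## Forward models (synthetic spectra)

Real spectra from acclimation studies are rarely deposited, so the
package generates spectra with analytically known ground truth.

**Fast-motion triplet (16-SASL-like).**  Three ¹⁴N hyperfine lines at
`center ∓ aN` for mI = +1, 0, −1 (low-field line is mI = +1 and carries
h₊).  Each line is the analytic first derivative of an equal-area
Lorentzian or Gaussian absorption profile parameterised directly by its
peak-to-peak width ΔH(mI) = A + B·mI + C·mI².  For equal-area Lorentzian
lines the derivative peak-to-peak amplitude scales exactly as 1/ΔH², so
√(h₀/h±) = ΔH(±1)/ΔH(0) and the correlation-time formulas collapse to

    τ₂B = 6.51·10⁻¹⁰ · (−2·B)   and   τ₂C = 6.51·10⁻¹⁰ · (2·C)   (B, C in gauss),

which is the closed-form oracle used everywhere (`ground_truth_tau`; it
refuses the Gaussian lineshape, where the identity is only approximate).
Defaults: centre 335 mT in a 12 mT window (conventional X-band values,
chosen as pure convention), aN = 1.5 mT, and a validity rule
aN > 3×max ΔH that keeps the triplet resolved.  Field modulation is not
convolved explicitly; modulation broadening is treated as folded into
the effective widths.  Noise is additive i.i.d. Gaussian, the baseline
linear — enough to stress feature extraction without inventing
instrument physics.

**Axially anisotropic lineshape (5-SASL-like).**  A phenomenological
two-component construction, not a rigid-limit powder average: a
positive/negative absorption-shaped (Gaussian) pair at `center ∓ A∥` and
a negative/positive inner pair at `center ∓ A⊥`, antisymmetric about the
centre.  Its only contract is the realized extrema geometry — outermost
derivative extrema separated by 2A∥, inner pair by 2A⊥ — which is
exactly what the order-parameter formula consumes.  Component overlap
shifts extrema slightly, so the generator runs a fixed-point calibration
of the component placements and verifies by self-extraction that the
realized splittings match the requested ones within half a grid step;
unresolvable geometries (component width too large for four distinct
extrema) raise.  Because the positive/negative pairs carry equal area,
the running integral of the signal returns to zero at the window edges,
as it must for a derivative spectrum whose lines are contained.

`anisotropic_params_for_order(S, a0)` inverts S = 0.5407·(A∥ − A⊥)/a₀ at
fixed a₀ (default 1.55 mT) to produce ground truth for a requested order
parameter; `fast_motion_params_for_tau` does the same for τ pairs.

## Feature extraction

Spectra are baseline-corrected by a straight line fitted through the two
5 % field-edge windows (idempotent; raises if a smooth, above-noise
component remains in the windows, i.e. a line overlaps them).  Noise is
estimated robustly as 1.4826·median(|Δy|)/√2 over the edge windows —
first differences make the estimate immune to residual smooth trends.

**Analyzability rule.**  A spectrum is analyzable iff every required
extremum exceeds 3× the noise estimate; failures return
`analyzable=False` rather than raising, mirroring how measured spectra
stop being evaluable outside a temperature range.  Pure noise is
rejected by the same rule.

**Fast motion.**  Derivative lines are detected as a positive lobe
followed by a negative lobe (`scipy.signal.find_peaks`, prominence at
the noise threshold); the three largest peak-to-peak amplitudes ordered
by field give (h₊, h₀, h₋), and the central pair gives ΔH₀.  `h` is the
peak-to-peak amplitude of the line (positive lobe minus negative lobe):
the τ ratios are insensitive to the consistent alternative
(baseline-to-peak) only for symmetric lines, so peak-to-peak is the
robust choice.

**Anisotropic.**  2A′∥ is the separation of the global low-field maximum
and global high-field minimum; 2A′⊥ the separation of the most prominent
inner minimum (between the outer maximum and the centre) and inner
maximum (between the centre and the outer minimum).  If the global
maximum lies at higher field than the global minimum, the polarity is
normalised first, which makes the measurement invariant under mirroring
the field axis.

**Refinement.**  On effectively noiseless data every extremum is refined
by a 3-point quadratic through the sample and its neighbours — bias-free
to O(step²) and shape-agnostic.  On noisy data that estimator is
dominated by noise in its curvature term (on a 4096-point, 12 mT grid
the curvature signal across one step is far below the noise), so two
noise paths are used instead:

* anisotropic extrema are re-smoothed with a Savitzky–Golay filter whose
  window is ~60 % of the detected lobe width before the 3-point step —
  the symmetric order-2 kernel is exact through cubics, so its leading
  bias is fourth-order, unlike the O(W²) odd-order bias a wide direct
  polynomial vertex fit would pick up on asymmetric lobes;
* the fast-motion triplet is refined by a joint least-squares fit of
  three pseudo-Voigt derivative lines with one shared mixing parameter
  and a linear baseline.  Sharing the lineshape across the triplet
  reflects the common broadening mechanism and removes the width/shape
  degeneracy that inflates per-line fit variance; the fit recovers
  widths and amplitudes near the information limit (≤1.5 % at
  signal-to-noise 50, where extremum picking alone scatters by several
  per cent).  If the fit fails to converge the adaptive Savitzky–Golay
  path is the fallback.

Smoothing defaults to automatic: off when the edge-noise estimate is
below 10⁻⁴ of the signal range, on otherwise; the window-5, order-2
detection filter is fixed for all spectra of a series.

## Dynamics formulas

`order_parameter` evaluates a₀ = (A′∥ + 2A′⊥)/3 and
S = 0.5407·(A′∥ − A′⊥)/a₀; S outside [0, 1] (possible near the rigid
limit) sets a flag rather than raising or clamping, and flagged values
are excluded from downstream statistics by default.  No correction terms
are applied to A′⊥.

`correlation_times` evaluates the τ₂B/τ₂C expressions with ΔH₀ converted
from the stored mT to gauss by default; the 6.51·10⁻¹⁰ prefactor then
yields seconds on the 10⁻¹⁰–10⁻⁹ s scale typical for such membranes.
The unit convention is explicit (`units="gauss"|"mT"`) because the
formulas are printed without a field unit in much of the applied
literature; gauss is adopted and documented rather than asserted.

## Pigments and lipids

The 80 %-acetone equations are linear forms in (A663.2, A664.8, A470)
with the exact additivity Ca + Cb = Ca+b (coefficient identity
12.25 − 5.10 = 7.15, 21.50 − 2.79 = 18.71, asserted to 10⁻⁹).  Negative
concentrations are flagged, preserving auditability of blank/turbid
extracts.  The default dilution factor 210 back-calculates per-sample
values for the 2.09 mL + 0.01 mL extraction geometry and is overridable.

Fatty-acid saturation is classified purely from the
`carbon:double_bonds` identifier (positional tags like Δ9cis ignored);
`<LOD` cells parse to zero with a flag and never abort a ratio.  The
bundled barley chloroplast table (wild-type Delisa vs the
brassinosteroid-deficient 522DK mutant at 20/5/27 °C growth) serves as
the worked input; recomputed U/S matches the published row to ±0.03 and
18:3/18:2 to ±0.07 — the published ratios were evidently computed before
rounding the composition to two decimals, so validation tolerances are
±0.05 for U/S and for the named 18:3/18:2 columns.

## Statistics

Aggregation averages technical replicates within each biological
replicate first, then reports mean ± SE (sample SD/√n, 0 for n = 1)
across biological means.  Genotype contrasts are classical
pooled-variance Student t-tests (not Welch), two-sided, run separately
per measurement temperature, significant at p ≤ α (α = 0.05 default).
The degenerate zero-pooled-variance case is handled explicitly (t = 0,
p = 1 for equal means; ±∞, p = 0 flagged otherwise) since the generic
implementation returns NaN there.  **No multiple-testing correction is
applied across measurement temperatures** — each temperature is its own
contrast, as is conventional for these per-temperature asterisk plots;
users comparing many temperatures should interpret accordingly.  Letter
groups: two groups share a letter iff not significantly different.
The t statistic is signed as mean_a − mean_b (swapping groups negates
it); worked magnitudes are therefore quoted as |t|.

## Pipeline and problem sizes

`run_pipeline` regenerates a synthetic acclimation experiment with the
protocol's structure: 2 genotypes × 3 growth temperatures, measurement
grids 0–40 °C in 5 °C steps (20 °C- and 27 °C-grown groups) and
0–25 °C in 2.5 °C steps (5 °C group), both spin labels, 2 biological ×
2 technical replicates, 2048-point spectra at signal-to-noise 80 — a
realistic reduced-scale emulation (464 spectra, ~10 s on one core).
The ground-truth trends make S and τ decrease with measurement
temperature and the mutant slightly more ordered/rigid, most at 5 °C
acclimation and not at 27 °C, so the per-temperature contrasts reproduce
the qualitative pattern expected of a cold-acclimated rigid mutant.
Runs are deterministic given the config seed (per-spectrum seeds are
drawn from one master generator); the run log records every effective
setting.

## What the synthetic data does and does not show

The generators cover: mI-dependent linewidths, anisotropic splitting
geometry, additive Gaussian noise, linear baselines, replicate scatter
(log-normal-like multiplicative jitter).  They do not cover: slow-motion
lineshapes outside the fast-motion regime, g/A-tensor anisotropy beyond
effective splittings, saturation or modulation distortion, correlated
baseline drift, or overlapping free-label signals.  Passing tests
therefore demonstrate correctness of the measurement chain on spectra
whose anatomy matches the phenomenological models, not robustness to
every pathology of real instrument data.

## Known limitations

* The anisotropic model is a two-component superposition; A′⊥ values
  from real powder-like spectra carry polarity-correction issues that
  are deliberately out of scope (the raw two-splitting formula is used).
* The pseudo-Voigt refinement assumes near-symmetric lines; strongly
  asymmetric (slow-motion) lines fall back to extremum picking and lose
  precision.
* U/S and 18:3/18:2 validation tolerances are bounded below by the
  two-decimal rounding of published composition tables.
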