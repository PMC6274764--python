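# Methods

## The measurement problem

Matrix mineralization by osteogenic cells is conventionally quantified by
Alizarin Red S (ARS) staining: the dye chelates calcium, and the amount of
bound dye is read either in situ by absorbance at 515 nm on the stained
monolayer, or by absorbance of the acid extract. On opaque, strongly
absorbing substrates — graphene oxide (GO) coatings in particular — in-situ
absorbance is impossible: the substrate baseline (OD ≈ 2) swamps the dye
signal. The workaround implemented here reads the *shape* of the 2-D
fluorescence spectrum (excitation–emission matrix, EEM) instead.

Undifferentiated cell layers show a single emission peak near 500 nm. As
the ARS–calcium complex forms, a second emission peak grows at 670 nm, and a
saddle appears between the two lobes near 560 nm emission. The quantitative
statistic is the **normalized ratio index**

    R = I(λ_exc = 420 nm, λ_em = 670 nm) / I(λ_exc = 420 nm, λ_em = 560 nm)

— the 670 nm maximum over the 560 nm saddle, both at 420 nm excitation.
Because R is a ratio of two intensities of the same surface, any scalar
attenuation of the signal cancels. This is the property that makes the
index usable on opaque substrates: an absorbing support multiplies the
whole fluorescence surface by one factor and leaves R unchanged, whereas
absorbance readings are destroyed. Results per condition are expressed as
**fold induction**: the condition's readout divided by the undifferentiated
control's readout under the same method.

## Spectra and their representation

EEMs live on a rectangular wavelength grid (default excitation 400–580 nm,
emission 440–700 nm, 10 nm step) with a triangular validity mask: only
cells with emission ≥ excitation + 40 nm are measurable (the fixed offset
keeps the monochromator away from the Rayleigh scatter line). The mask is
stored explicitly; no operation reads a masked cell, and mask-aware
Gaussian smoothing renormalizes its kernel over valid cells so constants
are preserved and nothing bleeds across the scatter edge. The emission
step is taken equal to the stated 10 nm excitation step, which puts the
560 and 670 nm readout wavelengths on-grid. Intensity lookups between grid
nodes are bilinear over the four surrounding valid cells.

## Saddle detection

Critical points of the smoothed surface (default σ = 1 grid unit = 10 nm)
are detected in two stages:

1. **Stationarity.** An interior valid cell is stationary along an axis
   when its central-difference gradient per grid step is below
   `grad_tol_frac` (default 0.02) of the surface dynamic range, *or* when
   its one-sided differences change sign (the cell brackets a discrete
   extremum). The second branch matters near the scatter-mask staircase,
   where kernel renormalization inflates the central difference at genuine
   on-node peaks.
2. **Classification and corroboration.** Stationary cells are classified
   by the eigenvalue signs of the discrete Hessian (both negative →
   maximum, both positive → minimum, mixed → saddle; eigenvalues below
   10⁻⁹ of the dynamic range are treated as zero and the cell discarded).
   Each cell must additionally be corroborated by the strict neighbourhood
   pattern on the same smoothed surface: maxima dominate all 8 neighbours,
   minima are dominated, saddles are a strict extremum of opposite sense
   along the two grid axes. Tolerance-based stationarity alone admits
   gentle slopes and plateaus; the corroboration makes the detector
   exactly equivalent to an exhaustive neighbour-comparison scan on
   well-resolved surfaces (a property the test suite asserts against an
   independent brute-force oracle on grids up to 31×31).

`has_saddle` requires two independent pieces of evidence to agree: a 2-D
saddle inside the emission window 520–600 nm, and a prominent local
minimum of the 1-D emission slice at the 420 nm probe excitation inside
the same window. Disagreement yields `indeterminate` rather than a guess.
Two robustness devices back this up:

* **Prominence.** A 1-D minimum (or peak) counts only if its relief
  exceeds 2% of the surface dynamic range. This is set above the residual
  cell-to-cell variation that survives smoothing at the instrument's 1–2%
  noise level; the mineralization saddle's relief is about 10%, an order
  of magnitude larger. Without this floor, noisy plateaus in
  undifferentiated spectra sprout spurious saddles.
* **Two smoothing scales.** The surface is nearly flat along excitation at
  the saddle, so the 2-D detection is attempted at σ and 1.5σ; either
  suffices. At a single scale, roughly 1 perturbation in 200 at 1% noise
  lost the saddle; with two scales, none do (checked over 3 perturbation
  seeds × 100 perturbations).

Spectrum classification follows: agreement of both saddle checks →
`mineralized_double_peak` (a prominent minimum necessarily sits between
two higher emission lobes, so this certifies the double peak even when the
red lobe is truncated at the 700 nm detector edge); a single prominent
emission maximum below 560 nm → `undifferentiated_single_peak`; above
600 nm → `free_dye_single_peak`; anything else → `indeterminate`.

## Calibrations

Free dye in solution is linear in concentration in both channels
(Beer–Lambert absorbance at 515 nm; fluorescence at 420/670 nm), so all
calibrations are ordinary least squares with intercept — blank subtraction
is imperfect under noise, and forcing the line through the origin would
bias the slope. R² = 1 − SS_res/SS_tot. The default ladder is 12
geometrically spaced concentrations spanning 0.00125–4 mM (an exact
two-fold ladder cannot hit both endpoints in 12 points; the ratio is ≈2.08
per step). No heteroscedasticity weighting is applied; with 2%
multiplicative noise the fits stay above R² = 0.999 regardless.

## The synthetic twin

No raw spectra are deposited with the study, so everything is exercised on
a seeded generator with known ground truth. Three separable
excitation×emission components:

| component | emission | excitation | plateau |
|---|---|---|---|
| cellular | Gaussian 500/18 nm | Gaussian 440/50 nm | 0.12 of apex |
| complex (ARS–Ca) | Gaussian 670/45 nm | Gaussian 430/60 nm | — |
| free dye | Gaussian 670/50 nm | Gaussian 430/60 nm | — |

The cellular **plateau** is the deliberate modelling choice here: real
cell layers show broadband autofluorescence extending into the red, and
without it the control's 670/560 ratio would be a Gaussian tail value of
order 10⁻⁵ — unmeasurable against any realistic detector floor, and
incompatible with fold inductions of 2–4 ever producing a visible 670 nm
lobe. With the plateau, the control index is ≈0.97, and the widths are
set so that the two-component surface forms its emission minimum at the
420 nm slice exactly at 560 nm (on-grid) across the study's fold range —
verified by brute-force scan in the tests.

A scenario is `(condition, substrate, a_cell, a_complex)`. The complex
amplitude that realizes a target fold is found by bisection on the
strictly increasing map a_complex → index (the 670 nm numerator grows ~20×
faster than the 560 nm denominator), to 10⁻⁹ relative tolerance. Scenario
truths: GO alone 2.7 and GO + osteogenic medium 3.5 (the study's reported
values); glass + medium 2.0 at day 7 and 3.0 at day 14 (free choices — no
numbers are printed for them). Control: a_complex = 0, a_cell = 1.

Substrates are purely optical: glass (OD baseline 0.02, attenuation 1.0),
GO (OD baseline 2.0, fluorescence attenuation 0.6, wavelength-independent
by model assumption — this is what makes the index's robustness a provable
property rather than an approximation), solution (baseline 0.04).

Absorbance: OD(λ) = baseline + 0.15·load·g(λ), with g a Gaussian peaked at
515 nm (σ 40 nm) and `load` the bound-dye amount in mM-equivalents:
`0.2·a_cell` of nonspecific background staining plus `1.55·a_complex` per
unit of complex. The background term keeps the control's OD positive (a
fold cannot be formed against a zero control), and the per-complex term is
set so absorbance folds track index folds over the studied range — the
synthetic counterpart of the cross-calibration. On GO the ARS-attributable
share of OD@515 is ≈4%: in-situ absorbance is structurally uninformative
there and is excluded from method comparisons, not imputed.

The acid extract ("liquid" mode) carries the surface composition
proportionally — extraction efficiency 0.9 with per-replicate lognormal
jitter (sd 0.02) applied to both the dye and the co-extracted
cellular-associated background. An extract containing the complex-derived
dye alone would have a fixed free-dye spectral shape, whose scale-invariant
ratio index could not track the amount extracted at all; the proportional
model is what lets the liquid fluorescence method quantify anything.

Noise: each stored spectrum is the average of 3 independent instrument
readings (matching the acquisition protocol of triplicate spectral reads),
each reading carrying 2% multiplicative noise and a folded-normal additive
floor of 0.5% of the instrument full scale (1 a.u.). The floor is tied to
the instrument, not to the sample's own maximum — detector noise does not
scale with the specimen. All randomness derives from streams keyed by
`(seed, sample_id, replicate)`, so runs are reproducible byte for byte.

## What the twin does and does not show

Passing tests demonstrate that the analysis pipeline recovers configured
ground truth under the modelled noise and substrate optics: calibrations
at R² ≥ 0.99 under 2% noise, four-method agreement within 10% on glass,
and GO fold recovery within a few percent of 2.7/3.5 over 50 replicates.
They do not validate the spectroscopic model itself against real cultures:
real lineshapes are not separable Gaussians, GO attenuation is not exactly
wavelength-independent, inner-filter effects, photobleaching and scatter
beyond the fixed +40 nm cutoff are not modelled, and dilution members
below roughly 5× the additive floor (≲0.01 mM here) carry no usable shape
information — their classification is legitimately indeterminate.

## Numerical choices and degenerate inputs

* Ratio-index denominator floored at 10⁻⁶ of the surface maximum
  (near-dark extracts must not blow the ratio up); all-zero surfaces are a
  domain error.
* Background subtraction clips at zero: counts are non-negative and the
  index must never divide by a negative value.
* Pairwise method differences use the pair mean as denominator (symmetric
  in the two methods).
* Replicates are averaged on the raw readout before folds are formed.
* Ties among equal-intensity saddles break to the lowest emission
  wavelength; merged stationary regions keep their most extreme cell.
* Constant surfaces have no critical points (empty result, not an error);
  grids with fewer than 5×5 valid interior cells are a domain error.
* Problem sizes used throughout (19×27 default grid, 3 replicates, 12
  dilution points, 50 replicates for fold recovery) are the study's own
  scales; every simulation in the tests and the acceptance script runs in
  seconds.
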