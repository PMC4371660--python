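# Methods

This note documents the models, numerical choices and limitations behind
each analysis stage, and what the synthetic-data generators do and do not
emulate.

## Spin-probe ESR microviscosity

**Model.** A small nitroxide (TEMPONE) tumbling isotropically in the
fast-motion regime gives a three-line first-derivative X-band spectrum in
which rotational modulation of the anisotropic hyperfine interaction
broadens the high-field line relative to the low-field line. The rotational
correlation time follows the Kivelson line-width relation

    tau_c = K * dW_+1 * (sqrt(h_+1/h_-1) - 1)

with K = 6.5e-10 s/G, dW_+1 the peak-to-peak width of the low-field line in
gauss, and h_+1, h_-1 the low- and high-field derivative heights. The
effective viscosity comes from rotational Stokes–Einstein,
eta = 3 k T tau_c / (4 pi a^3), with probe radius a = 3 Å. The analysis is
valid for tau_c roughly below 1e-9 s (fast motion); slower regimes are out
of scope.

**Parameters.** `SpinProbeConstants` holds K (s/G), a (m), Boltzmann's
constant, and the temperature assumed for the viscosity conversion. The
default temperature is 298.15 K: the conversion is not pinned by the
measurement itself, and 25 °C reproduces water's handbook viscosity
(0.89 cP) from the probe's correlation time in water, which anchors the
convention. All constants are overridable.

**Background subtraction.** The recorded spectrum of a spore suspension is
the intracellular narrow triplet plus a broad extracellular background
(probe quenched/broadened by ferricyanide). The background, recorded on the
spore-free supernatant, is scaled by the factor c minimizing the squared
residual over "wing" field windows that exclude the narrow-line
neighbourhoods, then subtracted. Because the narrow lines are Lorentzian,
their tails reach into any wing choice and bias c upward by 1.5–3.5%
depending on the exclusion width; `SpinProbeModel.fit` therefore iterates:
reconstruct the narrow triplet analytically from the measured line
parameters, remove it from the total, refit c on the cleaned wings
(2 iterations by default). The bias is then second order in the line
measurement error; noise-free simulations recover c to 4 decimal places.

**Line measurement.** Each line is sought in a window of half-width 0.5×
the hyperfine splitting (default 16 G, typical for an aqueous nitroxide and
configurable — the splitting is instrument metadata, not something this
analysis estimates) around its nominal position. Raw extrema give initial
height (max − min) and width (extremum separation, parabolic sub-grid
refinement). Raw extremum heights are biased upward by noise (a maximum
over noisy samples), which matters for the small high-field line, so the
default measurement refines all three lines by a joint least-squares fit of
the derivative-Lorentzian triplet, with the centre/high-field widths tied
to the heights through the equal-integrated-intensity law (height ∝
width⁻²) and a linear baseline term. `method="extremum"` disables the
refinement. Detection errors are raised when a line's height does not clear
8× the wing noise floor (1.4826×MAD of the outer wings), when an extremum
sits at a window edge, or when the derivative lobes are inverted.

**Numerical domain.** Height ratios in (0.98, 1.0) are clamped to 1
(tau_c = 0), absorbing noise around the symmetric limit; smaller ratios are
outside the fast-motion model and raise an error.

## FTIR glass-transition analysis

**Band position.** Spectra are cropped to the OH-stretch region
(3000–3600 cm⁻¹ by default) and baseline-corrected by the straight line
between the region endpoints. The band position is defined at 75% of the
baseline-corrected peak height: the two flank crossings of that level are
located by linear interpolation, and the position is the mean of 50 points
placed uniformly across the contour between them — which is exactly the
midpoint of the two crossings, for symmetric and asymmetric bands alike
(`n_contour` is kept in the API for contour-density experiments). The
position is invariant to intensity scaling and to any added linear
baseline, by construction.

**Two-segment regression.** Band position vs temperature is piecewise
linear: a shallow slope in the glass, a steep slope in the liquid, with the
glass transition at the crossing of the two regression lines. The slope of
a segment is the wavenumber–temperature coefficient (WTC); lower WTC means
stronger hydrogen bonding and a denser glass. `GlassTransitionModel`
searches every split leaving ≥ 4 points per side (stable OLS at ~1.5–2 °C
sampling), fits independent OLS lines to each side (numpy least squares
inside the search loop; statsmodels OLS for the chosen split, providing
slope standard errors), and minimizes pooled SSE, breaking ties toward the
split nearest the median temperature. Degenerate data (segment slopes equal
within 1e-6) and intersections outside [min T − 20, max T + 20] °C are
errors rather than answers. The fit is equivariant under temperature shifts
and invariant under position offsets.

The reported WTC defaults to the liquid-side (above-T_g) slope: the
0.17–0.27 cm⁻¹ °C⁻¹ magnitudes characteristic of sugar glasses match the
steep liquid branch. Both slopes are exposed (`wtc(segment=...)`) because
the convention is not universal.

**Crystallization.** A crystallizing component (mannitol) replaces the
broad amorphous OH band with a sharp peak near 3250 cm⁻¹ and invalidates
the regression. Two configurable detectors run per spectrum in acquisition
order: band FWHM falling below 0.6× the series' initial FWHM, and a
resolved sub-peak narrower than 60 cm⁻¹ within 3200–3300 cm⁻¹ with
prominence ≥ 0.15× the band maximum. The thresholds are qualitative
contrast choices, not fitted quantities.

**Protocol analysis.** A full measurement heats −10→140 °C (scan heat1),
cools back (cool), and heats again (heat2); the first heating "matures" the
glass, so T_g1 and T_g2 differ and are fitted separately on heat1 and
heat2 only (whether cooling data should contribute to T_g2 is unsettled;
they are not used). Crystallization is checked scan by scan; once a scan
crystallizes, it and all later scans report no T_g/WTC.

## Compatible-solute quantification

Cytoplasmic volumes use wall-excluded protoplast dimensions: sphere
V = 4/3 πr³ (*N. fischeri*, r = 2.0 µm → 33.5 fl) or prolate spheroid
V = 4/3 πab² (*T. macrosporus*, a = 2.6, b = 2.3 µm → 57.6 fl); 1 µm³ =
1 fl. Wall thickness is carried as metadata only. Per-spore mass converts
to molarity as mM = (pg / (g/mol)) / fl × 10⁶ — exact, unit-checked, and
the round trip concentration → mass → concentration is the identity.

Molar masses default to anhydrous values (mannitol 182.17, glucose 180.16,
trehalose 342.30, isobemisiose 504.44, neosartose 666.58, fischerose
828.72 g/mol); whether calibration standards were hydrated is generally
unknown, so the masses are configurable per analyte. Calibration is an
unweighted free-intercept OLS of peak area on standard concentration
(refractive-index detection is linear over the dilute standard range).
Peak areas are trapezoidal sums above a local linear baseline drawn between
the retention-window endpoints; windows must not overlap (no co-elution
deconvolution is attempted). Estimated extract concentrations at or below
a numerical floor (1e-9 mg/ml, far beneath any real RI detector's
quantification limit) report zero with a below-LOQ flag. Composition
proportions normalize the four trehalose-family sugars (trehalose +
tri/tetra/penta extensions) over their own total — mannitol and other
solutes are outside the panel — keeping exact fractions alongside rounded
display percentages.

## Thermal survival

Dormant ascospores require heat activation, so survivor curves rise before
they fall. The decimal reduction time D (one decade of kill) is estimated
by OLS of log10(germination %) on time inside a user-chosen decay window —
typical series are far too short for reliable automatic change-point
detection, so the activation/decay split is an explicit analysis input.
Zero-germination points cannot enter a log fit and are excluded with a
warning (unbiased on the remaining decade range). A non-negative slope
reports "non-inactivating" (infinite D) rather than a negative D. The
normal-approximation confidence interval for D is derived from the slope's
standard error.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) with explicit
`numpy.random.default_rng` seeding; no global state.

* **FTIR**: a single Gaussian band (default centre 3320 cm⁻¹ at T_g, FWHM
  180 cm⁻¹, unit amplitude) whose centre moves piecewise-linearly with
  temperature (glass slope 0.06, liquid slope 0.272 cm⁻¹ °C⁻¹, the
  trehalose-like defaults), sampled −10…140 °C in 2 °C steps on a 2 cm⁻¹
  grid, with white absorbance noise. `position_noise_to_absorbance`
  converts a target band-position scatter (cm⁻¹) into the absorbance noise
  that propagates to it through the 75%-contour rule; the analytic
  conversion is slightly conservative (0.3 cm⁻¹ requested ≈ 0.26 cm⁻¹
  realized). Crystallization is an additive sharp Gaussian (3250 cm⁻¹,
  FWHM 40 cm⁻¹) for temperatures at and above an onset — additive rather
  than replacing the amorphous band, the simplest form that exercises both
  detectors. The protocol generator chains heat1/cool/heat2; the cool scan
  defaults to the heat2 (matured-glass) parameters with reversed
  temperatures.
* **ESR**: the narrow triplet realizes a prescribed tau_c by inverting the
  Kivelson relation — height ratio (tau_c/(K·dW₊₁) + 1)², widths
  {dW₊₁, dW₊₁, dW₊₁√ratio}, derivative-Lorentzian lines of equal
  integrated intensity at centre ± 16 G and centre on a 0.05 G grid. The
  broad extracellular triplet shares the line positions with width 5 G
  (≥5× the narrow width, reproducing the broad-component morphology) and
  relative amplitude 0.8. The supernatant trace is the broad component with
  independent noise.
* **HPLC**: Gaussian peaks (area = amount × response factor, width = σ in
  min) on a linear drifting baseline with white noise.
* **Survival**: S(t) = A·(1 − e^(−k_a t))·10^(−t/D) (activation toward
  plateau A at rate k_a, one decade of kill per D minutes) with binomial
  counting of n spores per time point (default 300, i.e. "at least 100 in
  triplicate").

**What the generators do not emulate** — and hence what passing tests do
not certify about real data: FTIR band asymmetry and multi-band structure
(the OH-stretch of a real sugar glass is a composite), instrument drift and
baseline curvature, ESR hyperfine anisotropy and slow-motion line shapes,
field-modulation distortion, chromatographic tailing and retention drift,
and non-log-linear (shouldered or tailed) inactivation kinetics. Recovery
tolerances quoted in the tests are statements about this synthetic
structure at the stated noise levels.

## Problem sizes and statistical reading of recovery tests

Recovery tests run 50 seeds (100 for the bias bound) at the study noise
levels: ESR at 1% amplitude noise recovers tau_c with ~1.5% mean absolute
error (per-seed worst case ~4.7%, at the estimator's information limit);
the T_g fit at 0.3 cm⁻¹ position noise and 2 °C spacing recovers a
mid-ramp transition with ~0.67 °C mean absolute error. Recovery assertions
therefore bound seed-averaged errors. A transition near the top of the
ramp (e.g. 120.4 °C, ~10 liquid-side points) carries a ~1.3 °C error floor
and a small downward breakpoint bias; the tests document this rather than
hide it.

## Known limitations

* JCAMP-DX support covers only XYPOINTS=(XY..XY) and uncompressed
  XYDATA=(X++(Y..Y)) tables — enough for exported instrument files, not a
  full DX implementation (no SQZ/DIF compression, no binary vendor
  formats, no interferogram processing).
* The Stokes–Einstein temperature convention is an assumption (298.15 K);
  viscosities inherit its ~±2% ambiguity over plausible lab temperatures.
* The D-value window is user-supplied; a poorly placed window spanning the
  activation phase will bias D upward.
* δOH-region (1300–1000 cm⁻¹) analysis, multi-band deconvolution, Weibull
  inactivation models and retention-time alignment are out of scope.
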