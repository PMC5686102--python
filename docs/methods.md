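# Methods

This note records the models, parameter choices and numerical decisions
behind `sfdiscope`, and what the synthetic-data experiments do and do
not demonstrate.

## Forward model of spatially modulated reflectance

The diffuse reflectance of a homogeneous semi-infinite medium under a
sinusoidal illumination pattern of spatial frequency `f` is modelled in
the diffusion approximation with a partial-current (Robin) boundary:

    mu_tr   = mu_a + mu_s'
    a'      = mu_s'/mu_tr
    mu_eff' = sqrt(3 mu_a mu_tr + (2 pi f)^2)
    R_d(f)  = 3 A a' / [(mu_eff'/mu_tr + 1)(mu_eff'/mu_tr + 3A)]

with `A = (1 - R_eff)/(2 (1 + R_eff))` and the Groenhuis polynomial for
the effective internal reflection at refractive index n = 1.4 (standard
soft-tissue value; the Monte Carlo uses Henyey–Greenstein anisotropy
g = 0.9, the diffusion expression consumes mu_s' only).

Plain diffusion is biased against transport at low albedo and high
reduced frequency: benchmarked against the in-repo Monte Carlo it is
+18 % at (mu_a, mu_s', f) = (2.5, 12.5, 0) and +30 % at f = 2 cm^-1,
which would break both the claimed model/oracle agreement and any
physical realism of the rendered scenes at the dark end of the phantom
grid. `R_d` obeys an exact similarity scaling — it depends on
(mu_a, mu_s', f) only through `a'` and `v = f/mu_tr` for fixed (g, n) —
so the shipped forward model multiplies the diffusion expression by a
tabulated correction `C(a', v) = R_MC/R_diffusion` (10 albedo nodes in
[0.60, 0.985], 13 reduced-frequency nodes in [0, 1], bilinear
interpolation, clamped outside). The table lives in
`sfdiscope/data/rd_mc_table.json` (3.6 kB) and is regenerated by
`scripts/build_forward_table.py` (~4×10^6 photons, fixed seed). With the
correction, the forward model tracks independently seeded Monte Carlo
runs to within ~1.5 % over mu_a ∈ [0.5, 2.5], mu_s' ∈ [12.5, 25],
f ∈ [0, 2] cm^-1, and remains strictly monotone decreasing in f and
mu_a (verified numerically on a dense grid). The uncorrected
`rd_diffusion` stays exported as the analytic reference.

## Monte Carlo oracles

`mc_sfd_reflectance` is a deliberately simple MCML-style weighted walk:
pencil beam, implicit absorption, Russian roulette (threshold 1e-4,
survival 0.1), Fresnel partial reflection at the boundary, and the
spatial-frequency response scored as `E[w_exit J0(2 pi f rho_exit)]`
(J0 via the Abramowitz–Stegun rational approximations). Photons deeper
than 15 diffusion penetration depths are terminated; in the
non-absorbing limit the cutoff is 5000 transport lengths, keeping the
energy-conservation leak far below the statistical error of a 10^4
photon run. Standard errors come from per-photon contribution moments.

`mc_fluorescence_yield` chains two stages: the excitation walk deposits
absorbed weight into a depth histogram (proportional to fluence in a
homogeneous medium), then isotropic emission photons launched from
fluence-sampled depths walk in the emission-wavelength medium and score
their escaping weight. The product (fluence integral × escape
probability) is the transport analogue of X_1D up to a constant, so
yield *ratios* between media validate the analytic factor.

## X_1D attenuation correction

The correction factor is the depth integral of the planar-illumination
diffusion fluence at the excitation properties times the escape profile
at the emission properties; by reciprocity the escape profile shares the
fluence's functional form (buried plane source at one transport length,
image sink across the extrapolated boundary), so

    X_1D = ∫0^∞ phi_ex(z) phi_em(z) dz

evaluated by trapezoidal quadrature on a surface-refined grid to 12
penetration depths (about 600 nodes; batch calls share one grid, so
scalar and vectorized evaluations agree to quadrature accuracy, ~1e-4
relative). Exact coefficients of the original semi-empirical 1-D model
are not reproduced; the parameterization is validated behaviourally:
strict monotone decrease in absorption at either wavelength,
independence from fluorophore amount, and agreement of between-media
ratios with the two-stage Monte Carlo within 15 %. Dividing raw
fluorescence by a correction computed from *recovered* (not true)
optical properties is what collapses the pooled signal-vs-concentration
relation from r² ≈ 0.52 to ≈ 1.00 in the four-phantom experiment.

## Virtual instrument

Scenes hold per-pixel maps (mu_a/mu_s' at 490 and 590 nm, drug
concentration in ug/mL, height in mm, tumor mask) plus an instrument
description. Rendering models the measurement chain:

* Fringe geometry: patterns are defined at the focal plane; a surface
  h mm below it sees `f_eff = f (1 + h/d0)` with intensity scaled by
  `(1 + h/d0)^-2` and a fixed-pixel phase shift `kappa·f·h`
  (small-angle triangulation). Defaults: working distance d0 = 10 mm
  (yields the stated order of pattern-frequency growth at 8 mm);
  kappa = 0.1 rad/(mm·cm^-1), set by the geometric requirement that the
  first-pixel absolute phase stays inside (-pi, pi] over the whole
  calibrated 0–8 mm range so that 2-D unwrapped phase maps are absolute
  (anchoring convention below). The f = 0 channel is rendered as
  unmodulated full-field illumination — identical across the three
  phase indices — and is calibrated through the DC image.
* Artifacts: multiplicative hexagonal honeycomb pattern (three cosines
  at 60°, pitch 8 px, configurable depth) and radial barrel/pincushion
  distortion (normalized-radius cubic model).
* Noise: Poisson shot noise (default 1.25 photoelectrons per count,
  ~1 % at a 10^4-count signal), Gaussian read noise (2 counts), and an
  optional purely multiplicative term used by the 1 %-noise replication
  experiments. All randomness flows through seeded generators; fixed
  seeds reproduce frames bit-identically.
* Release kinetics: first-order in time, `released = 1 - exp(-k t)`,
  `k = k0 · fluence_rate · exp(-c · mu_a)` with k0 = 0.032 cm²/J,
  coupling c = 0.58 per cm^-1 (at the treatment wavelength; the 590 nm
  map stands in unless a dedicated map is given) and fluence rate
  350 mW/cm² (300 mW/cm² is the in-vivo preset; both are config
  values, neither is canonical). These defaults reproduce the observed
  ordering that a phantom with twice the absorption releases over
  minutes rather than seconds and measurably slower than a clear one
  (≈8 vs ≈6 min to completion at 0.5 vs 1.0 cm^-1). Encapsulated drug
  fluoresces at 12 % of the released brightness (self-quenching),
  consistent with the ~1 vs ~8 ug/mL apparent pre/post-release levels
  reported in vivo.

What the generator does **not** emulate: speckle, lens ray aberrations
beyond the single radial term, photobleaching, surface-angle (Lambertian)
effects — the latter deliberately out of scope, matching the
instrument's own deferral — spatially varying illumination within the
treatment field, and any biological heterogeneity beyond piecewise-
constant inclusions. Tests passing on these scenes therefore demonstrate
the correctness and self-consistency of the *processing chain*, not
instrument-grade accuracy on real tissue.

## Demodulation, profilometry and calibration

The three-phase identities are exact for the projected phase set
(0, 2pi/3, 4pi/3). Phase maps are wrapped to (-pi, pi], flagged invalid
where the modulation amplitude vanishes (relative threshold against the
DC level), and unwrapped with scikit-image's reliability-sorted 2-D
unwrapper; the result is re-anchored so the first valid pixel keeps its
wrapped value, which makes the unwrapped surface absolute given the
generator's phase-range guarantee.

Height calibration fits, per pixel and wavelength, the linear map
h = s·phi + b across ≥3 known heights (phase at the highest frequency,
2.0 cm^-1) and stores the demodulated reference amplitude at *every*
frequency and height; correction replaces the flat reference amplitude
by the piecewise-linear interpolation at the recovered height. Heights
outside the calibrated range are clamped and flagged, never
extrapolated. The DC channel is corrected exactly; AC channels retain a
second-order residual when the sample's frequency response differs from
the reference's, because the stretched pattern frequency probes the two
media differently — the same error class as the instrument's reported
~19 %/~6 % residuals at 8 mm. The height-correction replication
experiment accordingly re-images the calibration phantom itself (fresh
noise realizations), mirroring the original single-phantom distance
experiment; calibration transfer to a different medium is exercised
separately as a qualitative test.

## Inversion and concentration

Per-pixel fitting minimizes the squared residual over the acquired
frequencies with a damped Gauss–Newton iteration in log-parameter
space, batched over all pixels (numerically equivalent to a trust-region
solver for this smooth 2-parameter problem and cross-checked against
scipy's `least_squares` in the tests; bounds mu_a ∈ [0.01, 10],
mu_s' ∈ [1, 50] cm^-1 by clipping). Two fixed starts, (0.5, 10) and
(2.0, 25), guard against local minima; pixels whose two solutions
disagree by >5 % are flagged invalid. The lookup-table path
(nearest node on a 60×60 geometric grid + short Gauss–Newton polish)
agrees with the full fit within 2 % on the calibration range and flags
out-of-grid queries instead of extrapolating.

The concentration calibration is an ordinary least-squares line with
free intercept (the intercept absorbs residual background) over ≥3
levels including zero; maps are `(F_corr - intercept)/slope`, clipped at
zero with a flag. ROI statistics follow the 50 %-of-peak threshold
convention. `time_to_fraction` estimates the full-release plateau as the
mean of the final three samples and interpolates the crossing linearly;
with that estimator a fraction ≤ 1 of the plateau is always attainable
on any curve whose maximum is positive, so the "never reached" flag is
defensive. Spectral unmixing of plate-reader emission spectra
(530–700 nm, 10 nm steps) uses nonnegative least squares — physical
concentrations cannot be negative — and reports coefficients in
standard-curve units.

## Problem sizes and determinism

The replication experiments run on 32×32-pixel scenes (hundreds of
independent noisy pixels per ROI) and the pipeline tests on 24×24; the
acceptance script finishes in well under a minute after the first numba
compilation. Every stochastic routine takes an explicit seed and derives
all child seeds from it; reruns are bit-identical including written CSV
output.

## Known limitations

* The forward model is homogeneous and semi-infinite per pixel; layered
  or depth-resolved recovery (3-D fluorescence tomography) is out of
  scope.
* The Monte Carlo correction table is built for (g, n) = (0.9, 1.4);
  other boundary conditions fall back to plain diffusion via
  `rd_diffusion`.
* X_1D is a 1-D model: it ignores lateral transport between excitation
  and detection, which is acceptable for wide-field illumination but not
  for focal geometries.
* Absolute in-vivo quantities (release half-times in animals, ex-vivo
  tissue concentrations in ug/g) depend on biology the simulator does
  not model; the package mirrors them only as qualitative orderings
  (higher absorption releases slower; corrected concentrations agree
  across optical backgrounds).
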