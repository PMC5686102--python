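# sfdiscope

Quantitative endoscopic spatial-frequency-domain imaging (SFDI) in
Python: from structured-illumination reflectance frames to per-pixel
tissue optical properties, attenuation-corrected fluorescence, absolute
drug-concentration maps, and photo-triggered release kinetics.

## Who this is for

Dual-channel fiber endoscopes can project sinusoidal light patterns onto
tissue and image the remitted light at several spatial frequencies and
wavelengths. The frequency-dependent damping of the pattern separates
absorption (µ_a) from reduced scattering (µ_s′), and those coefficients
in turn let raw drug fluorescence be converted into an absolute
concentration — the quantity that matters when near-infrared light is
used to trigger doxorubicin release from porphyrin–phospholipid
liposomes and the release must be monitored in real time. This package
implements that full computational chain for such an instrument,
together with a synthetic acquisition simulator (virtual scenes, fringe
projection with divergence, fiber honeycomb artifact, lens distortion,
shot/read noise, first-order release kinetics) so every stage runs and
is testable with no hardware attached.

## The models at the core

**Forward reflectance.** For a homogeneous semi-infinite medium the
diffusion approximation with a partial-current boundary gives

    R_d(f) = 3 A a′ / [(µ_eff′/µ_tr + 1)(µ_eff′/µ_tr + 3A)],
    µ_eff′ = sqrt(3 µ_a µ_tr + (2πf)²),  µ_tr = µ_a + µ_s′,  a′ = µ_s′/µ_tr.

The shipped forward model multiplies this by a Monte Carlo-derived
correction C(a′, f/µ_tr) tabulated in exact similarity coordinates
(regenerable with `scripts/build_forward_table.py`), keeping it
transport-accurate (≲2 %) down to low albedo and up to high reduced
frequency where plain diffusion is 15–30 % biased. An MCML-style photon
Monte Carlo (`sfdiscope.montecarlo`) serves as the independent oracle.

**Demodulation and calibration.** Three phase-shifted frames
(0, 2π/3, 4π/3) give `M_AC = (√2/3)·√[(I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²]`
and the fringe phase `atan2(√3(I₃−I₂), 2I₁−I₂−I₃)`; ratioing against a
reference phantom of known properties converts amplitudes to absolute
R_d(f), which a two-start per-pixel least-squares fit inverts to
(µ_a, µ_s′) maps. Surfaces below the focal plane are handled by
phase-shifting profilometry: a once-acquired stack of flat-phantom
measurements at known offsets (0–8 mm) yields a per-pixel phase→height
fit and a height-adjusted reference amplitude.

**Fluorescence correction.** The correction factor X_1D(λ_ex, λ_em) —
the depth integral of excitation fluence times emission escape in a 1-D
diffusion model — divides the raw fluorescence, making the result
proportional to fluorophore concentration independent of the optical
background; an OLS calibration line converts it to µg/mL.

## Worked example

```python
import numpy as np
from sfdiscope import OpticalProperties, sfd_reflectance, x1d_factor
from sfdiscope.pipeline import default_config, run_pipeline

op = OpticalProperties(mu_a=1.0, mu_s_prime=15.0, wavelength=490.0)
print([round(float(sfd_reflectance(op, f)), 4) for f in (0.0, 2/3, 4/3, 2.0)])
# [0.3236, 0.2786, 0.203, 0.1447]   <- R_d decays with pattern frequency

cfg = default_config()
cfg.update({"seed": 1, "shape": [32, 32],
            "noise": {"shot_scale": 0.0, "read_sigma": 0.0, "multiplicative_sigma": 0.01},
            "sample": {"mu_a_ex": 1.0, "mu_s_ex": 20.0, "mu_a_em": 0.5, "mu_s_em": 20.0,
                       "dox": 10.0, "height_mm": 0.0, "tumor": None}})
res = run_pipeline(cfg)
m = res.optical_maps[490.0]
print(f"mu_a {np.nanmean(m.mu_a):.3f}  mu_s' {np.nanmean(m.mu_s_prime):.2f}")
# mu_a 1.002  mu_s' 20.02            <- truth was (1.0, 20.0)
print(f"final {res.curve.mean[-1]:.2f} +- {res.curve.sd[-1]:.2f} ug/mL, t95 = {res.t95.time_s:.0f} s")
# final 9.94 +- 0.31 ug/mL, t95 = 330 s
```

The run simulates a 10 µg/mL phantom, recovers its optical properties
from the structured reflectance frames at both wavelengths (490/590 nm),
builds the X_1D correction map from the *recovered* properties, converts
the triggered-release fluorescence series into concentration maps, and
reports the 50 %-of-peak ROI release curve with the time to 95 % of the
full-release plateau.

The same workflow is scriptable from the shell:

```
sfdiscope process --seed 1 --out runs/demo
sfdiscope report runs/demo
```

with further subcommands `simulate`, `calibrate-reference`,
`calibrate-height`, `kinetics`, and `unmix` (spectral decomposition of
plate-reader emission spectra into drug + autofluorescence bases).

## Layout

| module | contents |
|---|---|
| `optics` | forward R_d(f) model, X_1D factor, fluorescence correction |
| `montecarlo` | photon-transport oracles (reflectance, fluorescence yield) |
| `scene` | synthetic scenes, virtual camera, release simulator |
| `preprocess` | dark subtraction, honeycomb notch filter, distortion, binning, ROI |
| `demod` | three-phase demodulation, phase extraction/unwrapping |
| `calibration` | reference calibration, profilometry height correction |
| `inversion` | per-pixel (µ_a, µ_s′) fitting, lookup table, X_1D maps |
| `concentration` | calibration line, concentration maps, dilution arithmetic |
| `kinetics` | release curves, t₉₅, spectral unmixing, USAF arithmetic |
| `pipeline`, `cli`, `io`, `experiments` | orchestration, shell interface, TIFF/JSON serialization, replication experiments |

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and known limitations.
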