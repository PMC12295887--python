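# Methods

## Kinetic model

Actin assembly is represented by a minimal Oosawa-type nucleation–
elongation scheme with state variables `m` (free monomer, µM), `c_f`
(polymerized actin, µM) and `N` (filament number concentration, µM):

```
dN/dt   = k_nuc·m^n_c + k_seed·P·m^s_c
dc_f/dt = n_c·dN/dt + (k_plus·m − k_minus)·N
dm/dt   = −dc_f/dt
```

Assumptions: a single filament population growing at one end; no
fragmentation, annealing, capping, or nucleotide-state kinetics; the
nucleator `P` (nM) acts catalytically (it is not consumed, and persists
after mid-run addition). Each spontaneous or seeded nucleus books `n_c`
monomers into `c_f` at creation, which makes mass conservation
(`m + c_f = actin_total`) exact by construction. The fixed point of the
elongation term puts the steady-state free monomer at the critical
concentration `Cc = k_minus/k_plus` independently of both nucleation
channels — the property that lets seeding accelerate assembly without
moving the steady state, and the property the critical-concentration
module is built to measure.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `k_plus` | 11.6 | µM⁻¹ s⁻¹ | elongation on-rate (literature-typical barbed-end value) |
| `k_minus` | 1.4 | s⁻¹ | depolymerization rate; `Cc ≈ 0.121 µM` |
| `k_nuc` | 2×10⁻⁸ | µM⁻² s⁻¹ | spontaneous nucleation; set so a 4 µM control run reaches steady state inside a 2000 s measurement window (half-time ≈ 360 s) |
| `n_c` | 3 | – | spontaneous nucleus size |
| `k_seed` | 1×10⁻⁷ | nM⁻¹ µM⁻¹ s⁻¹ | nucleator-mediated seeding; 125 nM nucleator gives a ≈30-fold initial-rate enhancement over the control |
| `s_c` | 1 | – | monomer order of seeded nucleation |
| `actin_total` | 4.0 | µM | standard assay composition, 10 % labeled |

The nucleation constants were fixed once against the two stated
operating conditions (steady state within 2000 s; strong dose response
across the 3.25–125 nM nucleator range) and are configurable.

### Numerics

Integration uses a stiff-safe solver (LSODA, rtol 1e−8, atol 1e−10)
piecewise between addition events, sampled onto the user grid. Two
guards keep trajectories physical without hiding solver failure:
monomer is clamped to ≥0 inside the rate law only, and net-negative
elongation is scaled by `c_f/(c_f + 10⁻³ µM)` so sub-critical runs
cannot drive polymer mass negative. The floor scale (10⁻³ µM) leaves
residual polymer of order 10⁻⁷ µM in sub-critical runs — far below any
observable signal — and was chosen over a smaller value because a
narrower floor makes sub-critical trajectories needlessly stiff.
Negative excursions beyond 10⁻⁹ µM raise an integration error rather
than being clipped.

## Observation model

`F(t) = baseline + gain·f_label·c_f(t)·exp(−k_bleach·E(t)) + ε(t)`,
with `E(t)` the cumulative *illuminated* time under the schedule
(continuous, or intermittent with a 10 s window every 600 s by default,
emulating one reading per 10 min) and ε i.i.d. Gaussian with per-trace
seeds (`base_seed + trace index`). Photobleaching therefore accrues only
during illumination, which is why intermittent protocols preserve signal
in long runs. Steady-state concentration series are read at exactly
`t_end` with the schedule's accumulated exposure (a deliberate final
reading, even if `t_end` falls between illumination windows); a run whose
|dc_f/dt| at `t_end` exceeds 10⁻⁵ µM/s raises an error naming the
offending concentration.

The synthetic concentration series includes 60 nM nucleator by default:
with spontaneous nucleation alone, sub-micromolar actin would not reach
steady state within an 8000 s experiment under this rate law.

## Trace metrics

All slopes are ordinary least squares with standard errors from the
residuals. Defaults: initial rate over 0–40 s; half-maximal rate over an
adaptive window `t_half ± 30 s` (clipped to the trace), where `t_half`
interpolates the first upward crossing of `baseline + (peak−baseline)/2`
and the baseline is the mean of the first three samples; the peak is the
maximum of a 5-sample moving average (reported value is the smoothed
one; ties broken by earliest time). Traces that never rise above
baseline have no half-maximum and raise an error rather than returning a
meaningless window. No bleach correction is applied before metric
extraction (raw-intensity convention).

## Critical concentration

Classical steady-state construction: a least-squares line through the
points whose intensity exceeds `baseline + 3·noise_sd`, with
`Cc = max(0, −intercept/slope)` on blank-subtracted intensities. When no
blank is supplied, intensities are assumed already blank-subtracted and
the lowest-concentration point stands in as the selection baseline; when
no `noise_sd` is supplied it is estimated as 1.4826×MAD of residuals
about a provisional all-points line. Confidence intervals are 95 %
percentile intervals over residual-bootstrap refits (default 1000); the
interval is widened, if necessary, to contain the point estimate (only
relevant in zero-residual edge cases). Two conditions are compared by a
paired bootstrap on `Cc_a − Cc_b`; "same Cc" means the interval covers
zero. A non-positive fitted slope is an error: a polymerization signal
must increase with actin.

## Worm-like-chain geometry

`L_C = 0.38 nm × n_residues`, `R = √(L_C·L_P)` (ideal-chain limit — note
some texts use `√(2·L_C·L_P)`; the convention here matches the assay
literature this package accompanies), `R_G = R/√6`. Reported values are
rounded to 3 significant figures; full precision is kept internally. The
lattice-reach construction assumes the ideal vertebrate hexagonal
double-lattice with thin filaments at trigonal positions, giving a
thick–thin distance of `2·d10/3` (`d10 = 37.4 nm` by default); this is an
idealized geometric interpretation, not a measured quantity.

## Synthetic AFM images and periodicity detection

Paracrystals are fields of parallel Gaussian ridges (default σ 4 nm,
height 6 nm — plausible F-actin dimensions under AFM) at a fixed spacing
(default 13.3 nm) and orientation; each pixel takes the height of the
nearest ridge, so the noise-free maximum equals the filament height, and
the lattice phase is seed-independent so replicate images differ only in
noise. Radial fields place non-overlapping asters (centres ≥ half the
maximum filament length apart), each a 12 nm globule with ridges of
random direction and length uniform in [0.3, 1]×500 nm (all below 1 µm);
ridges composite by maximum, as for surface-adsorbed filaments. The
default field is 512 px × 2 nm/px ≈ 1 µm, placing a 13.3 nm spacing well
above Nyquist. Gaussian pixel noise (default 0.3 nm) is added last.

The spectrum is the amplitude of the 2D DFT of the mean-subtracted,
Hann-windowed image (normalized so Σ|A|² equals the windowed-image
energy), with per-metre frequency axes. Directional profiles average
amplitudes over an angular sector (default ±5°, angles mod 180°) into
radial bins one frequency-resolution wide; empty bins are reported as
missing (NaN), never zero, and each bin carries its pixel count.

Peak detection operates inside a spatial-frequency band (default
5×10⁶–75×10⁶ m⁻¹, i.e. periodicities of 200 nm down to ≈13.3 nm). Three
numerical choices matter:

- **Band membership at bin resolution.** A bin is in-band if its
  frequency interval overlaps the band. The 13.3 nm fundamental sits at
  75.19×10⁶ m⁻¹ — marginally past a band edge that is itself a rounded
  periodicity limit — and is admitted by the overlap rule, while the
  6.65 nm harmonic (150×10⁶ m⁻¹) is not. Local maxima are located on the
  full profile before band filtering, so a peak in the band's edge bin
  is still recognized as a maximum.
- **Count-scaled prominence threshold.** The base threshold is 5× the
  MAD of the in-band amplitudes; each bin's threshold is additionally
  scaled by `√(median count / bin count)`, because a bin mean averaged
  over few spectral pixels (small annuli at low frequency) fluctuates
  more. For equal-count bins the rule reduces to the plain MAD
  threshold.
- **Local prominence.** Prominence is evaluated within ±2 bins: a
  genuine lattice peak rises straight out of a near-zero local
  background, whereas unwindowed prominence on a flat noisy profile
  measures the full excursion range and flags spurious maxima.

For deciding whether an image contains *any* periodicity, `analyze_image`
probes the azimuthally averaged profile (±90°): narrow sectors contain
single-pixel speckle at low frequency that no local detector can reject,
while azimuthal averaging suppresses speckle and preserves genuine
lattice peaks. The probe direction is chosen automatically as the angle
of the strongest in-band spectral pixel (the automated analogue of aiming
a directional read-out at the visible peak). Peaks are reported sorted by
amplitude, ties broken by lower frequency; periodicity in nm is
`10⁹/SF`.

## What the generators do and do not emulate

The trace generator reproduces the phase structure, dose response,
photobleaching and illumination scheduling of pyrene assays, with
independent Gaussian noise; it does not model filament length
distributions, ATP hydrolysis, pointed-end kinetics, capping, mixing
dead time, or the slow instrument drifts and sample-to-sample
variability of real experiments. The image generator reproduces
inter-filament spacing and aster morphology but not tip convolution,
scan-line artifacts, helical substructure, or long-range paracrystal
order beyond the fundamental spacing. Tests passing on these synthetic
data therefore validate the *analysis chain* — metric extraction,
Cc estimation, periodicity detection — under controlled conditions, not
the biological conclusions one would draw from real traces or images.

## Problem sizes

Default analyses use 2000 s trace grids at 1 s resolution, 8000 s
concentration series over 8 concentrations, 500–1000 bootstrap
replicates, 512×512 images, and 50-seed-per-mode classification sweeps;
all complete in seconds to a few tens of seconds on a single CPU.

## Known limitations

- Seeded nucleation treats the nucleator as purely catalytic; if seeds
  were consumed stoichiometrically, late-time dose responses would
  differ (the steady state would not).
- The Cc estimator assumes a shared observation model (gain, blank,
  bleaching) between conditions being compared.
- The azimuthally averaged detector trades angular specificity for
  speckle robustness; a weak periodicity confined to a narrow direction
  band could be diluted below threshold.
- `R = √(L_C·L_P)` is the ideal-chain limit and underestimates excluded-
  volume swelling; persistence length is treated as sequence-independent.
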