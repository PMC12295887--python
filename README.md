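# pevkactin

Quantitative analysis of how a nucleating agent — such as titin's
intrinsically disordered PEVK domain — modulates actin polymerization, for
researchers working with pyrene-fluorescence assays and AFM imaging of
filament fields. The package bundles five pieces that normally live in
ad-hoc spreadsheets:

1. **A nucleation–elongation simulator** producing pyrene-like fluorescence
   traces (lag, log and steady-state phases, photobleaching, intermittent
   illumination, mid-run nucleator addition).
2. **Trace quantitation** — initial rate, half-maximal (log-phase) rate,
   peak intensity, time to peak, and pre/post-addition slope ratios.
3. **Critical-concentration estimation** from steady-state intensity vs
   actin concentration, with bootstrap CIs and two-condition comparison.
4. **Worm-like-chain geometry** of a disordered chain and its reach in the
   sarcomeric filament lattice.
5. **Synthetic AFM height images** (parallel paracrystals vs radial asters)
   and 2D-FFT detection of inter-filament periodicities.

## Model

The simulator integrates a minimal Oosawa-type scheme for monomer
concentration `m`, polymer mass `c_f`, and filament number `N`:

```
dN/dt   = k_nuc · m^n_c  +  k_seed · P · m^s_c
dc_f/dt = n_c · dN/dt    +  (k₊ · m − k₋) · N
dm/dt   = −dc_f/dt
```

with `P` the nucleator concentration. Seeding (`k_seed·P`) accelerates
nucleation only; the steady-state free monomer is the critical
concentration `Cc = k₋/k₊` regardless of either nucleation pathway — the
model-level statement of "faster assembly, unchanged steady state" that
the analysis modules are designed to test. Fluorescence is observed as
`F = baseline + gain·f_label·c_f·exp(−k_bleach·E(t)) + ε`, where `E(t)` is
cumulative illuminated exposure under the chosen schedule.

For a disordered chain of `n` residues (0.38 nm spacing) with persistence
length `L_P`, the relaxed-chain statistics are `L_C = 0.38·n`,
`R = √(L_C·L_P)`, and `R_G = R/√6`.

## Worked example

Chain geometry of the full-length 2174-residue PEVK domain at
`L_P = 1 nm` in the vertebrate filament lattice (`d10 = 37.4 nm`):

```
$ pevkactin geometry --n-residues 2174 --lp 1.0
contour length Lc       = 826 nm
end-to-end distance R   = 28.7 nm
radius of gyration RG   = 11.7 nm
thick–thin distance     = 24.9 nm (2·d10/3, d10 = 37.4 nm)
reach margin RG − dist  = -13.2 nm
```

The 826 nm contour collapses to a ~29 nm coil with an ~12 nm radius of
gyration; the negative reach margin says a relaxed chain tethered at a
thick filament does not span the 24.9 nm to the nearest thin filament in
the overlap region on its own.

Rendering a 512×512 paracrystal (13.3 nm inter-filament spacing, 2 nm/px)
and reading its spectrum back:

```
$ pevkactin render-afm --spec afm.yaml --out img.tif --seed 2
$ pevkactin fft --image img.tif
{
  "probe_angle_deg": 90.0,
  "has_periodicity": true,
  "peaks": [
    { "spatial_frequency": 75195312.5, "periodicity_nm": 13.2987, ... }
```

The dominant peak sits at 75.2×10⁶ m⁻¹ ≡ 13.3 nm — the planted spacing,
recovered to within one frequency bin. A radial-aster image analyzed the
same way reports `has_periodicity: false`.

Simulating a steady-state concentration series (60 nM nucleator, 0.05–2 µM
actin, intermittent 10-min readings to 8000 s) and fitting the critical
concentration:

```
$ pevkactin simulate-cc --config cc.yaml --out series.csv --seed 4
$ pevkactin ccfit --series series.csv --bootstrap 500 --seed 1 --blank 5.0
pevk: Cc = 0.1142 µM (95% CI 0.1034–0.1281, 6 points, slope 9.933 au/µM)
```

The fitted x-intercept recovers the simulator's analytic
`Cc = k₋/k₊ = 1.4/11.6 ≈ 0.121 µM` within its bootstrap CI.

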