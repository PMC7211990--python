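# rbcgas

Reaction–diffusion modeling of gas exchange in single red blood cells
(RBCs), for cellular biophysicists and physiologists studying why O₂
unloading is slower than classical estimates and what that costs in
disease.

A red cell attached to a coverslip and superfused with an anoxic
(dithionite) solution unloads its O₂ with a monoexponential time constant
τ_O2 ≈ 1 s — strikingly slow for a cell less than 2 µm thick. This
package implements the modeling stack needed to interpret such
measurements:

- **`rbcgas.hb_kinetics`** — a four-step sequential (Adair-type)
  cooperative Hb–O₂ scheme. Per-site off-rates with statistical factors;
  the first unbinding step is slow (k_d ≈ 20–30 s⁻¹), later steps faster,
  so the ensemble dissociation rate approaches ~100 s⁻¹. Equilibrium is
  calibrated to a configurable (P50, Hill n).
- **`rbcgas.gas_diffusion`** — a 1-D slab reaction–diffusion solver for
  O₂ unloading (method of lines, implicit BDF), with the membrane folded
  into an effective diffusivity

  &nbsp;&nbsp;&nbsp;&nbsp;(D_O2^eff)⁻¹ = (D_c,O2)⁻¹ + (h·P_m,O2)⁻¹

  (h = mean diffusion distance ≈ half-thickness, MCV/area/2), plus the
  inverse problem: the (k_d, D_eff) trade-off curve fitting a measured
  τ_O2.
- **`rbcgas.trace_kinetics`** — ratiometric trace handling: saturation
  normalization, the 23-ms solution-switch convolution, deterministic
  monoexponential fitting (shared between experiment and model), cohort
  summaries.
- **`rbcgas.h_uncaging`** — facilitated H⁺ diffusion (mobile-buffer
  shuttle): D_H^app = (β_Hb·D_Hb + β_CO2·D_c,CO2)/(β_Hb + β_CO2);
  simulation and fitting of 10-ROI photolytic-uncaging time courses,
  inversion for the cytoplasmic CO₂/HCO₃⁻ diffusivity, and the empirical
  law D halving per 62 g/L of MCHC.
- **`rbcgas.membrane_assays`** — glycerol (AQP3), acetic-acid (bilayer)
  and AE1 (Cl⁻/OH⁻ exchange) estimators with explicit monoexponential /
  initial-rate contracts.
- **`rbcgas.population_stats`** — T95 = −ln(0.05)·τ_O2 with temperature
  (×0.774), two-sided-exchange (÷4 or model rerun at h/2) and CO₂
  (affinity ×0.949, model rerun) corrections; Gaussian-mixture
  subpopulation analysis (BIC, seeded restarts).
- **`rbcgas.capillary`** — O₂ delivery from a 500-µm capillary versus
  perfusion for a T95 population; per-cell unloaded fraction
  1 − 0.05^(t/T95), analytic plateau C·ln 20·mean(1/T95).
- **`rbcgas.synthetic`** — generators for every input: cell populations
  (wild type, HbH thalassemia, anemic/compensated hereditary
  spherocytosis, osmolarity presets), 7.8-Hz ratio traces, uncaging sets,
  assay traces; seeded and reproducible.
- **`rbcgas.io`** — delimited trace/fit/ROI tables, strict YAML/JSON run
  configs with provenance, optional two-channel TIFF round trip.

The library is used from Python; the `examples/` directory holds one
short narrative script per capability.

## Worked example

```sh
python examples/unloading_inversion.py
```

```
k_d_first (s^-1)   D_eff (um^2/s)
            20         64.4
            60         64.1
           100         64.1
```

Across the entire supported dissociation range, the effective O₂
diffusivity that reproduces τ_O2 = 0.971 s at h = 0.885 µm stays below
70 µm²/s — more than 35-fold below free-solution diffusivity — so
cytoplasmic crowding by hemoglobin, not membrane permeation, is the
rate-limiting barrier.

```sh
python examples/t95_population.py
```

```
raw T95 = -ln(0.05) x 0.971 = 2.909 s
corrected T95 = 0.532 s   factors: temp_factor=0.774, two_sided=0.25, co2=0.945

             WT:  97.7% unload within 0.71 s | mixture k=1: 1.00xN(0.51,0.10)
            HbH: 100.0% unload within 0.71 s | mixture k=1: 1.00xN(0.36,0.08)
      HS_anemic:  74.9% unload within 0.71 s | mixture k=2: 0.57xN(0.45,0.11), 0.43xN(0.77,0.32)
 HS_compensated:  43.9% unload within 0.71 s | mixture k=2: 0.39xN(0.45,0.10), 0.61xN(1.37,0.48)
```

After correcting to in-vivo conditions the typical wild-type cell needs
~0.5 s to unload 95% of its O₂ — comparable to a resting capillary
transit (0.71 s), leaving little reserve. Spherocytosis populations split
into fast/slow Gaussian subpopulations; the slow fraction grows with
compensation, which is why restored hematocrit does not restore O₂
delivery at high perfusion (see `examples/capillary_delivery.py`).

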