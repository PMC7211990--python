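# Methods

This note records the models, parameter choices and numerical decisions
behind `rbcgas`, including where the design was genuinely open and what
the synthetic-data generators do and do not emulate.

## Hb–O₂ reaction scheme

The reaction term is a four-step sequential scheme
Hb(O₂)₀ ⇌ … ⇌ Hb(O₂)₄ with per-site intrinsic rate constants and
statistical factors (state *i* loses O₂ at total rate *i·k_off,i*, binds
at *(4−i)·k_on,i₊₁·[O₂]*). Two experimental facts anchor the kinetics:
the first unbinding step from oxyhemoglobin is slow (k_d ≈ 20–30 s⁻¹)
and cooperativity makes the ensemble dissociation of the whole tetramer
several-fold faster (~100 s⁻¹).

**Ensemble rate.** We define the ensemble k_d as the rate constant of
the equal-area single exponential of the zero-O₂ dissociation cascade.
For per-site off-rates k_i this has the closed form 4/Σ(1/k_i) (harmonic
mean): it equals k_d,first exactly when cooperativity is absent and is
bounded above by 4·k_d,first. Tests cross-check it against the 1/e time
of the integrated ODE cascade (agreement ≤ 5 %). Because of the 4× bound,
an ensemble target of 100 s⁻¹ requires k_d,first ≥ 25 s⁻¹ — consistent
with the upper half of the measured first-step range — and
`build_scheme` raises a parameterization error for unreachable targets.
Cooperativity is a geometric ladder (g, g², g³) on the off-rates of
steps 3, 2, 1, solved for the ensemble target. `scheme_for_kd` treats
cooperativity as structural (later steps always faster), with the ladder
fixed at ensemble = 3.5 × k_d,first, mapping first-step 20–30 s⁻¹ onto
ensemble 70–105 s⁻¹.

**Equilibrium.** Per-site association constants a_j are calibrated by
bounded least squares so the generalized Adair curve reproduces the
configured half-saturation point exactly and the logit (Hill) slope at
P50 within 1 %. A four-constant Adair scheme cannot coincide pointwise
with an idealized Hill function; the maximum absolute saturation
deviation over 1–150 mmHg is kept as a diagnostic (typically ≈ 0.01).
The affinity ladder is constrained to physically plausible magnitudes
because an unconstrained pointwise fit converges to an alternating
ladder with on-rates far beyond the diffusion limit, which breaks the
kinetics. Defaults: P50 = 26 mmHg, Hill n = 2.7, MCHC = 330 g/L (heme =
MCHC/16 114 g mol⁻¹), O₂ solubility 1.3 µM/mmHg; all configurable. The
CO₂ affinity correction multiplies every step's association constant by
a factor (default 0.949 for 40 mmHg P_CO2), equivalent to shifting the
whole curve so P50 scales by 1/factor; the factor composes
multiplicatively and is recorded on the scheme.

## O₂ unloading PDE

Geometry is a 1-D slab normal to the coverslip. In the experiment the
attached cell exchanges through its solution-facing side only; the mean
diffusion distance h (default 0.885 µm, half of MCV/area) is the
one-sided pathlength, with a Dirichlet pO₂ = 0 face (dithionite sink)
and a zero-flux coverslip face. `two_sided` mode models the in-vivo
cell with both faces exchanging: the pathlength halves, which by Fick's
law gives a ~fourfold shorter delay; it is solved on the symmetric
half-domain of length h/2. (A literal "sinks on both faces of thickness
2h" reading is by symmetry identical to the one-sided problem and would
predict no speed-up; the fourfold reduction is the physically and
empirically correct statement, so that is what the mode implements.)
A `closed` mode (zero flux everywhere) supports conservation checks.

The membrane is folded into the effective diffusivity
(D_eff)⁻¹ = (D_c)⁻¹ + (h·P_m)⁻¹ by default; an explicit Robin membrane
boundary is provided as a cross-check and agrees with the lumped form
within 5 % when the membrane is a minor series resistance (P_m in the
thousands of µm/s, as the stretch-activation experiments imply). At
Biot numbers near 1 the two formulations genuinely differ in their
transients — the lumped form is primary.

Discretization: cell-centered finite volumes (so boundary hemoglobin is
handled naturally), 64 nodes by default, stiff BDF integration with an
analytic Jacobian sparsity pattern, rtol 1e-6. A mandatory convergence
check (when enabled) re-runs at double resolution and requires the
fitted τ to move < 1 %. The solver is validated against the analytic
Fourier-series slab solution (reaction disabled, max error < 1e-4),
closed-box O₂ conservation (< 1e-6 relative), the well-mixed
dissociation cascade at huge D, Fickian τ ∝ h² scaling, and the
two-sided/one-sided ≈ 1/4 ratio.

τ extraction from simulated traces uses the *same* monoexponential
fitter as experimental traces, so model and data share one code path.

**Inversion.** `fit_deff_for_tau` brackets D_eff on a log grid and
root-finds τ(D_eff) = τ_target (relative tolerance 1e-3); τ is monotone
decreasing in D_eff. The reaction-limited floor (τ at D → ∞) is computed
first and targets at/below it raise an error naming the floor.

**Assay conditions for the inversion.** The unloading experiments were
performed at 23 °C in air-equilibrated superfusate, so the published
τ = 0.971 s is inverted under O₂ solubility 1.6 µM/mmHg (Henry's law,
water at 23 °C) and initial pO₂ 150 mmHg (`EXPERIMENT_23C`), with the
default P50/Hill (the source experiments' P50 is not published; this is
the main open parameter). Under these conditions the fitted D_eff is
≈ 64–65 µm²/s across k_d,first = 20–100 s⁻¹ — below the 70 µm²/s bound.
The answer is condition-sensitive: with 37 °C-style constants
(1.3 µM/mmHg, 100 mmHg) the same inversion gives ≈ 79 µm²/s.

## Trace kinetics

Fitting v(t) = baseline + Δ·exp(−(t−t₀)/τ) uses deterministic starting
values from a log-linear regression; t₀ defaults to the detected switch
onset (3-sample-smoothed steepest change) and is configurable — cohort
pipelines should pass the known protocol switch time. Flat traces
(range below 5× a second-difference noise estimate) return
`converged=False` with amplitude 0 rather than raising; non-convergence
is a per-cell flag counted (never silently dropped) by
`population_summary`. τ is invariant to affine rescaling of the trace,
so fitting the raw ratio or the normalized saturation is equivalent.

The finite solution switch is a first-order lag (exact update for
piecewise-linear input; area- and asymptote-preserving; τ_switch = 0 is
the identity). At the experimental scale (τ_O2 ≈ 40× the 23-ms switch)
convolution moves the fitted τ by < 3 %, justifying neglecting the
switch; at only 10× separation the bias reaches ~5 %, which is why the
generators still apply the kernel.

## Facilitated H⁺ diffusion and D_c,CO2

Mobile-buffer theory: free H⁺ is immobilized by binding, so the
apparent H⁺ diffusivity is the buffering-weighted mean of the carrier
diffusivities, D_H^app = (β_Hb·D_Hb + β_CO2·D_c,CO2)/(β_Hb + β_CO2).
This closed form is adopted as the concrete facilitated-diffusion model;
CO₂/HCO₃⁻ is taken at instantaneous chemical equilibrium (carbonic
anhydrase fast) and DIDS closure makes the cell a closed compartment
(zero-flux ends). The uncaging forward model is linear diffusion of the
buffered acid load, solved spectrally (64 cosine modes, exact per-frame
updates) with acid injected in the first tenth of the cell during
alternating frames of the 0.133-s cadence; pH in 10 equal ROIs is
pH_start − acid/β_total. `fit_dh_app` is a bounded scalar least-squares
over all ROIs simultaneously; uniform traces raise an unidentifiable
error. Pairing ± CO₂/HCO₃⁻ conditions inverts the weighted mean for
D_c,CO2; a negative result is reported as physically inconsistent, not
clamped. Buffering capacities default to β_Hb = 50 mM/pH and β_CO2 = 50
mM/pH and D_Hb = 8 µm²/s — assumptions (the source buffering data are
not published), which is why the D_c,CO2 targets are generator
round-trips rather than absolute reproductions. The MCHC law
D(MCHC) = D_ref·2^(−ΔMCHC/62 g/L) is fitted log-linearly.

## Membrane assays

Each estimator is an explicit contract: glycerol — monoexponential
volume relaxation, estimate k·(V_eq−V₀)/Δglycerol (∝ P·SA up to a fixed
osmotic proportionality); acetic acid — monoexponential pH decline,
estimate (ΔpH/τ)·β/[acetate] = P·SA/MCV; AE1 — initial-rate
|dpH/dt|₀·β/ΔpH_o (×SA). All three are homogeneous of degree 1 in the
underlying coefficient. The synthetic generators integrate the matching
flux ODEs; the glycerol presets relax between the published equilibrium
volumes (79→86 fL isotonic, 123→148 fL hypotonic), and hypotonic
coefficients exceed isotonic ones (stretch activation), which the
ordering tests verify. The AE1 activity unit is a relative readout; only
ordering/scaling claims are asserted.

## T95 statistics and mixtures

T95 = −ln(0.05)·τ (natural log — τ is defined by a base-e exponential,
and base-10 would be numerically inconsistent with the published
corrected means). Corrections: ×0.774 (empirical 23→37 °C), two-sided
÷4 (or model rerun at h/2; the two agree within 10 % in the
diffusion-limited regime), CO₂ via model rerun with affinity ×0.949
(default) or a user-supplied multiplicative shortcut. The full chain
maps τ = 0.971 s to ≈ 0.53 s, within ~10 % of the published 0.51-s
wild-type mean — a consistency check, not a fitted result.

Mixtures: scikit-learn Gaussian mixtures for k = 1, 2 with 5 seeded EM
restarts (tol 1e-7, up to 1000 iterations, so the k = 2 likelihood never
falls below k = 1), selected by BIC (the selection criterion is not
published; BIC is this package's choice). Published "variance" values
quoted in seconds are dimensionally standard deviations; spreads are
stored as SDs with an explicit interpretation flag. The τ gate for HS
subpopulation analysis (1.6 s) is exposed as a constant.

## Capillary delivery

Per-cell monoexponential unloading replaces an explicit intracapillary
PDE: fraction unloaded in transit t is 1 − 0.05^(t/T95), flux(m) =
(C/transit(m))·mean(fraction), transit(m) = 0.71 s/m. This is the
minimal model consistent with the T95 framing; axial O₂ gradients and
myoglobin uptake are neglected (anoxic tissue sink). O₂ content C uses a
5-µm × 500-µm capillary, the preset blood [Hb], and a 0.5
capillary-to-systemic hematocrit ratio (Fåhræus effect) — C ≈ 44 fmol
for wild type. These choices put the wild-type high-perfusion delivery
at the right order of magnitude (~10² fmol/s); only order-of-magnitude
and relative/ordering claims are asserted for absolute fluxes.

## Synthetic populations — what is and is not published

Published and used as-is: blood [Hb] (89/142 g/L anemic/compensated HS),
MCHC (339/353 g/L), reticulocyte fractions (7.8/10.3 %), the HS slow
fractions (48 %/62 %), the +25 % HS pathlength, wild-type mean
τ = 0.971 s, T95 single-Gaussian parameters (WT 0.51/0.10 s, HbH
0.36/0.08 s), the glycerol equilibrium volumes, and the osmolarity
series 180–414 mOsm/kg. Package assumptions: all other distribution
widths, the HbH mean τ (0.68 s, from "~30 % faster"), and the HS
mixture component means/SDs — the latter fixed once so the mixtures
reproduce the published cumulative unloading fractions at the 0.71-s
transit (≈ 75 % anemic, ≈ 44 % compensated) together with the published
weights. Under the SD interpretation the wild-type Gaussian puts 97.7 %
below 0.71 s (the published cumulative curve reads ~93 % — the real
distribution is not exactly Gaussian). The osmolarity presets rescale
volume by a van 't Hoff relation (30 % osmotically inactive), conserve
Hb content, and emulate the observed biphasic τ–osmolarity relation
with a symmetric quadratic (nadir at 297 mOsm/kg); the package's own
h² and CO₂-halving laws alone would not reproduce the hypotonic slowing,
indicating O₂'s effective diffusivity is less MCHC-sensitive than
CO₂'s — the empirical shape is used instead.

Generators produce idealized data: no photobleaching, cell motion,
segmentation error, optics, or dye-calibration nonlinearity. Passing
round-trip tests therefore demonstrates estimator correctness on the
stated forward models, not robustness to those real-world effects.
Reproducibility is bit-exact under a fixed seed (numpy Generator); every
generator returns a metadata dict sufficient to rerun it.

## Problem sizes

Defaults were chosen so the full test suite runs in well under a minute
of CPU: PDE grids of 64 (256 for the analytic-oracle comparison),
trade-off grids of 3–5 k_d points, cohorts of 200–700 cells for trace
statistics, and n = 10⁴ for distribution-recovery checks.
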