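"""Synthetic-data generators for every pipeline input.

Emulates the single-cell assays at their stated acquisition settings:
ratio traces sampled at 7.8 Hz convolved with the 23-ms solution switch
(mean normalized ratio decrease 39%), 10-ROI uncaging time courses on the
0.133-s cadence, and membrane-assay traces from explicit flux ODE models.
Cell populations (MCV, area, height = MCV/area, MCHC, tau_O2) are drawn
from condition presets for wild-type blood, HbH thalassemia, hereditary
spherocytosis (anemic and compensated), hereditary elliptocytosis, iron
deficiency and an osmolarity series.

Preset provenance: blood [Hb], MCHC, reticulocyte fractions, the HS slow
subpopulation weights (48% anemic / 62% compensated), the +25% HS
pathlength, the WT mean tau (0.971 s) and the T95 single-Gaussian
parameters (0.51/0.10 s WT, 0.36/0.08 s HbH) are published values; the
remaining distribution widths and the HS component means/SDs are this
package's assumptions (see docs/methods.md).  Every generator is
deterministic under its seed and returns a metadata dict sufficient to
rerun it.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .h_uncaging import (
    BufferSystem,
    UncagingExperiment,
    UncagingProtocol,
    simulate_uncaging,
)
from .membrane_assays import CellGeometry
from .trace_kinetics import DEFAULT_DT, SWITCH_TAU, RatioTrace, convolve_switch

#: mean normalized ratio decrease on full deoxygenation
DEFAULT_AMPLITUDE = 0.39

#: osmolarity series probed experimentally (mOsm/kg)
OSMOLARITY_SERIES = (180, 209, 238, 267, 297, 326, 355, 414)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative + additive Gaussian trace noise; seeded."""

    additive_sd: float = 0.0
    multiplicative_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise DomainError("noise SDs must be nonnegative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.multiplicative_sd > 0:
            v = v * (1.0 + self.multiplicative_sd * rng.standard_normal(v.shape))
        if self.additive_sd > 0:
            v = v + self.additive_sd * rng.standard_normal(v.shape)
        return v


@dataclass(frozen=True)
class ConditionPreset:
    """Distribution parameters of one blood condition.

    ``tau_components`` / ``t95_components`` are lists of
    (weight, mean, sd) tuples — one entry for single-Gaussian conditions,
    two (fast, slow) for HS.  Geometry entries are (mean, sd).
    """

    name: str
    mcv: tuple          # fL
    area: tuple         # um^2
    mchc: tuple         # g/L
    tau_components: tuple
    t95_components: tuple
    hb_blood: float     # g/L
    retic_fraction: float  # %
    notes: str = ""


def _preset(name, mcv, area, mchc, tau, t95, hb, retic, notes=""):
    return ConditionPreset(name, mcv, area, mchc, tuple(tau), tuple(t95),
                           hb, retic, notes)


#: nominal multiplicative chain tau -> corrected T95 used to keep the tau
#: and T95 preset families mutually consistent: 2.9957 * 0.774 / 4 * 0.95
_TAU_TO_T95_NOMINAL = 0.55

PRESETS = {
    "WT": _preset(
        "WT", (90, 5), (50.8, 4), (330, 12),
        tau=[(1.0, 0.971, 0.30)],
        t95=[(1.0, 0.51, 0.10)],
        hb=145, retic=1.5,
        notes="height 1.77 um -> half-thickness 0.885 um",
    ),
    "HbH": _preset(
        "HbH", (65, 6), (44, 4), (280, 15),
        tau=[(1.0, 0.68, 0.15)],
        t95=[(1.0, 0.36, 0.08)],
        hb=91, retic=3.0,
        notes="microcytic, hypochromic; ~30% faster unloading than WT",
    ),
    "HS_anemic": _preset(
        "HS_anemic", (85, 9), (38.4, 4), (339, 15),
        tau=[(0.52, 0.82, 0.18), (0.48, 1.31, 0.55)],
        t95=[(0.52, 0.45, 0.10), (0.48, 0.72, 0.35)],
        hb=89, retic=7.8,
        notes="spherical remodeling: +25% pathlength; 48% slow subpopulation",
    ),
    "HS_compensated": _preset(
        "HS_compensated", (85, 9), (38.4, 4), (353, 15),
        tau=[(0.38, 0.82, 0.18), (0.62, 2.45, 0.85)],
        t95=[(0.38, 0.45, 0.10), (0.62, 1.35, 0.50)],
        hb=142, retic=10.3,
        notes="62% slow subpopulation after hematocrit recovery",
    ),
    "HE": _preset(
        "HE", (88, 6), (48, 4), (332, 12),
        tau=[(1.0, 1.05, 0.30)],
        t95=[(1.0, 0.55, 0.11)],
        hb=130, retic=2.0,
        notes="elliptocytosis; mildly slowed unloading (assumption)",
    ),
    "iron_deficiency": _preset(
        "iron_deficiency", (70, 7), (46, 4), (300, 15),
        tau=[(1.0, 0.85, 0.25)],
        t95=[(1.0, 0.45, 0.09)],
        hb=100, retic=1.5,
        notes="microcytic with reduced MCHC (assumption)",
    ),
}


def osmolarity_preset(osm: float, base: ConditionPreset | None = None
                      ) -> ConditionPreset:
    """WT cells equilibrated at a different extracellular osmolarity.

    Volume follows a van 't Hoff relation with 30% osmotically inactive
    fraction; Hb content per cell is conserved (MCHC rescales); projected
    area is unchanged, so thickness tracks volume.  tau follows the
    empirically observed biphasic relation — slower at both osmotic
    extremes, fastest near physiological osmolarity — emulated by a
    symmetric quadratic in relative osmolarity (swelling lengthens the
    diffusion path; shrinkage concentrates Hb and slows diffusion; the
    two effects trade off with a nadir at ~297 mOsm/kg).
    """
    if osm <= 0:
        raise DomainError("osmolarity must be positive")
    if base is None:
        base = PRESETS["WT"]
    iso = 297.0
    shrink = 0.7 * iso / osm + 0.3
    mcv = base.mcv[0] * shrink
    mchc = base.mchc[0] / shrink
    tau_scale = 1.0 + 2.0 * ((osm - iso) / iso) ** 2
    tau = tuple((w, m * tau_scale, s * tau_scale)
                for w, m, s in base.tau_components)
    t95 = tuple((w, m * tau_scale, s * tau_scale)
                for w, m, s in base.t95_components)
    return ConditionPreset(
        f"osmo_{osm:g}", (mcv, base.mcv[1] * shrink), base.area,
        (mchc, base.mchc[1] / shrink), tau, t95, base.hb_blood,
        base.retic_fraction,
        notes=f"WT preset rescaled to {osm:g} mOsm/kg",
    )


def get_preset(name: str) -> ConditionPreset:
    if name in PRESETS:
        return PRESETS[name]
    if name.startswith("osmo_"):
        return osmolarity_preset(float(name.split("_", 1)[1]))
    raise DomainError(
        f"unknown preset {name!r}; available: {sorted(PRESETS)} "
        "or 'osmo_<mOsm>'"
    )


def _truncated_normal(rng, mean, sd, n, lo=1e-6):
    """Normal draws truncated to positive values (rejection)."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= lo
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= lo
    return out


def _sample_mixture(rng, components, n):
    w = np.array([c[0] for c in components])
    comp = rng.choice(len(components), size=n, p=w / w.sum())
    out = np.empty(n)
    for i, (_w, m, s) in enumerate(components):
        k = int((comp == i).sum())
        out[comp == i] = _truncated_normal(rng, m, s, k)
    return out


def generate_population(preset: ConditionPreset | str, n: int, seed: int = 0):
    """Cell table (cell_id, mcv, area, height, mchc, tau_true, label, retic).

    Returns ``(DataFrame, metadata dict)``; reproducible under ``seed``.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mcv = _truncated_normal(rng, *preset.mcv, n)
    area = _truncated_normal(rng, *preset.area, n)
    mchc = _truncated_normal(rng, *preset.mchc, n)
    tau = _sample_mixture(rng, preset.tau_components, n)
    retic = rng.random(n) < preset.retic_fraction / 100.0
    df = pd.DataFrame({
        "cell_id": [f"{preset.name}_{i:05d}" for i in range(n)],
        "mcv": mcv, "area": area, "height": mcv / area, "mchc": mchc,
        "tau_true": tau, "label": preset.name, "retic": retic,
    })
    meta = {"generator": "generate_population", "preset": asdict(preset),
            "n": n, "seed": seed}
    return df, meta


@dataclass(frozen=True)
class SwitchProtocol:
    """Timing of a deoxygenation exposure."""

    pre_switch: float = 2.0     # s of oxygenated baseline
    exposure: float = 30.0      # s in deoxygenated solution
    dt: float = DEFAULT_DT      # 7.8-Hz sampling
    switch_tau: float = SWITCH_TAU
    amplitude: float = DEFAULT_AMPLITUDE


def generate_ratio_traces(
    cells: pd.DataFrame,
    protocol: SwitchProtocol | None = None,
    noise: NoiseModel | None = None,
    mode: str = "exponential",
):
    """Per-cell normalized ratio traces for the deoxygenation protocol.

    ``exponential`` mode draws the ideal trace from each cell's tau_true;
    ``pde`` mode runs the reaction-diffusion model on each cell's geometry
    (slow; meant for small cohorts).  Both are convolved with the solution
    switch and then noised.  Returns ``(list of RatioTrace, metadata)``.
    """
    if protocol is None:
        protocol = SwitchProtocol()
    if noise is None:
        noise = NoiseModel()
    if mode not in ("exponential", "pde"):
        raise DomainError("mode must be 'exponential' or 'pde'")
    rng = np.random.default_rng(noise.seed)
    t = np.arange(0.0, protocol.pre_switch + protocol.exposure, protocol.dt)
    warn = bool(protocol.exposure < 3.0 * float(cells["tau_true"].max()))
    traces = []
    for row in cells.itertuples():
        if mode == "exponential":
            v = np.ones_like(t)
            after = t >= protocol.pre_switch
            v[after] = 1.0 - protocol.amplitude * (
                1.0 - np.exp(-(t[after] - protocol.pre_switch) / row.tau_true)
            )
        else:
            v = _pde_trace(row, t, protocol)
        tr = RatioTrace(t, v, cell_id=row.cell_id)
        tr = convolve_switch(tr, protocol.switch_tau)
        traces.append(tr.with_values(noise.apply(tr.values, rng)))
    meta = {"generator": "generate_ratio_traces", "mode": mode,
            "protocol": asdict(protocol), "noise": asdict(noise),
            "n_cells": len(traces), "duration_warning": warn}
    return traces, meta


def _pde_trace(row, t, protocol):
    """Reaction-diffusion trace from the cell's own geometry and MCHC."""
    from .gas_diffusion import (
        DiffusionBarrier, EXPERIMENT_23C, UnloadingSimConfig,
        simulate_unloading,
    )
    from .h_uncaging import mchc_halving_law
    from .hb_kinetics import scheme_for_kd

    # cytoplasmic crowding law anchored at D_eff ~65 um^2/s for WT MCHC
    d_eff = mchc_halving_law(d_ref=65.0, mchc_ref=330.0)(row.mchc)
    scheme = scheme_for_kd(25.0, mchc=row.mchc,
                           solubility=EXPERIMENT_23C["solubility"])
    cfg = UnloadingSimConfig(
        barrier=DiffusionBarrier.from_deff(d_eff, h=row.height / 2.0),
        scheme=scheme, duration=float(protocol.exposure),
        initial_pO2=EXPERIMENT_23C["initial_pO2"],
    )
    sim = simulate_unloading(cfg, check_convergence=False)
    sat = np.interp(np.clip(t - protocol.pre_switch, 0, None),
                    sim.trace.time, sim.trace.values)
    sat0 = sat[0]
    v = 1.0 - protocol.amplitude * (1.0 - sat / sat0)
    v[t < protocol.pre_switch] = 1.0
    return v


def generate_uncaging_set(
    buffer: BufferSystem,
    n_cells: int = 10,
    seed: int = 0,
    protocol: UncagingProtocol | None = None,
    noise: NoiseModel | None = None,
    length_jitter: float = 0.1,
):
    """Uncaging experiments with per-cell geometry jitter.

    Returns ``(list of UncagingExperiment, metadata)``.
    """
    if protocol is None:
        protocol = UncagingProtocol()
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_cells):
        L = protocol.cell_length * (1.0 + length_jitter * rng.uniform(-1, 1))
        p = UncagingProtocol(
            cell_length=L, uncage_fraction=protocol.uncage_fraction,
            source_strength=protocol.source_strength,
            frame_interval=protocol.frame_interval,
            n_source_frames=protocol.n_source_frames,
            duration=protocol.duration, ph_start=protocol.ph_start,
        )
        exp = simulate_uncaging(buffer, p)
        ph = noise.apply(exp.roi_ph, rng)
        out.append(UncagingExperiment(
            time=exp.time, roi_ph=ph, protocol=p, buffer=buffer,
            acid_roi=exp.acid_roi,
        ))
    meta = {"generator": "generate_uncaging_set", "n_cells": n_cells,
            "seed": seed, "buffer": asdict(buffer),
            "protocol": asdict(protocol), "noise": asdict(noise),
            "length_jitter": length_jitter}
    return out, meta


#: equilibrium MCV pairs of the glycerol protocol (fL): published values
GLYCEROL_VOLUMES = {
    "isotonic": {"sucrose": 79.0, "glycerol": 86.0},   # 140 mM NaCl
    "hypotonic": {"sucrose": 123.0, "glycerol": 148.0},  # 65 mM NaCl
}

#: generating transport coefficients per tonicity; magnitudes are
#: package assumptions, the hypotonic > isotonic ordering reflects the
#: stretch-activation of membrane transport seen in all three assays
ASSAY_COEFFICIENTS = {
    "isotonic": {"glycerol": 0.15, "acetic": 0.35, "ae1": 3.0},
    "hypotonic": {"glycerol": 0.24, "acetic": 0.45, "ae1": 4.5},
}


def generate_assay_traces(
    assay: str,
    true_coefficient: float,
    geometry: CellGeometry,
    noise: NoiseModel | None = None,
    seed: int = 0,
    duration: float = 30.0,
    dt: float = DEFAULT_DT,
    tonicity: str = "isotonic",
    acetate_out: float = 10.0,
    buffering: float = 50.0,
    delta_pho: float = 0.6,
    ph_start: float = 7.3,
    ae1_relax_tau: float = 20.0,
):
    """Forward ODE trace for one membrane assay with a known coefficient.

    * glycerol — ``true_coefficient`` is the volume relaxation rate k
      (s^-1); the trace relaxes between the preset equilibrium volumes of
      the chosen ``tonicity``.
    * acetic — ``true_coefficient`` is P*SA/MCV (s^-1); the pH declines by
      ``acetate_out/buffering`` with time constant 1/k.
    * ae1 — ``true_coefficient`` is the activity coefficient (mM s^-1 per
      pH unit); initial slope = coeff * delta_pho / buffering, relaxing
      with ``ae1_relax_tau``.

    Returns ``(RatioTrace, metadata)``.
    """
    if true_coefficient < 0:
        raise DomainError("true_coefficient must be nonnegative")
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    if assay == "glycerol":
        vols = GLYCEROL_VOLUMES[tonicity]
        v0, veq = vols["sucrose"], vols["glycerol"]
        v = veq + (v0 - veq) * np.exp(-true_coefficient * t)
    elif assay == "acetic":
        dph = acetate_out / buffering
        v = ph_start - dph * (1.0 - np.exp(-true_coefficient * t))
    elif assay == "ae1":
        slope0 = true_coefficient * delta_pho / buffering
        v = ph_start - slope0 * ae1_relax_tau * (
            1.0 - np.exp(-t / ae1_relax_tau)
        )
    else:
        raise DomainError(
            f"unknown assay {assay!r}; expected glycerol, acetic or ae1"
        )
    trace = RatioTrace(t, noise.apply(v, rng), cell_id=f"{assay}_synth")
    meta = {"generator": "generate_assay_traces", "assay": assay,
            "true_coefficient": true_coefficient, "seed": seed,
            "tonicity": tonicity, "acetate_out": acetate_out,
            "buffering": buffering, "delta_pho": delta_pho,
            "noise": asdict(noise), "geometry": asdict(geometry)}
    return trace, meta


def sample_t95(preset: ConditionPreset | str, n: int, seed: int = 0):
    """Corrected-T95 draws (s) from a condition preset's mixture."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    rng = np.random.default_rng(seed)
    return _sample_mixture(rng, preset.t95_components, n)


def write_two_channel_stack(
    traces, tiff_path, mask_path, frame_shape=(64, 64), radius: int = 4,
    seed: int = 0,
):
    """Optional TIFF emission: a two-channel time-lapse plus a mask image.

    Cells are disks on a grid; channel 0 (green) is constant, channel 1
    (deep red) carries the trace, so red/green recovers the ratio.  Mask
    pixel value i+1 labels cell i.
    """
    import tifffile

    rng = np.random.default_rng(seed)
    n = len(traces)
    ny, nx = frame_shape
    per_row = max(1, nx // (3 * radius))
    mask = np.zeros(frame_shape, dtype=np.uint16)
    centers = []
    for i in range(n):
        cy = radius + 1 + 3 * radius * (i // per_row)
        cx = radius + 1 + 3 * radius * (i % per_row)
        if cy + radius >= ny or cx + radius >= nx:
            raise DomainError("too many cells for the frame size")
        yy, xx = np.ogrid[:ny, :nx]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        mask[disk] = i + 1
        centers.append((cy, cx))
    n_frames = min(len(tr.values) for tr in traces)
    stack = np.zeros((n_frames, 2, ny, nx), dtype=np.float32)
    stack[:, 0] = 1000.0
    for i, tr in enumerate(traces):
        disk = mask == i + 1
        for f in range(n_frames):
            stack[f, 1][disk] = 1000.0 * tr.values[f]
    tifffile.imwrite(tiff_path, stack)
    tifffile.imwrite(mask_path, mask)
    return {"n_cells": n, "n_frames": n_frames, "frame_shape": frame_shape,
            "centers": centers, "seed": seed}
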