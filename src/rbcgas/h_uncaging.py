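"""Facilitated H+ diffusion in RBC cytoplasm and CO2 diffusivity.

Free H+ ions cannot diffuse measurable distances in the heavily buffered
cytoplasm of a red cell; acid spreads aboard mobile buffers (hemoglobin
and, when present, CO2/HCO3-).  The apparent H+ diffusivity is therefore
the buffering-weighted mean of the carrier diffusivities,

    D_H_app = (beta_hb * D_hb + beta_co2 * D_c_CO2) / (beta_hb + beta_co2)

so pairing measurements with and without CO2/HCO3- isolates the
cytoplasmic CO2/HCO3- shuttle diffusivity D_c_CO2.

The photolytic-uncaging experiment is modeled as 1-D diffusion of the
buffered acid load along the cell (closed ends: AE1 blocked with DIDS, the
cell is a closed compartment for H+), with acid produced in the uncaging
region (first tenth of the cell) during alternating "source" frames of the
0.133-s imaging cadence.  The linear PDE is solved spectrally (cosine
modes, exact per-frame updates), and pH is read out in 10 equally spaced
ROIs.

Crowding by hemoglobin restricts all cytoplasmic diffusion; empirically
the CO2 diffusivity halves for every ~62 g/L rise in MCHC
(:func:`mchc_halving_law`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import (
    DomainError,
    PhysicallyInconsistentError,
    UnidentifiableError,
)

#: imaging cadence of the uncaging protocol (s)
FRAME_INTERVAL = 0.133

#: number of readout regions spanning the cell
N_ROI = 10

#: reference value of the cytoplasmic CO2/HCO3- diffusivity (um^2/s)
D_C_CO2_REF = 48.9

#: MCHC rise that halves cytoplasmic CO2 diffusivity (g/L)
MCHC_HALVING_G_PER_L = 62.0


@dataclass(frozen=True)
class BufferSystem:
    """Mobile-buffer composition of the cytoplasm.

    beta_* are buffering capacities (mM per pH unit); D_* the diffusivities
    (um^2/s) of the corresponding carrier.  ``beta_co2 = 0`` describes
    CO2/HCO3--free (Hepes) superfusion.
    """

    beta_hb: float = 50.0
    D_hb: float = 8.0
    beta_co2: float = 0.0
    D_c_CO2: float = D_C_CO2_REF

    def __post_init__(self):
        if self.beta_hb <= 0:
            raise DomainError("beta_hb must be positive")
        if self.beta_co2 < 0 or self.D_hb < 0 or self.D_c_CO2 < 0:
            raise DomainError("buffer parameters must be nonnegative")

    @property
    def beta_total(self) -> float:
        return self.beta_hb + self.beta_co2

    @property
    def d_h_app(self) -> float:
        """Buffering-weighted mean carrier diffusivity (um^2/s)."""
        return (self.beta_hb * self.D_hb + self.beta_co2 * self.D_c_CO2) \
            / self.beta_total


@dataclass(frozen=True)
class UncagingProtocol:
    """Timing/geometry of one uncaging run."""

    cell_length: float = 8.0          # um
    uncage_fraction: float = 0.1      # source region = first tenth
    source_strength: float = 8.0      # mM/s of acid during source frames
    frame_interval: float = FRAME_INTERVAL
    n_source_frames: int = 8          # alternating frames 0,2,4,... uncage
    duration: float = 6.0             # s
    ph_start: float = 7.8             # alkaline-offset starting pH_i

    def __post_init__(self):
        if not (0 < self.uncage_fraction < 1):
            raise DomainError("uncage_fraction must be in (0, 1)")
        if self.frame_interval <= 0 or self.cell_length <= 0:
            raise DomainError("frame_interval and cell_length must be positive")
        if self.duration < 3 * self.frame_interval:
            raise DomainError("duration must cover several frame intervals")

    def source_on(self, frame: int) -> bool:
        """Alternating uncage/read cadence during the uncaging phase."""
        return frame < self.n_source_frames and frame % 2 == 0


@dataclass(frozen=True)
class UncagingExperiment:
    """Simulated or measured 10-ROI pH time course plus its metadata."""

    time: np.ndarray                  # frame times (s)
    roi_ph: np.ndarray                # shape (n_frames, N_ROI)
    protocol: UncagingProtocol
    buffer: BufferSystem
    acid_roi: np.ndarray = field(repr=False, default=None)  # mM, per ROI
    D_H_app: float | None = None      # filled by fit_dh_app


def _mode_matrices(protocol: UncagingProtocol, n_modes: int):
    """Source projections and ROI-averaging weights for cosine modes."""
    L = protocol.cell_length
    w = protocol.uncage_fraction * L
    k = np.arange(n_modes)
    kpi = k * np.pi / L
    # projection of a unit-strength source on [0, w] onto cos(k pi x / L)
    s = np.empty(n_modes)
    s[0] = w / L
    s[1:] = 2.0 / (k[1:] * np.pi) * np.sin(kpi[1:] * w)
    # ROI averages of each mode over 10 equal segments
    edges = np.linspace(0.0, L, N_ROI + 1)
    A = np.empty((N_ROI, n_modes))
    A[:, 0] = 1.0
    for r in range(N_ROI):
        x1, x2 = edges[r], edges[r + 1]
        A[r, 1:] = (np.sin(kpi[1:] * x2) - np.sin(kpi[1:] * x1)) \
            / (kpi[1:] * (x2 - x1))
    return s, A


def _acid_frames(d_app: float, protocol: UncagingProtocol, n_modes: int = 64):
    """Cosine-mode amplitudes of the acid load at each frame time."""
    L = protocol.cell_length
    lam = d_app * (np.arange(n_modes) * np.pi / L) ** 2
    s, A = _mode_matrices(protocol, n_modes)
    n_frames = int(np.floor(protocol.duration / protocol.frame_interval)) + 1
    dt = protocol.frame_interval
    a = np.zeros(n_modes)
    out = np.empty((n_frames, N_ROI))
    out[0] = A @ a
    decay = np.exp(-lam * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(lam > 0, (1.0 - decay) / lam, dt)
    for f in range(1, n_frames):
        a = a * decay
        if protocol.source_on(f - 1):
            a = a + protocol.source_strength * s * gain
        out[f] = A @ a
    t = np.arange(n_frames) * dt
    return t, out


def simulate_uncaging(
    buffer: BufferSystem,
    protocol: UncagingProtocol | None = None,
    n_modes: int = 64,
) -> UncagingExperiment:
    """Forward model of one uncaging run.

    Acid produced in the uncaging region spreads with the apparent
    diffusivity of the buffer system; ends are zero-flux (closed cell), so
    total acid is conserved between source pulses.  pH in each ROI is
    ``ph_start - acid / beta_total``.
    """
    if buffer.beta_total <= 0:
        raise DomainError("total buffering capacity must be positive")
    if protocol is None:
        protocol = UncagingProtocol()
    t, acid = _acid_frames(buffer.d_h_app, protocol, n_modes)
    ph = protocol.ph_start - acid / buffer.beta_total
    return UncagingExperiment(time=t, roi_ph=ph, protocol=protocol,
                              buffer=buffer, acid_roi=acid)


def fit_dh_app(
    exp: UncagingExperiment,
    bounds: tuple[float, float] = (0.05, 500.0),
) -> float:
    """Fit the apparent H+ diffusivity to all ROI traces simultaneously.

    Global least squares of the forward model over D_H_app (scalar,
    bounded Brent search; deterministic).  Raises
    :class:`UnidentifiableError` when the traces carry no spatial gradient.
    """
    ph = np.asarray(exp.roi_ph)
    if ph.shape[1] < 3:
        raise UnidentifiableError("need >= 3 ROIs with a resolvable gradient")
    spread = np.max(np.ptp(ph, axis=1))
    noise = np.std(np.diff(ph, n=2, axis=0)) if ph.shape[0] > 2 else 0.0
    if spread < max(3.0 * noise, 1e-9):
        raise UnidentifiableError(
            "no spatial pH gradient across ROIs; D_H_app is unidentifiable"
        )

    beta = exp.buffer.beta_total
    target_acid = (exp.protocol.ph_start - ph) * beta

    def sse(d):
        _, acid = _acid_frames(d, exp.protocol)
        n = min(len(acid), len(target_acid))
        return float(np.sum((acid[:n] - target_acid[:n]) ** 2))

    res = minimize_scalar(sse, bounds=bounds, method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def derive_dc_co2(
    dh_without: float, dh_with: float, buffer: BufferSystem
) -> float:
    """Invert the buffering-weighted mean for the CO2/HCO3- diffusivity.

    ``dh_without`` (Hepes condition, beta_co2 = 0) identifies D_hb;
    ``dh_with`` is measured with CO2/HCO3- present, whose buffering
    capacity is ``buffer.beta_co2``.
    """
    if buffer.beta_co2 <= 0:
        raise DomainError(
            "beta_co2 must be positive in the with-CO2 condition"
        )
    d = (dh_with * (buffer.beta_hb + buffer.beta_co2)
         - dh_without * buffer.beta_hb) / buffer.beta_co2
    if d < 0:
        raise PhysicallyInconsistentError(
            f"derived D_c_CO2 = {d:.3g} um^2/s is negative: the with-CO2 "
            "D_H_app is too low relative to the Hepes condition"
        )
    return float(d)


def mchc_halving_law(
    d_ref: float = D_C_CO2_REF,
    mchc_ref: float = 330.0,
    halving: float = MCHC_HALVING_G_PER_L,
):
    """Exponential crowding law: D(mchc) = d_ref * 2^(-(mchc-mchc_ref)/halving).

    Returns a vectorized callable mapping MCHC (g/L) to diffusivity.
    """
    if halving <= 0 or d_ref <= 0:
        raise DomainError("d_ref and halving must be positive")

    def law(mchc):
        return d_ref * 2.0 ** (-(np.asarray(mchc, dtype=float) - mchc_ref)
                               / halving)

    law.d_ref = d_ref
    law.mchc_ref = mchc_ref
    law.halving = halving
    return law


def fit_halving(mchc, d, mchc_ref: float = 330.0):
    """Log-linear least-squares fit of the halving law.

    Returns ``(d_ref, halving)`` such that
    ``D = d_ref * 2^(-(mchc - mchc_ref)/halving)``.
    """
    mchc = np.asarray(mchc, dtype=float)
    d = np.asarray(d, dtype=float)
    if mchc.size < 3:
        raise DomainError("need >= 3 points to fit the halving law")
    if np.any(d <= 0):
        raise DomainError("diffusivities must be positive")
    slope, intercept = np.polyfit(mchc - mchc_ref, np.log2(d), 1)
    if slope >= 0:
        raise PhysicallyInconsistentError(
            "diffusivity does not decrease with MCHC; halving constant "
            "undefined"
        )
    return float(2.0 ** intercept), float(-1.0 / slope)
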