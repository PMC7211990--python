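"""1-D slab reaction-diffusion model of O2 unloading from a red blood cell.

The cell is treated as a slab of cytoplasm normal to the coverslip.  Free
O2 diffuses with an effective diffusivity that lumps cytoplasmic diffusion
and membrane permeation,

    1 / D_eff = 1 / D_c + 1 / (h * P_m)

where ``h`` is the mean diffusion distance (half-thickness of the cell)
and ``P_m`` the membrane O2 permeability.  Dissolved O2 reacts with
hemoglobin according to the four-step cooperative scheme of
:mod:`rbcgas.hb_kinetics`; hemoglobin is immobile.  A dithionite-containing
superfusate is an effective zero-O2 Dirichlet boundary.

Geometry modes
--------------
``one_sided``  (the experiment: cell attached to the coverslip) — sink at
the solution-facing surface, zero flux at the coverslip face, domain
length ``h``.

``two_sided``  (in vivo: both faces exchange) — halves the diffusion
pathlength; by symmetry solved on a half-domain of length ``h/2`` with the
sink at the face and zero flux at the midplane.  In the diffusion-limited
regime this gives a fourfold shorter time constant (Fick scaling).

``closed``     — zero flux everywhere (conservation checks).

Discretization: cell-centered finite volumes, method of lines, implicit
BDF integration with an analytic sparsity pattern.  The time constant
tau_O2 of a simulated trace is extracted with the same monoexponential
fitter used for experimental traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import DomainError, InfeasibleTarget, SolverFailure
from .hb_kinetics import HbO2Scheme
from .trace_kinetics import RatioTrace, fit_monoexponential

#: default RBC half-thickness (um): mean diffusion distance of the
#: attached-cell (one-sided) exchange geometry
DEFAULT_H_UM = 0.885

#: conditions of the single-cell unloading experiment: 23 C superfusate
#: equilibrated with room air (O2 solubility in water at 23 C is
#: ~1.6 uM/mmHg; air-saturated pO2 ~150 mmHg)
EXPERIMENT_23C = {"solubility": 1.6, "initial_pO2": 150.0}


def effective_diffusivity(D_c_O2: float, P_m_O2: float, h: float) -> float:
    """Compose cytoplasmic diffusion and membrane permeation (harmonic sum).

    ``P_m_O2`` may be ``inf`` (no membrane resistance).
    """
    if not (D_c_O2 > 0 and P_m_O2 > 0 and h > 0):
        raise DomainError("D_c_O2, P_m_O2 and h must all be positive")
    if math.isinf(P_m_O2):
        return float(D_c_O2)
    return 1.0 / (1.0 / D_c_O2 + 1.0 / (h * P_m_O2))


@dataclass(frozen=True)
class DiffusionBarrier:
    """Series barrier to O2 exit: cytoplasm + membrane, lumped by Eq. above."""

    D_c_O2: float          # um^2/s
    P_m_O2: float = math.inf  # um/s
    h: float = DEFAULT_H_UM   # um

    def __post_init__(self):
        if not (self.h > 0 and self.D_c_O2 > 0 and self.P_m_O2 > 0):
            raise DomainError("h, D_c_O2 and P_m_O2 must be positive")

    @property
    def D_eff_O2(self) -> float:
        return effective_diffusivity(self.D_c_O2, self.P_m_O2, self.h)

    @classmethod
    def from_deff(cls, D_eff: float, h: float = DEFAULT_H_UM) -> "DiffusionBarrier":
        """Barrier with all resistance assigned to cytoplasm (P_m infinite)."""
        return cls(D_c_O2=D_eff, P_m_O2=math.inf, h=h)


@dataclass(frozen=True)
class UnloadingSimConfig:
    barrier: DiffusionBarrier
    scheme: HbO2Scheme
    grid_points: int = 64
    duration: float = 6.0
    boundary_mode: str = "one_sided"   # one_sided | two_sided | closed
    boundary_pO2: float = 0.0
    initial_pO2: float = 100.0
    explicit_membrane: bool = False
    n_report: int = 300

    def __post_init__(self):
        if self.grid_points < 20:
            raise DomainError("grid_points must be >= 20")
        if self.duration <= 0:
            raise DomainError("duration must be positive")
        if self.boundary_pO2 < 0 or self.initial_pO2 < 0:
            raise DomainError("pO2 values must be nonnegative")
        if self.boundary_mode not in ("one_sided", "two_sided", "closed"):
            raise DomainError(
                f"unknown boundary_mode {self.boundary_mode!r}; "
                "expected one_sided, two_sided or closed"
            )
        if self.explicit_membrane and math.isinf(self.barrier.P_m_O2):
            raise DomainError("explicit_membrane requires a finite P_m_O2")


@dataclass(frozen=True)
class SimResult:
    """Saturation trace plus fields for conservation/profile checks."""

    trace: RatioTrace
    total_o2: np.ndarray = field(repr=False)  # volume-avg free+bound O2 (uM)
    free_profile: np.ndarray = field(repr=False, default=None)  # (t, x) uM
    config: UnloadingSimConfig = field(repr=False, default=None)


def _sparsity(n: int) -> sparse.csr_matrix:
    """Jacobian sparsity of the block state [c, f1, f2, f3, f4]."""
    S = sparse.lil_matrix((5 * n, 5 * n), dtype=np.int8)
    idx = np.arange(n)
    # diffusion tridiagonal in c
    S[idx, idx] = 1
    S[idx[:-1], idx[:-1] + 1] = 1
    S[idx[1:], idx[1:] - 1] = 1
    # reaction couples c and all f at the same node
    for b1 in range(5):
        for b2 in range(5):
            S[b1 * n + idx, b2 * n + idx] = 1
    return S.tocsr()


def simulate_unloading(
    config: UnloadingSimConfig, check_convergence: bool = True
) -> SimResult:
    """Integrate the coupled diffusion-reaction system; return the
    volume-averaged bound-saturation time course.

    With an anoxic boundary the saturation is monotonically nonincreasing.
    ``check_convergence=True`` re-runs at double resolution and raises
    :class:`SolverFailure` if the fitted time constant moves by >= 1%.
    """
    res = _simulate(config)
    if check_convergence:
        fine = _simulate(replace(config, grid_points=2 * config.grid_points))
        if config.boundary_mode != "closed":
            tau_c = fit_monoexponential(res.trace, fit_window=(0, config.duration)).tau
            tau_f = fit_monoexponential(fine.trace, fit_window=(0, config.duration)).tau
            if abs(tau_c - tau_f) / tau_f >= 0.01:
                raise SolverFailure(
                    "spatial discretization not converged: doubling the grid "
                    f"moved tau from {tau_c:.4g} to {tau_f:.4g} s",
                    diagnostics={"tau_coarse": tau_c, "tau_fine": tau_f,
                                 "grid_points": config.grid_points},
                )
    return res


def _simulate(config: UnloadingSimConfig) -> SimResult:
    sch = config.scheme
    bar = config.barrier
    n = config.grid_points

    L = bar.h / 2.0 if config.boundary_mode == "two_sided" else bar.h
    dx = L / n
    if config.explicit_membrane:
        D = bar.D_c_O2
        p_m = bar.P_m_O2
    else:
        D = bar.D_eff_O2
        p_m = math.inf

    tet_total = sch.heme_total * 1000.0 / 4.0  # uM tetramer
    koff = sch.k_off_site                       # per-site, steps 1..4
    kon = sch.k_on                              # per-site uM^-1 s^-1
    stat_off = np.arange(1, 5) * koff           # j * k_off_j
    stat_on = (5 - np.arange(1, 5)) * kon       # (5-j) * k_on_j

    c_b = sch.solubility * config.boundary_pO2
    occ0 = sch.equilibrium_occupancies(config.initial_pO2)
    y0 = np.empty(5 * n)
    y0[:n] = sch.solubility * config.initial_pO2
    for j in range(1, 5):
        y0[j * n:(j + 1) * n] = occ0[j] * tet_total

    sink = config.boundary_mode in ("one_sided", "two_sided")
    inv_dx2 = 1.0 / dx**2
    # Dirichlet via half-cell flux, or Robin flux for an explicit membrane
    if sink:
        bnd_coeff = (p_m / dx) if config.explicit_membrane else (2.0 * D * inv_dx2)

    def rhs(_t, y):
        c = y[:n]
        f = y[n:].reshape(4, n)
        f0 = tet_total - f.sum(axis=0)
        dc = np.empty(n)
        dc[1:-1] = D * (c[2:] - 2 * c[1:-1] + c[:-2]) * inv_dx2
        dc[0] = D * (c[1] - c[0]) * inv_dx2
        dc[-1] = D * (c[-2] - c[-1]) * inv_dx2
        if sink:
            dc[0] += bnd_coeff * (c_b - c[0])
        # sequential binding: step j is f_{j-1} + O2 <-> f_j
        prev = np.vstack([f0, f[:-1]])
        bind = stat_on[:, None] * c[None, :] * prev
        diss = stat_off[:, None] * f
        df = bind - diss
        # net change of state j: gain from step j, loss to step j+1
        dfdt = df.copy()
        dfdt[:-1] -= df[1:]
        dc += (diss - bind).sum(axis=0)
        return np.concatenate([dc, dfdt.ravel()])

    t_eval = np.linspace(0.0, config.duration, config.n_report)
    sol = solve_ivp(
        rhs, (0.0, config.duration), y0, method="BDF", t_eval=t_eval,
        jac_sparsity=_sparsity(n), rtol=1e-6, atol=1e-6,
    )
    if not sol.success:
        raise SolverFailure(
            f"BDF integration failed: {sol.message}",
            diagnostics={"nfev": sol.nfev, "status": sol.status},
        )
    c = sol.y[:n]
    f = sol.y[n:].reshape(4, n, -1)
    bound = (np.arange(1, 5)[:, None, None] * f).sum(axis=0)  # uM O2
    sat = bound.mean(axis=0) / (4.0 * tet_total)
    total = c.mean(axis=0) + bound.mean(axis=0)
    trace = RatioTrace(sol.t, sat, cell_id="sim")
    return SimResult(trace=trace, total_o2=total, free_profile=c.T,
                     config=config)


def unloading_tau(
    config: UnloadingSimConfig, check_convergence: bool = False
) -> float:
    """Simulate and extract tau_O2 with the shared monoexponential fitter."""
    res = simulate_unloading(config, check_convergence=check_convergence)
    fit = fit_monoexponential(res.trace, fit_window=(0.0, config.duration))
    if not fit.converged:
        raise SolverFailure("tau fit on simulated trace did not converge")
    return fit.tau


def reaction_limited_tau(scheme: HbO2Scheme, **sim_kwargs) -> float:
    """Floor of tau_O2: unloading time constant with no diffusion limit.

    Simulated at a very large diffusivity, where free O2 clears instantly
    and the rate is set purely by Hb-O2 dissociation.
    """
    barrier = DiffusionBarrier.from_deff(1e6, h=sim_kwargs.pop("h", DEFAULT_H_UM))
    kens = 4.0 / float(np.sum(1.0 / scheme.k_off_site))
    cfg = UnloadingSimConfig(
        barrier=barrier, scheme=scheme, duration=8.0 / kens, **sim_kwargs
    )
    return unloading_tau(cfg)


def fit_deff_for_tau(
    tau_target: float,
    scheme: HbO2Scheme,
    h: float = DEFAULT_H_UM,
    boundary_mode: str = "one_sided",
    initial_pO2: float = 100.0,
    grid_points: int = 64,
    rtol: float = 1e-3,
) -> float:
    """Invert the model: find D_eff such that the simulated tau_O2 equals
    ``tau_target`` (monotone bracketed root-find, relative tol ``rtol``).

    Raises :class:`InfeasibleTarget` (naming the floor) if ``tau_target``
    is at or below the reaction-limited minimum.
    """
    if tau_target <= 0:
        raise DomainError("tau_target must be positive")
    floor = reaction_limited_tau(scheme, h=h, boundary_mode=boundary_mode,
                                 initial_pO2=initial_pO2)
    if tau_target <= floor * 1.02:
        raise InfeasibleTarget(
            f"tau_target {tau_target:.4g} s is at/below the reaction-limited "
            f"floor {floor:.4g} s for this scheme", floor=floor,
        )

    duration = 6.0 * tau_target

    def tau_of(log10_d: float) -> float:
        cfg = UnloadingSimConfig(
            barrier=DiffusionBarrier.from_deff(10.0 ** log10_d, h=h),
            scheme=scheme, duration=duration, boundary_mode=boundary_mode,
            initial_pO2=initial_pO2, grid_points=grid_points,
        )
        return unloading_tau(cfg)

    lo, hi = -2.0, 5.0
    f_lo = tau_of(lo) - tau_target   # slow diffusion -> tau large -> positive
    f_hi = tau_of(hi) - tau_target
    if f_lo < 0 or f_hi > 0:
        raise InfeasibleTarget(
            f"tau_target {tau_target:.4g} s outside bracketed range "
            f"[{tau_of(hi):.4g}, {tau_of(lo):.4g}] s", floor=floor,
        )
    log_d = brentq(lambda ld: tau_of(ld) - tau_target, lo, hi,
                   xtol=rtol / 3.0, rtol=1e-12)
    d_eff = 10.0 ** log_d
    # verify spatial convergence at the solution
    cfg = UnloadingSimConfig(
        barrier=DiffusionBarrier.from_deff(d_eff, h=h), scheme=scheme,
        duration=duration, boundary_mode=boundary_mode,
        initial_pO2=initial_pO2, grid_points=grid_points,
    )
    simulate_unloading(cfg, check_convergence=True)
    return d_eff


def tradeoff_curve(
    tau_target: float,
    kd_grid,
    h: float = DEFAULT_H_UM,
    scheme_factory=None,
    **fit_kwargs,
):
    """(k_d, D_eff) pairs fitting ``tau_target`` across ensemble k_d values.

    Faster reaction shifts the limitation to diffusion, so D_eff is
    nonincreasing along the curve.  Infeasible grid points are recorded
    (D_eff = nan) rather than fatal.  ``scheme_factory(kd)`` defaults to
    :func:`rbcgas.hb_kinetics.scheme_for_kd` (kd = first-step dissociation
    rate of the cooperative scheme).
    """
    kd_grid = list(kd_grid)
    if not kd_grid or any(b <= a for a, b in zip(kd_grid, kd_grid[1:])):
        raise DomainError("kd_grid must be nonempty and strictly increasing")
    if scheme_factory is None:
        from .hb_kinetics import scheme_for_kd
        scheme_factory = scheme_for_kd
    rows = []
    for kd in kd_grid:
        try:
            deff = fit_deff_for_tau(tau_target, scheme_factory(kd), h=h,
                                    **fit_kwargs)
            rows.append({"k_d": kd, "D_eff": deff, "status": "ok"})
        except InfeasibleTarget as exc:
            rows.append({"k_d": kd, "D_eff": float("nan"),
                         "status": f"infeasible: {exc}"})
    return rows
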