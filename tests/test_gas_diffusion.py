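"""Slab reaction-diffusion solver: oracles, scalings and inversion."""

import math
from dataclasses import replace

import numpy as np
import pytest

from rbcgas import gas_diffusion as gd
from rbcgas import hb_kinetics as hk
from rbcgas.errors import DomainError, InfeasibleTarget
from rbcgas.trace_kinetics import convolve_switch, fit_monoexponential


def tau_of(result, duration):
    return fit_monoexponential(result.trace, fit_window=(0.0, duration)).tau


class TestEffectiveDiffusivity:
    def test_no_membrane_resistance(self):
        assert gd.effective_diffusivity(100.0, math.inf, 0.885) == 100.0

    def test_harmonic_symmetry(self):
        # P_m*h == D_c gives exactly half
        assert gd.effective_diffusivity(140.0, 140.0 / 0.885, 0.885) \
            == pytest.approx(70.0)

    def test_unhindered_cytoplasm_needs_slow_membrane(self):
        """If cytoplasm were as permissive as free solution (2500 um^2/s),
        an effective diffusivity of ~70 um^2/s pins the membrane near
        80 um/s."""
        assert gd.effective_diffusivity(2500.0, 81.4, 0.885) \
            == pytest.approx(70.0, rel=0.01)

    def test_domain_errors(self):
        for args in [(0.0, 10.0, 1.0), (10.0, -1.0, 1.0), (10.0, 10.0, 0.0)]:
            with pytest.raises(DomainError):
                gd.effective_diffusivity(*args)

    def test_barrier_invariants(self):
        b = gd.DiffusionBarrier(D_c_O2=140.0, P_m_O2=100.0, h=0.885)
        assert b.D_eff_O2 <= b.D_c_O2
        assert b.D_eff_O2 <= b.h * b.P_m_O2


class TestSimulateUnloading:
    def test_closed_box_conserves_o2(self, plain_scheme):
        cfg = gd.UnloadingSimConfig(
            barrier=gd.DiffusionBarrier.from_deff(70.0), scheme=plain_scheme,
            duration=2.0, boundary_mode="closed",
        )
        res = gd.simulate_unloading(cfg, check_convergence=False)
        assert np.ptp(res.total_o2) / res.total_o2[0] < 1e-6

    def test_saturation_monotone_with_anoxic_boundary(self, plain_scheme):
        cfg = gd.UnloadingSimConfig(
            barrier=gd.DiffusionBarrier.from_deff(70.0), scheme=plain_scheme,
            duration=6.0,
        )
        res = gd.simulate_unloading(cfg, check_convergence=False)
        assert np.all(np.diff(res.trace.values) <= 1e-9)

    def test_well_mixed_limit_matches_relaxation_ode(self, plain_scheme):
        """At huge diffusivity the slab reduces to the well-mixed
        dissociation cascade."""
        cfg = gd.UnloadingSimConfig(
            barrier=gd.DiffusionBarrier.from_deff(1e6), scheme=plain_scheme,
            duration=0.4, n_report=200,
        )
        res = gd.simulate_unloading(cfg, check_convergence=False)
        occ0 = plain_scheme.equilibrium_occupancies(cfg.initial_pO2)
        t_ode, sat_ode = hk.simulate_relaxation(
            plain_scheme, duration=0.4, n_times=200,
            initial_occupancies=occ0,
        )
        ref = np.interp(res.trace.time, t_ode, sat_ode)
        assert np.max(np.abs(res.trace.values - ref)) < 0.01

    def test_pure_diffusion_matches_fourier_series(self):
        """With reaction disabled the profile follows the analytic slab
        solution (sink at x=0, sealed at x=L, uniform start)."""
        scheme = hk.build_scheme(20.0, 20.0, mchc=1e-6)  # no Hb to bind
        L, D, c0_po2 = 0.885, 70.0, 100.0
        cfg = gd.UnloadingSimConfig(
            barrier=gd.DiffusionBarrier.from_deff(D, h=L), scheme=scheme,
            duration=0.004, grid_points=256, n_report=12, initial_pO2=c0_po2,
        )
        res = gd._simulate(cfg)
        n = cfg.grid_points
        x = (np.arange(n) + 0.5) * L / n
        c0 = scheme.solubility * c0_po2
        t = 0.004
        series = np.zeros_like(x)
        for k in range(200):
            lam = (2 * k + 1) * math.pi / (2 * L)
            series += (4.0 / ((2 * k + 1) * math.pi)) * np.sin(lam * x) \
                * math.exp(-D * lam**2 * t)
        # reconstruct the free-O2 profile at the final time
        c_num = res.free_profile[-1]
        assert np.max(np.abs(c_num - c0 * series)) < 1e-4 * c0

    def test_config_validation(self, plain_scheme):
        barrier = gd.DiffusionBarrier.from_deff(70.0)
        with pytest.raises(DomainError):
            gd.UnloadingSimConfig(barrier=barrier, scheme=plain_scheme,
                                  grid_points=10)
        with pytest.raises(DomainError):
            gd.UnloadingSimConfig(barrier=barrier, scheme=plain_scheme,
                                  boundary_mode="sideways")
        with pytest.raises(DomainError):
            gd.UnloadingSimConfig(barrier=barrier, scheme=plain_scheme,
                                  explicit_membrane=True)


class TestGeometryScalings:
    def test_fick_h_squared(self, fast_scheme):
        """Diffusion-limited: doubling the pathlength quadruples tau."""
        base = gd.UnloadingSimConfig(
            barrier=gd.DiffusionBarrier.from_deff(64.5), scheme=fast_scheme,
            duration=5.0, initial_pO2=150.0,
        )
        tau1 = gd.unloading_tau(base)
        big = replace(base, barrier=gd.DiffusionBarrier.from_deff(
            64.5, h=2 * gd.DEFAULT_H_UM), duration=20.0)
        tau2 = gd.unloading_tau(big)
        assert tau2 / tau1 == pytest.approx(4.0, rel=0.05)

    def test_two_sided_is_fourfold_faster(self, fast_scheme):
        """Opening both faces halves the pathlength: tau drops ~4x."""
        base = gd.UnloadingSimConfig(
            barrier=gd.DiffusionBarrier.from_deff(64.5), scheme=fast_scheme,
            duration=5.0, initial_pO2=150.0,
        )
        tau1 = gd.unloading_tau(base)
        tau2 = gd.unloading_tau(replace(base, boundary_mode="two_sided",
                                        duration=1.5))
        assert tau1 / tau2 == pytest.approx(4.0, rel=0.10)

    def test_explicit_membrane_agrees_with_lumped(self, plain_scheme):
        """A Robin membrane boundary with P_m matches folding the membrane
        into D_eff within 5% at the default (cytoplasm-dominated)
        parameterization, where the membrane is a minor series resistance
        (P_m ~2000 um/s vs the ~80 um/s that would be needed for the
        membrane to matter)."""
        D_c, P_m, h = 70.0, 2000.0, 0.885
        lumped = gd.UnloadingSimConfig(
            barrier=gd.DiffusionBarrier(D_c_O2=gd.effective_diffusivity(
                D_c, P_m, h), h=h),
            scheme=plain_scheme, duration=6.0,
        )
        explicit = gd.UnloadingSimConfig(
            barrier=gd.DiffusionBarrier(D_c_O2=D_c, P_m_O2=P_m, h=h),
            scheme=plain_scheme, duration=6.0, explicit_membrane=True,
        )
        t_l = gd.unloading_tau(lumped)
        t_e = gd.unloading_tau(explicit)
        assert t_e == pytest.approx(t_l, rel=0.05)

    def test_switch_convolution_negligible_on_simulated_trace(
        self, coop_scheme
    ):
        cfg = gd.UnloadingSimConfig(
            barrier=gd.DiffusionBarrier.from_deff(64.5), scheme=coop_scheme,
            duration=6.0, initial_pO2=150.0,
        )
        res = gd.simulate_unloading(cfg, check_convergence=False)
        tau_raw = fit_monoexponential(res.trace, fit_window=(0, 6)).tau
        conv = convolve_switch(res.trace, 0.023)
        tau_conv = fit_monoexponential(conv, fit_window=(0, 6)).tau
        assert abs(tau_conv - tau_raw) / tau_raw < 0.03


class TestInversion:
    def test_roundtrip_self_consistency(self, plain_scheme):
        """Simulate at the fitted D_eff, refit: tau within 0.5%."""
        target = 0.8
        d = gd.fit_deff_for_tau(target, plain_scheme)
        cfg = gd.UnloadingSimConfig(
            barrier=gd.DiffusionBarrier.from_deff(d), scheme=plain_scheme,
            duration=6.0 * target,
        )
        res = gd.simulate_unloading(cfg, check_convergence=False)
        tau = fit_monoexponential(res.trace, fit_window=(0, 6 * target)).tau
        assert tau == pytest.approx(target, rel=0.005)

    def test_tau_monotone_decreasing_in_deff(self, plain_scheme):
        taus = []
        for d in (30.0, 120.0):
            cfg = gd.UnloadingSimConfig(
                barrier=gd.DiffusionBarrier.from_deff(d),
                scheme=plain_scheme, duration=10.0,
            )
            taus.append(tau_of(gd.simulate_unloading(
                cfg, check_convergence=False), 10.0))
        assert taus[0] > taus[1]

    def test_infeasible_target_names_floor(self, plain_scheme):
        with pytest.raises(InfeasibleTarget) as exc:
            gd.fit_deff_for_tau(0.01, plain_scheme)
        assert exc.value.floor is not None and exc.value.floor > 0.01

    def test_single_point_tradeoff_matches_direct_fit(self):
        scheme = hk.scheme_for_kd(25.0, solubility=1.6)
        rows = gd.tradeoff_curve(
            0.971, [25.0 * 3.5], initial_pO2=150.0,
            scheme_factory=lambda kd: hk.scheme_for_kd(kd / 3.5,
                                                       solubility=1.6),
        )
        direct = gd.fit_deff_for_tau(0.971, scheme, initial_pO2=150.0)
        assert rows[0]["D_eff"] == pytest.approx(direct, rel=1e-3)

    def test_tradeoff_curve_nonincreasing(self):
        """Faster dissociation shifts the limit to diffusion: D_eff falls
        (within root-find noise) along the k_d axis."""
        rows = gd.tradeoff_curve(
            0.971, [20.0, 60.0, 100.0],
            scheme_factory=lambda kd: hk.scheme_for_kd(kd, solubility=1.6),
            initial_pO2=150.0,
        )
        deff = [r["D_eff"] for r in rows]
        assert all(np.isfinite(deff))
        for a, b in zip(deff, deff[1:]):
            assert b <= a * 1.01

    def test_tradeoff_grid_validation(self):
        with pytest.raises(DomainError):
            gd.tradeoff_curve(0.971, [])
        with pytest.raises(DomainError):
            gd.tradeoff_curve(0.971, [50.0, 30.0])
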