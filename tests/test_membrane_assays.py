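"""Membrane-assay estimators: arithmetic contracts and generator round trips."""

import numpy as np
import pytest

from rbcgas import membrane_assays as ma
from rbcgas import synthetic as sy
from rbcgas.errors import DomainError
from rbcgas.trace_kinetics import RatioTrace

GEOM = ma.CellGeometry(mcv=90.0, area=50.8, mchc=330.0)


class TestCellGeometry:
    def test_height_is_mcv_over_area(self):
        assert GEOM.height == pytest.approx(90.0 / 50.8)
        assert GEOM.half_thickness == pytest.approx(90.0 / 50.8 / 2.0)

    def test_positive_fields_required(self):
        with pytest.raises(DomainError):
            ma.CellGeometry(mcv=-1.0, area=50.0, mchc=330.0)


class TestGlycerol:
    def test_roundtrip(self):
        k_true = 0.15
        trace, _ = sy.generate_assay_traces("glycerol", k_true, GEOM)
        res = ma.fit_glycerol_permeability(trace, 100.0, GEOM)
        assert res.rate_constant == pytest.approx(k_true, rel=0.01)
        expected = k_true * (86.0 - 79.0) / 100.0
        assert res.scaled_estimate == pytest.approx(expected, rel=0.01)

    def test_zero_glycerol_flags_zero_flux(self):
        trace, _ = sy.generate_assay_traces("glycerol", 0.15, GEOM)
        res = ma.fit_glycerol_permeability(trace, 0.0, GEOM)
        assert res.zero_flux

    def test_preset_equilibrium_volumes(self):
        """Generator relaxes between the published equilibrium MCVs."""
        iso, _ = sy.generate_assay_traces("glycerol", 0.3, GEOM,
                                          tonicity="isotonic")
        assert iso.values[0] == pytest.approx(79.0, rel=1e-6)
        assert iso.values[-1] == pytest.approx(86.0, rel=1e-3)
        hyp, _ = sy.generate_assay_traces("glycerol", 0.3, GEOM,
                                          tonicity="hypotonic")
        assert hyp.values[0] == pytest.approx(123.0, rel=1e-6)
        assert hyp.values[-1] == pytest.approx(148.0, rel=1e-3)


class TestAcetic:
    def test_stated_ratio_arithmetic(self):
        """delta_pH 0.4, tau 2 s, buffering 50, acetate 65 ->
        0.4/2 * 50/65 = 0.1538 s^-1-scale."""
        t = np.arange(0.0, 20.0, 0.05)
        trace = RatioTrace(t, 7.3 - 0.4 * (1 - np.exp(-t / 2.0)))
        res = ma.fit_acetic_permeability(trace, 65.0, 50.0, GEOM)
        assert res.scaled_estimate == pytest.approx(0.15385, rel=0.01)

    def test_doubling_tau_halves_estimate(self):
        t = np.arange(0.0, 40.0, 0.05)
        fast = RatioTrace(t, 7.3 - 0.4 * (1 - np.exp(-t / 2.0)))
        slow = RatioTrace(t, 7.3 - 0.4 * (1 - np.exp(-t / 4.0)))
        rf = ma.fit_acetic_permeability(fast, 65.0, 50.0, GEOM)
        rs = ma.fit_acetic_permeability(slow, 65.0, 50.0, GEOM)
        assert rs.scaled_estimate == pytest.approx(rf.scaled_estimate / 2,
                                                   rel=0.01)

    def test_ode_generator_roundtrip(self):
        p_scaled = 0.35  # P * SA/MCV
        trace, meta = sy.generate_assay_traces("acetic", p_scaled, GEOM)
        res = ma.fit_acetic_permeability(trace, meta["acetate_out"],
                                         meta["buffering"], GEOM)
        assert res.scaled_estimate == pytest.approx(p_scaled, rel=0.02)

    def test_non_monotone_flagged(self):
        t = np.arange(0.0, 10.0, 0.05)
        v = 7.3 - 0.4 * (1 - np.exp(-t / 2.0)) + 0.3 * (t > 5.0)
        res = ma.fit_acetic_permeability(RatioTrace(t, v), 65.0, 50.0, GEOM)
        assert res.fit_quality == "non-monotone"


class TestAe1:
    def test_stated_initial_rate_arithmetic(self):
        """slope 0.05 pH/s, buffering 50, delta_pHo 0.6 -> 4.17 activity."""
        t = np.arange(0.0, 10.0, 0.05)
        trace = RatioTrace(t, 7.3 - 0.05 * t)
        res = ma.fit_ae1_activity(trace, 0.6, 50.0, GEOM)
        assert res.scaled_estimate / GEOM.surface_area \
            == pytest.approx(4.1667, rel=0.01)

    def test_zero_slope_zero_activity(self):
        t = np.arange(0.0, 10.0, 0.05)
        res = ma.fit_ae1_activity(RatioTrace(t, np.full(t.size, 7.3)),
                                  0.6, 50.0, GEOM)
        assert res.zero_flux

    def test_ode_generator_roundtrip(self):
        a_true = 3.0
        trace, meta = sy.generate_assay_traces("ae1", a_true, GEOM)
        res = ma.fit_ae1_activity(trace, meta["delta_pho"],
                                  meta["buffering"], GEOM)
        assert res.scaled_estimate / GEOM.surface_area \
            == pytest.approx(a_true, rel=0.02)

    def test_needs_early_samples(self):
        t = np.linspace(0.0, 10.0, 12)
        with pytest.raises(DomainError):
            ma.fit_ae1_activity(RatioTrace(t, 7.3 - 0.05 * t), 0.6, 50.0,
                                GEOM, n_initial=20)


class TestSharedProperties:
    @pytest.mark.parametrize("assay", ["glycerol", "acetic", "ae1"])
    def test_homogeneous_degree_one(self, assay):
        """Doubling the generating transport coefficient doubles the
        estimate (within 2%)."""
        coeffs = sy.ASSAY_COEFFICIENTS["isotonic"]
        est = []
        for mult in (1.0, 2.0):
            c = coeffs[assay] * mult
            trace, meta = sy.generate_assay_traces(assay, c, GEOM)
            if assay == "glycerol":
                r = ma.fit_glycerol_permeability(trace, 100.0, GEOM)
                est.append(r.rate_constant)
            elif assay == "acetic":
                r = ma.fit_acetic_permeability(trace, meta["acetate_out"],
                                               meta["buffering"], GEOM)
                est.append(r.scaled_estimate)
            else:
                r = ma.fit_ae1_activity(trace, meta["delta_pho"],
                                        meta["buffering"], GEOM)
                est.append(r.scaled_estimate)
        assert est[1] / est[0] == pytest.approx(2.0, rel=0.02)

    @pytest.mark.parametrize("assay", ["glycerol", "acetic", "ae1"])
    def test_hypotonic_exceeds_isotonic(self, assay):
        """Stretch activation: every estimator reads higher in swollen
        cells."""
        results = {}
        for tonicity in ("isotonic", "hypotonic"):
            c = sy.ASSAY_COEFFICIENTS[tonicity][assay]
            trace, meta = sy.generate_assay_traces(assay, c, GEOM,
                                                   tonicity=tonicity)
            if assay == "glycerol":
                r = ma.fit_glycerol_permeability(trace, 100.0, GEOM)
            elif assay == "acetic":
                r = ma.fit_acetic_permeability(trace, meta["acetate_out"],
                                               meta["buffering"], GEOM)
            else:
                r = ma.fit_ae1_activity(trace, meta["delta_pho"],
                                        meta["buffering"], GEOM)
            results[tonicity] = r.scaled_estimate
        assert results["hypotonic"] > results["isotonic"]
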