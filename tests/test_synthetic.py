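"""Synthetic-data generators: determinism, presets and parameter recovery."""

import numpy as np
import pytest

from rbcgas import h_uncaging as hu
from rbcgas import synthetic as sy
from rbcgas.errors import DomainError, UnidentifiableError
from rbcgas.trace_kinetics import fit_monoexponential


class TestGeneratePopulation:
    def test_seed_determinism(self):
        a, _ = sy.generate_population("WT", 50, seed=3)
        b, _ = sy.generate_population("WT", 50, seed=3)
        c, _ = sy.generate_population("WT", 50, seed=4)
        assert a.equals(b)
        assert not a.equals(c)

    def test_single_row(self):
        df, meta = sy.generate_population("HbH", 1, seed=0)
        assert len(df) == 1
        assert (df[["mcv", "area", "mchc", "tau_true"]] > 0).all().all()
        assert meta["n"] == 1

    def test_height_is_mcv_over_area(self):
        df, _ = sy.generate_population("HS_anemic", 100, seed=1)
        np.testing.assert_allclose(df["height"], df["mcv"] / df["area"])

    def test_wt_mean_tau_recovery(self):
        """Sample mean tau of a large WT cohort sits within 2 SE of the
        generating 0.971 s."""
        df, _ = sy.generate_population("WT", 10_000, seed=5)
        se = df["tau_true"].std() / np.sqrt(len(df))
        assert abs(df["tau_true"].mean() - 0.971) < 2 * se + 0.01

    def test_unknown_preset_lists_options(self):
        with pytest.raises(DomainError, match="WT"):
            sy.generate_population("XYZ", 5)

    def test_osmolarity_series_biphasic(self):
        """tau is slowest at both osmotic extremes, fastest near
        physiological osmolarity."""
        taus = {osm: sy.get_preset(f"osmo_{osm}").tau_components[0][1]
                for osm in sy.OSMOLARITY_SERIES}
        nadir = min(taus, key=taus.get)
        assert nadir == 297
        assert taus[180] > taus[297] and taus[414] > taus[297]

    def test_osmolarity_geometry_direction(self):
        hypo = sy.get_preset("osmo_180")
        hyper = sy.get_preset("osmo_414")
        wt = sy.get_preset("WT")
        assert hypo.mcv[0] > wt.mcv[0] > hyper.mcv[0]
        assert hypo.mchc[0] < wt.mchc[0] < hyper.mchc[0]


class TestGenerateRatioTraces:
    def test_noiseless_per_cell_roundtrip(self):
        """Without the switch kernel the fitted tau matches tau_true to
        0.5% per cell."""
        df, _ = sy.generate_population("WT", 8, seed=2)
        proto = sy.SwitchProtocol(switch_tau=0.0)
        traces, _ = sy.generate_ratio_traces(df, protocol=proto)
        for tr, tau_true in zip(traces, df["tau_true"]):
            fit = fit_monoexponential(tr)
            assert fit.tau == pytest.approx(tau_true, rel=0.005)

    def test_pure_exponential_analytic(self):
        df, _ = sy.generate_population("WT", 1, seed=0)
        proto = sy.SwitchProtocol(switch_tau=0.0, pre_switch=0.0)
        traces, _ = sy.generate_ratio_traces(df, protocol=proto)
        t = traces[0].time
        tau = df["tau_true"].iloc[0]
        expected = 1 - 0.39 * (1 - np.exp(-t / tau))
        np.testing.assert_allclose(traces[0].values, expected, atol=1e-12)

    def test_noisy_cohort_mean_recovery(self):
        """Population mean tau of a noisy 700-cell cohort falls within
        2 SEM of the generating mean."""
        df, _ = sy.generate_population("WT", 700, seed=6)
        noise = sy.NoiseModel(additive_sd=0.01, seed=7)
        proto = sy.SwitchProtocol()
        traces, _ = sy.generate_ratio_traces(df, protocol=proto, noise=noise)
        end = proto.pre_switch + proto.exposure
        taus = np.array([
            fit_monoexponential(tr, fit_window=(proto.pre_switch, end)).tau
            for tr in traces
        ])
        ok = np.isfinite(taus)
        sem = taus[ok].std() / np.sqrt(ok.sum())
        assert abs(taus[ok].mean() - df["tau_true"].mean()) < 2 * sem + 0.02

    def test_short_duration_warns_in_metadata(self):
        df, _ = sy.generate_population("WT", 3, seed=0)
        proto = sy.SwitchProtocol(exposure=1.0)
        _, meta = sy.generate_ratio_traces(df, protocol=proto)
        assert meta["duration_warning"]

    def test_pde_mode_runs_and_is_slower_for_thicker_cells(self):
        df, _ = sy.generate_population("WT", 2, seed=1)
        df = df.copy()
        df.loc[df.index[1], "height"] = 2.4
        df.loc[df.index[0], "height"] = 1.5
        proto = sy.SwitchProtocol(exposure=12.0, pre_switch=1.0)
        traces, _ = sy.generate_ratio_traces(df, protocol=proto, mode="pde")
        taus = [fit_monoexponential(tr).tau for tr in traces]
        assert taus[1] > taus[0]


class TestGenerateUncagingSet:
    def test_hepes_condition_centers_on_dhb(self):
        buf = hu.BufferSystem(beta_hb=50.0, D_hb=8.0)
        exps, _ = sy.generate_uncaging_set(buf, n_cells=5, seed=1)
        fits = [hu.fit_dh_app(e) for e in exps]
        assert np.mean(fits) == pytest.approx(8.0, rel=0.02)

    def test_zero_source_unidentifiable(self):
        buf = hu.BufferSystem()
        proto = hu.UncagingProtocol(source_strength=0.0)
        exps, _ = sy.generate_uncaging_set(buf, n_cells=1, seed=0,
                                           protocol=proto)
        with pytest.raises(UnidentifiableError):
            hu.fit_dh_app(exps[0])

    def test_paired_conditions_recover_dc_co2(self):
        """+/- CO2 pairs generated at D_c_CO2 = 48.9 um^2/s invert back to
        the generating value within 2%."""
        without = hu.BufferSystem(beta_hb=50.0, D_hb=8.0)
        with_co2 = hu.BufferSystem(beta_hb=50.0, D_hb=8.0, beta_co2=50.0,
                                   D_c_CO2=48.9)
        a, _ = sy.generate_uncaging_set(without, n_cells=3, seed=2)
        b, _ = sy.generate_uncaging_set(with_co2, n_cells=3, seed=2)
        dh_wo = np.mean([hu.fit_dh_app(e) for e in a])
        dh_w = np.mean([hu.fit_dh_app(e) for e in b])
        d = hu.derive_dc_co2(dh_wo, dh_w, with_co2)
        assert d == pytest.approx(48.9, rel=0.02)

    def test_seed_determinism(self):
        buf = hu.BufferSystem()
        a, _ = sy.generate_uncaging_set(buf, n_cells=2, seed=9)
        b, _ = sy.generate_uncaging_set(buf, n_cells=2, seed=9)
        np.testing.assert_array_equal(a[0].roi_ph, b[0].roi_ph)


class TestGenerateAssayTraces:
    def test_zero_coefficient_flat(self):
        geom = __import__("rbcgas.membrane_assays",
                          fromlist=["CellGeometry"]).CellGeometry(
            mcv=90, area=50, mchc=330)
        tr, _ = sy.generate_assay_traces("acetic", 0.0, geom)
        assert np.ptp(tr.values) == 0.0

    def test_unknown_assay(self):
        geom = __import__("rbcgas.membrane_assays",
                          fromlist=["CellGeometry"]).CellGeometry(
            mcv=90, area=50, mchc=330)
        with pytest.raises(DomainError):
            sy.generate_assay_traces("osmotic", 1.0, geom)


class TestNoiseModel:
    def test_validation(self):
        with pytest.raises(DomainError):
            sy.NoiseModel(additive_sd=-0.1)

    def test_noise_changes_values_deterministically(self):
        rng1 = np.random.default_rng(1)
        rng2 = np.random.default_rng(1)
        nm = sy.NoiseModel(additive_sd=0.05)
        v = np.ones(100)
        a = nm.apply(v, rng1)
        b = nm.apply(v, rng2)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, v)


class TestTiffPath:
    def test_stack_roundtrip(self, tmp_path):
        """Traces written as a two-channel stack are recovered by the
        mean-ROI extraction."""
        from rbcgas.io import read_tiff_traces

        df, _ = sy.generate_population("WT", 3, seed=0)
        proto = sy.SwitchProtocol(exposure=3.0, pre_switch=0.5)
        traces, _ = sy.generate_ratio_traces(df, protocol=proto)
        tiff = tmp_path / "stack.tif"
        mask = tmp_path / "mask.tif"
        sy.write_two_channel_stack(traces, tiff, mask)
        back = read_tiff_traces(tiff, mask)
        assert len(back) == 3
        for orig, rec in zip(traces, back):
            np.testing.assert_allclose(
                rec.values, orig.values[: len(rec.values)], rtol=1e-5
            )
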