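import numpy as np
import pytest

from dibkit import droplet_geometry as dg, dsc, raman, synthetic_data as sd
from dibkit._ode import UM3_PER_L
from dibkit.errors import ConfigError, GeometryError

# closed-form initial volume flux for the derived example:
# Pf·A·v_w·Δc = 74 μm/s · π·30² μm² · 18e12 μm³/mol · 0.2e-15 osmol/μm³
EXPECTED_INITIAL_SLOPE = 74.0 * np.pi * 30**2 * 18.0e12 * 0.2e-15  # 753.23 μm³/s


class TestDIBSimConfig:
    def test_invariants(self):
        with pytest.raises(ConfigError):
            sd.DIBSimConfig(initial_radius_1=-1)
        with pytest.raises(ConfigError):
            sd.DIBSimConfig(initial_contact_radius=60.0)
        with pytest.raises(ConfigError):
            sd.DIBSimConfig(true_Pf=-5.0)
        with pytest.raises(ConfigError):
            sd.DIBSimConfig(duration=0)
        with pytest.raises(ConfigError):
            sd.DIBSimConfig(shrinkage_mode="bogus")


class TestSimulateDibTrajectory:
    def test_zero_gradient_constant_volumes(self):
        cfg = sd.DIBSimConfig(osmolality_1=0.2, osmolality_2=0.2, duration=10)
        traj = sd.simulate_dib_trajectory(cfg)
        v1, v2 = traj.volumes()
        assert np.ptp(v1) == 0 and np.ptp(v2) == 0

    def test_zero_permeability_constant_volumes(self):
        cfg = sd.DIBSimConfig(true_Pf=0.0, duration=10)
        traj = sd.simulate_dib_trajectory(cfg)
        v1, _ = traj.volumes()
        assert np.ptp(v1) == 0

    def test_initial_slope_matches_closed_form(self):
        # finite difference over the first two noiseless samples at tiny dt
        cfg = sd.DIBSimConfig(
            true_Pf=74.0, duration=0.02, sample_interval=0.01, noise_sd_radius=0.0
        )
        traj = sd.simulate_dib_trajectory(cfg)
        v1, _ = traj.volumes()
        slope = (v1[1] - v1[0]) / (traj.time_s[1] - traj.time_s[0])
        assert EXPECTED_INITIAL_SLOPE == pytest.approx(753.228, abs=0.001)
        assert slope == pytest.approx(-EXPECTED_INITIAL_SLOPE, rel=1e-4)

    @pytest.mark.parametrize("mode", sd.SHRINKAGE_MODES)
    def test_conservation_laws(self, mode):
        cfg = sd.DIBSimConfig(
            osmolality_1=0.05, osmolality_2=0.25, true_Pf=100.0, shrinkage_mode=mode
        )
        traj = sd.simulate_dib_trajectory(cfg)
        v1, v2 = traj.volumes()
        # water conservation
        total = v1 + v2
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-9
        # solute conservation is structural (c_i = n_i / V_i); verify the
        # osmole content recomputed from volumes is constant
        n1 = cfg.osmolality_1 / UM3_PER_L * v1[0]
        n2 = cfg.osmolality_2 / UM3_PER_L * v2[0]
        c1 = n1 / v1 * UM3_PER_L
        c2 = n2 / v2 * UM3_PER_L
        assert np.max(np.abs(c1 * v1 / UM3_PER_L - n1)) <= 1e-9 * n1
        # monotone approach to osmotic equilibrium
        gradient = np.abs(c1 - c2)
        assert np.all(np.diff(gradient) <= 1e-12 * gradient[0])

    def test_hypotonic_droplet_shrinks(self):
        traj = sd.simulate_dib_trajectory(sd.DIBSimConfig())
        v1, _ = traj.volumes()
        assert np.all(np.diff(v1) < 0)

    def test_seeded_reproducibility(self):
        cfg = sd.DIBSimConfig(noise_sd_radius=0.5, seed=42)
        a = sd.simulate_dib_trajectory(cfg)
        b = sd.simulate_dib_trajectory(cfg)
        np.testing.assert_array_equal(a.R1_um, b.R1_um)
        np.testing.assert_array_equal(a.R2_um, b.R2_um)

    def test_noise_added_after_integration(self):
        clean = sd.simulate_dib_trajectory(sd.DIBSimConfig(seed=7))
        noisy = sd.simulate_dib_trajectory(
            sd.DIBSimConfig(noise_sd_radius=0.5, seed=7)
        )
        # underlying volumes in meta identical; only radii differ
        np.testing.assert_allclose(
            clean.meta["V1_um3"], noisy.meta["V1_um3"], rtol=1e-12
        )
        assert not np.allclose(clean.R1_um, noisy.R1_um)


class TestRenderDropletImage:
    def test_roundtrip_radii(self):
        state = dg.DropletPairState(50, 50, 30)
        frame = sd.render_droplet_image(state, 1.0, (256, 256))
        fit = dg.fit_droplet_pair(frame)
        assert fit.R1 == pytest.approx(50, abs=0.5)
        assert fit.R2 == pytest.approx(50, abs=0.5)

    def test_truth_recorded(self):
        frame = sd.render_droplet_image(dg.DropletPairState(50, 50, 30), 1.0)
        assert frame.truth["R1_um"] == 50
        assert frame.truth["rc_um"] == 30

    def test_out_of_frame_rejected(self):
        with pytest.raises(GeometryError):
            sd.render_droplet_image(dg.DropletPairState(50, 50, 30), 1.0, (64, 64))

    def test_degenerate_droplet_rejected(self):
        with pytest.raises(GeometryError):
            dg.DropletPairState(0.0, 50.0, 0.0)


class TestSimulateThermogram:
    def test_gaussian_amplitude_identity(self):
        # amplitude = dH/(σ√2π), σ = FWHM/2.3548
        cfg = sd.DSCSimConfig(dH_true=8.76, dT_half_true=2.04, noise_sd=0.0)
        sigma = 2.04 / (2 * np.sqrt(2 * np.log(2)))
        expected_amp = 8.76 / (sigma * np.sqrt(2 * np.pi))
        assert sigma == pytest.approx(0.8663, abs=2e-4)
        assert expected_amp == pytest.approx(4.034, abs=0.001)
        cp = sd.excess_cp_profile(np.array([cfg.Tm_true]), cfg)
        assert cp[0] == pytest.approx(expected_amp, rel=1e-12)

    def test_noiseless_roundtrip(self):
        cfg = sd.DSCSimConfig(noise_sd=0.0, baseline_slope=0.0)
        tg = sd.simulate_thermogram(cfg)
        trace = dsc.subtract_baseline(
            dsc.heatflow_to_molar_cp(tg), (-38, -30), (-6, -1)
        )
        m = dsc.transition_metrics(trace)
        assert m.Tm == pytest.approx(cfg.Tm_true, abs=cfg.T_step)
        assert m.dH == pytest.approx(cfg.dH_true, rel=5e-3)
        assert m.dT_half == pytest.approx(cfg.dT_half_true, abs=cfg.T_step)

    def test_doubling_moles_doubles_heatflow_not_dH(self):
        base = sd.DSCSimConfig(sample_moles=3.05e-7)
        double = sd.DSCSimConfig(sample_moles=6.10e-7)
        tg1 = sd.simulate_thermogram(base)
        tg2 = sd.simulate_thermogram(double)
        np.testing.assert_allclose(tg2.heatflow_mW, 2 * tg1.heatflow_mW, rtol=1e-12)
        m1 = dsc.transition_metrics(
            dsc.subtract_baseline(dsc.heatflow_to_molar_cp(tg1), (-38, -30), (-6, -1))
        )
        m2 = dsc.transition_metrics(
            dsc.subtract_baseline(dsc.heatflow_to_molar_cp(tg2), (-38, -30), (-6, -1))
        )
        assert m2.dH == pytest.approx(m1.dH, rel=1e-9)

    def test_skewed_shape_calibration(self):
        cfg = sd.DSCSimConfig(peak_shape="skewed_gaussian", skew=4.0)
        T = np.arange(-40, 0, 0.002)
        cp = sd.excess_cp_profile(T, cfg)
        apex = T[np.argmax(cp)]
        area = np.trapezoid(cp, T)
        assert apex == pytest.approx(cfg.Tm_true, abs=0.005)
        assert area == pytest.approx(cfg.dH_true, rel=1e-3)

    def test_truncated_peak_warns_and_flags(self):
        cfg = sd.DSCSimConfig(Tm_true=-39.0, T_range=(-40.0, 0.0))
        with pytest.warns(UserWarning):
            tg = sd.simulate_thermogram(cfg)
        assert tg.meta["truncated"]

    def test_seeded_reproducibility(self):
        cfg = sd.DSCSimConfig(noise_sd=0.05, seed=11)
        a = sd.simulate_thermogram(cfg)
        b = sd.simulate_thermogram(cfg)
        np.testing.assert_array_equal(a.heatflow_mW, b.heatflow_mW)

    def test_invariants(self):
        with pytest.raises(ConfigError):
            sd.DSCSimConfig(dH_true=-1)
        with pytest.raises(ConfigError):
            sd.DSCSimConfig(Tm_true=10.0)  # outside default range
        with pytest.raises(ConfigError):
            sd.DSCSimConfig(scan_rate=0)


class TestSimulateRamanSpectrum:
    def test_single_band_peak_equals_amplitude(self):
        cfg = sd.RamanSimConfig(band_table=(sd.Band(2930.0, 15.0, 0.84),))
        spec = sd.simulate_raman_spectrum(cfg)
        i = np.argmax(spec.intensity)
        assert spec.wavenumber[i] == pytest.approx(2930.0, abs=cfg.step)
        assert spec.intensity[i] == pytest.approx(0.84, rel=1e-9)

    def test_calibrated_control_ratios(self, control_bands):
        spec = sd.simulate_raman_spectrum(sd.RamanSimConfig(band_table=control_bands))
        r = raman.band_ratios(spec)
        assert r.ratio_2930_2848 == pytest.approx(0.84, abs=0.005)
        assert r.ratio_2930_2890 == pytest.approx(0.90, abs=0.005)

    def test_zero_amplitudes_missing_peak_downstream(self):
        bands = tuple(sd.Band(c, 15.0, 0.0) for c in (2848.0, 2890.0, 2930.0))
        cfg = sd.RamanSimConfig(band_table=bands, baseline_poly_coeffs=(3.0, 0.001))
        spec = sd.simulate_raman_spectrum(cfg)
        corrected = raman.baseline_correct(spec)
        with pytest.raises(raman.MissingPeakError):
            raman.band_ratios(corrected)

    def test_seeded_reproducibility(self):
        cfg = sd.RamanSimConfig(
            band_table=(sd.Band(2930.0, 15.0, 1.0),), noise_sd=0.01, seed=3
        )
        a = sd.simulate_raman_spectrum(cfg)
        b = sd.simulate_raman_spectrum(cfg)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_invariants(self):
        with pytest.raises(ConfigError):
            sd.RamanSimConfig(band_table=(sd.Band(100.0, 15.0, 1.0),))  # off-grid
        with pytest.raises(ConfigError):
            sd.RamanSimConfig(band_table=(sd.Band(2930.0, -1.0, 1.0),))
        with pytest.raises(ConfigError):
            sd.RamanSimConfig(step=0)


class TestOsmolalityConversion:
    def test_default_density_convention(self):
        assert sd.mosm_per_kg_to_osmol_per_l(200.0) == pytest.approx(0.2)

    def test_explicit_density(self):
        assert sd.mosm_per_kg_to_osmol_per_l(200.0, 1.02) == pytest.approx(0.204)
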