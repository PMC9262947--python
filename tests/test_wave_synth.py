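"""Ground-truth properties of the synthetic wave/kinetics/peptide generators."""

import numpy as np
import pandas as pd
import pytest

from minwaves.geometry import DropletGeometry, GeometryError, StackGeometry
from minwaves.synth import (
    AliasingError,
    KineticsSimParams,
    WaveSimParams,
    simulate_droplet_pattern,
    simulate_kinetics,
    simulate_peptide_table,
    simulate_standing_wave,
    simulate_traveling_wave,
)
from minwaves.kinetics import sigmoid_eval


class TestTravelingWave:
    def test_phase_advances_by_v_dt_per_frame(self, wave_geometry):
        """lam=60, v=0.5, dt=2 s: each frame is the previous one shifted by
        exactly 1 um along the propagation direction."""
        p = WaveSimParams(wavelength_um=60, velocity_um_s=0.5, direction_deg=0, noise_sd=0)
        stack = simulate_traveling_wave(p, wave_geometry)
        shift_px = 0.5 * 2.0 / wave_geometry.pixel_size_um  # 1 px along columns
        assert shift_px == 1.0
        np.testing.assert_allclose(
            stack.data[1][:, 1:], stack.data[0][:, :-1], atol=1e-9
        )

    def test_antiphase_pair_perfectly_anticorrelated(self, wave_geometry):
        """Width factor 1, zero noise: per-frame Pearson r between channels is -1."""
        p = WaveSimParams(
            wavelength_um=60, velocity_um_s=0.5, antiphase_channel=True, noise_sd=0
        )
        a, b = simulate_traveling_wave(p, wave_geometry)
        for t in (0, 30, 59):
            r = np.corrcoef(a.data[t].ravel(), b.data[t].ravel())[0, 1]
            assert r == pytest.approx(-1.0, abs=1e-10)

    def test_seeded_determinism(self, wave_geometry):
        p = WaveSimParams(wavelength_um=76, velocity_um_s=0.5, noise_sd=20, seed=42)
        s1 = simulate_traveling_wave(p, wave_geometry)
        s2 = simulate_traveling_wave(p, wave_geometry)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_spatial_mean_conserves_baseline(self, wave_geometry):
        """Noiseless planar sinusoid over >= 3 wavelengths averages to baseline."""
        p = WaveSimParams(
            wavelength_um=80, velocity_um_s=0.5, baseline=200, amplitude=100, noise_sd=0
        )
        stack = simulate_traveling_wave(p, wave_geometry)
        assert np.mean(stack.data[0]) == pytest.approx(200, rel=0.01)

    def test_subnyquist_wavelength_rejected(self, wave_geometry):
        p = WaveSimParams(wavelength_um=1.5, velocity_um_s=0.5)
        with pytest.raises(AliasingError):
            simulate_traveling_wave(p, wave_geometry)

    @pytest.mark.parametrize("bad", [dict(wavelength_um=-5), dict(velocity_um_s=0)])
    def test_nonpositive_parameters_rejected(self, wave_geometry, bad):
        with pytest.raises(ValueError):
            simulate_traveling_wave(WaveSimParams(**bad), wave_geometry)

    def test_spiral_pattern_generates(self, wave_geometry):
        p = WaveSimParams(pattern="spiral", wavelength_um=60, velocity_um_s=0.5, noise_sd=0)
        stack = simulate_traveling_wave(p, wave_geometry)
        assert stack.data.shape == wave_geometry.shape
        assert np.all(stack.data >= 0)


class TestStandingWave:
    def test_pixel_autocorrelation_peaks_at_period(self, standing_geometry):
        """Period 105 s at dt=3 s: first off-zero autocorrelation maximum of
        any pixel's time series sits at lag 35."""
        p = WaveSimParams(pattern="standing", wavelength_um=60, period_s=105, noise_sd=0)
        stack = simulate_standing_wave(p, standing_geometry)
        series = stack.data[:, 10, 17] - stack.data[:, 10, 17].mean()
        n = series.size
        ac = np.correlate(series, series, mode="full")[n - 1 :]
        ac = ac / (n - np.arange(n))  # unbiased
        interior = ac[1:-1]
        peaks = np.nonzero((interior > ac[:-2]) & (interior >= ac[2:]))[0] + 1
        assert peaks[0] == 35

    def test_temporal_mean_is_baseline(self, standing_geometry):
        p = WaveSimParams(
            pattern="standing", wavelength_um=60, period_s=96, baseline=150, noise_sd=0
        )
        # record = 384 s = integer number of 96-s periods: exact mean
        stack = simulate_standing_wave(p, standing_geometry)
        np.testing.assert_allclose(stack.data.mean(axis=0), 150, atol=1e-9)

    def test_subnyquist_period_rejected(self, standing_geometry):
        p = WaveSimParams(pattern="standing", wavelength_um=60, period_s=4)
        with pytest.raises(AliasingError):
            simulate_standing_wave(p, standing_geometry)


class TestDropletPattern:
    def test_patch_revolution_time_matches_arc_kinematics(self, droplet_setup):
        """v=0.3 um/s on a 10-um radius: one revolution takes 2*pi*10/0.3 s,
        so the patch maximum returns to its start angle after ~209.4 s."""
        droplet, geom = droplet_setup
        p = WaveSimParams(pattern="droplet_ring", velocity_um_s=0.3, noise_sd=0)
        ch1, _ = simulate_droplet_pattern(p, droplet, geom)
        period_s = 2 * np.pi * droplet.radius_um / 0.3
        k = int(round(period_s / geom.frame_interval_s))  # ~70 frames
        # frame k should match frame 0 much better than a quarter-revolution frame
        d_full = np.abs(ch1.data[k] - ch1.data[0]).mean()
        d_quarter = np.abs(ch1.data[k // 4] - ch1.data[0]).mean()
        assert d_full < 0.2 * d_quarter

    def test_channels_occupy_opposite_arcs(self, droplet_setup):
        """Angular cross-correlation of the two rim profiles is maximal at a
        half-circumference rotation and minimal at zero rotation."""
        droplet, geom = droplet_setup
        p = WaveSimParams(pattern="droplet_ring", velocity_um_s=0.3, noise_sd=0)
        ch1, ch2 = simulate_droplet_pattern(p, droplet, geom)
        from minwaves.kymo import build_perimeter_kymograph

        k1 = build_perimeter_kymograph(ch1, droplet)
        k2 = build_perimeter_kymograph(ch2, droplet)
        a = k1.data[:, 0] - k1.data[:, 0].mean()
        b = k2.data[:, 0] - k2.data[:, 0].mean()
        cc = np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n=a.size)
        n = a.size
        assert abs(int(np.argmax(cc)) - n // 2) <= 2  # aligned after pi rotation
        assert min(int(np.argmin(cc)), n - int(np.argmin(cc))) <= 2  # anti at 0

    def test_circle_must_fit_in_frame(self, droplet_setup):
        _, geom = droplet_setup
        big = DropletGeometry(center=(63.5, 63.5), radius_um=40.0, rim_width_um=3.0)
        p = WaveSimParams(pattern="droplet_ring", velocity_um_s=0.3)
        with pytest.raises(GeometryError):
            simulate_droplet_pattern(p, big, geom)


class TestKineticsTable:
    def test_noiseless_table_equals_sigmoid(self):
        params = KineticsSimParams(noise_sd_uM=0.0, n_replicates=2)
        table = simulate_kinetics(params)
        for protein, pset in params.proteins.items():
            sub = table[(table.protein == protein) & (table.replicate == 1)]
            expected = sigmoid_eval(sub.time_min.to_numpy(), *pset)
            np.testing.assert_allclose(sub.conc_uM.to_numpy(), expected, atol=1e-12)

    def test_half_max_at_t_equals_K(self):
        assert sigmoid_eval(60.0, 0.0, 1.5, 60.0, 3.0) == pytest.approx(0.75)

    def test_seeded_determinism_and_noise_truncation(self):
        params = KineticsSimParams(noise_sd_uM=0.5, seed=7)
        t1, t2 = simulate_kinetics(params), simulate_kinetics(params)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1.conc_uM >= 0).all()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_kinetics(KineticsSimParams(noise_sd_uM=-0.1))


class TestPeptideTable:
    def test_exact_ratios_at_zero_noise(self):
        table = simulate_peptide_table(
            {"FtsA": 1.5}, ribo_conc_uM=1.0, qconcat_conc_uM=0.5, noise_cv=0.0
        )
        ribo = table[table.role == "ribosomal_reference"]
        np.testing.assert_allclose(ribo.light_area / ribo.heavy_area, 2.0)
        ftsa = table[table.protein == "FtsA"]
        np.testing.assert_allclose(ftsa.light_area / ftsa.heavy_area, 3.0)

    def test_panel_composition(self):
        table = simulate_peptide_table({"FtsA": 1.5, "MinD": 4.2, "MinE": 3.2})
        one_run = table[(table.bio_rep == 1) & (table.tech_rep == 1)]
        counts = one_run.groupby("protein")["peptide"].nunique()
        assert counts["FtsA"] == 2 and counts["MinD"] == 2 and counts["MinE"] == 1
        assert (one_run.role == "ribosomal_reference").sum() == 2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_peptide_table({"FtsA": -1.0})
        with pytest.raises(ValueError):
            simulate_peptide_table({"NotInPanel": 1.0})
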