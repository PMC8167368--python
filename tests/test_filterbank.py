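"""Opponent transform, filter profiles, zoning and linear responses."""

import numpy as np
import pytest

import spatialvision as sv
from spatialvision.filterbank import (
    _FreqDomain,
    _orient_gain,
    _pad_extent,
    _zone_freq_gains,
    FilterSpec,
)


def grating(grid, f, theta_deg=0.0, contrast=1.0, phase=0.0):
    x = grid.x_deg()[None, :]
    y = grid.y_deg()[:, None]
    th = np.radians(theta_deg)
    plane = contrast * np.cos(
        2 * np.pi * f * (x * np.cos(th) + y * np.sin(th)) + phase)
    z = np.zeros(grid.shape)
    return sv.OpponentImage(plane, z, z.copy())


def interior_mask(bank, zone_index, margin_px=32):
    """Zone pixels clear of the image border (mirror-padding artefacts)."""
    m = bank.zone_mask(zone_index).copy()
    m[:margin_px, :] = False
    m[-margin_px:, :] = False
    m[:, :margin_px] = False
    m[:, -margin_px:] = False
    assert m.any()
    return m


class TestOpponentTransform:
    def test_uniform_gray_is_zero_contrast(self):
        opp = sv.to_opponent(np.full((16, 16, 3), 0.5))
        assert np.allclose(opp.achr, 0.0, atol=1e-12)
        assert np.allclose(opp.by, 0.0, atol=1e-12)
        assert np.allclose(opp.rg, 0.0, atol=1e-12)

    def test_achromatic_grating_stays_achromatic(self):
        x = np.linspace(0, 6 * np.pi, 64)
        lum = 0.5 + 0.3 * np.cos(x)[None, :]
        rgb = np.repeat(lum[..., None], 3, axis=-1)
        opp = sv.to_opponent(np.broadcast_to(rgb, (64, 64, 3)))
        assert np.abs(opp.achr).max() > 0.1
        assert np.abs(opp.by).max() < 1e-3
        assert np.abs(opp.rg).max() < 1e-3

    def test_isoluminant_red_green_roundtrip(self):
        # built by inverting the opponent transform: energy lands in RG only
        from skimage import color

        a = 30 * np.cos(np.linspace(0, 8 * np.pi, 64))[None, :]
        lab = np.stack([np.full((64, 64), 60.0),
                        np.broadcast_to(a, (64, 64)),
                        np.zeros((64, 64))], axis=-1)
        rgb = np.clip(color.lab2rgb(lab), 0, 1)
        opp = sv.to_opponent(rgb)
        assert opp.rg.std() > 5 * opp.achr.std()
        assert opp.rg.std() > 5 * opp.by.std()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sv.to_opponent(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            sv.to_opponent(np.full((8, 8, 3), 1.5))


class TestFilterGain:
    def test_peak_gain_is_unity(self):
        spec = FilterSpec(sv.ChannelId.ACHR, 0, f_peak=4.0, theta_peak=45.0)
        assert sv.filter_gain(spec, 4.0, 45.0) == pytest.approx(1.0)

    def test_frequency_profile_sigma(self):
        spec = FilterSpec(sv.ChannelId.ACHR, 0, f_peak=4.0, theta_peak=0.0)
        f_one_sigma = 4.0 * 2 ** 0.7
        assert sv.filter_gain(spec, f_one_sigma, 0.0) == pytest.approx(
            np.exp(-0.5), rel=1e-9)

    def test_orientation_half_gain_at_half_fwhm(self):
        spec = FilterSpec(sv.ChannelId.ACHR, 0, f_peak=4.0, theta_peak=0.0)
        assert sv.filter_gain(spec, 4.0, 22.5) == pytest.approx(0.5, rel=1e-9)
        assert sv.filter_gain(spec, 4.0, 90.0) == 0.0
        # modulo-180 distance
        assert sv.filter_gain(spec, 4.0, 170.0) == pytest.approx(
            sv.filter_gain(spec, 4.0, 10.0), rel=1e-9)

    def test_orientation_tiling_sums_to_one(self):
        thetas = np.linspace(0, 180, 73)
        total = sum(_orient_gain(thetas, pk) for pk in sv.ORIENTATIONS_DEG)
        assert np.allclose(total, 1.0, atol=1e-12)


class TestBankStructure:
    def test_every_pixel_in_exactly_one_zone(self, small_calib):
        bank = small_calib.bank
        idx = bank.zone_index_map
        assert idx.min() >= 0 and idx.max() < len(bank.zones)
        counts = np.bincount(idx.ravel(), minlength=len(bank.zones))
        assert counts.sum() == idx.size

    def test_adjacent_zone_peaks_within_step(self, small_calib):
        bank = small_calib.bank
        for ch in sv.CHANNELS:
            fines = [z.peaks[ch][0] for z in bank.zones]
            steps = np.abs(np.diff(np.log2(fines)))
            assert np.all(steps <= bank.zoning_step_octaves + 1e-9)

    def test_band_counts_per_channel(self, small_calib):
        for zone in small_calib.bank.zones:
            assert len(zone.peaks[sv.ChannelId.ACHR]) == 4
            assert len(zone.peaks[sv.ChannelId.BY]) == 3
            assert len(zone.peaks[sv.ChannelId.RG]) == 3

    def test_foveal_finest_peak_near_third_of_acuity(self, small_calib):
        zone = small_calib.bank.zone_of_eccentricity(0.0)
        expected = sv.acuity_limit(0.0, sv.ChannelId.ACHR) / 3
        # within the lattice quantization (half of 1/8 octave)
        assert abs(np.log2(zone.peaks[sv.ChannelId.ACHR][0] / expected)) < 0.0626

    def test_zone_count_grows_with_finer_step(self):
        grid = sv.VisualFieldGrid.horizontal_strip(
            max_ecc_deg=8.0, px_per_deg=16.0, height_deg=4.0)
        coarse = sv.build_bank(grid, zoning_step_octaves=0.25)
        fine = sv.build_bank(grid, zoning_step_octaves=0.125)
        assert len(fine.zones) > len(coarse.zones)

    def test_step_limit_enforced(self):
        grid = sv.VisualFieldGrid.horizontal_strip(
            max_ecc_deg=8.0, px_per_deg=16.0, height_deg=4.0)
        with pytest.raises(ValueError):
            sv.build_bank(grid, zoning_step_octaves=0.5)

    def test_bank_json_export(self, small_calib, tmp_path):
        import json

        path = tmp_path / "bank.json"
        small_calib.bank.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["zones"][0]["peaks_cpd"]["Achr"]
        assert doc["grid"]["extent_deg"] == small_calib.bank.grid.extent_deg


class TestLinearResponses:
    def test_preferred_grating_unit_magnitude(self, small_calib):
        bank = small_calib.bank
        fpk = bank.zones[0].peaks[sv.ChannelId.ACHR][0]
        lin = sv.linear_responses(grating(bank.grid, fpk), bank,
                                  channels=(sv.ChannelId.ACHR,))
        sel = interior_mask(bank, 0)
        mag = np.abs(lin.band[0, 0, 0])[sel]
        assert np.allclose(mag, 1.0, atol=1e-3)

    def test_linearity_in_contrast(self, small_calib):
        bank = small_calib.bank
        fpk = bank.zones[0].peaks[sv.ChannelId.ACHR][1]
        sel = interior_mask(bank, 0)
        m1 = np.abs(sv.linear_responses(
            grating(bank.grid, fpk, contrast=0.5), bank,
            channels=(sv.ChannelId.ACHR,)).band[0, 1, 0])[sel]
        assert np.allclose(m1, 0.5, atol=1e-3)

    def test_zero_image_zero_response(self, small_calib):
        bank = small_calib.bank
        z = np.zeros(bank.grid.shape)
        lin = sv.linear_responses(sv.OpponentImage(z, z.copy(), z.copy()), bank)
        assert not np.any(lin.band)
        assert not np.any(lin.lowpass)

    def test_quadrature_phase_invariance(self, small_calib):
        bank = small_calib.bank
        fpk = bank.zones[0].peaks[sv.ChannelId.ACHR][0]
        sel = interior_mask(bank, 0)
        mags = []
        for ph in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            lin = sv.linear_responses(
                grating(bank.grid, fpk, phase=ph), bank,
                channels=(sv.ChannelId.ACHR,), pixel_mask=sel)
            mags.append(np.abs(lin.band[0, 0, 0])[sel].mean())
        mags = np.array(mags)
        assert np.ptp(mags) / mags.mean() < 0.01

    def test_orthogonal_orientation_rejected(self, small_calib):
        bank = small_calib.bank
        fpk = bank.zones[0].peaks[sv.ChannelId.ACHR][0]
        lin = sv.linear_responses(grating(bank.grid, fpk, theta_deg=90.0), bank,
                                  channels=(sv.ChannelId.ACHR,))
        sel = interior_mask(bank, 0)
        assert np.abs(lin.band[0, 0, 0])[sel].max() < 1e-3

    def test_dimension_mismatch_rejected(self, small_calib):
        z = np.zeros((8, 8))
        with pytest.raises(ValueError):
            sv.linear_responses(sv.OpponentImage(z, z.copy(), z.copy()),
                                small_calib.bank)

    def test_frequency_domain_matches_direct_convolution(self):
        # brute-force oracle: circular convolution with the filter kernel on a
        # small patch reproduces the frequency-domain product
        n = 64
        ppd = 16.0
        fd = _FreqDomain.__new__(_FreqDomain)
        fx = np.fft.fftfreq(n, d=1.0 / ppd)
        FX, FY = fx[None, :], fx[:, None]
        f = np.hypot(FX, FY)
        theta = np.degrees(np.arctan2(-FY, FX)) % 180.0
        half = ((FX > 0) | ((FX == 0) & (-FY > 0))).astype(float) * 2.0
        from spatialvision.filterbank import _freq_gain, _orient_gain

        H = _freq_gain(f, 2.0, 0.7) * _orient_gain(theta, 0.0) * half
        rng = np.random.default_rng(0)
        img = rng.standard_normal((n, n))
        freq_result = np.fft.ifft2(np.fft.fft2(img) * H)
        kernel = np.fft.ifft2(H)
        direct = np.zeros((n, n), dtype=complex)
        for dy in range(n):
            for dx in range(n):
                direct += kernel[dy, dx] * np.roll(img, (dy, dx), axis=(0, 1))
        assert np.allclose(freq_result, direct, atol=1e-6)

    def test_zone_boundary_compositing_continuity(self, small_calib):
        # a smooth low-frequency stimulus: responses on the two sides of a
        # zone boundary differ by less than the zoning step's gain change
        bank = small_calib.bank
        f = bank.zones[0].peaks[sv.ChannelId.ACHR][2]  # coarse, smooth
        lin = sv.linear_responses(grating(bank.grid, f), bank,
                                  channels=(sv.ChannelId.ACHR,))
        mag = np.abs(lin.band[0, 2, 0])
        row = bank.grid.height_px // 2
        cols = slice(60, -60)
        prof = np.log(np.maximum(mag[row, cols], 1e-9))
        zidx = bank.zone_index_map[row, cols]
        lf = np.log2(f)
        sigma2 = 2 * 0.7 ** 2
        checked = 0
        for i in np.where(np.diff(zidx) != 0)[0]:
            z1, z2 = bank.zones[zidx[i]], bank.zones[zidx[i + 1]]
            lp1 = np.log2(z1.peaks[sv.ChannelId.ACHR][2])
            lp2 = np.log2(z2.peaks[sv.ChannelId.ACHR][2])
            predicted = abs((lf - lp1) ** 2 - (lf - lp2) ** 2) / sigma2
            observed = abs(prof[i + 1] - prof[i])
            assert observed <= predicted + 0.02
            checked += 1
        assert checked >= 3

    def test_low_pass_residual_complements_bands(self, small_calib):
        bank = small_calib.bank
        fd = _FreqDomain(bank.grid, _pad_extent(bank))
        zone = bank.zones[0]
        gains, residual = _zone_freq_gains(bank, zone, sv.ChannelId.ACHR, fd)
        total = np.sum(gains, axis=0) + residual
        f_fine = zone.peaks[sv.ChannelId.ACHR][0]
        inband = (fd.f > 0) & (fd.f < f_fine)
        assert np.all(total[inband] >= 1.0 - 1e-6)   # no spectral hole
        assert np.all(residual[fd.f >= f_fine] == 0)
        assert residual[0, 0] == 0                    # DC excluded
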