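"""Visible image, sampling windows, colourfulness and sharpness statistics."""

import numpy as np
import pandas as pd
import pytest

import spatialvision as sv
from spatialvision.quality_metrics import (
    EccentricityProfile,
    SATURATION_QUANTILES,
    filter_completeness,
)
from spatialvision.response_model import AccuracyField, accuracy_field, field_responses


class TestWindowRadius:
    def test_scaled_rule_values(self):
        rule = sv.SamplingRule(kind="scaled")
        assert sv.window_radius(0.0, rule) == pytest.approx(5 / 60 + 1, rel=1e-9)
        # k0 term doubles at E = E2
        r0 = sv.window_radius(0.0, rule) - 1.0
        r2 = sv.window_radius(0.34, rule) - 1.0
        assert r2 == pytest.approx(2 * r0, rel=1e-9)

    def test_fixed_rule(self):
        rule = sv.SamplingRule(kind="fixed")
        for E in (0.0, 10.0, 30.0):
            assert sv.window_radius(E, rule) == 3.75

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            sv.SamplingRule(kind="adaptive")


class TestHueEntropy:
    def test_single_bin_zero_bits(self):
        h = np.full(1000, 0.37)
        s = np.full(1000, 0.9)
        assert sv.hue_entropy(h, s) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_distribution_eight_bits(self, rng):
        h = (np.arange(256 * 50) % 256 + 0.5) / 256.0
        s = np.ones_like(h)
        assert sv.hue_entropy(h, s) == pytest.approx(8.0, abs=1e-9)

    def test_two_bins_one_bit(self):
        h = np.concatenate([np.full(500, 0.1), np.full(500, 0.6)])
        s = np.ones(1000)
        assert sv.hue_entropy(h, s) == pytest.approx(1.0, abs=1e-9)

    def test_empty_selection_undefined(self):
        h = np.linspace(0, 1, 100, endpoint=False)
        s = np.full(100, 0.05)  # below the 0.2 saturation bar
        assert sv.hue_entropy(h, s) is None


class TestFilterCompleteness:
    def test_product_of_four_high_accuracies(self):
        band = np.zeros((3, 4, 4, 2, 2))
        band[0] = 0.99
        acc = AccuracyField(band, np.zeros((3, 2, 2)))
        fcmap = filter_completeness(acc, bank=None)
        assert fcmap.fc.max() == pytest.approx(0.99 ** 4, rel=1e-9)
        assert fcmap.fc.max() == pytest.approx(0.9606, abs=1e-4)
        assert fcmap.sharp_mask.all()

    def test_one_dead_band_annihilates(self):
        band = np.full((3, 4, 4, 2, 2), 0.999)
        band[0, 2] = 0.0
        acc = AccuracyField(band, np.zeros((3, 2, 2)))
        fcmap = filter_completeness(acc, bank=None)
        assert np.all(fcmap.fc == 0.0)
        assert not fcmap.sharp_mask.any()


class TestReconstruction:
    def test_zero_accuracy_gives_mean_image(self, scene_calib):
        bank = scene_calib.bank
        rgb = sv.make_synthetic_scene(sv.SceneSpec(seed=6, size_px=512))
        lin = sv.linear_responses(sv.to_opponent(rgb), bank, boundary="wrap")
        acc0 = AccuracyField(np.zeros(lin.band.shape), np.zeros(lin.lowpass.shape))
        vis = sv.reconstruct_visible(lin, acc0, bank, boundary="wrap")
        assert np.allclose(vis.opponent.achr, 0.0, atol=1e-9)
        assert np.ptp(vis.rgb.reshape(-1, 3), axis=0).max() < 1e-6

    def test_unit_accuracy_recovers_coverage_content(self, scene_calib):
        # band-limited content within every zone's coverage comes back nearly
        # unchanged
        bank = scene_calib.bank
        fmin = min(z.peaks[sv.ChannelId.ACHR][0] for z in bank.zones)
        rng = np.random.default_rng(0)
        n = 512
        F = np.fft.fft2(rng.standard_normal((n, n)))
        fr = np.hypot(*np.meshgrid(np.fft.fftfreq(n, 1 / 16.0),
                                   np.fft.fftfreq(n, 1 / 16.0)))
        keep = (fr > 0.1) & (fr < fmin * 0.9)
        plane = np.real(np.fft.ifft2(F * keep / np.maximum(fr, 1e-6)))
        plane *= 0.3 / np.abs(plane).max()
        opp = sv.OpponentImage(plane, np.zeros_like(plane), np.zeros_like(plane))
        lin = sv.linear_responses(opp, bank, channels=(sv.ChannelId.ACHR,),
                                  boundary="wrap")
        acc1 = AccuracyField(np.ones(lin.band.shape), np.ones(lin.lowpass.shape))
        vis = sv.reconstruct_visible(lin, acc1, bank, boundary="wrap")
        err = np.linalg.norm(vis.opponent.achr - plane) / np.linalg.norm(plane)
        assert err < 0.05

    def test_idempotent_for_suprathreshold_grating(self, scene_calib):
        # content already restricted to visible bands passes through the model
        # almost unchanged on a second pass
        bank = scene_calib.bank
        x = bank.grid.x_deg()[None, :]
        plane = 0.6 * np.cos(2 * np.pi * 1.0 * x) * np.ones(bank.grid.shape)

        def run(p):
            opp = sv.OpponentImage(p, np.zeros_like(p), np.zeros_like(p))
            lin = sv.linear_responses(opp, bank, channels=(sv.ChannelId.ACHR,))
            resp = field_responses(lin, scene_calib)
            return sv.reconstruct_visible(lin, accuracy_field(resp), bank)

        v1 = run(plane).opponent.achr
        v2 = run(v1).opponent.achr
        assert np.linalg.norm(v2 - v1) / np.linalg.norm(v1) < 0.05

    def test_subthreshold_pattern_vanishes(self, scene_calib):
        bank = scene_calib.bank
        x = bank.grid.x_deg()[None, :]
        carrier = np.cos(2 * np.pi * 1.0 * x) * np.ones(bank.grid.shape)

        def visible_energy(contrast):
            p = contrast * carrier
            opp = sv.OpponentImage(p, np.zeros_like(p), np.zeros_like(p))
            lin = sv.linear_responses(opp, bank, channels=(sv.ChannelId.ACHR,))
            resp = field_responses(lin, scene_calib)
            vis = sv.reconstruct_visible(lin, accuracy_field(resp), bank)
            return np.abs(vis.opponent.achr).max() / contrast

        assert visible_energy(0.001) < 0.05   # far below threshold: removed
        assert visible_energy(0.6) > 0.8      # far above: survives


@pytest.fixture(scope="module")
def analysis(scene_calib):
    rgb = sv.make_synthetic_scene(sv.SceneSpec(seed=11, size_px=512))
    return sv.analyze_scene(rgb, scene_calib, sv.SamplingRule(),
                            boundary="wrap")


class TestProfilesAndSummary:
    def test_profile_fields_and_ranges(self, analysis):
        df = analysis.profile.to_frame()
        assert len(df) == 31  # 1-degree steps along the midline, 0..30
        ent = df.entropy_bits.dropna()
        assert ((ent >= 0) & (ent <= 8)).all()
        assert ((df.edge_density >= 0) & (df.edge_density <= 1)).all()
        qcols = [f"q{int(100 * q)}" for q in SATURATION_QUANTILES]
        assert (df[qcols].to_numpy() >= -1e-9).all()
        # quantiles are ordered
        assert np.all(np.diff(df[qcols].to_numpy(), axis=1) >= -1e-9)

    def test_window_validity_flags(self, analysis):
        df = analysis.profile.to_frame()
        # the foveal window extends past the left field edge (1 deg margin)
        assert not bool(df.valid.iloc[0])
        assert bool(df.valid.iloc[5])

    def test_desaturated_scene_entropy_undefined(self, scene_calib):
        # moderate-contrast grayscale input (kept inside the sRGB gamut so
        # reconstruction clipping cannot manufacture chroma)
        field = sv.make_synthetic_scene(
            sv.SceneSpec(seed=5, size_px=512, saturation_shape=(1.0, 1e6),
                         value_contrast=0.15, edge_amplitude=(0.05, 0.1))
        )[:, :, 1]
        gray = np.repeat(field[..., None], 3, axis=-1)
        res = sv.analyze_scene(gray, scene_calib, sv.SamplingRule(),
                               boundary="wrap")
        assert np.all(np.isnan(res.profile.entropy_bits))

    def test_summary_bands_and_attention_adjustment(self, analysis):
        prof = analysis.profile
        table = sv.summarize(prof, prof, attention_factor=0.75)
        assert set(table.band) == {"parafovea", "periphery"}
        un = table[(table.condition == "unattended")]
        assert np.allclose(un.beta_adjusted, un.beta_mean * 0.75)
        att = table[table.condition == "attended"]
        # identical profiles: attended and unattended statistics agree
        assert np.allclose(att.edge_density.to_numpy(),
                           un.edge_density.to_numpy())

    def test_summary_grid_mismatch_rejected(self, analysis):
        prof = analysis.profile
        other = EccentricityProfile(
            eccentricities=prof.eccentricities[:-1],
            saturation_quantiles=prof.saturation_quantiles.iloc[:-1],
            entropy_bits=prof.entropy_bits[:-1],
            edge_density=prof.edge_density[:-1],
            beta_mean=prof.beta_mean[:-1],
            valid=prof.valid[:-1],
        )
        with pytest.raises(ValueError):
            sv.summarize(prof, other)

    def test_attention_reduces_every_accuracy(self, scene_calib):
        rgb = sv.make_synthetic_scene(sv.SceneSpec(seed=12, size_px=512))
        lin = sv.linear_responses(sv.to_opponent(rgb), scene_calib.bank,
                                  boundary="wrap")
        att = accuracy_field(field_responses(lin, scene_calib))
        un = accuracy_field(field_responses(
            lin, scene_calib, sv.apply_attention(scene_calib.tp, 0.75)))
        assert np.all(un.band <= att.band + 1e-9)
        assert np.all(un.lowpass <= att.lowpass + 1e-9)
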