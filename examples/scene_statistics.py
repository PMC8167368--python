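"""Colourfulness and sharpness of a synthetic panorama across eccentricity.

Generates a colourful, approximately scale-invariant scene, runs the full
model (opponent transform, filter bank, transducer, accuracy-weighted
visible-image reconstruction) and samples saturation quantiles, hue entropy,
edge density and apparent blur in attention-scaled windows along the
horizontal midline; then summarizes parafoveal (<5 deg) versus peripheral
(>15 deg) means for attended and unattended (Rmax reduced 25%) states.
"""

import spatialvision as sv

grid = sv.VisualFieldGrid.scene_scaled(512)
bank = sv.build_bank(grid, zoning_step_octaves=0.25)
calib = sv.calibrate_bank(bank, sv.TransducerParams())
rgb = sv.make_synthetic_scene(sv.SceneSpec(seed=1, size_px=512))
rule = sv.SamplingRule(kind="scaled")

attended = sv.analyze_scene(rgb, calib, rule, boundary="wrap")
unattended = sv.analyze_scene(rgb, calib, rule,
                              sv.apply_attention(calib.tp, 0.75),
                              boundary="wrap")

print(attended.profile.to_frame().round(3).to_string(index=False))
print()
table = sv.summarize(attended.profile, unattended.profile,
                     attention_factor=0.75)
print(table.round(3).to_string(index=False))
print("""
Quality statistics are close to flat across eccentricity under the scaled
sampling rule; withdrawing attention lowers saturation and edge density
modestly while hue entropy barely moves.""")
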