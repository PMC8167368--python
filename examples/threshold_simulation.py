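"""Simulate grating detection thresholds through the full model front end.

Builds the eccentricity-scaled filter bank on a horizontal strip of the
visual field, calibrates every mechanism from the sensitivity model, and
finds the contrast at which a Gabor patch elicits a peak cross-frequency
response of d' = 2 (the simulated detection threshold). Compares against the
closed-form sensitivity model at the same frequency and eccentricity.
"""

import spatialvision as sv

grid = sv.VisualFieldGrid.horizontal_strip(max_ecc_deg=12, px_per_deg=48,
                                           height_deg=10)
bank = sv.build_bank(grid)
calib = sv.calibrate_bank(bank, sv.TransducerParams())

print("channel   f (cpd)  E (deg)  simulated t   closed-form t")
for ch, E in ((sv.ChannelId.ACHR, 0.0), (sv.ChannelId.ACHR, 10.0),
              (sv.ChannelId.RG, 0.0)):
    f = bank.zone_of_eccentricity(E).peaks[ch][1]
    spec = sv.GaborSpec(f=f, center=(E, 0.0), envelope_sigma=min(3.0 / f, 3.0),
                        channel=ch)
    res = sv.find_threshold(calib, spec)
    closed = sv.detection_threshold(f, E, ch)
    print(f"{ch.value:6s}  {f:7.2f}  {E:6.1f}   {res.threshold:10.4f}   {closed:10.4f}")

print("""
Simulated thresholds sit a few percent above the closed form: the grating's
45-degree-neighbour filters feed the divisive normalization pool and
self-suppress the target, an interaction the mechanism calibration
deliberately ignores (thresholds are measured without masks).""")
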