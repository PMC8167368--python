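"""Closed-form contrast sensitivity and acuity across the visual field.

Prints detection thresholds (Michelson contrast) for each colour-opponent
channel over spatial frequency and eccentricity, and the acuity limit (the
frequency where threshold reaches 1). Sensitivity is 1/threshold: smaller
numbers mean more sensitive.
"""

import numpy as np

import spatialvision as sv

for ch in sv.CHANNELS:
    print(f"\n{ch.value} channel")
    print("  E (deg)   t(1 cpd)   t(4 cpd)   acuity (cpd)   band peaks (cpd)")
    for E in (0.0, 5.0, 10.0, 20.0):
        t1 = sv.detection_threshold(1.0, E, ch)
        t4 = sv.detection_threshold(4.0, E, ch)
        ac = sv.acuity_limit(E, ch)
        peaks = ", ".join(f"{p:.2f}" for p in sv.peak_frequencies(E, ch))
        print(f"  {E:5.1f}   {t1:9.4f}  {t4:9.3f}   {ac:8.2f}       [{peaks}]")

print("""
Thresholds rise (sensitivity falls) with eccentricity and, above the
low-frequency plateau, exponentially with spatial frequency; the red-green
channel declines fastest with eccentricity (E2 = 1.82 deg vs 6.22 for
luminance). The filter bank places its finest band at one third of the local
acuity limit, with coarser bands one octave apart.""")
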