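"""Contrast sensitivity over spatial frequency, eccentricity and colour channel.

The model expresses threshold (Michelson) contrast for a grating of spatial
frequency ``f`` (cycles/degree) at retinal eccentricity ``E`` (degrees) as

    t(f, E) = t0 * exp( (f / f0) * (E + E2) / E2 ) * L(f)
    L(f)    = 1 + alpha / (1 + (f / f1)**2)

The exponential term carries the intertwined high-frequency and eccentricity
declines of sensitivity (both exponential, with the frequency decline becoming
steeper as eccentricity grows); ``L`` carries the low-frequency plateau, which
is independent of eccentricity so that sensitivity across the visual field
converges for very low spatial frequencies.

Three colour-opponent channels are modelled: achromatic luminance contrast
(Achr), blue-yellow (BY) and red-green (RG), each with its own parameter set.
The acuity limit at an eccentricity is the frequency where threshold contrast
reaches 1; filter peak frequencies are derived from it (finest band at one
third of acuity, coarser bands one octave apart).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq


class ChannelId(str, enum.Enum):
    """The three colour-opponent channels."""

    ACHR = "Achr"
    BY = "BY"
    RG = "RG"

    @property
    def n_bands(self) -> int:
        """Number of band-pass scales carried by the channel.

        The achromatic channel carries four octave-spaced band-pass scales;
        the chromatic channels carry three (their acuity is lower, so a
        fourth, finer scale would have no support).
        """
        return 4 if self is ChannelId.ACHR else 3


# Octave spacing of band peak frequencies below the acuity limit: the finest
# band sits at acuity/3 and coarser bands at acuity/6, /12, /24.
BAND_DIVISORS: tuple[int, ...] = (3, 6, 12, 24)


@dataclass(frozen=True)
class ChannelParams:
    """Sensitivity parameters for one colour channel.

    Parameters
    ----------
    t0 : float
        Overall threshold amplitude (dimensionless Michelson contrast).
    E2_ecc : float
        Eccentricity (deg) at which the effective spatial scale of the
        sensitivity function doubles.
    alpha : float
        Weight of the low-spatial-frequency threshold elevation (the plateau
        level is ``t0 * (1 + alpha)``).
    f0 : float
        High-spatial-frequency decline constant (cpd).
    f1 : float
        Low-spatial-frequency decline constant (cpd).
    gain_g : float
        Linear filter gain. It does not enter the empirical threshold
        surface; it only enters transducer calibration, where contrast and
        threshold always appear as ``g*c`` and ``g*t``.
    """

    t0: float
    E2_ecc: float
    alpha: float
    f0: float
    f1: float
    gain_g: float

    def __post_init__(self) -> None:
        for name in ("t0", "E2_ecc", "alpha", "f0", "f1", "gain_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ChannelParams.{name} must be strictly positive")


#: Default parameterization of the contrast sensitivity model.
DEFAULT_PARAMS: Mapping[ChannelId, ChannelParams] = {
    ChannelId.ACHR: ChannelParams(
        t0=0.0051, E2_ecc=6.22, alpha=5.26, f0=4.51, f1=0.32, gain_g=2.5
    ),
    ChannelId.BY: ChannelParams(
        t0=0.0051, E2_ecc=6.22, alpha=5.26, f0=4.51 / 6, f1=0.32, gain_g=1.0
    ),
    ChannelId.RG: ChannelParams(
        t0=0.0082, E2_ecc=1.82, alpha=2.53, f0=5.37, f1=0.94, gain_g=2.0
    ),
}


def get_params(ch: ChannelId, params: ChannelParams | None = None) -> ChannelParams:
    """Resolve explicit params or fall back to the channel default."""
    return DEFAULT_PARAMS[ChannelId(ch)] if params is None else params


def low_frequency_plateau(f, params: ChannelParams):
    """The eccentricity-independent low-frequency threshold elevation L(f)."""
    f = np.asarray(f, dtype=float)
    return 1.0 + params.alpha / (1.0 + (f / params.f1) ** 2)


def detection_threshold(f, E, ch: ChannelId, params: ChannelParams | None = None):
    """Michelson-contrast detection threshold t(f, E) for one channel.

    Parameters
    ----------
    f : array_like
        Spatial frequency in cycles per degree (>= 0).
    E : array_like
        Eccentricity in degrees (>= 0).
    ch : ChannelId
        Colour channel.
    params : ChannelParams, optional
        Override the channel's default parameters.

    Returns
    -------
    ndarray or float
        Threshold contrast, strictly positive. At ``f = 0`` the value is
        ``t0 * (1 + alpha)`` independent of eccentricity.
    """
    p = get_params(ch, params)
    f = np.asarray(f, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(f < 0):
        raise ValueError("spatial frequency must be non-negative")
    if np.any(E < 0):
        raise ValueError("eccentricity must be non-negative")
    t = p.t0 * np.exp((f / p.f0) * (E + p.E2_ecc) / p.E2_ecc) * low_frequency_plateau(f, p)
    return t if t.ndim else float(t)


def acuity_limit(E, ch: ChannelId, params: ChannelParams | None = None,
                 *, f_max: float = 200.0, tol: float = 1e-6):
    """Acuity limit: the frequency (cpd) where threshold contrast reaches 1.

    Found by bracketed bisection; threshold is monotone increasing in ``f``
    above the plateau so the root is unique. Strictly decreasing in ``E``.
    """
    p = get_params(ch, params)

    def solve(e: float) -> float:
        # work with log-threshold directly: the exponent overflows at large f
        def g(f: float) -> float:
            return (math.log(p.t0) + (f / p.f0) * (e + p.E2_ecc) / p.E2_ecc
                    + math.log(low_frequency_plateau(f, p)))
        lo = 1e-6
        if g(lo) >= 0:  # threshold already >= 1 at ~zero frequency
            return lo
        return brentq(g, lo, f_max, xtol=tol)

    E_arr = np.asarray(E, dtype=float)
    if np.any(E_arr < 0):
        raise ValueError("eccentricity must be non-negative")
    if E_arr.ndim == 0:
        return solve(float(E_arr))
    return np.array([solve(float(e)) for e in E_arr.ravel()]).reshape(E_arr.shape)


def peak_frequencies(E: float, ch: ChannelId,
                     params: ChannelParams | None = None) -> list[float]:
    """Band-pass peak frequencies (cpd) at eccentricity ``E``, finest first.

    The finest peak is one third of the local acuity limit; successive peaks
    lie one octave apart (divisors 3, 6, 12, 24). The achromatic channel gets
    four bands, chromatic channels three.
    """
    ch = ChannelId(ch)
    acuity = acuity_limit(E, ch, params)
    return [acuity / d for d in BAND_DIVISORS[: ch.n_bands]]


@dataclass
class ThresholdSurface:
    """A grid of detection thresholds over frequency and eccentricity."""

    frequencies: Sequence[float]
    eccentricities: Sequence[float]
    thresholds: np.ndarray  # shape (len(frequencies), len(eccentricities))
    channel: ChannelId

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        expected = (len(self.frequencies), len(self.eccentricities))
        if self.thresholds.shape != expected:
            raise ValueError(
                f"threshold grid shape {self.thresholds.shape} != {expected}"
            )
        if np.any(self.thresholds <= 0):
            raise ValueError("thresholds must be strictly positive")

    @classmethod
    def from_model(cls, frequencies: Sequence[float], eccentricities: Sequence[float],
                   ch: ChannelId, params: ChannelParams | None = None
                   ) -> "ThresholdSurface":
        f = np.asarray(frequencies, dtype=float)[:, None]
        E = np.asarray(eccentricities, dtype=float)[None, :]
        grid = detection_threshold(f, E, ch, params)
        return cls(list(map(float, np.ravel(frequencies))),
                   list(map(float, np.ravel(eccentricities))), grid, ChannelId(ch))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns channel, f_cpd, E_deg, threshold."""
        rows = [
            (self.channel.value, f, E, self.thresholds[i, j])
            for i, f in enumerate(self.frequencies)
            for j, E in enumerate(self.eccentricities)
        ]
        return pd.DataFrame(rows, columns=["channel", "f_cpd", "E_deg", "threshold"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
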