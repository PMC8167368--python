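"""Nonlinear contrast transduction and signal-detection arithmetic.

The linear contrast magnitude ``c`` of each filter is transduced to a
signal-to-noise ratio (d') by a divisive-normalization (Foley) transducer:

    d' = Rmax * (g*c)^(p+q) / ( z^p + sum_theta (g*c_theta)^p )

where the denominator sum runs over the same-location, same-frequency,
same-channel filters at all orientations (the target's own response plus
cross-orientation terms), producing dipper-shaped contrast-discrimination
functions and cross-orientation masking. The per-filter threshold parameter
``z`` is calibrated so that a stimulus at the empirical detection threshold
``t`` elicits exactly the experimental criterion d' (2 in all simulations):

    z^p = (Rmax / d_exp) * (g*t)^(p+q) - (g*t)^p

Accuracy maps d' onto [0, 1] as the largest hit-rate/false-alarm-rate
difference of an unbiased yes/no observer: ``Phi(d'/2) - Phi(-d'/2)``.

Withdrawing spatial attention is modelled as a multiplicative reduction of
``Rmax`` (default 0.75, i.e. Rmax 30 -> 22.5) with the calibration ``z``
frozen at its attended values: attention changes the response state, not the
mechanism's noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.special import ndtr


@dataclass(frozen=True)
class TransducerParams:
    """Parameters of the nonlinear contrast response.

    Rmax : nonlinear gain (response ceiling scale), default 30.
    p, q : low- and high-contrast exponents (2 and 0.4); the transducer is
        expansive (slope p+q) at low contrast and compressive (slope q) at
        high contrast.
    d_exp : the experimental d' criterion used for threshold calibration (2,
        an unbiased yes/no hit rate of ~84%).
    M : cross-scale pooling norm (4, a deliberately sub-optimal combination).
    w_x : weight of cross-orientation inputs in the normalization pool.
    attention_factor : multiplier on Rmax; 1.0 = attended, 0.75 = unattended.
    """

    Rmax: float = 30.0
    p: float = 2.0
    q: float = 0.4
    d_exp: float = 2.0
    M: float = 4.0
    w_x: float = 1.0
    attention_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.Rmax <= 0:
            raise ValueError("Rmax must be positive")
        if not (self.p > self.q > 0):
            raise ValueError("exponents must satisfy p > q > 0")
        if self.M < 1:
            raise ValueError("pooling norm M must be >= 1")
        if not (0 < self.attention_factor <= 1):
            raise ValueError("attention_factor must be in (0, 1]")

    @property
    def effective_rmax(self) -> float:
        return self.Rmax * self.attention_factor


class CalibrationError(ValueError):
    """Raised when a mechanism's empirical threshold cannot be inverted."""


def threshold_z(t: float, gain_g: float, tp: TransducerParams, *,
                label: str = "") -> float:
    """Invert the transducer at the detection criterion to get z.

    Given an empirical threshold contrast ``t`` the threshold parameter
    satisfies ``z^p = (Rmax/d_exp)*(g t)^(p+q) - (g t)^p``; plugging ``c = t``
    back into the mask-free transducer then returns d' = d_exp exactly.
    Calibration always uses the attended Rmax.
    """
    if t <= 0:
        raise CalibrationError(f"threshold must be positive {label}".strip())
    gt = gain_g * t
    zp = (tp.Rmax / tp.d_exp) * gt ** (tp.p + tp.q) - gt ** tp.p
    if zp < 0:
        raise CalibrationError(
            f"(g*t)^q must exceed d_exp/Rmax; threshold too low to calibrate "
            f"{label}".strip()
        )
    return float(zp ** (1.0 / tp.p))


def transduce(c, z, gain_g: float, tp: TransducerParams,
              mask_responses: Iterable[float] | np.ndarray | None = None):
    """Transduce linear contrast magnitude(s) to d'.

    ``c`` may be a scalar or array. The normalization pool always contains the
    target's own response ``(g c)^p`` plus ``z^p``; ``mask_responses`` are
    same-location, same-frequency, same-channel magnitudes at the *other*
    orientations, entering at weight ``w_x``. ``Rmax`` is scaled by the
    attention factor; ``z`` is not.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("contrast magnitude must be non-negative")
    gc = gain_g * c
    denom = np.asarray(z, dtype=float) ** tp.p + gc ** tp.p
    if mask_responses is not None:
        gm = gain_g * np.asarray(list(np.atleast_1d(mask_responses)), dtype=float)
        denom = denom + tp.w_x * np.sum(gm ** tp.p)
    with np.errstate(invalid="ignore"):
        d = tp.effective_rmax * gc ** (tp.p + tp.q) / denom
    d = np.where(gc == 0, 0.0, d)
    return float(d) if d.ndim == 0 else d


def pool_scales(d_values, M: float = 4.0):
    """Pool per-band d' across scales with an M-norm: (sum d^M)^(1/M).

    Applied along the last axis for array input. With M = 4 four equal values
    v pool to v*4^(1/4) = v*sqrt(2); as M -> infinity the pool tends to the
    maximum.
    """
    d = np.asarray(d_values, dtype=float)
    if np.any(d < 0):
        raise ValueError("pooled responses must be non-negative")
    return np.sum(d ** M, axis=-1) ** (1.0 / M)


def accuracy(d_prime):
    """Map d' to accuracy in [0, 1]: Phi(d'/2) - Phi(-d'/2).

    The greatest achievable difference between the yes/no hit rate and false
    alarm rate for an unbiased observer at sensitivity d'.
    """
    d = np.asarray(d_prime, dtype=float)
    if np.any(d < 0):
        raise ValueError("d' must be non-negative")
    a = ndtr(d / 2.0) - ndtr(-d / 2.0)
    return float(a) if a.ndim == 0 else a


def apply_attention(tp: TransducerParams, factor: float) -> TransducerParams:
    """Return params with the attention factor set (calibration unchanged)."""
    if not (0 < factor <= 1):
        raise ValueError("attention factor must be in (0, 1]")
    return replace(tp, attention_factor=factor)


def detection_threshold_from_z(z: float, gain_g: float, tp: TransducerParams,
                               *, tol: float = 1e-10) -> float:
    """Solve the mask-free transducer for the contrast where d' = d_exp.

    Used to re-simulate detection thresholds after a response-state change
    (e.g. reduced Rmax under inattention) with ``z`` held at its attended
    calibration. Solved by bisection in log-contrast; the mask-free transducer
    is strictly increasing in contrast.
    """
    from scipy.optimize import brentq

    f = lambda logc: transduce(np.exp(logc), z, gain_g, tp) - tp.d_exp
    lo, hi = np.log(1e-8), np.log(1e4)
    if f(hi) < 0:
        raise ValueError("criterion unreachable at any contrast")
    return float(np.exp(brentq(f, lo, hi, xtol=tol)))


# --------------------------------------------------------------------------
# field-level calibration and responses
# --------------------------------------------------------------------------

from dataclasses import dataclass as _dataclass  # noqa: E402

import pandas as pd  # noqa: E402

from .csf_core import detection_threshold  # noqa: E402
from .filterbank import CHANNELS, FilterBank, LinearResponseField  # noqa: E402


@_dataclass
class CalibratedBank:
    """Per-mechanism threshold parameters z for a filter bank.

    ``z_band[zone, channel, band]`` and ``z_lowpass[zone, channel]`` (z does
    not depend on orientation: detection thresholds are established without
    masks). Calibration always uses the attended Rmax; attention later scales
    only the response.
    """

    bank: FilterBank
    tp: TransducerParams
    z_band: np.ndarray
    z_lowpass: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Calibration table: zone, channel, band, f_peak, threshold t, z."""
        rows = []
        for z in self.bank.zones:
            for ci, ch in enumerate(CHANNELS):
                p = self.bank.params[ch]
                for b, fp in enumerate(z.peaks[ch]):
                    t = detection_threshold(fp, z.representative_E, ch, p)
                    rows.append((z.zone_index, ch.value, b, fp, t,
                                 self.z_band[z.zone_index, ci, b]))
                t_lp = p.t0 * (1.0 + p.alpha)
                rows.append((z.zone_index, ch.value, -1, 0.0, t_lp,
                             self.z_lowpass[z.zone_index, ci]))
        return pd.DataFrame(
            rows, columns=["zone", "channel", "band", "f_peak_cpd",
                           "threshold", "z"])


def calibrate_bank(bank: FilterBank, tp: TransducerParams) -> CalibratedBank:
    """Set each mechanism's z from the empirical threshold at its tuning.

    Band-pass mechanisms are calibrated at their peak frequency and the
    zone's representative eccentricity; the low-pass residual at the
    frequency-zero plateau threshold ``t0 * (1 + alpha)``, which is identical
    at all eccentricities.
    """
    n_zones = len(bank.zones)
    n_bands = bank.max_bands()
    z_band = np.full((n_zones, len(CHANNELS), n_bands), np.nan)
    z_lp = np.full((n_zones, len(CHANNELS)), np.nan)
    for zone in bank.zones:
        for ci, ch in enumerate(CHANNELS):
            p = bank.params[ch]
            for b, fp in enumerate(zone.peaks[ch]):
                t = detection_threshold(fp, zone.representative_E, ch, p)
                z_band[zone.zone_index, ci, b] = threshold_z(
                    t, p.gain_g, tp,
                    label=f"(zone {zone.zone_index}, {ch.value}, band {b})")
            t_lp = p.t0 * (1.0 + p.alpha)
            z_lp[zone.zone_index, ci] = threshold_z(
                t_lp, p.gain_g, tp,
                label=f"(zone {zone.zone_index}, {ch.value}, low-pass)")
    return CalibratedBank(bank, tp, z_band, z_lp)


@_dataclass
class ResponseField:
    """Transduced d' responses on the grid.

    ``d_band`` has shape (n_channels, n_bands, n_orientations, H, W);
    ``d_lowpass`` (n_channels, H, W); ``pooled`` is the M-norm across bands
    per (channel, orientation); ``cross_frequency`` the maximum of the pooled
    values over channel and orientation at each pixel.
    """

    bank: FilterBank
    tp: TransducerParams
    d_band: np.ndarray
    d_lowpass: np.ndarray

    @property
    def pooled(self) -> np.ndarray:
        d = np.moveaxis(self.d_band, 1, -1)  # bands last
        return pool_scales(d, self.tp.M)

    @property
    def cross_frequency(self) -> np.ndarray:
        return self.pooled.max(axis=(0, 1))


def field_responses(linear: LinearResponseField, calib: CalibratedBank,
                    tp: TransducerParams | None = None) -> ResponseField:
    """Transduce a linear response field to d' with cross-orientation masking.

    The normalization pool of each oriented mechanism contains its own
    response plus the other orientations' responses at the same pixel, band
    and channel (weight ``w_x``); the unoriented low-pass residual is
    transduced without cross terms. ``tp`` may override the calibration's
    transducer state (e.g. a reduced attention factor); z values stay frozen.
    """
    tp = calib.tp if tp is None else tp
    bank = calib.bank
    mag = np.abs(linear.band)          # (C, B, O, H, W)
    n_zones = len(bank.zones)

    # broadcast z per pixel via the zone index map
    zidx = bank.zone_index_map          # (H, W)
    z_band_px = calib.z_band[zidx]      # (H, W, C, B)
    z_band_px = np.moveaxis(z_band_px, (2, 3), (0, 1))  # (C, B, H, W)
    z_lp_px = np.moveaxis(calib.z_lowpass[zidx], 2, 0)  # (C, H, W)

    gains = np.array([bank.params[ch].gain_g for ch in CHANNELS])
    g = gains[:, None, None, None, None]
    gm = (g * mag) ** tp.p
    pool = np.nansum(gm, axis=2, keepdims=True)         # sum over orientations
    denom = (np.nan_to_num(z_band_px[:, :, None]) ** tp.p
             + gm + tp.w_x * (pool - gm))
    with np.errstate(invalid="ignore", divide="ignore"):
        d_band = tp.effective_rmax * (g * mag) ** (tp.p + tp.q) / denom
    d_band = np.nan_to_num(d_band)

    lp_mag = np.abs(linear.lowpass)
    glp = gains[:, None, None]
    denom_lp = z_lp_px ** tp.p + (glp * lp_mag) ** tp.p
    d_lp = tp.effective_rmax * (glp * lp_mag) ** (tp.p + tp.q) / denom_lp
    return ResponseField(bank, tp, d_band.astype(np.float32),
                         np.nan_to_num(d_lp).astype(np.float32))


@_dataclass
class AccuracyField:
    """Accuracy-mapped responses: values in [0, 1], monotone in d'."""

    band: np.ndarray
    lowpass: np.ndarray


def accuracy_field(resp: ResponseField) -> AccuracyField:
    return AccuracyField(accuracy(resp.d_band), accuracy(resp.d_lowpass))
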