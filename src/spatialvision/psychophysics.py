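"""Simulated psychophysical experiments on the calibrated model.

Detection thresholds are obtained exactly as in a threshold experiment: the
stimulus contrast is adjusted iteratively (Newton's method in log contrast,
with a bisection fallback) until the peak cross-frequency response — the
maximum over channels and orientations of the M-norm-pooled d' across scales
— equals the experimental criterion d' = 2.

Because the front end is linear, the complex filter responses to a
unit-contrast stimulus are computed once and rescaled inside the iteration,
which makes the search cheap: each candidate contrast costs only pointwise
transducer arithmetic over the stimulus neighbourhood.

The module also provides contrast-discrimination (dipper) curves with
optional cross-oriented masks, the apparent-blur statistic beta (the slope of
the per-scale response against log peak frequency, normalized by the pooled
response), the fovea/periphery blur-matching experiment, and the
attention-withdrawal threshold elevation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

from .csf_core import ChannelId, ThresholdSurface, detection_threshold
from .filterbank import (
    CHANNELS,
    OpponentImage,
    VisualFieldGrid,
    linear_responses,
)
from .response_model import (
    CalibratedBank,
    TransducerParams,
    apply_attention,
    detection_threshold_from_z,
    pool_scales,
    threshold_z,
)
from .stimuli import EdgeSpec, GaborSpec, make_blurred_edge, make_gabor

#: Default test eccentricities of the blur experiments: fovea plus five
#: peripheral positions.
BLUR_ECCENTRICITIES: tuple[float, ...] = (0.0, 8.3, 16.7, 24.0, 32.0, 40.0)

#: Default eleven Gaussian-blur scale constants (arcmin). The range spans the
#: monotone limb of the foveal apparent-blur curve; beyond ~13 arcmin even the
#: coarsest foveal filters stop responding and the statistic folds back
#: toward zero.
DEFAULT_BLUR_LEVELS: tuple[float, ...] = tuple(np.linspace(0.0, 12.0, 11))


# --------------------------------------------------------------------------
# threshold search
# --------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    stimulus: object
    threshold: float
    iterations: int
    converged: bool
    peak_response: float
    unresolvable: bool = False


class _UnitResponses:
    """Complex unit-contrast responses of the bank near a stimulus.

    Stores per-pixel complex responses (channel, band, orientation, pixel)
    and the matching z values, restricted to a region of interest; the
    response to the stimulus at contrast c is c times these, so threshold
    search never repeats the filtering.
    """

    def __init__(self, calib: CalibratedBank, img: OpponentImage,
                 roi: np.ndarray, channels=CHANNELS):
        bank = calib.bank
        lin = linear_responses(img, bank, channels=channels, pixel_mask=roi)
        sel = np.where(roi.ravel())[0]
        C, B, O, H, W = lin.band.shape
        self.band = lin.band.reshape(C, B, O, -1)[..., sel]
        self.lowpass = lin.lowpass.reshape(C, -1)[..., sel]
        zidx = bank.zone_index_map.ravel()[sel]
        self.z_band = np.moveaxis(calib.z_band[zidx], (1, 2), (0, 1))  # (C,B,px)
        self.z_lp = calib.z_lowpass[zidx].T                            # (C,px)
        self.gains = np.array([bank.params[ch].gain_g for ch in CHANNELS])
        self.tp = calib.tp

    def cross_frequency(self, scale: complex | float,
                        tp: TransducerParams | None = None,
                        extra: "_UnitResponses | None" = None,
                        extra_scale: complex | float = 0.0) -> float:
        """Peak cross-frequency d' for the stimulus scaled by ``scale``
        (optionally superposed with a second stimulus, e.g. a mask)."""
        tp = self.tp if tp is None else tp
        band = self.band * scale
        lp = self.lowpass * scale
        if extra is not None:
            band = band + extra.band * extra_scale
            lp = lp + extra.lowpass * extra_scale
        mag = np.abs(band)
        g = self.gains[:, None, None, None]
        gm = np.nan_to_num((g * mag) ** tp.p)
        pool = gm.sum(axis=2, keepdims=True)
        denom = np.nan_to_num(self.z_band[:, :, None]) ** tp.p + gm \
            + tp.w_x * (pool - gm)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = tp.effective_rmax * (g * mag) ** (tp.p + tp.q) / denom
        d = np.nan_to_num(d)
        glp = self.gains[:, None]
        mlp = np.abs(lp)
        d_lp = tp.effective_rmax * (glp * mlp) ** (tp.p + tp.q) / (
            self.z_lp ** tp.p + (glp * mlp) ** tp.p)
        d_lp = np.nan_to_num(d_lp)
        # pool across scale (bands plus the unoriented low-pass residual)
        stack = np.concatenate(
            [np.moveaxis(d, 1, -1),
             np.broadcast_to(d_lp[:, None, :, None],
                             (*d.shape[:1], d.shape[2], d.shape[3], 1))],
            axis=-1)
        pooled = pool_scales(stack, tp.M)
        return float(pooled.max())


def _stimulus_roi(spec: GaborSpec, grid: VisualFieldGrid,
                  radius_sigma: float = 1.0) -> np.ndarray:
    """Probe region for threshold search: pixels within ``radius_sigma``
    envelope sigmas of the stimulus centre.

    The response peak of the target-centred mechanism lies here; a wider
    probe would instead read out mechanisms centred at lower eccentricities,
    where sensitivity is higher, and report their thresholds."""
    x = grid.x_deg()[None, :]
    y = grid.y_deg()[:, None]
    r2 = (x - spec.center[0]) ** 2 + (y - spec.center[1]) ** 2
    radius = min(radius_sigma * spec.envelope_sigma, 0.5)
    roi = r2 <= radius ** 2
    if not np.any(roi):
        roi = r2 <= np.min(r2) + 1e-12
    return roi


def find_threshold(calib: CalibratedBank, spec: GaborSpec,
                   *, tp: TransducerParams | None = None,
                   tol: float = 0.01, max_iter: int = 50) -> ThresholdResult:
    """Detection threshold of a Gabor: contrast where the peak
    cross-frequency response equals the experimental d' criterion.

    Newton iteration in log contrast with a numerical derivative; if a step
    leaves the bracket established so far, it falls back to bisection. A
    stimulus that cannot reach the criterion at contrast 1 is flagged
    unresolvable (local acuity exceeded).
    """
    tp = calib.tp if tp is None else tp
    grid = calib.bank.grid
    unit = _UnitResponses(
        calib, make_gabor(GaborSpec(**{**spec.__dict__, "contrast": 1.0}), grid),
        _stimulus_roi(spec, grid), channels=(ChannelId(spec.channel),))

    target = tp.d_exp
    resp = lambda logc: unit.cross_frequency(np.exp(logc), tp)

    r1 = resp(0.0)
    if r1 < target:
        return ThresholdResult(spec, 1.0, 0, False, r1, unresolvable=True)

    lo, hi = np.log(1e-7), 0.0
    logc = np.log(0.01)
    r = resp(logc)
    it = 0
    while abs(r - target) > tol and it < max_iter:
        if r > target:
            hi = min(hi, logc)
        else:
            lo = max(lo, logc)
        h = 1e-4
        deriv = (resp(logc + h) - r) / h
        step = (target - r) / deriv if deriv > 0 else np.nan
        new = logc + step
        if not np.isfinite(new) or not (lo < new < hi):
            new = 0.5 * (lo + hi)
        logc = new
        r = resp(logc)
        it += 1
    return ThresholdResult(spec, float(np.exp(logc)), it,
                           abs(r - target) <= tol, r)


# --------------------------------------------------------------------------
# CSF simulation
# --------------------------------------------------------------------------

def _csf_envelope(f: float) -> float:
    """Gabor envelope used in the CSF simulations: several carrier cycles
    (a nearly flat carrier around the probe), clipped to keep stimuli inside
    the strip field. Vertical gratings continue exactly under the mirror
    padding, so a generous vertical extent costs nothing."""
    return float(np.clip(3.0 / f, 0.25, 4.0))


@dataclass
class CsfSimResult:
    surface: ThresholdSurface
    acuities: dict[float, float]     # eccentricity -> extrapolated acuity (cpd)
    unresolvable: np.ndarray          # bool grid (f, E)


def simulate_csf(calib: CalibratedBank, frequencies: Sequence[float],
                 eccentricities: Sequence[float], ch: ChannelId,
                 *, tp: TransducerParams | None = None) -> CsfSimResult:
    """Simulate grating detection thresholds over a frequency/eccentricity
    grid and extrapolate acuity from the high-frequency limb.

    Acuity at each eccentricity is where the extrapolated sensitivity curve
    reaches 1: the simulated log thresholds, corrected by the channel's known
    low-frequency plateau term, are regressed linearly against frequency (the
    exponential high-frequency limb) and the curve is solved for threshold 1.
    """
    ch = ChannelId(ch)
    thr = np.full((len(frequencies), len(eccentricities)), np.nan)
    unres = np.zeros_like(thr, dtype=bool)
    for j, E in enumerate(eccentricities):
        for i, f in enumerate(frequencies):
            spec = GaborSpec(f=f, theta=0.0, center=(float(E), 0.0),
                             envelope_sigma=_csf_envelope(f), contrast=0.5,
                             channel=ch)
            res = find_threshold(calib, spec, tp=tp)
            thr[i, j] = res.threshold
            unres[i, j] = res.unresolvable

    from .csf_core import get_params, low_frequency_plateau

    p = get_params(ch, calib.bank.params.get(ch))
    acuities: dict[float, float] = {}
    fs = np.asarray(frequencies, dtype=float)
    for j, E in enumerate(eccentricities):
        ok = ~unres[:, j]
        order = np.argsort(fs[ok])
        f_ok = fs[ok][order]
        t_ok = thr[ok, j][order]
        if len(f_ok) < 2:
            continue
        y = np.log(t_ok) - np.log(low_frequency_plateau(f_ok, p))
        slope, icpt = np.polyfit(f_ok, y, 1)
        if slope <= 0:
            continue
        g = lambda f: icpt + slope * f + np.log(low_frequency_plateau(f, p))
        if g(0.05) < 0 < g(500.0):
            acuities[float(E)] = float(brentq(g, 0.05, 500.0))
    surface = ThresholdSurface(list(map(float, frequencies)),
                               list(map(float, eccentricities)),
                               np.where(np.isnan(thr), 10.0, thr), ch)
    return CsfSimResult(surface, acuities, unres)


# --------------------------------------------------------------------------
# dipper (threshold versus contrast) curves
# --------------------------------------------------------------------------

def dipper_curve(calib: CalibratedBank, target: GaborSpec,
                 pedestal_contrasts: Sequence[float],
                 mask_contrast: float | None = None,
                 *, tol: float = 0.01, max_iter: int = 60) -> np.ndarray:
    """Increment thresholds on pedestals sharing the target's filter tuning.

    The increment criterion is a response difference: the peak
    cross-frequency response to pedestal-plus-increment exceeds the response
    to the pedestal alone by d_exp. An optional orthogonal mask (same
    frequency and position, rotated 90 degrees) at ``mask_contrast`` is
    superposed on both intervals, entering through the cross-orientation
    normalization pool.
    """
    tp = calib.tp
    grid = calib.bank.grid
    roi = _stimulus_roi(target, grid)
    ch = (ChannelId(target.channel),)
    unit = _UnitResponses(
        calib, make_gabor(GaborSpec(**{**target.__dict__, "contrast": 1.0}), grid),
        roi, channels=ch)
    mask_unit = None
    if mask_contrast is not None:
        mspec = GaborSpec(**{**target.__dict__, "contrast": 1.0,
                             "theta": (target.theta + 90.0) % 180.0})
        mask_unit = _UnitResponses(calib, make_gabor(mspec, grid), roi, channels=ch)

    def peak(c: float) -> float:
        return unit.cross_frequency(
            c, tp, extra=mask_unit,
            extra_scale=0.0 if mask_contrast is None else mask_contrast)

    out = np.empty(len(pedestal_contrasts))
    for k, cp in enumerate(pedestal_contrasts):
        base = peak(cp)
        g = lambda log_dc: peak(cp + np.exp(log_dc)) - base - tp.d_exp
        lo, hi = np.log(1e-7), np.log(2.0)
        if g(hi) < 0:
            out[k] = np.nan
            continue
        out[k] = float(np.exp(brentq(g, lo, hi, xtol=tol * 1e-2, maxiter=max_iter)))
    return out


# --------------------------------------------------------------------------
# apparent blur
# --------------------------------------------------------------------------

def beta_metric(responses: Sequence[float], f_peaks: Sequence[float],
                M: float = 4.0) -> float:
    """Apparent blur beta: slope of response against log peak frequency,
    normalized by the pooled (M-norm) response.

    Flat responses across scale give beta = 0; responses declining toward
    fine scales give beta < 0 (blurry); fine-scale-dominated responses give
    beta > 0 (oversharp). Returns 0 when the pooled response is 0.
    """
    R = np.asarray(responses, dtype=float)
    f = np.asarray(f_peaks, dtype=float)
    if R.size < 2:
        raise ValueError("need responses at two or more scales")
    pooled = pool_scales(R, M)
    if pooled == 0:
        return 0.0
    m = np.polyfit(np.log(f), R, 1)[0]
    return float(m / pooled)


def beta_at_probe(calib: CalibratedBank, img: OpponentImage,
                  probe_x_deg: float, *, probe_halfheight_deg: float = 0.125,
                  tp: TransducerParams | None = None) -> float:
    """Beta for the achromatic channel at one field location.

    Per-scale responses are the maximum over orientation of the achromatic
    band d' at the probe column, averaged over +/- ``probe_halfheight_deg``
    vertically.
    """
    tp = calib.tp if tp is None else tp
    bank = calib.bank
    grid = bank.grid
    x = grid.x_deg()
    y = grid.y_deg()
    col = int(np.argmin(np.abs(x - probe_x_deg)))
    rows = np.where(np.abs(y) <= probe_halfheight_deg)[0]
    roi = np.zeros(grid.shape, dtype=bool)
    roi[rows.min(): rows.max() + 1, col] = True

    lin = linear_responses(img, bank, channels=(ChannelId.ACHR,), pixel_mask=roi)
    zone = bank.zones[int(bank.zone_index_map[rows[0], col])]
    f_peaks = zone.peaks[ChannelId.ACHR]
    g = bank.params[ChannelId.ACHR].gain_g
    nb = len(f_peaks)
    mag = np.abs(lin.band[0, :nb, :, rows.min(): rows.max() + 1, col])  # (B,O,rows)
    z = calib.z_band[zone.zone_index, 0, :nb][:, None, None]
    gm = (g * mag) ** tp.p
    pool = gm.sum(axis=1, keepdims=True)
    denom = z ** tp.p + gm + tp.w_x * (pool - gm)
    d = tp.effective_rmax * (g * mag) ** (tp.p + tp.q) / denom
    R = d.max(axis=1).mean(axis=-1)   # max over orientation, mean over rows
    return beta_metric(R, f_peaks, tp.M)


# --------------------------------------------------------------------------
# blur matching experiment
# --------------------------------------------------------------------------

def _gaussian_curve(s, amp, width, offset):
    return amp * np.exp(-(s ** 2) / (2.0 * width ** 2)) + offset


@dataclass
class BetaCurveFit:
    eccentricity: float
    blur_levels: np.ndarray
    betas: np.ndarray
    amplitude: float
    width: float
    offset: float
    rmse: float

    def __post_init__(self) -> None:
        # width enters the Gaussian squared; normalize its sign
        self.width = abs(self.width)

    def predict(self, s):
        return _gaussian_curve(np.asarray(s, dtype=float),
                               self.amplitude, self.width, self.offset)

    def invert(self, beta: float) -> tuple[float, bool]:
        """Blur level whose fitted beta equals ``beta``; clamps (and flags)
        values outside the curve's range."""
        u = (beta - self.offset) / self.amplitude
        if u >= 1.0:
            return 0.0, True
        if u <= 0.0:
            return float(self.blur_levels.max()), True
        return float(self.width * np.sqrt(-2.0 * np.log(u))), False


@dataclass
class BlurMatchResult:
    peripheral_eccentricity: float
    peripheral_blur: np.ndarray       # arcmin
    matched_foveal_blur: np.ndarray   # arcmin
    clamped: np.ndarray               # bool per level


def blur_matching_experiment(
    calib: CalibratedBank,
    eccentricities: Sequence[float] = BLUR_ECCENTRICITIES,
    blur_levels: Sequence[float] | None = None,
    *, edge_contrast: float = 0.5,
    tp: TransducerParams | None = None,
) -> tuple[list[BetaCurveFit], list[BlurMatchResult]]:
    """Replicate the fovea/periphery blur-matching experiment.

    For each eccentricity, beta is measured at the centre of a vertical edge
    across the Gaussian-blur series; a three-parameter Gaussian (amplitude,
    width, vertical offset) is fit to beta as a function of blur. The foveal
    match for a peripheral blur level is found by numerically inverting the
    foveal curve at the peripheral beta.
    """
    if blur_levels is None:
        blur_levels = DEFAULT_BLUR_LEVELS
    blur_levels = np.asarray(blur_levels, dtype=float)
    grid = calib.bank.grid
    fits: list[BetaCurveFit] = []
    for E in eccentricities:
        betas = []
        for s in blur_levels:
            img = make_blurred_edge(
                EdgeSpec(blur_sigma=float(s), position=float(E),
                         contrast=edge_contrast), grid)
            betas.append(beta_at_probe(calib, img, float(E), tp=tp))
        betas = np.asarray(betas)
        span = betas.max() - betas.min()
        p0 = (span if span > 0 else 1e-3, blur_levels.max() / 2.0, betas.min())
        try:
            popt, _ = curve_fit(_gaussian_curve, blur_levels, betas, p0=p0,
                                maxfev=20000)
        except RuntimeError:
            popt = p0
        rmse = float(np.sqrt(np.mean(
            (betas - _gaussian_curve(blur_levels, *popt)) ** 2)))
        fits.append(BetaCurveFit(float(E), blur_levels, betas, *map(float, popt),
                                 rmse))

    fovea = fits[0]
    matches: list[BlurMatchResult] = []
    for fit in fits[1:]:
        matched = np.empty_like(blur_levels)
        clamped = np.zeros(len(blur_levels), dtype=bool)
        for i, s in enumerate(blur_levels):
            beta_p = fit.predict(s)
            matched[i], clamped[i] = fovea.invert(float(beta_p))
        matches.append(BlurMatchResult(fit.eccentricity, blur_levels.copy(),
                                       matched, clamped))
    return fits, matches


# --------------------------------------------------------------------------
# attention
# --------------------------------------------------------------------------

def attention_elevation(frequencies: Sequence[float],
                        eccentricities: Sequence[float],
                        ch: ChannelId = ChannelId.ACHR,
                        factor: float = 0.75,
                        tp: TransducerParams | None = None) -> np.ndarray:
    """Percent threshold elevation when attention is withdrawn.

    Each (frequency, eccentricity) mechanism is calibrated from the
    contrast-sensitivity model at the attended Rmax; detection thresholds are
    then re-solved through the transducer with Rmax scaled by ``factor`` and
    z frozen. For a single mask-free mechanism this inversion is exactly the
    Newton threshold search restricted to that mechanism. Returns
    ``100 * (t_unattended / t_attended - 1)`` with shape (len(f), len(E)).
    """
    tp = TransducerParams() if tp is None else tp
    ch = ChannelId(ch)
    from .csf_core import get_params

    p = get_params(ch)
    out = np.empty((len(frequencies), len(eccentricities)))
    tp_un = apply_attention(tp, factor)
    for i, f in enumerate(frequencies):
        for j, E in enumerate(eccentricities):
            t = detection_threshold(f, E, ch, p)
            z = threshold_z(t, p.gain_g, tp)
            t_att = detection_threshold_from_z(z, p.gain_g, tp)
            t_un = detection_threshold_from_z(z, p.gain_g, tp_un)
            out[i, j] = 100.0 * (t_un / t_att - 1.0)
    return out
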