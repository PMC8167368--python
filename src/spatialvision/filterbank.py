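"""Eccentricity-scaled, colour-opponent, oriented quadrature filter bank.

The visual field is a rectangular grid of locations (degrees from fixation).
At every location the model assigns a complement of band-pass filters — one
per combination of spatial scale and orientation, for each of the three
colour-opponent channels — plus an unoriented low-pass residual. Filter peak
frequencies scale with the local acuity limit, so only the *scale* of the
complement changes across the field; its structure does not.

Filters are log-Gabors defined on the frequency plane: a Gaussian profile in
log2 frequency (2*sigma_f = 1.4 octaves) times a raised-cosine orientation
profile with 45 degree full width at half maximum (the four orientations 0,
45, 90, 135 from vertical tile the orientation domain exactly). In the space
domain these are quadrature pairs; the complex response carries a
phase-invariant contrast magnitude plus a phase. Each filter is normalized so
its response magnitude to a full-contrast grating at its preferred frequency
and orientation is 1, equating the linear response with the Michelson
contrast of a standard sensitivity test stimulus.

Per-pixel scaling of the complement is realized by quantizing eccentricity
into zones whose finest peak frequency changes by at most a fixed fraction of
an octave (default 1/8, far below the 1.4-octave bandwidth); each zone's
filters act globally via FFT products and responses are composited by zone
membership.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.fft as sfft
from skimage import color

from .csf_core import (
    BAND_DIVISORS,
    DEFAULT_PARAMS,
    ChannelId,
    ChannelParams,
    acuity_limit,
)

CHANNELS: tuple[ChannelId, ...] = (ChannelId.ACHR, ChannelId.BY, ChannelId.RG)
ORIENTATIONS_DEG: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
SIGMA_F_OCTAVES: float = 0.7          # 2*sigma_f = 1.4 octaves
ORIENTATION_FWHM_DEG: float = 45.0    # raised cosine, support +/- 45 deg


# --------------------------------------------------------------------------
# visual field geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VisualFieldGrid:
    """Pixel raster of the model visual field.

    ``extent_deg`` is the field width in degrees; height follows from the
    pixel aspect. ``fixation_deg`` is the fixation point measured in field
    coordinates from the lower-left corner (x rightward, y upward), so pixel
    eccentricities are distances from that point.
    """

    width_px: int
    height_px: int
    extent_deg: float
    fixation_deg: tuple[float, float] = (0.0, 0.0)

    @property
    def px_per_deg(self) -> float:
        return self.width_px / self.extent_deg

    @property
    def height_deg(self) -> float:
        return self.height_px / self.px_per_deg

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def x_deg(self) -> np.ndarray:
        """x coordinate (deg from fixation) of each pixel column centre."""
        ppd = self.px_per_deg
        return (np.arange(self.width_px) + 0.5) / ppd - self.fixation_deg[0]

    def y_deg(self) -> np.ndarray:
        """y coordinate (deg from fixation) of each pixel row centre (row 0 on top)."""
        ppd = self.px_per_deg
        return (self.height_px - np.arange(self.height_px) - 0.5) / ppd - self.fixation_deg[1]

    def eccentricity_map(self) -> np.ndarray:
        x = self.x_deg()[None, :]
        y = self.y_deg()[:, None]
        return np.hypot(x, y)

    @classmethod
    def scene_default(cls) -> "VisualFieldGrid":
        """The standard scene field: 32 deg square at 1536 px (48 px/deg),
        fixation 1 deg right of the left edge on the vertical midline, so the
        field runs from 1 deg left of fixation to 31 deg right and +/- 16 deg
        vertically."""
        return cls(1536, 1536, 32.0, fixation_deg=(1.0, 16.0))

    @classmethod
    def scene_scaled(cls, size_px: int) -> "VisualFieldGrid":
        """The 32-deg scene field sampled at ``size_px`` pixels."""
        return cls(size_px, size_px, 32.0, fixation_deg=(1.0, 16.0))

    @classmethod
    def horizontal_strip(cls, max_ecc_deg: float = 42.0, px_per_deg: float = 32.0,
                         height_deg: float = 10.0, lead_deg: float = 4.0
                         ) -> "VisualFieldGrid":
        """A wide, short field for threshold / blur experiments along the
        horizontal meridian: x from -lead_deg to +max_ecc_deg, fixation on the
        vertical midline."""
        width_deg = max_ecc_deg + lead_deg
        w = int(round(width_deg * px_per_deg))
        h = int(round(height_deg * px_per_deg))
        return cls(w, h, width_deg, fixation_deg=(lead_deg, height_deg / 2.0))


# --------------------------------------------------------------------------
# opponent colour transform
# --------------------------------------------------------------------------

@dataclass
class OpponentImage:
    """Colour-opponent contrast planes of an image.

    Derived from CIELAB: the achromatic plane is (L* - mean L*)/mean L* —
    a Michelson-like luminance-contrast signal — and the chromatic planes are
    the red-green (a*) and blue-yellow (b*) components scaled by 1/100, with
    the channel means (DC terms) stored separately.
    """

    achr: np.ndarray
    by: np.ndarray
    rg: np.ndarray
    mean_L: float = 50.0
    mean_a: float = 0.0
    mean_b: float = 0.0

    def plane(self, ch: ChannelId) -> np.ndarray:
        return {ChannelId.ACHR: self.achr, ChannelId.BY: self.by,
                ChannelId.RG: self.rg}[ChannelId(ch)]

    @property
    def shape(self) -> tuple[int, int]:
        return self.achr.shape

    def copy_scaled(self, factor: float) -> "OpponentImage":
        return OpponentImage(self.achr * factor, self.by * factor, self.rg * factor,
                             self.mean_L, self.mean_a, self.mean_b)

    def to_rgb(self) -> tuple[np.ndarray, float]:
        """Invert the opponent transform back to sRGB.

        Returns the RGB image (clipped to [0, 1]) and the fraction of pixels
        that fell outside the sRGB gamut before clipping.
        """
        L = self.achr * self.mean_L + self.mean_L
        a = self.rg * 100.0 + self.mean_a
        b = self.by * 100.0 + self.mean_b
        lab = np.stack([L, a, b], axis=-1)
        import warnings
        with warnings.catch_warnings():
            # out-of-gamut values are expected and reported via the clipped fraction
            warnings.filterwarnings("ignore", message=".*color space resulted in.*")
            rgb = color.lab2rgb(lab)
        # lab2rgb already clips; detect out-of-gamut via round trip
        lab_back = color.rgb2lab(rgb)
        clipped = np.any(np.abs(lab_back - lab) > 0.5, axis=-1)
        return rgb, float(np.mean(clipped))


def to_opponent(rgb: np.ndarray) -> OpponentImage:
    """Transform an sRGB image (values in [0, 1], 3 planes) to opponent contrast."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an RGB image with three planes")
    if rgb.min() < -1e-9 or rgb.max() > 1 + 1e-9:
        raise ValueError("RGB values must lie in [0, 1]")
    lab = color.rgb2lab(np.clip(rgb, 0, 1))
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    mean_L = float(L.mean())
    if mean_L <= 0:
        # black image: no luminance contrast is defined; planes are zero
        mean_L = 1.0
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return OpponentImage(
        achr=(L - L.mean()) / mean_L,
        by=(b - mean_b) / 100.0,
        rg=(a - mean_a) / 100.0,
        mean_L=mean_L, mean_a=mean_a, mean_b=mean_b,
    )


# --------------------------------------------------------------------------
# filter profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """One oriented band-pass filter: channel, scale and orientation tuning."""

    channel: ChannelId
    band_index: int
    f_peak: float
    theta_peak: float
    sigma_f: float = SIGMA_F_OCTAVES
    fwhm_theta: float = ORIENTATION_FWHM_DEG


def _freq_gain(f, f_peak: float, sigma_f: float):
    """Gaussian profile in log2 frequency; zero at f = 0."""
    f = np.asarray(f, dtype=float)
    with np.errstate(divide="ignore"):
        lf = np.log2(np.where(f > 0, f, np.nan))
    g = np.exp(-((lf - np.log2(f_peak)) ** 2) / (2.0 * sigma_f ** 2))
    return np.where(f > 0, np.nan_to_num(g), 0.0)


def _orient_gain(theta, theta_peak: float, fwhm: float = ORIENTATION_FWHM_DEG):
    """Raised-cosine orientation profile, distance taken modulo 180 deg.

    Half gain at ``fwhm/2`` off peak, zero gain at and beyond ``fwhm`` — so
    with 45-degree spacing the four orientations tile to unit total gain and
    a filter is blind to the orthogonal orientation.
    """
    d = np.abs(np.mod(np.asarray(theta, dtype=float) - theta_peak + 90.0, 180.0) - 90.0)
    g = 0.5 * (np.cos(np.pi * d / fwhm) + 1.0)
    return np.where(d < fwhm, g, 0.0)


def filter_gain(spec: FilterSpec, f, theta):
    """Separable filter gain g_f(f) * g_theta(theta) in [0, 1]."""
    return _freq_gain(f, spec.f_peak, spec.sigma_f) * _orient_gain(
        theta, spec.theta_peak, spec.fwhm_theta)


# --------------------------------------------------------------------------
# eccentricity zones and the bank
# --------------------------------------------------------------------------

@dataclass
class EccentricityZone:
    """One annulus of the field sharing a single filter complement."""

    zone_index: int
    E_lo: float
    E_hi: float
    representative_E: float
    peaks: Mapping[ChannelId, list[float]]


@dataclass
class FilterBank:
    """The zoned filter complement for one visual field grid."""

    grid: VisualFieldGrid
    zones: list[EccentricityZone]
    params: Mapping[ChannelId, ChannelParams]
    zoning_step_octaves: float

    def __post_init__(self) -> None:
        edges = [z.E_lo for z in self.zones] + [self.zones[-1].E_hi]
        ecc = self.grid.eccentricity_map()
        idx = np.clip(np.searchsorted(edges, ecc, side="right") - 1,
                      0, len(self.zones) - 1)
        self.zone_index_map = idx.astype(np.int32)

    def zone_mask(self, zone_index: int) -> np.ndarray:
        return self.zone_index_map == zone_index

    def zone_of_eccentricity(self, E: float) -> EccentricityZone:
        for z in self.zones:
            if z.E_lo <= E <= z.E_hi:
                return z
        return self.zones[-1] if E > self.zones[-1].E_hi else self.zones[0]

    def specs(self, zone: EccentricityZone, ch: ChannelId) -> list[FilterSpec]:
        return [
            FilterSpec(channel=ch, band_index=b, f_peak=fp, theta_peak=th)
            for b, fp in enumerate(zone.peaks[ch])
            for th in ORIENTATIONS_DEG
        ]

    def max_bands(self) -> int:
        return max(ChannelId(ch).n_bands for ch in CHANNELS)

    def to_json(self, path) -> None:
        """Export the bank description (zones, peak frequencies) for reproducibility."""
        doc = {
            "grid": {
                "width_px": self.grid.width_px, "height_px": self.grid.height_px,
                "extent_deg": self.grid.extent_deg,
                "fixation_deg": list(self.grid.fixation_deg),
            },
            "zoning_step_octaves": self.zoning_step_octaves,
            "normalization": "unit response magnitude to a full-contrast preferred grating",
            "zones": [
                {
                    "zone_index": z.zone_index,
                    "E_lo": z.E_lo, "E_hi": z.E_hi,
                    "representative_E": z.representative_E,
                    "peaks_cpd": {ch.value: z.peaks[ch] for ch in CHANNELS},
                }
                for z in self.zones
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def build_bank(grid: VisualFieldGrid,
               params: Mapping[ChannelId, ChannelParams] | None = None,
               zoning_step_octaves: float = 0.125) -> FilterBank:
    """Quantize the field into eccentricity zones and assign filter complements.

    Each channel's finest peak frequency (acuity/3) is quantized onto a global
    lattice of ``zoning_step_octaves`` in log2 frequency; zone edges fall
    where any channel's lattice index changes, so adjacent zones' finest
    peaks differ by at most one step. Because band ladders are exact octave
    divisions of lattice values, the same physical filter recurs across zones
    and is computed only once during filtering.
    """
    if zoning_step_octaves > 0.25:
        raise ValueError("zoning step must be <= 1/4 octave")
    params = dict(DEFAULT_PARAMS) if params is None else dict(params)
    step = zoning_step_octaves

    ecc = grid.eccentricity_map()
    E_min, E_max = float(ecc.min()), float(ecc.max())

    # dense eccentricity grid; quantized log2(acuity/3) drives the zone cuts
    E_dense = np.linspace(E_min, E_max, 1024)
    lattice = {
        ch: np.round(
            np.log2(np.asarray(acuity_limit(E_dense, ch, params[ch])) / 3.0)
            / step).astype(int)
        for ch in CHANNELS
    }

    cuts = [0]
    for i in range(1, len(E_dense)):
        if any(lattice[ch][i] != lattice[ch][cuts[-1]] for ch in CHANNELS):
            cuts.append(i)

    zones = []
    for k, start in enumerate(cuts):
        lo = E_min if k == 0 else float(E_dense[start])
        hi = (E_max * (1 + 1e-9) + 1e-9 if k == len(cuts) - 1
              else float(E_dense[cuts[k + 1]]))
        rep = 0.5 * (lo + hi)
        # finest peak is the quantized acuity/3; coarser bands exact octaves below
        peaks = {
            ch: [float(2.0 ** (lattice[ch][start] * step)) * 3.0 / d
                 for d in BAND_DIVISORS[: ChannelId(ch).n_bands]]
            for ch in CHANNELS
        }
        zones.append(EccentricityZone(k, lo, hi, rep, peaks))

    bank = FilterBank(grid, zones, params, zoning_step_octaves)

    # the coarsest filter must fit: its peak wavelength within the padded field
    f_min = min(min(z.peaks[ch][-1] for ch in CHANNELS) for z in zones)
    if 1.0 / f_min > 4.0 * max(grid.extent_deg, grid.height_deg):
        raise ValueError(
            "grid too small for the coarsest filter; enlarge the field or "
            "reduce the number of bands")
    return bank


# --------------------------------------------------------------------------
# linear responses
# --------------------------------------------------------------------------

@dataclass
class LinearResponseField:
    """Complex quadrature responses on the grid.

    ``band`` has shape (n_channels, n_bands_max, n_orientations, H, W); slots
    beyond a channel's band count are zero. ``lowpass`` has shape
    (n_channels, H, W). Magnitudes equal Michelson-type contrast for grating
    inputs; phase is the local phase of the band-limited content.
    """

    bank: FilterBank
    band: np.ndarray
    lowpass: np.ndarray
    dc: tuple[float, float, float] = (50.0, 0.0, 0.0)  # mean L*, a*, b*


class _FreqDomain:
    """Cached frequency-plane coordinates for a padded grid."""

    def __init__(self, grid: VisualFieldGrid, pad: int):
        self.pad = pad
        if pad == 0:
            # periodic (wrap) filtering: exact grid, no extension
            ny, nx = grid.height_px, grid.width_px
        else:
            ny = sfft.next_fast_len(grid.height_px + 2 * pad)
            nx = sfft.next_fast_len(grid.width_px + 2 * pad)
        self.ny, self.nx = ny, nx
        ppd = grid.px_per_deg
        fx = sfft.fftfreq(nx, d=1.0 / ppd)
        fy = sfft.fftfreq(ny, d=1.0 / ppd)
        FX = fx[None, :]
        FY = fy[:, None]
        self.f = np.hypot(FX, FY)
        # wave-vector angle from the x axis == stimulus orientation from vertical
        # (a vertical grating modulates along x); y row frequency increases
        # downward in array order, negate for y-up convention
        self.theta = np.degrees(np.arctan2(-FY, FX)) % 180.0
        # analytic-signal half plane: fx > 0, or fx == 0 and fy > 0
        self.half = (FX > 0) | ((FX == 0) & (-FY > 0))
        self.half = self.half.astype(float) * 2.0  # doubled gain, DC excluded


def _pad_extent(bank: FilterBank) -> int:
    """Mirror-padding width: half the wavelength of the coarsest band peak."""
    f_min = min(min(z.peaks[ch][-1] for ch in CHANNELS) for z in bank.zones)
    ppd = bank.grid.px_per_deg
    return int(np.ceil(ppd / (2.0 * f_min)))


def _zone_freq_gains(bank: FilterBank, zone: EccentricityZone, ch: ChannelId,
                     fd: _FreqDomain) -> tuple[list[np.ndarray], np.ndarray]:
    """Frequency-plane radial gains per band plus the low-pass residual gain."""
    gains = [
        _freq_gain(fd.f, fp, SIGMA_F_OCTAVES).astype(np.float32)
        for fp in zone.peaks[ch]
    ]
    total = np.sum(gains, axis=0)
    f_fine = zone.peaks[ch][0]
    residual = np.where(fd.f < f_fine, np.maximum(0.0, 1.0 - total), 0.0)
    residual[fd.f == 0] = 0.0
    return gains, residual.astype(np.float32)


def linear_responses(img: OpponentImage, bank: FilterBank,
                     *, channels: Sequence[ChannelId] = CHANNELS,
                     pixel_mask: np.ndarray | None = None,
                     boundary: str = "mirror") -> LinearResponseField:
    """Compute complex quadrature responses of the whole bank to an image.

    Each zone's filters are applied globally in the frequency domain (after
    mirror padding) and composited by zone membership. ``pixel_mask`` may
    restrict compositing (and zone selection) to a region of interest, which
    skips zones without selected pixels.

    ``boundary`` is ``"mirror"`` (reflect-pad by the coarsest filter's
    half-support, for photographs) or ``"wrap"`` (periodic filtering with no
    padding — exact for FFT-periodic synthetic scenes).

    Responses are linear in image contrast; a full-contrast grating at a
    filter's preferred frequency/orientation yields magnitude 1 at pixels in
    that filter's zone.
    """
    if img.shape != bank.grid.shape:
        raise ValueError(f"image shape {img.shape} != grid shape {bank.grid.shape}")
    if boundary not in ("mirror", "wrap"):
        raise ValueError("boundary must be 'mirror' or 'wrap'")

    pad = 0 if boundary == "wrap" else _pad_extent(bank)
    fd = _FreqDomain(bank.grid, pad)
    H, W = bank.grid.shape
    n_bands = bank.max_bands()
    n_or = len(ORIENTATIONS_DEG)

    band_out = np.zeros((len(CHANNELS), n_bands, n_or, H, W), dtype=np.complex64)
    lp_out = np.zeros((len(CHANNELS), H, W), dtype=np.complex64)

    # mirror-pad then zero-extend to the fast FFT size
    def padded_fft(plane: np.ndarray) -> np.ndarray:
        p = np.pad(plane, pad, mode="reflect")
        full = np.zeros((fd.ny, fd.nx), dtype=np.float32)
        full[: p.shape[0], : p.shape[1]] = p
        return sfft.fft2(full)

    orient_gain = [
        _orient_gain(fd.theta, th).astype(np.float32) for th in ORIENTATIONS_DEG
    ]

    active = set(np.unique(
        bank.zone_index_map if pixel_mask is None
        else bank.zone_index_map[pixel_mask]))

    def zone_sel(zone_index: int) -> np.ndarray:
        mask = bank.zone_mask(zone_index)
        return mask & pixel_mask if pixel_mask is not None else mask

    crop = (slice(pad, pad + H), slice(pad, pad + W))
    for ci, ch in enumerate(CHANNELS):
        if ch not in channels:
            continue
        plane = img.plane(ch)
        if not np.any(plane):
            continue
        F = (padded_fft(plane) * fd.half).astype(np.complex64)

        # identical filters recur across zones (band ladders live on a shared
        # log2-frequency lattice): group band tasks by distinct peak frequency
        # and compute each filter response once
        band_users: dict[int, list[tuple[int, int]]] = {}
        for zone in bank.zones:
            if zone.zone_index not in active:
                continue
            for b, fp in enumerate(zone.peaks[ch]):
                band_users.setdefault(round(np.log2(fp) * 64), []).append(
                    (zone.zone_index, b))

        for key, users in band_users.items():
            fp = 2.0 ** (key / 64.0)
            gf = _freq_gain(fd.f, fp, SIGMA_F_OCTAVES).astype(np.float32)
            for oi, go in enumerate(orient_gain):
                resp = sfft.ifft2(F * (gf * go))[crop]
                for zone_index, b in users:
                    sel = zone_sel(zone_index)
                    band_out[ci, b, oi][sel] = resp[sel]

        # low-pass residuals: distinct per (finest peak, band count)
        lp_users: dict[tuple[int, int], list[int]] = {}
        for zone in bank.zones:
            if zone.zone_index not in active:
                continue
            key = (round(np.log2(zone.peaks[ch][0]) * 64), len(zone.peaks[ch]))
            lp_users.setdefault(key, []).append(zone.zone_index)
        for (key, nb), zone_indices in lp_users.items():
            zone = bank.zones[zone_indices[0]]
            _, residual = _zone_freq_gains(bank, zone, ch, fd)
            resp = sfft.ifft2(F * residual)[crop]
            for zone_index in zone_indices:
                sel = zone_sel(zone_index)
                lp_out[ci][sel] = resp[sel]

    return LinearResponseField(bank, band_out, lp_out,
                               dc=(img.mean_L, img.mean_a, img.mean_b))


def synthesis_normalize(planes: np.ndarray, bank: FilterBank,
                        channels: Sequence[ChannelId] = CHANNELS,
                        boundary: str = "mirror") -> np.ndarray:
    """Divide reconstructed planes by the bank's composite transfer function.

    The analysis gains overlap (neighbouring bands sum to ~1.6 at band
    peaks), so a sum of band-limited contributions overweights mid
    frequencies. This applies the zone-wise synthesis correction
    1 / max(T, 1) where T(f) is the summed band gain plus low-pass residual:
    content within the complement's coverage is restored to unit gain while
    content above the local finest scale stays attenuated as the analysis
    left it. ``planes`` has shape (n_channels, H, W).
    """
    pad = 0 if boundary == "wrap" else _pad_extent(bank)
    fd = _FreqDomain(bank.grid, pad)
    H, W = bank.grid.shape
    crop = (slice(pad, pad + H), slice(pad, pad + W))
    out = np.zeros_like(planes, dtype=float)

    for ci, ch in enumerate(CHANNELS):
        if ch not in channels or not np.any(planes[ci]):
            continue
        p = np.pad(planes[ci], pad, mode="reflect")
        full = np.zeros((fd.ny, fd.nx))
        full[: p.shape[0], : p.shape[1]] = p
        F = sfft.fft2(full)
        # distinct transfer functions per (finest peak, band count)
        groups: dict[tuple[int, int], list[int]] = {}
        for zone in bank.zones:
            key = (round(np.log2(zone.peaks[ch][0]) * 64), len(zone.peaks[ch]))
            groups.setdefault(key, []).append(zone.zone_index)
        for key, zone_indices in groups.items():
            zone = bank.zones[zone_indices[0]]
            gains, residual = _zone_freq_gains(bank, zone, ch, fd)
            T = np.sum(gains, axis=0) + residual
            corr = 1.0 / np.maximum(T, 1.0)
            rec = np.real(sfft.ifft2(F * corr))[crop]
            for zi in zone_indices:
                sel = bank.zone_mask(zi)
                out[ci][sel] = rec[sel]
    return out
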