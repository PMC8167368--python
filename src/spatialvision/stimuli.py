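"""Test stimuli: Gabor patches, blurred edges and synthetic colourful scenes.

The synthetic scene generator emulates the statistical structure of colourful
panoramic photographs — an approximately 1/f amplitude spectrum (natural
scenes are approximately scale invariant), a controllable palette of hues
laid out in smooth random regions, and a saturation distribution skewed
toward low saturations (highly saturated colours are rare in natural images)
— with spatially stationary statistics and optional embedded blurred step
edges. It is a statistical stand-in, not a photorealistic renderer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import erf, ndtr
from skimage import color, transform

from .csf_core import ChannelId
from .filterbank import OpponentImage, VisualFieldGrid


# --------------------------------------------------------------------------
# Gabor patches
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GaborSpec:
    """A windowed sinusoid in one opponent channel.

    ``f`` cycles/degree; ``theta`` degrees from vertical; ``center`` in
    degrees from fixation; ``envelope_sigma`` degrees; ``contrast`` the
    Michelson-type amplitude in opponent contrast units.
    """

    f: float
    theta: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    envelope_sigma: float = 1.0
    contrast: float = 0.5
    channel: ChannelId = ChannelId.ACHR
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must lie in [0, 1]")
        if self.envelope_sigma <= 0:
            raise ValueError("envelope_sigma must be positive")


def make_gabor(spec: GaborSpec, grid: VisualFieldGrid) -> OpponentImage:
    """Render a Gabor patch as an opponent-contrast image on ``grid``."""
    x = grid.x_deg()[None, :]
    y = grid.y_deg()[:, None]
    cx, cy = spec.center
    if not (x.min() <= cx <= x.max() and y.min() <= cy <= y.max()):
        raise ValueError("Gabor centre lies outside the field")
    th = np.radians(spec.theta)
    carrier = np.cos(
        2 * np.pi * spec.f * ((x - cx) * np.cos(th) + (y - cy) * np.sin(th))
        + np.radians(spec.phase)
    )
    env = np.exp(-(((x - cx) ** 2) + ((y - cy) ** 2)) / (2 * spec.envelope_sigma ** 2))
    plane = spec.contrast * carrier * env
    zeros = np.zeros(grid.shape)
    planes = {ChannelId.ACHR: zeros, ChannelId.BY: zeros, ChannelId.RG: zeros}
    planes[ChannelId(spec.channel)] = plane
    return OpponentImage(planes[ChannelId.ACHR], planes[ChannelId.BY],
                         planes[ChannelId.RG])


# --------------------------------------------------------------------------
# blurred edges
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeSpec:
    """A vertical step edge with Gaussian blur.

    ``blur_sigma`` is the blur scale constant in minutes of arc; ``contrast``
    the Michelson contrast of the step; ``position`` the horizontal location
    of the edge in degrees from fixation.
    """

    blur_sigma: float = 0.0
    width_deg: float = 10.67
    polarity: int = 1
    contrast: float = 0.5
    position: float = 0.0

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be non-negative")


def make_blurred_edge(spec: EdgeSpec, grid: VisualFieldGrid) -> OpponentImage:
    """A monochrome vertical edge at ``spec.position``, blurred by a Gaussian.

    The achromatic plane follows the analytic Gaussian-blurred step
    ``contrast * erf((x - x0) / (sigma * sqrt(2)))``; a zero blur gives an
    ideal step.
    """
    x = grid.x_deg()[None, :]
    sigma_deg = spec.blur_sigma / 60.0
    if sigma_deg == 0:
        profile = np.sign(x - spec.position)
    else:
        profile = erf((x - spec.position) / (sigma_deg * np.sqrt(2.0)))
    plane = spec.polarity * spec.contrast * np.broadcast_to(
        profile, grid.shape).copy()
    z = np.zeros(grid.shape)
    return OpponentImage(plane, z, z.copy())


def edge_blur_series(grid: VisualFieldGrid, position: float = 0.0,
                     blur_levels: Sequence[float] | None = None,
                     contrast: float = 0.5) -> list[tuple[EdgeSpec, OpponentImage]]:
    """The eleven-level Gaussian-blur edge series used for blur experiments.

    Default blur scale constants run from 0 to 12 arcmin in eleven steps
    (the monotone limb of the foveal apparent-blur response).
    """
    if blur_levels is None:
        blur_levels = np.linspace(0.0, 12.0, 11)
    out = []
    for s in blur_levels:
        spec = EdgeSpec(blur_sigma=float(s), position=position, contrast=contrast)
        out.append((spec, make_blurred_edge(spec, grid)))
    return out


# --------------------------------------------------------------------------
# synthetic colourful scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Recipe for a reproducible synthetic colourful scene.

    ``amplitude_slope`` is the exponent of the 1/f^slope amplitude spectrum of
    the value (lightness) plane. ``hue_palette`` lists HSV hue centres; hue is
    piecewise constant over smooth random regions so a single-hue palette
    yields zero hue entropy. ``saturation_shape`` are Beta-distribution
    parameters for the pointwise saturation distribution (defaults skewed low,
    as in natural images). ``n_edges`` blurred step edges are embedded at
    uniformly random positions/orientations so edge statistics stay spatially
    stationary.
    """

    seed: int = 0
    size_px: int = 512
    amplitude_slope: float = 1.0
    hue_palette: tuple[float, ...] = (0.08, 0.16, 0.33, 0.55, 0.62, 0.95)
    saturation_shape: tuple[float, float] = (2.0, 5.0)
    n_edges: int = 12
    edge_blur_range: tuple[float, float] = (0.5, 8.0)
    value_contrast: float = 0.30
    edge_amplitude: tuple[float, float] = (0.15, 0.30)
    hue_field_slope: float = 1.3
    saturation_field_slope: float = 2.0


def _power_noise(rng: np.random.Generator, n: int, slope: float) -> np.ndarray:
    """Zero-mean field with amplitude spectrum proportional to 1/f^slope,
    normalized to unit standard deviation."""
    white = rng.standard_normal((n, n))
    F = np.fft.fft2(white)
    fx = np.fft.fftfreq(n)
    f = np.hypot(fx[None, :], fx[:, None])
    f[0, 0] = 1.0
    amp = f ** (-slope)
    amp[0, 0] = 0.0
    field_ = np.real(np.fft.ifft2(F * amp))
    return field_ / field_.std()


def make_synthetic_scene(spec: SceneSpec) -> np.ndarray:
    """Generate a colourful, approximately scale-invariant RGB scene.

    Deterministic given ``spec.seed``. The HSV value plane carries the
    1/f^slope structure plus embedded blurred step edges, at contrasts that
    leave scene content deeply suprathreshold for the model — as colourful
    panoramic photographs are. Hue and saturation are driven by steeper
    power-law random fields (chromatic spectra of natural scenes fall faster
    than luminance spectra): hue is the palette entry with the largest of one
    random field per palette colour (piecewise constant, so a single-hue
    palette carries exactly one hue), and saturation is a rank-preserving
    Beta transform of another field. Statistics are spatially stationary and
    approximately self-similar by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size_px

    # value plane: 1/f noise around mid grey, plus oriented blurred edges
    v = 0.55 + spec.value_contrast * _power_noise(rng, n, spec.amplitude_slope)
    xx, yy = np.meshgrid(np.arange(n), np.arange(n))
    for _ in range(spec.n_edges):
        x0, y0 = rng.uniform(0, n, size=2)
        ang = rng.uniform(0, np.pi)
        blur_arcmin = rng.uniform(*spec.edge_blur_range)
        # blur in pixels assumes the 32-deg scene field
        sigma_px = blur_arcmin / 60.0 * (n / 32.0)
        d = (xx - x0) * np.cos(ang) + (yy - y0) * np.sin(ang)
        step = erf(d / (np.sqrt(2.0) * max(sigma_px, 1e-6)))
        window = np.exp(-(((xx - x0) ** 2 + (yy - y0) ** 2)
                          / (2 * (0.25 * n) ** 2)))
        v += rng.uniform(*spec.edge_amplitude) * rng.choice([-1, 1]) * step * window
    v = np.clip(v, 0.02, 0.98)

    # saturation: Beta-distributed via rank transform of a power-law field
    a, b = spec.saturation_shape
    s = stats.beta.ppf(
        ndtr(_power_noise(rng, n, spec.saturation_field_slope)), a, b)
    s = np.clip(s, 0.0, 1.0)

    # hue: piecewise palette over self-similar region fields
    palette = np.asarray(spec.hue_palette, dtype=float) % 1.0
    if len(palette) == 1:
        h = np.full((n, n), palette[0])
    else:
        fields = np.stack([_power_noise(rng, n, spec.hue_field_slope)
                           for _ in palette])
        h = palette[np.argmax(fields, axis=0)]

    hsv = np.stack([h, s, v], axis=-1)
    rgb = color.hsv2rgb(hsv)
    return np.clip(rgb, 0.0, 1.0)


# --------------------------------------------------------------------------
# scene preparation
# --------------------------------------------------------------------------

def prepare_scene(rgb: np.ndarray, target: int = 1536) -> np.ndarray:
    """Crop (and if needed resize) a photograph to the model input size.

    Centre-crop to ``target`` square; if the least dimension exceeds
    ``2 * target``, first centre-crop to the nearest multiple of ``target``
    not exceeding the least dimension, then resize down to ``target``.
    """
    rgb = np.asarray(rgb)
    h, w = rgb.shape[:2]
    if min(h, w) < target:
        raise ValueError(f"image must be at least {target} px in both dimensions")

    def center_crop(img, ch, cw):
        top = (img.shape[0] - ch) // 2
        left = (img.shape[1] - cw) // 2
        return img[top: top + ch, left: left + cw]

    if min(h, w) > 2 * target:
        side = (min(h, w) // target) * target
        cropped = center_crop(rgb, side, side)
        out = transform.resize(cropped, (target, target, *rgb.shape[2:]),
                               anti_aliasing=True, preserve_range=True)
        return out.astype(float)
    return center_crop(rgb, target, target).astype(float)


def save_scene(rgb: np.ndarray, path, spec: SceneSpec | None = None) -> None:
    """Save a generated scene as 8-bit PNG with a JSON recipe sidecar."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    from imageio.v3 import imwrite

    path = Path(path)
    imwrite(path, (np.clip(rgb, 0, 1) * 255).astype(np.uint8))
    if spec is not None:
        path.with_suffix(".json").write_text(json.dumps(asdict(spec), indent=1))
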