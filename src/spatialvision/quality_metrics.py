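"""Visible-image reconstruction and eccentricity profiles of image quality.

The model's high-dimensional d' field is translated back into a *visible
image*: each filter's band-limited contribution (phase preserved from the
complex response) is weighted by its response accuracy and the weighted
contributions are summed per opponent channel, with the channel DC means
passed through. Content that fails to elicit psychophysically accurate
responses vanishes; strongly suprathreshold content survives essentially
unchanged. The reconstruction is converted to RGB and HSV for the
colourfulness statistics.

Quality statistics are sampled in circular windows stepped along the
horizontal midline at one-degree intervals, either with an attention-scaled
window radius (r = k0 * (1 + E/E2) + kc, the attentional "spotlight" scaling)
or a fixed radius. Windows extending outside the field are flagged invalid
and excluded from summary averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import color

from .csf_core import ChannelId
from .filterbank import CHANNELS, FilterBank, LinearResponseField, OpponentImage
from .response_model import AccuracyField, ResponseField, accuracy, pool_scales

SATURATION_QUANTILES: tuple[float, ...] = (0.5, 0.75, 0.9, 0.95, 0.99)
HUE_BINS: int = 256
SATURATION_BAR: float = 0.2
FC_CUTOFF: float = 0.96


# --------------------------------------------------------------------------
# visible image
# --------------------------------------------------------------------------

@dataclass
class VisibleImage:
    """Accuracy-weighted reconstruction of a stimulus."""

    opponent: OpponentImage
    rgb: np.ndarray
    hsv: np.ndarray
    clipped_fraction: float

    @property
    def hue(self) -> np.ndarray:
        return self.hsv[..., 0]

    @property
    def saturation(self) -> np.ndarray:
        return self.hsv[..., 1]

    @property
    def value(self) -> np.ndarray:
        return self.hsv[..., 2]


def reconstruct_visible(linear: LinearResponseField, acc: AccuracyField,
                        bank: FilterBank, *, boundary: str = "mirror"
                        ) -> VisibleImage:
    """Sum accuracy-weighted band-limited reconstructions per channel.

    The real part of each complex quadrature response is the band-passed
    signal itself (the "positive cosine phase" of the filter), so weighting it
    by the accuracy in [0, 1] and summing over bands, orientations and the
    low-pass residual reconstructs the visible portion of each opponent
    plane. With unit accuracies the sum approaches the original band-limited
    content because the filter gains tile the frequency plane.
    """
    if linear.band.shape != acc.band.shape:
        raise ValueError("responses and accuracies must share indexing")
    from .filterbank import synthesis_normalize

    planes = []
    for ci, ch in enumerate(CHANNELS):
        rec = np.sum(acc.band[ci] * np.real(linear.band[ci]), axis=(0, 1))
        rec = rec + acc.lowpass[ci] * np.real(linear.lowpass[ci])
        planes.append(rec)
    # undo the analysis filters' gain overlap so fully visible content comes
    # back at unit gain
    planes = synthesis_normalize(np.asarray(planes), bank, boundary=boundary)
    dc = linear.dc
    opp = OpponentImage(planes[0], planes[1], planes[2],
                        mean_L=dc[0], mean_a=dc[1], mean_b=dc[2])
    rgb, clipped = opp.to_rgb()
    hsv = color.rgb2hsv(rgb)
    return VisibleImage(opp, rgb, hsv, clipped)


# --------------------------------------------------------------------------
# sampling windows
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingRule:
    """Midline sampling window: attention-scaled or fixed radius.

    The scaled rule follows the eccentricity scaling of the spatial-attention
    spotlight, r = k0*(1 + E/E2) + kc with k0 = 5 arcmin and E2 = 0.34 deg,
    plus a 1-degree constant that prevents severe undersampling at the fovea.
    The fixed rule uses 3.75 deg (about the parafoveal region) everywhere.
    """

    kind: str = "scaled"               # "scaled" | "fixed"
    k0_arcmin: float = 5.0
    E2_attn: float = 0.34
    kc_deg: float = 1.0
    fixed_radius_deg: float = 3.75

    def __post_init__(self) -> None:
        if self.kind not in ("scaled", "fixed"):
            raise ValueError("rule kind must be 'scaled' or 'fixed'")


def window_radius(E: float, rule: SamplingRule) -> float:
    """Window radius in degrees at eccentricity ``E``."""
    if E < 0:
        raise ValueError("eccentricity must be non-negative")
    if rule.kind == "fixed":
        return rule.fixed_radius_deg
    return rule.k0_arcmin / 60.0 * (1.0 + E / rule.E2_attn) + rule.kc_deg


# --------------------------------------------------------------------------
# colourfulness
# --------------------------------------------------------------------------

def hue_entropy(hue: np.ndarray, saturation: np.ndarray,
                *, bar: float = SATURATION_BAR,
                bins: int = HUE_BINS) -> float | None:
    """Shannon entropy (bits) of the hue histogram over qualifying pixels.

    Only pixels with saturation above ``bar`` qualify. Returns ``None``
    (undefined, not zero) when no pixel qualifies — an empty sample carries no
    hue distribution, whereas 0 bits would assert a single hue.
    """
    h = np.asarray(hue, dtype=float).ravel()
    s = np.asarray(saturation, dtype=float).ravel()
    sel = s > bar
    if not np.any(sel):
        return None
    counts, _ = np.histogram(h[sel], bins=bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


@dataclass
class EccentricityProfile:
    """Per-eccentricity quality statistics along the horizontal midline."""

    eccentricities: np.ndarray
    saturation_quantiles: pd.DataFrame   # columns q50..q99
    entropy_bits: np.ndarray             # NaN where undefined
    edge_density: np.ndarray
    beta_mean: np.ndarray
    valid: np.ndarray                    # windows fully inside the field

    def to_frame(self) -> pd.DataFrame:
        df = self.saturation_quantiles.copy()
        df.insert(0, "eccentricity_deg", self.eccentricities)
        df["entropy_bits"] = self.entropy_bits
        df["edge_density"] = self.edge_density
        df["beta_mean"] = self.beta_mean
        df["valid"] = self.valid
        return df


def _midline_windows(bank: FilterBank, rule: SamplingRule,
                     eccentricities: Sequence[float] | None = None):
    """Yield (E, mask, fully_inside) for circular windows on the midline."""
    grid = bank.grid
    x = grid.x_deg()[None, :]
    y = grid.y_deg()[:, None]
    if eccentricities is None:
        eccentricities = np.arange(0.0, np.floor(x.max()) + 1.0)
    for E in eccentricities:
        r = window_radius(float(E), rule)
        mask = (x - E) ** 2 + y ** 2 <= r ** 2
        inside = (E - r >= x.min() - 1e-9) and (E + r <= x.max() + 1e-9) \
            and (r <= y.max() + 1e-9) and (-r >= y.min() - 1e-9)
        yield float(E), mask, bool(inside)


def colourfulness_profile(visible: VisibleImage, bank: FilterBank,
                          rule: SamplingRule,
                          eccentricities: Sequence[float] | None = None
                          ) -> pd.DataFrame:
    """Saturation quantiles and hue entropy per midline window.

    Quantiles are taken over all window pixels; the 0.2 saturation bar
    applies only to the entropy. Undefined entropies are NaN.
    """
    rows = []
    for E, mask, inside in _midline_windows(bank, rule, eccentricities):
        s = visible.saturation[mask]
        h = visible.hue[mask]
        q = np.quantile(s, SATURATION_QUANTILES)
        ent = hue_entropy(h, s)
        rows.append((E, *q, np.nan if ent is None else ent, inside))
    cols = ["eccentricity_deg"] + [f"q{int(100 * q)}" for q in SATURATION_QUANTILES] \
        + ["entropy_bits", "valid"]
    return pd.DataFrame(rows, columns=cols)


# --------------------------------------------------------------------------
# sharpness
# --------------------------------------------------------------------------

@dataclass
class FCMap:
    """Filter completeness per (orientation, pixel) with sharp-feature mask."""

    fc: np.ndarray           # (n_orientations, H, W)
    sharp_mask: np.ndarray   # (H, W) bool: FC > cutoff at any orientation
    cutoff: float = FC_CUTOFF


def filter_completeness(acc: AccuracyField, bank: FilterBank,
                        *, cutoff: float = FC_CUTOFF) -> FCMap:
    """Cross-scale product of achromatic band accuracies per orientation.

    FC approaches 1 only where all four achromatic scales respond strongly —
    an oriented feature resolved down to the local finest filter. Computed for
    the luminance channel only (its finer scale makes it the driver of
    sharpness judgements).
    """
    a = acc.band[0]                    # achromatic: (B, O, H, W)
    nb = ChannelId.ACHR.n_bands
    fc = np.prod(a[:nb], axis=0)       # (O, H, W)
    return FCMap(fc, np.any(fc > cutoff, axis=0), cutoff)


def edge_density_profile(fcmap: FCMap, bank: FilterBank, rule: SamplingRule,
                         eccentricities: Sequence[float] | None = None
                         ) -> pd.DataFrame:
    """Fraction of filter-complete (sharp) pixels per midline window."""
    rows = [
        (E, float(fcmap.sharp_mask[mask].mean()), inside)
        for E, mask, inside in _midline_windows(bank, rule, eccentricities)
    ]
    return pd.DataFrame(rows, columns=["eccentricity_deg", "edge_density", "valid"])


def beta_map(resp: ResponseField, bank: FilterBank) -> np.ndarray:
    """Apparent blur beta per pixel for the achromatic channel.

    Per-scale response is the maximum over orientation of the achromatic band
    d'; the regression of response against log peak frequency uses each
    pixel's own zone's peak frequencies.
    """
    nb = ChannelId.ACHR.n_bands
    R = resp.d_band[0, :nb].max(axis=1)        # (B, H, W)
    pooled = pool_scales(np.moveaxis(R, 0, -1), resp.tp.M)

    out = np.zeros(bank.grid.shape)
    for zone in bank.zones:
        mask = bank.zone_mask(zone.zone_index)
        if not np.any(mask):
            continue
        lf = np.log(np.asarray(zone.peaks[ChannelId.ACHR]))
        lf_c = lf - lf.mean()
        # closed-form least-squares slope of R against ln f per pixel
        m = np.tensordot(lf_c, R[:, mask], axes=(0, 0)) / np.sum(lf_c ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[mask] = np.where(pooled[mask] > 0, m / pooled[mask], 0.0)
    return out


def blur_profile(resp: ResponseField, bank: FilterBank, rule: SamplingRule,
                 eccentricities: Sequence[float] | None = None) -> pd.DataFrame:
    """Mean apparent blur beta per midline window."""
    bmap = beta_map(resp, bank)
    rows = [
        (E, float(bmap[mask].mean()), inside)
        for E, mask, inside in _midline_windows(bank, rule, eccentricities)
    ]
    return pd.DataFrame(rows, columns=["eccentricity_deg", "beta_mean", "valid"])


# --------------------------------------------------------------------------
# full profile and summary
# --------------------------------------------------------------------------

def eccentricity_profile(visible: VisibleImage, resp: ResponseField,
                         acc: AccuracyField, bank: FilterBank,
                         rule: SamplingRule,
                         eccentricities: Sequence[float] | None = None
                         ) -> EccentricityProfile:
    """All quality statistics per midline window on one grid pass."""
    colour = colourfulness_profile(visible, bank, rule, eccentricities)
    fcmap = filter_completeness(acc, bank)
    edges = edge_density_profile(fcmap, bank, rule, eccentricities)
    blur = blur_profile(resp, bank, rule, eccentricities)
    qcols = [f"q{int(100 * q)}" for q in SATURATION_QUANTILES]
    return EccentricityProfile(
        eccentricities=colour["eccentricity_deg"].to_numpy(),
        saturation_quantiles=colour[qcols],
        entropy_bits=colour["entropy_bits"].to_numpy(),
        edge_density=edges["edge_density"].to_numpy(),
        beta_mean=blur["beta_mean"].to_numpy(),
        valid=colour["valid"].to_numpy(dtype=bool),
    )


def summarize(profile_attended: EccentricityProfile,
              profile_unattended: EccentricityProfile | None = None,
              *, attention_factor: float = 0.75,
              parafovea_max_deg: float = 5.0,
              periphery_min_deg: float = 15.0) -> pd.DataFrame:
    """Parafoveal (< 5 deg) and peripheral (> 15 deg) means of each statistic.

    Invalid windows are excluded. For the unattended profile the apparent
    blur statistic is also reported adjusted by the attention factor (the
    response-amplitude reduction the statistic's normalization otherwise
    over-compensates for).
    """
    profiles = {"attended": profile_attended}
    if profile_unattended is not None:
        if not np.array_equal(profile_attended.eccentricities,
                              profile_unattended.eccentricities):
            raise ValueError("profiles must share the eccentricity grid")
        profiles["unattended"] = profile_unattended

    rows = []
    for label, prof in profiles.items():
        E = prof.eccentricities
        for band_label, sel in (
            ("parafovea", (E < parafovea_max_deg) & prof.valid),
            ("periphery", (E > periphery_min_deg) & prof.valid),
        ):
            stats = {
                f"sat_{c}": float(np.nanmean(prof.saturation_quantiles[c][sel]))
                for c in prof.saturation_quantiles.columns
            }
            beta = float(np.nanmean(prof.beta_mean[sel]))
            row = {
                "condition": label, "band": band_label, **stats,
                "entropy_bits": float(np.nanmean(prof.entropy_bits[sel])),
                "edge_density": float(np.nanmean(prof.edge_density[sel])),
                "beta_mean": beta,
            }
            if label == "unattended":
                row["beta_adjusted"] = beta * attention_factor
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# end-to-end scene analysis
# --------------------------------------------------------------------------

@dataclass
class SceneAnalysis:
    """Everything the model computes for one scene under one attention state."""

    visible: VisibleImage
    response: ResponseField
    accuracy: AccuracyField
    profile: EccentricityProfile


def analyze_scene(rgb: np.ndarray, calib, rule: SamplingRule,
                  tp=None, eccentricities: Sequence[float] | None = None,
                  *, boundary: str = "mirror") -> SceneAnalysis:
    """Run the full model on an RGB scene and collect the quality profile.

    ``calib`` is a CalibratedBank; ``tp`` may override the transducer state
    (e.g. an unattended attention factor) while z values stay frozen.
    Use ``boundary="wrap"`` for FFT-periodic synthetic scenes (exact, no
    border artifacts); keep the mirror default for photographs.
    """
    from .filterbank import linear_responses, to_opponent
    from .response_model import accuracy_field, field_responses

    bank = calib.bank
    opp = to_opponent(rgb)
    lin = linear_responses(opp, bank, boundary=boundary)
    resp = field_responses(lin, calib, tp)
    acc = accuracy_field(resp)
    visible = reconstruct_visible(lin, acc, bank, boundary=boundary)
    profile = eccentricity_profile(visible, resp, acc, bank, rule, eccentricities)
    return SceneAnalysis(visible, resp, acc, profile)
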