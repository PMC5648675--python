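"""Calibrated-image pathway: linearize, equalize, and segment throat photos.

Digital cameras apply a nonlinear (roughly power-law) transfer to scene
radiance. Quantitative color work therefore (1) fits a per-channel inverse
mapping from the six gray patches of a color-checker standard with known
reflectances, (2) equalizes the linearized channels against the gray patch
nearest the subject to remove illuminant gain, and (3) classifies each
throat pixel as gray, orange, or yellow from its chromaticity, yielding
color proportions per image.

Pixel scores: with chromaticities r = R/(R+G+B) etc., a pixel is orange if
r - g >= orange threshold (default 0.20), else yellow if (r+g)/2 - b >=
yellow threshold (default 0.15), else gray. The orange test runs first and
its threshold is the higher of the two, so saturated long-wave pixels are
never mislabeled yellow. The score functions are pluggable so alternative
published classifiers can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit

__all__ = [
    "GrayStandardSet",
    "CalibrationModel",
    "SegmentationMap",
    "Thresholds",
    "fit_linearization",
    "equalize_image",
    "classify_pixels",
    "classify_pixel",
    "segment_throat",
    "proportions_timeseries",
    "LABELS",
]

LABELS = ("gray", "orange", "yellow", "excluded")
LABEL_CODES = {name: i for i, name in enumerate(LABELS)}


@dataclass(frozen=True)
class Thresholds:
    """Chromaticity-score thresholds; orange is deliberately the stricter one."""
    orange: float = 0.20
    yellow: float = 0.15


@dataclass(frozen=True)
class GrayStandardSet:
    """Six gray-checker patches: known reflectances + mean camera responses."""

    known_reflectances: np.ndarray      # (6,), strictly increasing, in (0, 1)
    mean_responses: np.ndarray          # (6, 3) per-channel patch means

    def __post_init__(self) -> None:
        refl = np.asarray(self.known_reflectances, dtype=float)
        resp = np.asarray(self.mean_responses, dtype=float)
        object.__setattr__(self, "known_reflectances", refl)
        object.__setattr__(self, "mean_responses", resp)
        if refl.shape != (6,):
            raise ValueError("exactly six gray patches are required")
        if not np.all(np.diff(refl) > 0):
            raise ValueError("known reflectances must be strictly increasing")
        if not np.all((refl > 0) & (refl < 1)):
            raise ValueError("known reflectances must lie in (0, 1)")
        if resp.shape != (6, 3):
            raise ValueError("mean_responses must be shaped (6, 3)")


def _forward(refl, a, gamma, c):
    return a * refl ** (1.0 / gamma) + c


@dataclass
class CalibrationModel:
    """Per-channel monotone mapping from raw camera response to linear reflectance.

    Primary form: response = a * reflectance**(1/gamma) + c fitted by least
    squares per channel, inverted analytically. Channels with non-monotone
    patch responses fall back to a monotone interpolating spline.
    """

    params: list[tuple[float, float, float] | None]   # (a, gamma, c) or None if spline
    splines: list[PchipInterpolator | None]
    residual_rms: np.ndarray = field(default=None)    # per-channel RMS in reflectance units
    method: list[str] = field(default_factory=lambda: ["power", "power", "power"])

    def linearize_channel(self, values: np.ndarray, channel: int) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.splines[channel] is not None:
            out = self.splines[channel](values)
        else:
            a, gamma, c = self.params[channel]
            base = np.clip((values - c) / a, 0.0, None)
            out = base ** gamma
        return np.clip(out, 0.0, None)

    def linearize(self, image: np.ndarray) -> np.ndarray:
        """Map an (H, W, 3) raw image to linear reflectance-scaled values."""
        image = np.asarray(image, dtype=float)
        out = np.empty_like(image)
        for ch in range(3):
            out[..., ch] = self.linearize_channel(image[..., ch], ch)
        return out


def fit_linearization(standards: GrayStandardSet) -> CalibrationModel:
    """Fit the per-channel camera inverse from six gray-patch measurements.

    Raises on duplicate responses within a channel; warns and falls back to
    a shape-preserving monotone spline when patch responses are not
    monotone in known reflectance.
    """
    refl = standards.known_reflectances
    params: list[tuple[float, float, float] | None] = []
    splines: list[PchipInterpolator | None] = []
    methods: list[str] = []
    rms = np.empty(3)
    for ch in range(3):
        resp = standards.mean_responses[:, ch]
        if np.unique(resp).size != resp.size:
            raise ValueError(f"channel {ch}: duplicate patch responses; cannot calibrate")
        if not np.all(np.diff(resp) > 0):
            warnings.warn(f"channel {ch}: non-monotone patch responses; "
                          "falling back to monotone spline", stacklevel=2)
            order = np.argsort(resp)
            spline = PchipInterpolator(resp[order], refl[order], extrapolate=True)
            params.append(None)
            splines.append(spline)
            methods.append("pchip")
            rms[ch] = float(np.sqrt(np.mean((spline(resp) - refl) ** 2)))
            continue
        scale = max(resp.max(), 1e-12)
        p0 = (scale, 2.2, 0.0)
        popt, _ = curve_fit(_forward, refl, resp, p0=p0, maxfev=20000,
                            bounds=([1e-9, 0.2, -np.inf], [np.inf, 10.0, np.inf]))
        params.append(tuple(float(v) for v in popt))
        splines.append(None)
        methods.append("power")
        a, gamma, c = popt
        inv = np.clip((resp - c) / a, 0.0, None) ** gamma
        rms[ch] = float(np.sqrt(np.mean((inv - refl) ** 2)))
    return CalibrationModel(params=params, splines=splines,
                            residual_rms=rms, method=methods)


def equalize_image(linear_image: np.ndarray, patch_mask: np.ndarray,
                   reference_reflectance: float) -> np.ndarray:
    """Scale each channel so the reference gray patch reads its known reflectance.

    Removes residual per-channel illuminant gain: after equalization the
    patch has equal channel means, each equal to ``reference_reflectance``.
    Idempotent.
    """
    linear_image = np.asarray(linear_image, dtype=float)
    patch_mask = np.asarray(patch_mask, dtype=bool)
    if not patch_mask.any():
        raise ValueError("reference patch region is empty")
    means = linear_image[patch_mask].mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("degenerate reference patch: zero mean in a channel")
    gains = reference_reflectance / means
    return linear_image * gains


def pixel_scores(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orange and yellow chromaticity scores for an (..., 3) pixel array.

    orange score = r - g; yellow score = (r + g)/2 - b, with r, g, b the
    channel chromaticities. Pixels summing to zero get NaN scores.
    """
    pixels = np.asarray(pixels, dtype=float)
    total = pixels.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chrom = pixels / total[..., None]
    r, g, b = chrom[..., 0], chrom[..., 1], chrom[..., 2]
    return r - g, (r + g) / 2.0 - b


def classify_pixels(pixels: np.ndarray,
                    thresholds: Thresholds = Thresholds()) -> np.ndarray:
    """Label each pixel gray/orange/yellow (codes 0/1/2; 3 = excluded).

    Orange is tested first at its (higher) threshold; all-zero pixels are
    excluded rather than forced into a class.
    """
    pixels = np.asarray(pixels, dtype=float)
    if np.any(pixels < 0) or not np.all(np.isfinite(pixels)):
        raise ValueError("pixels must be finite and non-negative")
    orange_score, yellow_score = pixel_scores(pixels)
    labels = np.full(pixels.shape[:-1], LABEL_CODES["gray"], dtype=np.uint8)
    zero = pixels.sum(axis=-1) == 0
    is_orange = ~zero & (orange_score >= thresholds.orange)
    is_yellow = ~zero & ~is_orange & (yellow_score >= thresholds.yellow)
    labels[is_orange] = LABEL_CODES["orange"]
    labels[is_yellow] = LABEL_CODES["yellow"]
    labels[zero] = LABEL_CODES["excluded"]
    return labels


def classify_pixel(rgb, thresholds: Thresholds = Thresholds()) -> str:
    """Classify one linear, equalized RGB triple; returns the label name."""
    return LABELS[int(classify_pixels(np.asarray(rgb, dtype=float)[None, :],
                                      thresholds)[0])]


@dataclass(frozen=True)
class SegmentationMap:
    """Per-pixel labels over a throat mask with class proportions."""

    labels: np.ndarray                   # (H, W) uint8 codes into LABELS; excluded outside mask
    proportions: dict[str, float]        # over in-mask, non-excluded pixels; sums to 1
    orange_score: np.ndarray | None = None   # exported for audit
    yellow_score: np.ndarray | None = None

    def counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == LABEL_CODES[name]))
                for name in ("gray", "orange", "yellow")}


def segment_throat(image: np.ndarray, mask: np.ndarray,
                   thresholds: Thresholds = Thresholds()) -> SegmentationMap:
    """Segment a linearized, equalized image into gray/orange/yellow within a mask."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("image must be (H, W, 3)")
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape must match image")
    if not mask.any():
        raise ValueError("throat mask is empty")
    labels = classify_pixels(image, thresholds)
    labels[~mask] = LABEL_CODES["excluded"]
    valid = mask & (labels != LABEL_CODES["excluded"])
    n = int(valid.sum())
    if n == 0:
        raise ValueError("all in-mask pixels are excluded (zero-valued)")
    props = {name: float(np.sum(labels[valid] == LABEL_CODES[name])) / n
             for name in ("gray", "orange", "yellow")}
    orange_score, yellow_score = pixel_scores(image)
    return SegmentationMap(labels=labels, proportions=props,
                           orange_score=orange_score, yellow_score=yellow_score)


def proportions_timeseries(records: list[dict]) -> pd.DataFrame:
    """Assemble per-individual, per-week segmentations into a tidy table.

    Each record: {"id", "week", "treatment", "segmentation": SegmentationMap}.
    Returns rows {id, week, treatment, prop_gray, prop_orange, prop_yellow}.
    """
    rows = []
    for rec in records:
        seg = rec["segmentation"]
        rows.append({
            "id": rec["id"],
            "week": rec["week"],
            "treatment": rec["treatment"],
            "prop_gray": seg.proportions["gray"],
            "prop_orange": seg.proportions["orange"],
            "prop_yellow": seg.proportions["yellow"],
        })
    df = pd.DataFrame(rows)
    if df.duplicated(subset=["id", "week"]).any():
        dupes = df[df.duplicated(subset=["id", "week"], keep=False)]
        raise ValueError(f"duplicate (id, week) keys:\n{dupes[['id', 'week']]}")
    return df
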