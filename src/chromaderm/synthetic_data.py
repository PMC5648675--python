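"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators, each a pure function of (spec, seed):

* skin-class reflectance spectra (orange / yellow / dark_gray / cream /
  white_standard) — long-pass cut-on shapes for the pigmentary classes,
  flat spectra for the achromatic ones;
* reticulated throat images through a camera forward model (power-law
  transfer, gain, offset, noise, quantization) with an embedded six-patch
  gray checker and an exact per-pixel class ground truth;
* layered dermal micrograph masks (epidermis, iridophore cells with
  quasi-ordered guanine platelets, melanophore decoys) with achieved
  iridophore column-fraction and platelet fill computed by pixel counting;
* two-arm, three-timepoint longitudinal tables with per-individual random
  intercepts and configurable treatment-by-time effects.

Ground truth is always returned alongside the data so downstream
estimators are tested against it rather than against generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .spectra import Spectrum, default_grid
from .tem_morphometrics import DEFAULT_CLASS_MAP, LabeledMicrograph

__all__ = [
    "SceneSpec",
    "MicrographSpec",
    "EffectSpec",
    "generate_reflectance",
    "generate_throat_image",
    "generate_micrograph",
    "generate_longitudinal",
    "CHECKER_REFLECTANCES",
    "TABLE_ACHROMATIC_CELL_MEANS",
]

#: Six gray-checker patch reflectances (darkest to lightest).
CHECKER_REFLECTANCES = (0.03, 0.09, 0.19, 0.36, 0.59, 0.90)

SKIN_CLASSES = ("orange", "yellow", "dark_gray", "cream", "white_standard")


# ---------------------------------------------------------------------------
# reflectance spectra


def _logistic_cuton(grid: np.ndarray, cut_nm: float, width_nm: float,
                    base: float, amplitude: float) -> np.ndarray:
    return base + amplitude / (1.0 + np.exp(-(grid - cut_nm) / width_nm))


#: per-class shape parameters; jitter entries are 1-sigma seeded perturbations
_REFLECTANCE_PARAMS = {
    "orange": dict(cut_nm=565.0, width_nm=25.0, base=0.04, amplitude=0.45,
                   cut_jitter=5.0, amp_jitter=0.04),
    "yellow": dict(cut_nm=505.0, width_nm=20.0, base=0.05, amplitude=0.50,
                   cut_jitter=5.0, amp_jitter=0.04),
    "dark_gray": dict(mean=0.08, jitter=0.01),
    "cream": dict(mean=0.55, jitter=0.05),
}


def generate_reflectance(skin_class: str, params: dict | None = None,
                         seed: int | None = 0) -> Spectrum:
    """A plausible reflectance spectrum for one skin class.

    Orange and yellow are logistic long-pass cut-on curves (the orange
    cut-on sits at longer wavelengths than the yellow one); dark gray and
    cream are spectrally flat at low and high mean reflectance; the white
    standard is flat 0.99 with no jitter. Deterministic given the seed.
    """
    grid = default_grid()
    if skin_class == "white_standard":
        return Spectrum(grid, np.full(grid.size, 0.99), kind="reflectance",
                        name="white_standard")
    if skin_class not in SKIN_CLASSES:
        raise ValueError(f"unknown skin class {skin_class!r}; "
                         f"expected one of {SKIN_CLASSES}")
    p = dict(_REFLECTANCE_PARAMS[skin_class])
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    if skin_class in ("orange", "yellow"):
        cut = p["cut_nm"] + rng.normal(0.0, p["cut_jitter"])
        amp = p["amplitude"] + rng.normal(0.0, p["amp_jitter"])
        vals = _logistic_cuton(grid, cut, p["width_nm"], p["base"],
                               max(amp, 0.05))
    else:
        mean = p["mean"] + rng.normal(0.0, p["jitter"])
        vals = np.full(grid.size, max(mean, 0.01))
    return Spectrum(grid, np.clip(vals, 0.0, 1.0), kind="reflectance",
                    name=skin_class)


# ---------------------------------------------------------------------------
# throat images


@dataclass(frozen=True)
class SceneSpec:
    """Reticulated throat scene plus camera forward model.

    Default proportions echo a typical pre-treatment throat (mostly gray
    reticulation with orange and yellow patches); class RGB means are
    linear reflectance-scale values that the chromaticity classifier
    separates with wide margins.
    """

    proportions: tuple[float, float, float] = (0.77, 0.15, 0.08)  # gray, orange, yellow
    shape: tuple[int, int] = (160, 200)          # throat rows, cols
    reticulation_scale_px: float = 6.0
    class_rgb: dict = field(default_factory=lambda: {
        "gray": (0.30, 0.30, 0.30),
        "orange": (0.55, 0.20, 0.08),
        "yellow": (0.55, 0.50, 0.10),
    })
    class_noise_sigma: float = 0.01
    patch_reflectances: tuple = CHECKER_REFLECTANCES
    illuminant_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gamma: float = 2.2
    gain: float = 1.0
    offset: float = 0.0
    noise_sigma: float = 0.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(p < 0 for p in self.proportions):
            raise ValueError("class proportions must be non-negative")
        if self.class_noise_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")


def _apply_camera(linear: np.ndarray, spec: SceneSpec,
                  rng: np.random.Generator) -> np.ndarray:
    resp = spec.gain * np.clip(linear, 0.0, None) ** (1.0 / spec.gamma) + spec.offset
    if spec.noise_sigma > 0:
        resp = resp + rng.normal(0.0, spec.noise_sigma, size=resp.shape)
    resp = np.clip(resp, 0.0, 1.0)
    levels = 2 ** spec.bit_depth - 1
    return np.round(resp * levels) / levels


def generate_throat_image(spec: SceneSpec) -> dict:
    """Render a reticulated throat image with gray checker and ground truth.

    The throat texture is smoothed seeded noise thresholded at rank
    quantiles, so class pixel counts hit the target proportions exactly
    (up to +-1 pixel per class from rounding). Six neutral checker patches
    sit in a strip above the throat. Returns a dict with:

    ``raw`` (H, W, 3) camera response in [0, 1]; ``linear_scene`` the
    pre-camera linear image; ``true_labels`` (throat rows only; codes
    0=gray, 1=orange, 2=yellow); ``throat_mask``; ``patch_masks`` list of
    boolean masks; ``patch_reflectances``; ``annotations`` JSON-ready
    sidecar.
    """
    rng = np.random.default_rng(spec.seed)
    th, tw = spec.shape
    patch_h = 20
    gap = 4
    H, W = th + patch_h + gap, max(tw, 6 * 24)
    tw = W  # throat spans full width

    # --- exact-proportion reticulated labels over the throat block
    noise = ndimage.gaussian_filter(
        rng.standard_normal((th, tw)), sigma=spec.reticulation_scale_px)
    flat = noise.ravel()
    order = np.argsort(flat, kind="stable")
    n = flat.size
    n_gray = int(round(spec.proportions[0] * n))
    n_orange = int(round(spec.proportions[1] * n))
    n_orange = min(n_orange, n - n_gray)
    labels = np.empty(n, dtype=np.uint8)
    labels[order[:n_gray]] = 0
    labels[order[n_gray:n_gray + n_orange]] = 1
    labels[order[n_gray + n_orange:]] = 2
    labels = labels.reshape(th, tw)

    # --- linear scene
    linear = np.zeros((H, W, 3))
    linear[:patch_h, :, :] = 0.5  # neutral strip behind the checker
    class_names = ("gray", "orange", "yellow")
    throat = np.zeros((th, tw, 3))
    for code, cname in enumerate(class_names):
        mean = np.array(spec.class_rgb[cname])
        sel = labels == code
        vals = mean[None, :] + rng.normal(0.0, spec.class_noise_sigma,
                                          size=(int(sel.sum()), 3))
        throat[sel] = np.clip(vals, 0.01, 1.0)
    linear[patch_h + gap:, :, :] = throat

    # --- checker patches (neutral squares along the strip)
    patch_masks = []
    pw = W // 6
    side = min(patch_h - 4, pw - 4)
    for i, refl in enumerate(spec.patch_reflectances):
        r0, c0 = 2, i * pw + 2
        m = np.zeros((H, W), dtype=bool)
        m[r0:r0 + side, c0:c0 + side] = True
        linear[m] = refl
        patch_masks.append(m)

    throat_mask = np.zeros((H, W), dtype=bool)
    throat_mask[patch_h + gap:, :] = True

    # --- illuminant and camera
    lit = linear * np.asarray(spec.illuminant_gains)[None, None, :]
    raw = _apply_camera(lit, spec, rng)

    annotations = {
        "patches": [
            {"label": f"gray_{i+1}", "known_reflectance": float(refl),
             "rows": [2, 2 + side], "cols": [i * pw + 2, i * pw + 2 + side]}
            for i, refl in enumerate(spec.patch_reflectances)
        ],
        "throat_rows": [patch_h + gap, H],
        "seed": spec.seed,
    }
    return {
        "raw": raw,
        "linear_scene": linear,
        "true_labels": labels,
        "throat_mask": throat_mask,
        "patch_masks": patch_masks,
        "patch_reflectances": np.asarray(spec.patch_reflectances),
        "annotations": annotations,
    }


# ---------------------------------------------------------------------------
# micrographs


@dataclass(frozen=True)
class MicrographSpec:
    """Layered dermal micrograph geometry (all lengths in um).

    Defaults put iridophore cells in a 5-12 um band below the epidermis
    (the zone where they dominate in tawny dragon skin), at TEM-like
    0.02 um/px resolution, with a platelet fill typical of gray/yellow
    skin; melanophore decoys sit deeper.
    """

    width_um: float = 80.0
    height_um: float = 22.0
    pixel_size_um: float = 0.02
    epidermis_depth_um: float = 2.0
    iridophore_band_um: tuple[float, float] = (5.0, 12.0)
    cell_axes_um: tuple[float, float] = (4.5, 2.5)     # full lateral x depth axes
    target_column_fraction: float = 0.30
    max_cells: int = 400
    platelet_size_um: tuple[float, float] = (0.5, 0.10)  # length x thickness
    platelet_angle_jitter: float = 0.5                   # radians, uniform half-range
    target_fill: float = 0.40
    hole_fraction: float = 0.20
    n_melanophores: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fill <= 0.85):
            raise ValueError("target_fill outside feasible range [0, 0.85]")
        if not (0.0 <= self.target_column_fraction <= 0.95):
            raise ValueError("target_column_fraction outside [0, 0.95]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def _paint_ellipse(labels: np.ndarray, center_rc: tuple[float, float],
                   semi_rc: tuple[float, float], code: int) -> np.ndarray:
    """Paint an axis-aligned ellipse; returns the painted boolean region."""
    h, w = labels.shape
    cr, cc = center_rc
    sr, sc = semi_rc
    r0, r1 = max(int(cr - sr) - 1, 0), min(int(cr + sr) + 2, h)
    c0, c1 = max(int(cc - sc) - 1, 0), min(int(cc + sc) + 2, w)
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    inside = ((rr - cr) / sr) ** 2 + ((cc_ - cc) / sc) ** 2 <= 1.0
    region = np.zeros_like(labels, dtype=bool)
    region[r0:r1, c0:c1] = inside
    labels[region] = code
    return region


def _paint_platelet(labels: np.ndarray, cell: np.ndarray,
                    plate_mask: np.ndarray,
                    center_rc: tuple[float, float], angle: float,
                    half_len_px: float, half_thick_px: float,
                    code: int) -> int:
    """Paint a rotated rectangle clipped to the cell interior.

    Returns the number of newly platelet-covered pixels (``plate_mask`` is
    updated in place alongside ``labels``).
    """
    h, w = labels.shape
    cr, cc = center_rc
    rad = half_len_px + half_thick_px + 2
    r0, r1 = max(int(cr - rad), 0), min(int(cr + rad) + 1, h)
    c0, c1 = max(int(cc - rad), 0), min(int(cc + rad) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return 0
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr - cr, cc_ - cc
    u = dc * np.cos(angle) + dr * np.sin(angle)      # along the long axis
    v = -dc * np.sin(angle) + dr * np.cos(angle)
    inside = (np.abs(u) <= half_len_px) & (np.abs(v) <= half_thick_px)
    inside &= cell[r0:r1, c0:c1]
    new = inside & ~plate_mask[r0:r1, c0:c1]
    labels[r0:r1, c0:c1][inside] = code
    plate_mask[r0:r1, c0:c1][inside] = True
    return int(new.sum())


def generate_micrograph(spec: MicrographSpec) -> dict:
    """Build a labeled dermal micrograph with known morphometric truth.

    Iridophore ellipses are added in the depth band until the mean
    iridophore column-fraction over the 15-um measurement window reaches
    the target. Platelets are quasi-ordered: rotated rectangles on a
    jittered lattice sized for the target fill, topped up randomly until
    each cell's achieved fill reaches the target; a fixed fraction are
    relabeled as preparation holes (holes count as platelet material in
    all measurements). Returns the mask plus achieved (pixel-counted)
    column-fraction and fill.
    """
    cmap = DEFAULT_CLASS_MAP
    px = spec.pixel_size_um
    H = int(round(spec.height_um / px))
    W = int(round(spec.width_um / px))
    rng = np.random.default_rng(spec.seed)

    labels = np.full((H, W), cmap["xanthophore_or_collagen"], dtype=np.uint8)
    epi_px = int(round(spec.epidermis_depth_um / px))
    labels[:epi_px, :] = cmap["epidermis"]
    boundary = np.full(W, epi_px, dtype=int)

    win0, win1 = epi_px, min(epi_px + int(round(15.0 / px)), H)
    win_rows = win1 - win0
    sr = spec.cell_axes_um[1] / 2.0 / px   # depth semi-axis (rows)
    sc = spec.cell_axes_um[0] / 2.0 / px   # lateral semi-axis (cols)
    band0, band1 = spec.iridophore_band_um
    irid_code = cmap["iridophore"]

    n_cells = 0
    irid = np.zeros((H, W), dtype=bool)
    win_count = 0
    target_count = spec.target_column_fraction * win_rows * W
    for _ in range(spec.max_cells):
        if win_count >= target_count:
            break
        depth = rng.uniform(band0, band1)
        cr = epi_px + depth / px
        cc = rng.uniform(0, W)
        region = _paint_ellipse(labels, (cr, cc), (sr, sc), irid_code)
        win_count += int((region[win0:win1] & ~irid[win0:win1]).sum())
        irid |= region
        n_cells += 1

    # platelets, quasi-ordered within each merged iridophore region (cells
    # may overlap; laying one lattice per merged component keeps the fill
    # uniform instead of doubling up where cells meet)
    plate_len = spec.platelet_size_um[0] / px
    plate_th = spec.platelet_size_um[1] / px
    plate_area_px = plate_len * plate_th
    platelet_code, hole_code = cmap["platelet"], cmap["platelet_hole"]
    plate_codes = (platelet_code, hole_code)
    if spec.target_fill > 0 and irid.any():
        lattice = np.sqrt(plate_area_px / spec.target_fill)
        comp_labels, n_comp = ndimage.label(irid)
        plate_mask = np.zeros_like(irid)
        slices = ndimage.find_objects(comp_labels)
        for ci, sl in enumerate(slices, start=1):
            comp = comp_labels == ci
            rows, cols = np.nonzero(comp)
            comp_px = rows.size
            if comp_px == 0:
                continue
            plate_count = 0
            base_angle = rng.uniform(0, np.pi)

            def _add(center_rc) -> int:
                ang = base_angle + rng.uniform(-1, 1) * spec.platelet_angle_jitter
                code = (hole_code if rng.random() < spec.hole_fraction
                        else platelet_code)
                return _paint_platelet(labels, comp, plate_mask, center_rc,
                                       ang, plate_len / 2, plate_th / 2, code)

            for gr in np.arange(sl[0].start, sl[0].stop, lattice):
                for gc in np.arange(sl[1].start, sl[1].stop, lattice):
                    jr = gr + rng.uniform(-0.35, 0.35) * lattice
                    jc = gc + rng.uniform(-0.35, 0.35) * lattice
                    plate_count += _add((jr, jc))
            guard = 0
            while plate_count < spec.target_fill * comp_px and guard < comp_px:
                k = rng.integers(comp_px)
                plate_count += _add((float(rows[k]), float(cols[k])))
                guard += 1

    # melanophore decoys below the iridophore band
    mel_sr, mel_sc = 1.5 / px, 3.0 / px
    for _ in range(spec.n_melanophores):
        cr = epi_px + rng.uniform(16.0, spec.height_um - spec.epidermis_depth_um - 1.5) / px
        cc = rng.uniform(0, W)
        _paint_ellipse(labels, (min(cr, H - 2), cc), (mel_sr, mel_sc),
                       cmap["melanophore"])

    mask = LabeledMicrograph(labels=labels, pixel_size_um=px,
                             epidermis_boundary=boundary, class_map=dict(cmap))

    irid_all = np.isin(labels, [irid_code, platelet_code, hole_code])
    achieved_cf = irid_all[win0:win1].sum() / (win_rows * W)
    plate_px = int(np.isin(labels, plate_codes).sum())
    irid_px = int(irid_all.sum())
    achieved_fill = plate_px / irid_px if irid_px else 0.0
    return {
        "micrograph": mask,
        "achieved_column_fraction": float(achieved_cf),
        "achieved_fill": float(achieved_fill),
        "n_cells": n_cells,
        "spec": spec,
    }


# ---------------------------------------------------------------------------
# longitudinal tables


#: Achromatic-contrast cell means (JND) of the default treatment scenario:
#: corticosterone-treated animals decline by ~6.27 JND from pre-treatment to
#: week 4 while controls stay flat.
TABLE_ACHROMATIC_CELL_MEANS = {
    ("cort", "pre"): 19.518, ("cort", "week1"): 15.014, ("cort", "week4"): 13.253,
    ("control", "pre"): 15.651, ("control", "week1"): 14.985, ("control", "week4"): 15.018,
}

TIMEPOINTS = ("pre", "week1", "week4")


@dataclass(frozen=True)
class EffectSpec:
    """Two-group, three-timepoint repeated-measures design.

    ``cell_means`` maps (treatment, time) to the fixed-effect mean;
    individuals get Normal(0, sigma_id^2) random intercepts and
    observations Normal(0, sigma_resid^2) residuals.
    """

    n_cort: int = 12
    n_control: int = 11
    timepoints: tuple[str, ...] = TIMEPOINTS
    cell_means: dict = field(
        default_factory=lambda: dict(TABLE_ACHROMATIC_CELL_MEANS))
    sigma_id: float = 4.0
    sigma_resid: float = 3.0
    response_name: str = "achromatic_contrast"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cort < 2 or self.n_control < 2:
            raise ValueError("need at least 2 individuals per arm")
        if self.sigma_id < 0 or self.sigma_resid < 0:
            raise ValueError("variance components must be non-negative")

    @classmethod
    def null(cls, mu: float = 15.0, **kwargs) -> "EffectSpec":
        """A no-effect scenario: every cell mean equals ``mu``."""
        cells = {(g, t): mu for g in ("cort", "control") for t in TIMEPOINTS}
        return cls(cell_means=cells, **kwargs)


def generate_longitudinal(spec: EffectSpec) -> pd.DataFrame:
    """Simulate a tidy longitudinal table from an effect specification.

    Rows: {id, treatment, time, response, response_name}. Deterministic
    given spec.seed; in the noiseless limit responses equal the cell means
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    idn = 0
    for treatment, n in (("cort", spec.n_cort), ("control", spec.n_control)):
        for _ in range(n):
            idn += 1
            b = rng.normal(0.0, spec.sigma_id) if spec.sigma_id > 0 else 0.0
            for t in spec.timepoints:
                eps = rng.normal(0.0, spec.sigma_resid) if spec.sigma_resid > 0 else 0.0
                rows.append({
                    "id": f"L{idn:02d}",
                    "treatment": treatment,
                    "time": t,
                    "response": spec.cell_means[(treatment, t)] + b + eps,
                    "response_name": spec.response_name,
                })
    return pd.DataFrame(rows)
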