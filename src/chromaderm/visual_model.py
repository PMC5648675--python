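"""Receptor-noise-limited (RNL) visual model for a tetrachromatic lizard.

The model predicts whether two stimuli are discriminable to an animal
observer given its photoreceptor spectral sensitivities and channel noise.
Perceptual distance is expressed in just-noticeable-differences (JND):
1 JND is the discrimination threshold under the model's assumptions.

Pipeline: quantal catches Q_i = integral of R_i(lambda) S(lambda) I(lambda)
over 300-700 nm; log receptor contrasts dF_i = ln(Q_i^stim / Q_i^bg);
chromatic distance dS from the n-receptor RNL formula with Weber fractions
omega_i; achromatic distance dL = |dF_L| / omega_ach from the long-wave
(double-cone equivalent) channel alone.

Defaults match a tawny-dragon-like visual system: lambda_max at
365 (UVS), 440 (SWS), 493 (MWS), 571 (LWS) nm; receptor relative
abundances 1 : 1 : 3.5 : 6; omega_LWS = 0.1; achromatic omega = 0.05.
Sensitivities are the Govardovskii A1 visual-pigment nomogram (alpha band;
beta band optional). Ocular media transmission is not modeled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .spectra import Spectrum, default_grid, flat_spectrum, resample_spectrum

__all__ = [
    "PhotoreceptorClass",
    "VisualSystem",
    "ReceptorStimulation",
    "pigment_template",
    "quantal_catch",
    "derive_weber_fractions",
    "chromatic_contrast",
    "achromatic_contrast",
    "receptor_stimulation",
    "contrast_vs_white",
]


@dataclass(frozen=True)
class PhotoreceptorClass:
    """One photoreceptor class: peak wavelength, abundance, derived noise."""

    name: str
    lambda_max_nm: float
    relative_abundance: float
    weber_fraction: float | None = None

    def __post_init__(self) -> None:
        if not (300.0 < self.lambda_max_nm < 700.0):
            raise ValueError(f"lambda_max {self.lambda_max_nm} nm outside (300, 700)")
        if self.relative_abundance <= 0:
            raise ValueError("relative_abundance must be positive")
        if self.weber_fraction is not None and self.weber_fraction <= 0:
            raise ValueError("weber_fraction must be positive")


@dataclass(frozen=True)
class VisualSystem:
    """An ordered set of photoreceptor classes plus noise conventions.

    ``reference_class`` is the class whose Weber fraction is fixed at
    ``reference_weber``; the others are derived from relative abundances.
    ``achromatic_class`` drives the luminance channel with its own noise
    ``achromatic_weber``.
    """

    classes: tuple[PhotoreceptorClass, ...]
    reference_class: str = "LWS"
    reference_weber: float = 0.1
    achromatic_weber: float = 0.05
    achromatic_class: str = "LWS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        names = [c.name for c in self.classes]
        if len(self.classes) < 2:
            raise ValueError("a visual system needs at least 2 receptor classes")
        if len(set(names)) != len(names):
            raise ValueError("photoreceptor class names must be unique")
        for ref in (self.reference_class, self.achromatic_class):
            if ref not in names:
                raise ValueError(f"{ref!r} is not a member photoreceptor class")
        if self.reference_weber <= 0 or self.achromatic_weber <= 0:
            raise ValueError("Weber fractions must be positive")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.classes]

    def get(self, name: str) -> PhotoreceptorClass:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(name)

    def weber_fractions(self) -> np.ndarray:
        ws = [c.weber_fraction for c in self.classes]
        if any(w is None for w in ws):
            raise ValueError("Weber fractions not derived; call derive_weber_fractions")
        return np.array(ws, dtype=float)

    @classmethod
    def tawny_dragon(cls) -> "VisualSystem":
        """Default tetrachromatic system (UVS/SWS/MWS/LWS, abundances 1:1:3.5:6)."""
        return derive_weber_fractions(cls(
            classes=(
                PhotoreceptorClass("UVS", 365.0, 1.0),
                PhotoreceptorClass("SWS", 440.0, 1.0),
                PhotoreceptorClass("MWS", 493.0, 3.5),
                PhotoreceptorClass("LWS", 571.0, 6.0),
            ),
        ))

    @classmethod
    def from_dict(cls, cfg: dict) -> "VisualSystem":
        classes = tuple(
            PhotoreceptorClass(c["name"], float(c["lambda_max_nm"]),
                               float(c["relative_abundance"]))
            for c in cfg["classes"]
        )
        sys = cls(
            classes=classes,
            reference_class=cfg.get("reference_class", "LWS"),
            reference_weber=float(cfg.get("reference_weber", 0.1)),
            achromatic_weber=float(cfg.get("achromatic_weber", 0.05)),
            achromatic_class=cfg.get("achromatic_class", "LWS"),
        )
        return derive_weber_fractions(sys)

    @classmethod
    def from_yaml(cls, path) -> "VisualSystem":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ReceptorStimulation:
    """Per-class quantal catches and log contrasts against a background."""

    catches: np.ndarray          # Q_i, stimulus
    background_catches: np.ndarray
    log_contrasts: np.ndarray    # dF_i = ln(Q_i / Q_i^bg)

    def __post_init__(self) -> None:
        for arr in (self.catches, self.background_catches):
            if np.any(np.asarray(arr) <= 0):
                raise ValueError("quantal catches must be positive")


# Govardovskii et al. (2000) A1 alpha-band nomogram constants.
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


def _govardovskii_alpha(lambda_max: float, wl: np.ndarray) -> np.ndarray:
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    return 1.0 / (np.exp(_A * (a - x)) + np.exp(_B * (_b - x))
                  + np.exp(_C * (_c - x)) + _D)


def _govardovskii_beta(lambda_max: float, wl: np.ndarray) -> np.ndarray:
    a_beta = 0.26
    lm_beta = 189.0 + 0.315 * lambda_max
    d = -40.5 + 0.195 * lambda_max
    return a_beta * np.exp(-(((wl - lm_beta) / d) ** 2))


def pigment_template(lambda_max_nm: float, grid: np.ndarray | None = None,
                     beta_band: bool = False) -> Spectrum:
    """A1 visual-pigment absorbance template, peak-normalized to 1.

    The alpha band follows the standard rhodopsin nomogram; the small
    UV-side beta band is off by default. The maximum is renormalized to
    exactly 1 at the grid point nearest ``lambda_max_nm``.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if not (grid[0] <= lambda_max_nm <= grid[-1]):
        raise ValueError(f"lambda_max {lambda_max_nm} nm outside grid "
                         f"[{grid[0]}, {grid[-1]}] nm")
    vals = _govardovskii_alpha(lambda_max_nm, grid)
    if beta_band:
        vals = vals + _govardovskii_beta(lambda_max_nm, grid)
    vals = vals / vals.max()
    return Spectrum(grid, vals, kind="sensitivity", name=f"A1_{lambda_max_nm:g}nm")


def quantal_catch(sensitivity: Spectrum, reflectance: Spectrum,
                  irradiance: Spectrum) -> float:
    """Quantal catch Q = integral R(l) S(l) I(l) dl (trapezoidal rule).

    All three spectra must share the same wavelength grid.
    """
    for other in (reflectance, irradiance):
        if (sensitivity.wavelengths_nm.shape != other.wavelengths_nm.shape
                or not np.allclose(sensitivity.wavelengths_nm, other.wavelengths_nm)):
            raise ValueError("spectra must share a common wavelength grid; resample first")
    product = sensitivity.values * reflectance.values * irradiance.values
    return float(np.trapezoid(product, sensitivity.wavelengths_nm))


def derive_weber_fractions(system: VisualSystem) -> VisualSystem:
    """Derive per-class Weber fractions from relative receptor abundances.

    omega_i = omega_ref * sqrt(eta_ref / eta_i): channel noise shrinks with
    the square root of the number of receptors pooled into the channel.
    The reference class keeps omega_ref exactly. Idempotent.
    """
    ref = system.get(system.reference_class)
    new_classes = tuple(
        replace(c, weber_fraction=(
            system.reference_weber if c.name == system.reference_class
            else system.reference_weber * float(np.sqrt(
                ref.relative_abundance / c.relative_abundance))
        ))
        for c in system.classes
    )
    return replace(system, classes=new_classes)


def chromatic_contrast(stim: ReceptorStimulation | np.ndarray,
                       system: VisualSystem | np.ndarray) -> float:
    """Chromatic distance dS in JND from the n-receptor RNL formula.

    dS^2 = sum_{i<j} (dF_i - dF_j)^2 prod_{k != i,j} w_k^2
           / sum_i prod_{k != i} w_k^2

    which reduces to |dF_1 - dF_2| / sqrt(w_1^2 + w_2^2) for a dichromat
    and to the familiar published tri-/tetrachromat expressions. A pure
    intensity shift (constant added to every dF_i) leaves dS unchanged.

    Accepts either (ReceptorStimulation, VisualSystem) or two raw arrays
    (log contrasts, Weber fractions).
    """
    if isinstance(stim, ReceptorStimulation):
        df = np.asarray(stim.log_contrasts, dtype=float)
    else:
        df = np.asarray(stim, dtype=float)
    if isinstance(system, VisualSystem):
        w = system.weber_fractions()
    else:
        w = np.asarray(system, dtype=float)
    n = df.size
    if n < 2 or w.size != n:
        raise ValueError("need >= 2 receptor classes with matching Weber fractions")
    if np.any(w <= 0):
        raise ValueError("Weber fractions must be positive")
    w2 = w ** 2
    prod_all = np.prod(w2)
    # prod over k != i, and over k != i,j, via division (w > 0 guaranteed)
    num = 0.0
    for i, j in itertools.combinations(range(n), 2):
        num += (df[i] - df[j]) ** 2 * prod_all / (w2[i] * w2[j])
    den = float(np.sum(prod_all / w2))
    return float(np.sqrt(num / den))


def achromatic_contrast(stim_catch: float, bg_catch: float,
                        achromatic_weber: float = 0.05) -> float:
    """Achromatic (luminance) distance dL = |ln(Q_stim / Q_bg)| / omega."""
    if stim_catch <= 0 or bg_catch <= 0:
        raise ValueError("quantal catches must be positive")
    if achromatic_weber <= 0:
        raise ValueError("achromatic Weber fraction must be positive")
    return float(abs(np.log(stim_catch / bg_catch)) / achromatic_weber)


def receptor_stimulation(reflectance: Spectrum, background: Spectrum,
                         system: VisualSystem,
                         irradiance: Spectrum | None = None,
                         beta_band: bool = False) -> ReceptorStimulation:
    """Quantal catches and log contrasts of a stimulus against a background.

    All spectra are resampled to the default 1-nm grid; irradiance defaults
    to spectrally flat (results depend on the illuminant shape, so callers
    measuring under real light should pass their own spectrum).
    """
    grid = default_grid()
    if irradiance is None:
        irradiance = flat_spectrum(1.0, kind="irradiance", grid=grid)
    refl = resample_spectrum(reflectance)
    bg = resample_spectrum(background)
    irr = resample_spectrum(irradiance)
    q_stim, q_bg = [], []
    for c in system.classes:
        sens = pigment_template(c.lambda_max_nm, grid, beta_band=beta_band)
        qs = quantal_catch(sens, refl, irr)
        qb = quantal_catch(sens, bg, irr)
        if qs <= 0 or qb <= 0:
            raise ValueError(f"non-positive quantal catch in class {c.name}; "
                             "reflectance is zero over the receptor support")
        q_stim.append(qs)
        q_bg.append(qb)
    q_stim = np.array(q_stim)
    q_bg = np.array(q_bg)
    return ReceptorStimulation(q_stim, q_bg, np.log(q_stim / q_bg))


def contrast_vs_white(reflectance: Spectrum, system: VisualSystem,
                      irradiance: Spectrum | None = None,
                      white_reflectance: float = 0.99) -> dict:
    """Chromatic and achromatic JND of a surface against a neutral white standard.

    The background is a spectrally flat near-perfect diffuse reflector
    (default 99%, the usual white calibration standard). Returns the
    chromatic JND, the achromatic JND, and its natural log (NaN when the
    achromatic contrast is exactly 0, where the log is undefined).
    """
    if white_reflectance <= 0:
        raise ValueError("white_reflectance must be positive")
    white = flat_spectrum(white_reflectance, kind="reflectance")
    stim = receptor_stimulation(reflectance, white, system, irradiance=irradiance)
    ds = chromatic_contrast(stim, system)
    i_ach = system.names.index(system.achromatic_class)
    dl = achromatic_contrast(stim.catches[i_ach], stim.background_catches[i_ach],
                             system.achromatic_weber)
    return {
        "chromatic_jnd": ds,
        "achromatic_jnd": dl,
        "log_achromatic_jnd": float(np.log(dl)) if dl > 0 else float("nan"),
    }
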