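"""TEM morphometry of the dermal chromatophore unit from labeled masks.

Two stereological estimators over pre-labeled micrograph masks:

* Iridophore density: vertical transects run from the dermal side of the
  epidermis to a fixed depth (default 15 um), spaced laterally (default
  5 um). Each transect reports the proportion of its length intersecting
  iridophore material (iridophore cytoplasm, guanine platelets, and the
  holes platelets leave during sectioning all count); the per-sample
  summary is the median across transects.

* Platelet packing: square plots (default 1 x 1 um) placed wholly inside
  iridophore cells measure the area fraction occupied by platelets (holes
  merged with platelets) relative to cytoplasm; the per-sample summary is
  the median plot fraction.

Masks are assumed pre-rotated so the epidermis is horizontal and depth
increases with row index; "vertical" transects are therefore image columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_NAMES",
    "LabeledMicrograph",
    "TransectSet",
    "PlotGrid",
    "extract_transects",
    "median_iridophore_proportion",
    "depth_profile",
    "platelet_area_fraction",
    "morphometry_table",
]

CLASS_NAMES = (
    "background",
    "epidermis",
    "iridophore",
    "melanophore",
    "xanthophore_or_collagen",
    "platelet",
    "platelet_hole",
    "cytoplasm",
)
DEFAULT_CLASS_MAP = {name: i for i, name in enumerate(CLASS_NAMES)}

#: labels counted as iridophore material in transect intersections
IRIDOPHORE_CLASSES = ("iridophore", "platelet", "platelet_hole")
#: labels that may occur inside an iridophore cell (for plot placement)
IRIDOPHORE_INTERIOR = ("iridophore", "platelet", "platelet_hole")


@dataclass(frozen=True)
class LabeledMicrograph:
    """A 2-D class-label mask with physical scale and epidermal origin.

    ``epidermis_boundary[x]`` is the row index of the first dermal pixel
    below the epidermis in column x, or -1 where no tissue is annotated.
    """

    labels: np.ndarray                 # (H, W) int codes
    pixel_size_um: float
    epidermis_boundary: np.ndarray     # (W,) int row indices; -1 = undefined
    class_map: dict[str, int] = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        boundary = np.asarray(self.epidermis_boundary, dtype=int)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "epidermis_boundary", boundary)
        if self.class_map is None:
            object.__setattr__(self, "class_map", dict(DEFAULT_CLASS_MAP))
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if boundary.shape != (labels.shape[1],):
            raise ValueError("epidermis_boundary must have one entry per column")

    def codes(self, names) -> np.ndarray:
        return np.array([self.class_map[n] for n in names])

    def iridophore_mask(self) -> np.ndarray:
        """Boolean mask of iridophore-material pixels."""
        return np.isin(self.labels, self.codes(IRIDOPHORE_CLASSES))


@dataclass(frozen=True)
class TransectSet:
    """Per-transect iridophore intersection proportions at fixed lateral spacing."""

    columns_px: np.ndarray          # image column of each kept transect
    positions_um: np.ndarray        # lateral position of each kept transect
    proportions: np.ndarray         # in [0, 1]
    depth_um: float
    spacing_um: float
    n_dropped: int = 0

    def __len__(self) -> int:
        return self.proportions.size


@dataclass(frozen=True)
class PlotGrid:
    """Square sampling plots inside iridophore cells with platelet area fractions."""

    top_left_px: np.ndarray         # (n, 2) row, col
    plot_size_px: int
    plot_size_um: float
    fractions: np.ndarray           # in [0, 1]

    def __len__(self) -> int:
        return self.fractions.size


def _valid_transect_columns(mask: LabeledMicrograph, depth_px: int) -> np.ndarray:
    """Columns with an annotated boundary and tissue to full depth.

    A transect is kept only if its whole span stays inside the image and
    never crosses background (partial-coverage transects are dropped).
    """
    labels = mask.labels
    h = labels.shape[0]
    bg = mask.class_map["background"]
    boundary = mask.epidermis_boundary
    ok = boundary >= 0
    ok &= (boundary + depth_px) <= h
    cols = np.nonzero(ok)[0]
    keep = []
    for x in cols:
        span = labels[boundary[x]:boundary[x] + depth_px, x]
        if not np.any(span == bg):
            keep.append(x)
    return np.array(keep, dtype=int)


def extract_transects(mask: LabeledMicrograph, depth_um: float = 15.0,
                      spacing_um: float = 5.0) -> TransectSet:
    """Measure iridophore intersection proportions along vertical transects.

    Transects start at the epidermis boundary and run ``depth_um`` into the
    dermis, at every ``spacing_um`` laterally. Transects that exit the
    tissue are dropped (and counted in ``n_dropped``).
    """
    px = mask.pixel_size_um
    depth_px = int(round(depth_um / px))
    step_px = max(int(round(spacing_um / px)), 1)
    if depth_px < 1:
        raise ValueError("depth_um smaller than one pixel")
    candidates = np.arange(0, mask.labels.shape[1], step_px)
    valid = set(_valid_transect_columns(mask, depth_px).tolist())
    irid = mask.iridophore_mask()
    boundary = mask.epidermis_boundary
    cols, props = [], []
    dropped = 0
    for x in candidates:
        if x not in valid:
            dropped += 1
            continue
        span = irid[boundary[x]:boundary[x] + depth_px, x]
        cols.append(x)
        props.append(span.sum() / depth_px)
    if not cols:
        raise ValueError("no valid transect: tissue never spans the full depth")
    cols = np.array(cols, dtype=int)
    return TransectSet(columns_px=cols, positions_um=cols * px,
                       proportions=np.array(props, dtype=float),
                       depth_um=depth_px * px, spacing_um=step_px * px,
                       n_dropped=dropped)


def median_iridophore_proportion(transects: TransectSet) -> float:
    """Median intersection proportion (even count: mean of the two central values)."""
    if len(transects) == 0:
        raise ValueError("empty transect set")
    return float(np.median(transects.proportions))


def depth_profile(mask: LabeledMicrograph, depth_um: float = 15.0,
                  spacing_um: float = 5.0) -> pd.DataFrame:
    """Iridophore prevalence as a function of depth below the epidermis.

    For each pixel row of depth, prevalence is the fraction of transects
    whose pixel at that depth is iridophore material. Returns a DataFrame
    with columns ``depth_um`` and ``prevalence`` plus attrs ``peak_depth_um``
    (argmax; ties broken toward the shallowest depth, NaN when the profile
    is identically zero).
    """
    px = mask.pixel_size_um
    depth_px = int(round(depth_um / px))
    step_px = max(int(round(spacing_um / px)), 1)
    candidates = np.arange(0, mask.labels.shape[1], step_px)
    valid = _valid_transect_columns(mask, depth_px)
    cols = np.array([x for x in candidates if x in set(valid.tolist())], dtype=int)
    if cols.size == 0:
        raise ValueError("no valid transect: tissue never spans the full depth")
    irid = mask.iridophore_mask()
    boundary = mask.epidermis_boundary
    stack = np.stack([irid[boundary[x]:boundary[x] + depth_px, x] for x in cols])
    prevalence = stack.mean(axis=0)
    depths = (np.arange(depth_px) + 0.5) * px   # pixel-center depth
    df = pd.DataFrame({"depth_um": depths, "prevalence": prevalence})
    if np.all(prevalence == 0):
        df.attrs["peak_depth_um"] = float("nan")
        df.attrs["peak_prevalence"] = 0.0
    else:
        k = int(np.argmax(prevalence))
        df.attrs["peak_depth_um"] = float(depths[k])
        df.attrs["peak_prevalence"] = float(prevalence[k])
    df.attrs["n_transects"] = int(cols.size)
    return df


def platelet_area_fraction(mask: LabeledMicrograph, plot_size_um: float = 1.0,
                           n_plots: int = 25, seed: int = 0,
                           ) -> tuple[PlotGrid, float]:
    """Platelet area fraction in randomly placed square plots inside iridophores.

    Plots are ``plot_size_um`` squares placed at seeded-random positions
    wholly inside iridophore cells and non-overlapping with one another
    (greedy accept over a shuffled candidate list). Fraction = (platelet +
    platelet_hole pixels) / plot pixels. Returns the plots and their median
    fraction. If fewer than ``n_plots`` non-overlapping plots fit, places
    as many as possible and warns.
    """
    px = mask.pixel_size_um
    side = int(round(plot_size_um / px))
    if side < 1:
        raise ValueError("plot size smaller than one pixel")
    interior = np.isin(mask.labels, mask.codes(IRIDOPHORE_INTERIOR))
    # windows fully inside iridophore material, via a summed-area table
    ii = np.pad(interior.astype(np.int64), ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    h, w = interior.shape
    if h < side or w < side:
        raise ValueError("mask smaller than one plot")
    win = (ii[side:, side:] - ii[:-side, side:]
           - ii[side:, :-side] + ii[:-side, :-side])
    cand_r, cand_c = np.nonzero(win == side * side)
    if cand_r.size == 0:
        raise ValueError("no iridophore region large enough for a full plot")
    rng = np.random.default_rng(seed)
    order = rng.permutation(cand_r.size)
    taken: list[tuple[int, int]] = []
    for k in order:
        r, c = int(cand_r[k]), int(cand_c[k])
        if any(abs(r - r0) < side and abs(c - c0) < side for r0, c0 in taken):
            continue
        taken.append((r, c))
        if len(taken) == n_plots:
            break
    if len(taken) < n_plots:
        warnings.warn(f"only {len(taken)} of {n_plots} requested plots fit "
                      "without overlap", stacklevel=2)
    if not taken:
        raise ValueError("could not place any plot")
    platelet = np.isin(mask.labels, mask.codes(("platelet", "platelet_hole")))
    fractions = np.array([
        platelet[r:r + side, c:c + side].sum() / (side * side)
        for r, c in taken
    ])
    grid = PlotGrid(top_left_px=np.array(taken, dtype=int), plot_size_px=side,
                    plot_size_um=side * px, fractions=fractions)
    return grid, float(np.median(fractions))


def morphometry_table(samples: list[dict]) -> pd.DataFrame:
    """Tidy per-sample morphometry rows for the statistical stage.

    Each sample dict: {"id", "skin_color", "transects": TransectSet,
    "plots": PlotGrid}. skin_color must be one of
    orange/yellow/dark_gray/cream.
    """
    valid_colors = {"orange", "yellow", "dark_gray", "cream"}
    rows = []
    for s in samples:
        if "id" not in s or s["id"] is None:
            raise ValueError("sample missing individual ID")
        if s["skin_color"] not in valid_colors:
            raise ValueError(f"unknown skin color {s['skin_color']!r}")
        tr: TransectSet = s["transects"]
        pg: PlotGrid = s["plots"]
        rows.append({
            "id": s["id"],
            "skin_color": s["skin_color"],
            "median_iridophore_proportion": median_iridophore_proportion(tr),
            "median_platelet_fraction": float(np.median(pg.fractions)),
            "n_transects": len(tr),
            "n_plots": len(pg),
        })
    return pd.DataFrame(rows)
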