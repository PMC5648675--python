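"""File I/O: images, label masks with JSON sidecars, configs.

Formats follow the conventions of the analysis inputs: RGB photographs as
8/16-bit PNG or TIFF; micrograph label masks as indexed (uint8) PNG with a
JSON sidecar carrying the class map, the physical pixel size, and the
per-column epidermis boundary; polygon/rectangle annotations in JSON
sidecars next to the photographs. Coordinates are 0-based, row-major.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .tem_morphometrics import LabeledMicrograph

__all__ = [
    "read_rgb_image",
    "write_rgb_image",
    "read_micrograph",
    "write_micrograph",
    "read_annotations",
    "load_config",
]


def read_rgb_image(path) -> np.ndarray:
    """Read an 8/16-bit RGB image as float in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def write_rgb_image(path, image: np.ndarray, bit_depth: int = 16) -> None:
    """Write a float [0, 1] RGB image as 8-bit PNG/TIFF or 16-bit TIFF.

    16-bit RGB goes to TIFF (PNG writers for 16-bit color are not widely
    available); 8-bit accepts either container.
    """
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bit_depth == 16:
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("16-bit RGB output requires a .tif/.tiff path")
        iio.imwrite(path, np.round(image * 65535).astype(np.uint16))
    elif bit_depth == 8:
        iio.imwrite(path, np.round(image * 255).astype(np.uint8))
    else:
        raise ValueError("bit_depth must be 8 or 16")


def write_micrograph(mask: LabeledMicrograph, png_path, json_path=None) -> None:
    """Write a label mask as indexed PNG plus its JSON sidecar."""
    png_path = Path(png_path)
    if json_path is None:
        json_path = png_path.with_suffix(".json")
    iio.imwrite(png_path, mask.labels.astype(np.uint8))
    meta = {
        "class_map": mask.class_map,
        "pixel_size_um": mask.pixel_size_um,
        "epidermis_boundary": mask.epidermis_boundary.tolist(),
    }
    Path(json_path).write_text(json.dumps(meta))


def read_micrograph(png_path, json_path=None) -> LabeledMicrograph:
    """Read an indexed-PNG label mask and its JSON sidecar."""
    png_path = Path(png_path)
    if json_path is None:
        json_path = png_path.with_suffix(".json")
    labels = iio.imread(png_path)
    meta = json.loads(Path(json_path).read_text())
    return LabeledMicrograph(
        labels=np.asarray(labels, dtype=np.uint8),
        pixel_size_um=float(meta["pixel_size_um"]),
        epidermis_boundary=np.asarray(meta["epidermis_boundary"], dtype=int),
        class_map={k: int(v) for k, v in meta["class_map"].items()},
    )


def read_annotations(path) -> dict:
    """Read a JSON annotation sidecar (checker patches + throat region)."""
    return json.loads(Path(path).read_text())


def annotation_masks(annotations: dict, shape: tuple[int, int]
                     ) -> tuple[list[np.ndarray], list[float], np.ndarray]:
    """Materialize patch masks, known reflectances, and the throat mask."""
    patch_masks, reflectances = [], []
    for p in annotations["patches"]:
        m = np.zeros(shape, dtype=bool)
        r, c = p["rows"], p["cols"]
        m[r[0]:r[1], c[0]:c[1]] = True
        patch_masks.append(m)
        reflectances.append(float(p["known_reflectance"]))
    throat = np.zeros(shape, dtype=bool)
    tr = annotations["throat_rows"]
    throat[tr[0]:tr[1], :] = True
    return patch_masks, reflectances, throat


def load_config(path) -> dict:
    """Load a YAML (or JSON) config file into a dict."""
    text = Path(path).read_text()
    return yaml.safe_load(text)
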