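"""Pixel-level primitives for brightfield stain separation.

Brightfield histology obeys the Beer-Lambert law: the per-channel optical
density ``OD_c = log10(I0 / I_c)`` is linear in the concentrations of the
absorbing stains.  A periodic acid-Schiff (PAS) section of a pigmented
tumor is modelled as a mixture of three absorbers -- the magenta PAS
reaction product, melanin pigment, and a blue-green background tone --
each described by a unit RGB absorption vector.  Stacking the three unit
vectors as rows of a matrix ``M`` gives ``od = c @ M`` for concentration
row-vector ``c``, so concentrations are recovered by solving the linear
system per pixel (color deconvolution).

The module also implements the display-range adjustment used to intensify
the magenta signal before deconvolution: raising the minimum of the green
channel to ``gmin`` (default 104) and linearly rescaling the remainder to
the full 8-bit range, which is what an 8-bit minimum slider does when
applied to pixel data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "DEFAULT_STAIN_VECTORS",
    "OD_MAX",
    "StainVectors",
    "StainLayer",
    "adjust_green_min",
    "rgb_to_od",
    "od_to_rgb",
    "build_stain_matrix",
    "deconvolve",
    "deconvolve_od",
    "scale_layer",
    "invert_layer",
    "white_point_correct",
    "read_image",
    "write_image",
]

#: Largest representable optical density for an 8-bit image (intensity
#: floored at 1): log10(255).  Used as the absolute display scale when
#: mapping concentration layers to 8 bits, so intensities are comparable
#: across sections.
OD_MAX: float = float(np.log10(255.0))

STAIN_NAMES = ("pas", "background", "pigment")


def _as_unit(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"stain vector {name!r} must have 3 components")
    if np.any(arr < 0):
        raise ValueError(f"stain vector {name!r} has negative components")
    norm = float(np.linalg.norm(arr))
    if norm <= 0:
        raise ValueError(f"stain vector {name!r} has zero norm")
    return arr / norm


@dataclass(frozen=True)
class StainVectors:
    """Unit RGB absorption vectors for the three stains.

    Defaults are the user-defined deconvolution vectors for differential
    PAS scoring: magenta PAS, blue-green background, and brown pigment.
    Vectors are normalized to unit Euclidean norm on construction.
    """

    pas: tuple[float, float, float] = (0.182, 0.969, 0.169)
    background: tuple[float, float, float] = (0.776, 0.501, 0.382)
    pigment: tuple[float, float, float] = (0.446, 0.616, 0.649)

    def __post_init__(self) -> None:
        for name in STAIN_NAMES:
            unit = _as_unit(getattr(self, name), name)
            object.__setattr__(self, name, tuple(float(x) for x in unit))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with rows (pas, background, pigment)."""
        return build_stain_matrix(self)


DEFAULT_STAIN_VECTORS = StainVectors()


@dataclass
class StainLayer:
    """One deconvolved stain layer.

    ``values`` holds non-negative concentration-like scalars until
    :func:`scale_layer` maps the layer to 8 bits (``bit_scaled=True``),
    after which it is a brightfield-style uint8 image (255 = no stain).
    :func:`invert_layer` flips a bit-scaled layer so the stain appears
    bright on a dark background, linear in concentration.
    """

    values: np.ndarray
    stain_name: str
    bit_scaled: bool = False

    def __post_init__(self) -> None:
        if self.stain_name not in STAIN_NAMES:
            raise ValueError(f"unknown stain name {self.stain_name!r}")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {arr.shape}")
    return arr


def adjust_green_min(img: np.ndarray, gmin: int = 104) -> np.ndarray:
    """Remap the green channel so ``gmin`` becomes black, full scale stays.

    g' = clamp(round((g - gmin) * 255 / (255 - gmin)), 0, 255); red and
    blue are untouched.  ``gmin=0`` is the identity.
    """
    arr = _check_rgb(img)
    if not 0 <= gmin <= 254:
        raise ValueError(f"gmin must be in [0, 254], got {gmin}")
    out = arr.astype(np.float64).copy()
    g = out[..., 1]
    out[..., 1] = np.clip(np.round((g - gmin) * 255.0 / (255.0 - gmin)), 0, 255)
    return out.astype(np.uint8)


def rgb_to_od(img: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Per-channel optical density log10(i0 / I), intensity floored at 1."""
    if i0 <= 0:
        raise ValueError(f"i0 must be positive, got {i0}")
    arr = _check_rgb(img).astype(np.float64)
    return np.log10(i0 / np.maximum(arr, 1.0))


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` up to 8-bit quantization."""
    if i0 <= 0:
        raise ValueError(f"i0 must be positive, got {i0}")
    od = np.asarray(od, dtype=np.float64)
    return np.clip(np.round(i0 * 10.0 ** (-od)), 0, 255).astype(np.uint8)


def build_stain_matrix(vectors: StainVectors) -> np.ndarray:
    """Row-stack the unit stain vectors; must be nonsingular."""
    m = np.array([vectors.pas, vectors.background, vectors.pigment], dtype=float)
    m /= np.linalg.norm(m, axis=1, keepdims=True)
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("stain vectors are linearly dependent; cannot deconvolve")
    return m


def deconvolve_od(od: np.ndarray, matrix: np.ndarray, clip_negative: bool = True):
    """Solve ``od = c @ M`` per pixel and split into named layers."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError("stain matrix must be 3x3")
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError("stain matrix is singular")
    conc = np.asarray(od, dtype=np.float64) @ np.linalg.inv(matrix)
    if clip_negative:
        conc = np.maximum(conc, 0.0)
    return tuple(
        StainLayer(values=conc[..., i].copy(), stain_name=name)
        for i, name in enumerate(STAIN_NAMES)
    )


def deconvolve(img: np.ndarray, matrix: np.ndarray, clip_negative: bool = True):
    """Color-deconvolve an 8-bit RGB image into (pas, background, pigment)."""
    return deconvolve_od(rgb_to_od(img), matrix, clip_negative=clip_negative)


def scale_layer(layer: StainLayer) -> StainLayer:
    """Map a concentration layer to a brightfield-style 8-bit image.

    Concentration ``c`` maps to ``255 - round(clip(c / OD_MAX, 0, 1) * 255)``
    so an unstained pixel is white (255) and a saturated stain is black,
    as the deconvolved layer looks under the microscope.  The fixed
    ``OD_MAX`` scale keeps intensities comparable across sections, which
    the ratio-based glycogen estimate requires.
    """
    if layer.bit_scaled:
        raise ValueError("layer is already bit-scaled")
    scaled = np.round(np.clip(layer.values / OD_MAX, 0.0, 1.0) * 255.0)
    return StainLayer(
        values=(255.0 - scaled).astype(np.uint8),
        stain_name=layer.stain_name,
        bit_scaled=True,
    )


def invert_layer(layer: StainLayer) -> StainLayer:
    """Invert a bit-scaled layer: v' = 255 - v (an involution).

    Puts the stain at high pixel intensity against a dark background; the
    inverted value is linear in the clipped concentration, which is the
    image the region measurements are redirected to.
    """
    if not layer.bit_scaled:
        raise ValueError("invert_layer expects a bit-scaled layer; call scale_layer first")
    return replace(layer, values=(255 - layer.values).astype(np.uint8))


def white_point_correct(img: np.ndarray, white_rgb) -> np.ndarray:
    """Optional background correction: divide by a blank-region mean RGB.

    Rescales each channel so the supplied white point maps to 255.
    """
    arr = _check_rgb(img).astype(np.float64)
    white = np.asarray(white_rgb, dtype=float).reshape(3)
    if np.any(white <= 0):
        raise ValueError("white point must be strictly positive per channel")
    out = np.clip(np.round(arr * (255.0 / white)), 0, 255)
    return out.astype(np.uint8)


def read_image(path) -> np.ndarray:
    """Read an 8-bit RGB TIFF or PNG as an HxWx3 uint8 array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image data, got {arr.dtype}")
    return _check_rgb(arr)


def write_image(path, img: np.ndarray) -> None:
    """Write an HxWx3 uint8 array as TIFF or PNG depending on suffix."""
    path = Path(path)
    arr = _check_rgb(np.asarray(img, dtype=np.uint8))
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr, photometric="rgb")
    else:
        Image.fromarray(arr, mode="RGB").save(path)
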