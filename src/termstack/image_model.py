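"""View state and the deterministic slice-to-RGB display pipeline.

A :class:`ViewState` captures everything needed to turn a 5-D hyperstack into
one displayed 2-D RGB frame: the time/channel/plane indices, the sectioning
plane (XY, XZ or YZ), quarter-turn rotation and flips, a 256-entry colormap
lookup table with optional inversion, manual or automatic contrast limits,
and a zoom factor with nearest-neighbour or bilinear resampling.

The pipeline order is fixed:

    orthoslice -> rotate/flip -> contrast stretch -> LUT -> zoom

Contrast is applied after the geometric operations so that automatic limits
reflect the plane actually displayed; the LUT is applied before zoom so the
colour mapping stays per-source-pixel and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
from matplotlib import colormaps

from .errors import BoundsError, ConfigurationError
from .image_io import MultiDimImage

AUTO = "auto"

Plane = Literal["XY", "XZ", "YZ"]
Contrast = Union[Literal["auto"], tuple[float, float]]


@dataclass
class ViewState:
    """Display parameters binding a hyperstack to one 2-D RGB frame.

    ``plane_index`` selects the coordinate orthogonal to the sectioning
    plane: z for XY, y for XZ, x for YZ.  ``contrast`` is either the string
    ``"auto"`` (per-slice min/max stretch) or a manual ``(low, high)`` pair in
    image-value units with ``low < high``.
    """

    t_index: int = 0
    c_index: int = 0
    plane_index: int = 0
    plane: Plane = "XY"
    rotation_quarter_turns: int = 0
    flip_h: bool = False
    flip_v: bool = False
    colormap_name: str = "gray"
    colormap_inverted: bool = False
    contrast: Contrast = AUTO
    zoom_factor: float = 1.0
    interpolate: bool = False
    live_update: bool = True

    def __post_init__(self) -> None:
        if self.zoom_factor <= 0:
            raise ConfigurationError(f"zoom_factor must be > 0; got {self.zoom_factor}")
        self.rotation_quarter_turns %= 4


@dataclass(frozen=True)
class ColorLUT:
    """256-entry RGB lookup table realizing a named colormap."""

    entries: np.ndarray  # (256, 3) uint8
    name: str
    inverted: bool = field(default=False)


def orthoslice(img: MultiDimImage, view: ViewState) -> np.ndarray:
    """Extract the 2-D scalar section selected by ``view``.

    XY: rows=Y, cols=X at fixed (t, c, z=plane_index).
    XZ: rows=Z (increasing downward), cols=X at fixed y=plane_index.
    YZ: rows=Z, cols=Y at fixed x=plane_index.
    """
    t, c, z, y, x = img.shape
    if not 0 <= view.t_index < t:
        raise BoundsError(f"t_index {view.t_index} out of bounds for T={t}")
    if not 0 <= view.c_index < c:
        raise BoundsError(f"c_index {view.c_index} out of bounds for C={c}")
    vol = img.data[view.t_index, view.c_index]  # (Z, Y, X)
    p = view.plane_index
    if view.plane == "XY":
        if not 0 <= p < z:
            raise BoundsError(f"plane_index {p} out of bounds for Z={z}")
        return vol[p]
    if view.plane == "XZ":
        if not 0 <= p < y:
            raise BoundsError(f"plane_index {p} out of bounds for Y={y}")
        return vol[:, p, :]
    if view.plane == "YZ":
        if not 0 <= p < x:
            raise BoundsError(f"plane_index {p} out of bounds for X={x}")
        return vol[:, :, p]
    raise ConfigurationError(f"unknown plane {view.plane!r}")


def transform_slice(
    s: np.ndarray,
    rotation_quarter_turns: int = 0,
    flip_h: bool = False,
    flip_v: bool = False,
) -> np.ndarray:
    """Rotate clockwise by quarter turns, then flip columns, then rows."""
    out = np.rot90(s, -(rotation_quarter_turns % 4))
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def auto_contrast_limits(s: np.ndarray) -> tuple[float, float]:
    """Min/max stretch limits; a constant slice widens to (v, v + 1)."""
    lo = float(np.min(s))
    hi = float(np.max(s))
    if lo == hi:
        hi = lo + 1.0
    return lo, hi


def normalize(s: np.ndarray, low: float, high: float) -> np.ndarray:
    """Linear contrast stretch onto integer indices 0-255.

    ``index = floor(255 * clamp((v - low) / (high - low), 0, 1) + 0.5)``
    (round half up), so values <= low map to 0 and >= high to 255.
    """
    if low >= high:
        raise ConfigurationError(f"contrast limits require low < high; got ({low}, {high})")
    frac = np.clip((s.astype(np.float64) - low) / (high - low), 0.0, 1.0)
    return np.floor(frac * 255.0 + 0.5).astype(np.uint8)


def available_colormaps() -> list[str]:
    """Names accepted by :func:`make_lut` (the matplotlib registry)."""
    return sorted(colormaps)


def make_lut(name: str, inverted: bool = False) -> ColorLUT:
    """Build the 256-entry RGB table for a registered colormap.

    The colormap is sampled at ``i / 255`` in float and rounded half-up to
    8-bit so that ``gray`` is exactly the identity ramp.  ``inverted``
    reverses the entry order.
    """
    if name not in colormaps:
        raise ConfigurationError(
            f"unknown colormap {name!r}; available: {', '.join(available_colormaps())}"
        )
    rgba = colormaps[name](np.arange(256) / 255.0)
    entries = np.floor(np.asarray(rgba)[:, :3] * 255.0 + 0.5).astype(np.uint8)
    if inverted:
        entries = entries[::-1].copy()
    return ColorLUT(entries=entries, name=name, inverted=inverted)


def apply_lut(idx: np.ndarray, lut: ColorLUT) -> np.ndarray:
    """Map an index raster through the LUT: ``out[r, c] = entries[idx[r, c]]``."""
    return lut.entries[idx]


def _output_length(n: int, factor: float) -> int:
    return max(1, int(np.floor(n * factor + 0.5)))


def zoom(img2d: np.ndarray, factor: float, interpolate: bool = False) -> np.ndarray:
    """Resample a 2-D (or 2-D + channel) raster by ``factor``.

    Output size is ``max(1, round(dim * factor))`` per axis.  Nearest
    neighbour samples at output-pixel centres; bilinear interpolates with
    edge clamping.  ``factor == 1`` is an exact identity in both modes.
    """
    if factor <= 0:
        raise ConfigurationError(f"zoom factor must be > 0; got {factor}")
    img2d = np.asarray(img2d)
    h, w = img2d.shape[:2]
    if factor == 1.0:
        return img2d.copy()
    oh, ow = _output_length(h, factor), _output_length(w, factor)
    # source coordinate of each output-pixel centre
    u = (np.arange(oh) + 0.5) / factor - 0.5
    v = (np.arange(ow) + 0.5) / factor - 0.5
    if not interpolate:
        iy = np.clip(np.floor(u + 0.5).astype(int), 0, h - 1)
        ix = np.clip(np.floor(v + 0.5).astype(int), 0, w - 1)
        return img2d[iy[:, None], ix[None, :]].copy()
    uc = np.clip(u, 0.0, h - 1.0)
    vc = np.clip(v, 0.0, w - 1.0)
    y0 = np.floor(uc).astype(int)
    x0 = np.floor(vc).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (uc - y0)[:, None]
    wx = (vc - x0)[None, :]
    if img2d.ndim == 3:
        wy = wy[..., None]
        wx = wx[..., None]
    a = img2d[y0[:, None], x0[None, :]].astype(np.float64)
    b = img2d[y0[:, None], x1[None, :]].astype(np.float64)
    c = img2d[y1[:, None], x0[None, :]].astype(np.float64)
    d = img2d[y1[:, None], x1[None, :]].astype(np.float64)
    out = (1 - wy) * ((1 - wx) * a + wx * b) + wy * ((1 - wx) * c + wx * d)
    if np.issubdtype(img2d.dtype, np.integer):
        info = np.iinfo(img2d.dtype)
        out = np.clip(np.floor(out + 0.5), info.min, info.max)
    return out.astype(img2d.dtype)


def render_pipeline(img: MultiDimImage, view: ViewState) -> np.ndarray:
    """Produce the displayed ``(H, W, 3)`` uint8 frame for ``view``.

    Equivalent to ``zoom(apply_lut(normalize(transform_slice(orthoslice(...``
    with automatic limits computed on the transformed slice when
    ``contrast == "auto"``.
    """
    s = orthoslice(img, view)
    s = transform_slice(s, view.rotation_quarter_turns, view.flip_h, view.flip_v)
    if view.contrast == AUTO:
        low, high = auto_contrast_limits(s)
    else:
        low, high = view.contrast
    idx = normalize(s, low, high)
    lut = make_lut(view.colormap_name, view.colormap_inverted)
    rgb = apply_lut(idx, lut)
    return zoom(rgb, view.zoom_factor, view.interpolate)
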