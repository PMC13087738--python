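"""Canonical 5-D image model and loaders for the supported on-disk layouts.

Images are held in memory as a single numpy array indexed ``(t, c, z, y, x)``
(time, channel, z-plane, row, column) — the "hyperstack" convention.  Three
layouts can be read:

* multi-page TIFF — pages map to Z by default; explicit hints reassign them,
* zarr (v2 or v3) stores — an ``"axes"`` attribute overrides positional
  interpretation, otherwise missing leading axes are padded with singletons,
* folders of single-page TIFFs where a filename substring encodes one
  dimension (e.g. ``"GFP"`` / ``"RFP"`` for channels).

Rendered frames can be written back to disk as lossless 8-bit RGB PNG.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import zarr

from .errors import FormatError

ALLOWED_DTYPES = ("uint8", "uint16", "float32")

#: canonical axis order of the in-memory hyperstack
AXES = "TCZYX"


@dataclass
class MultiDimImage:
    """A 5-D scalar image indexed ``(t, c, z, y, x)``.

    ``data`` must be a 5-D array of one of the supported dtypes with every
    axis of length >= 1 and all values finite.  ``source`` is an optional
    provenance string (file path or generator description).
    """

    data: np.ndarray
    source: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise FormatError(
                f"hyperstack must be 5-D (T,C,Z,Y,X); got {self.data.ndim}-D"
            )
        if any(s < 1 for s in self.data.shape):
            raise FormatError(f"all axes must be >= 1; got shape {self.data.shape}")
        if self.data.dtype.name not in ALLOWED_DTYPES:
            raise FormatError(
                f"dtype {self.data.dtype.name!r} not supported; "
                f"expected one of {ALLOWED_DTYPES}"
            )
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise FormatError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def dtype(self) -> np.dtype:
        return self.data.dtype


def _resolve_page_hints(
    n_pages: int, t: int | None, c: int | None, z: int | None
) -> tuple[int, int, int]:
    """Turn optional per-axis page counts into a concrete (T, C, Z)."""
    if t is None and c is None and z is None:
        return 1, 1, n_pages
    hints = {"t": t, "c": c, "z": z}
    known = {k: v for k, v in hints.items() if v is not None}
    for k, v in known.items():
        if v < 1:
            raise FormatError(f"dimension hint {k}={v} must be >= 1")
    prod = int(np.prod(list(known.values())))
    unknown = [k for k, v in hints.items() if v is None]
    if len(unknown) <= 1:
        if unknown:
            if n_pages % prod:
                raise FormatError(
                    f"page count {n_pages} not divisible by hinted product {prod}"
                )
            known[unknown[0]] = n_pages // prod
        elif prod != n_pages:
            raise FormatError(
                f"dimension hints t*c*z={prod} do not match page count {n_pages}"
            )
    else:
        # two unknowns: the remaining pages go to the first unknown in
        # T-major order only if they divide evenly; the rest stay singleton
        if n_pages % prod:
            raise FormatError(
                f"page count {n_pages} not divisible by hinted product {prod}"
            )
        known[unknown[0]] = n_pages // prod
        known[unknown[1]] = 1
    return known["t"], known["c"], known["z"]


def load_tiff(
    path: str | os.PathLike,
    *,
    t: int | None = None,
    c: int | None = None,
    z: int | None = None,
) -> MultiDimImage:
    """Read a (multi-page) TIFF into the canonical 5-D model.

    Pages are flattened T-major, then C, then Z.  With no hints all pages
    become the Z axis; hints fix the size of one or more of T/C/Z and must be
    consistent with the page count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(
            f"TIFF {path} has unexpected page shape {arr.shape}; expected 2-D pages"
        )
    tt, cc, zz = _resolve_page_hints(arr.shape[0], t, c, z)
    data = arr.reshape(tt, cc, zz, arr.shape[1], arr.shape[2])
    return MultiDimImage(data, source=str(path))


def load_zarr(path: str | os.PathLike) -> MultiDimImage:
    """Read a zarr store holding one array of 2-5 dimensions.

    If the array carries an ``"axes"`` attribute (a string over ``TCZYX``),
    it names the stored axes and overrides positional interpretation;
    otherwise the array is left-padded with singleton axes up to 5-D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such zarr store: {path}")
    try:
        node = zarr.open(str(path), mode="r")
    except Exception as exc:  # zarr raises a mix of error types
        raise FileNotFoundError(f"cannot open zarr store {path}: {exc}") from exc
    if isinstance(node, zarr.Group):
        arrays = [a for _, a in node.arrays()]
        if not arrays:
            raise FileNotFoundError(f"zarr store {path} contains no array")
        if len(arrays) > 1:
            raise FormatError(f"zarr store {path} contains more than one array")
        node = arrays[0]
    if node.ndim > 5:
        raise FormatError(f"zarr array has {node.ndim} axes; at most 5 supported")
    if node.ndim < 2:
        raise FormatError(f"zarr array has {node.ndim} axes; at least 2 required")
    arr = node[:]
    axes = node.attrs.get("axes")
    if axes is not None:
        axes = str(axes).upper()
        if len(axes) != arr.ndim or len(set(axes)) != len(axes) or any(
            a not in AXES for a in axes
        ):
            raise FormatError(
                f"invalid axes attribute {axes!r} for a {arr.ndim}-D array"
            )
        # expand to 5-D in the canonical order
        for a in AXES:
            if a not in axes:
                arr = np.expand_dims(arr, 0)
                axes = a + axes
        arr = np.transpose(arr, [axes.index(a) for a in AXES])
    else:
        while arr.ndim < 5:
            arr = arr[None]
    return MultiDimImage(arr, source=str(path))


_TIFF_SUFFIXES = (".tif", ".tiff")


def load_sequence(
    directory: str | os.PathLike,
    substrings: list[str],
    encoded_dim: str = "C",
) -> MultiDimImage:
    """Assemble a hyperstack from a folder of single-page TIFFs.

    ``substrings`` are distinct filename tokens; token order defines the index
    order along ``encoded_dim`` (one of ``"T"``, ``"C"``, ``"Z"``).  Within a
    token, files sorted lexicographically stack along Z (or T when the encoded
    dimension is Z itself).  Every TIFF in the folder must match exactly one
    token and per-token file counts must be equal.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such directory: {directory}")
    encoded_dim = encoded_dim.upper()
    if encoded_dim not in ("T", "C", "Z"):
        raise FormatError(f"encoded_dim must be T, C or Z; got {encoded_dim!r}")
    if not substrings:
        raise FormatError("substrings must be a non-empty list of tokens")
    if len(set(substrings)) != len(substrings):
        raise FormatError("substring tokens must be distinct")

    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES
    )
    if not files:
        raise FormatError(f"no TIFF files in {directory}")
    buckets: dict[str, list[Path]] = {tok: [] for tok in substrings}
    for f in files:
        matches = [tok for tok in substrings if tok in f.name]
        if len(matches) != 1:
            raise FormatError(
                f"file {f.name!r} matches {len(matches)} tokens; expected exactly 1"
            )
        buckets[matches[0]].append(f)
    counts = {tok: len(v) for tok, v in buckets.items()}
    if len(set(counts.values())) != 1 or 0 in counts.values():
        raise FormatError(f"unequal file counts per token: {counts}")

    planes_per_token = []
    shape_yx: tuple[int, int] | None = None
    for tok in substrings:
        planes = []
        for f in buckets[tok]:  # already lexicographic
            try:
                page = tifffile.imread(f)
            except (tifffile.TiffFileError, ValueError) as exc:
                raise FormatError(f"cannot read TIFF {f}: {exc}") from exc
            if page.ndim != 2:
                raise FormatError(f"{f.name!r} is not a single-page 2-D TIFF")
            if shape_yx is None:
                shape_yx = page.shape
            elif page.shape != shape_yx:
                raise FormatError(
                    f"plane shape mismatch: {f.name!r} is {page.shape}, "
                    f"expected {shape_yx}"
                )
            planes.append(page)
        planes_per_token.append(np.stack(planes))  # (n, Y, X)

    stacked = np.stack(planes_per_token)  # (encoded, n, Y, X)
    n = stacked.shape[1]
    k = len(substrings)
    y, x = shape_yx  # type: ignore[misc]
    if encoded_dim == "T":
        data = stacked.reshape(k, 1, n, y, x)  # files stack along Z
    elif encoded_dim == "C":
        data = stacked.reshape(1, k, n, y, x)  # files stack along Z
    else:  # encoded Z: files stack along T
        data = stacked.transpose(1, 0, 2, 3).reshape(n, 1, k, y, x)
    return MultiDimImage(data, source=str(directory))


def save_png(rgb: np.ndarray, path: str | os.PathLike) -> Path:
    """Write an ``(H, W, 3)`` uint8 raster as a lossless PNG."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.dtype != np.uint8:
        raise FormatError(
            f"expected (H, W, 3) uint8 raster; got shape {rgb.shape}, dtype {rgb.dtype}"
        )
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"{path} is a directory")
    iio.imwrite(path, rgb, extension=".png")
    return path
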