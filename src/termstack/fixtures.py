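"""Synthetic hyperstack generation and on-disk fixture writers.

Everything the loaders can read can be produced here programmatically, with
known, assertable structure: intensity ramps along a chosen axis, a 3-D
checkerboard, constant fills, and seeded random noise.  Generation is a pure
function of ``(spec, seed)``: identical inputs give bit-identical arrays.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import zarr

from .errors import ConfigurationError
from .image_io import ALLOWED_DTYPES, AXES, MultiDimImage

PATTERNS = ("ramp-x", "ramp-y", "ramp-z", "checker", "constant", "random")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic hyperstack.

    ``shape`` is the full ``(T, C, Z, Y, X)`` tuple.  ``pattern`` selects the
    intensity structure; ramps clamp at the dtype maximum so values are
    nondecreasing along the ramp axis.  ``seed`` only affects ``random``.
    """

    shape: tuple[int, int, int, int, int]
    pattern: str = "ramp-x"
    dtype: str = "uint8"
    seed: int = 0
    constant_value: float = 7.0


def _dtype_high(dtype: np.dtype) -> float:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return 1.0


def make_hyperstack(spec: FixtureSpec) -> MultiDimImage:
    """Generate the hyperstack described by ``spec`` deterministically."""
    if len(spec.shape) != 5 or any(int(s) < 1 for s in spec.shape):
        raise ConfigurationError(
            f"shape must be five positive integers; got {spec.shape!r}"
        )
    if spec.pattern not in PATTERNS:
        raise ConfigurationError(
            f"unknown pattern {spec.pattern!r}; expected one of {PATTERNS}"
        )
    if spec.dtype not in ALLOWED_DTYPES:
        raise ConfigurationError(
            f"unknown dtype {spec.dtype!r}; expected one of {ALLOWED_DTYPES}"
        )
    t, c, z, y, x = (int(s) for s in spec.shape)
    dtype = np.dtype(spec.dtype)
    high = _dtype_high(dtype)

    if spec.pattern.startswith("ramp-"):
        axis = {"ramp-x": 4, "ramp-y": 3, "ramp-z": 2}[spec.pattern]
        n = spec.shape[axis]
        ramp = np.minimum(np.arange(n, dtype=np.float64), high)
        if dtype == np.float32:
            ramp = np.arange(n, dtype=np.float64)
        idx = [None] * 5
        idx[axis] = slice(None)
        data = np.broadcast_to(ramp[tuple(idx)], (t, c, z, y, x))
        data = data.astype(dtype)
    elif spec.pattern == "checker":
        grids = np.indices((t, c, z, y, x)).sum(axis=0)
        data = ((grids % 2) * high).astype(dtype)
    elif spec.pattern == "constant":
        data = np.full((t, c, z, y, x), spec.constant_value, dtype=dtype)
    else:  # random
        rng = np.random.default_rng(int(spec.seed))
        if np.issubdtype(dtype, np.integer):
            data = rng.integers(0, int(high) + 1, size=(t, c, z, y, x)).astype(dtype)
        else:
            data = rng.random(size=(t, c, z, y, x)).astype(dtype)
    return MultiDimImage(
        np.ascontiguousarray(data),
        source=f"fixture:{spec.pattern}/{spec.dtype}/seed={spec.seed}",
    )


def write_fixture_tiff(img: MultiDimImage, path: str | os.PathLike) -> Path:
    """Write ``img`` as a multi-page TIFF.

    Page order is the canonical flattening: T-major, then C, then Z — one
    Y x X page per ``(t, c, z)`` triple.
    """
    path = Path(path)
    t, c, z, y, x = img.shape
    pages = np.ascontiguousarray(img.data).reshape(t * c * z, y, x)
    # pin grayscale pages; tifffile would otherwise guess RGB when a stack
    # axis happens to be 3
    tifffile.imwrite(path, pages, photometric="minisblack")
    return path


def write_fixture_zarr(
    img: MultiDimImage,
    path: str | os.PathLike,
    chunks: tuple[int, ...] | None = None,
) -> Path:
    """Write the full 5-D array to a zarr v2 store.

    The canonical axis order is recorded in the array attributes under
    ``"axes" = "TCZYX"``.  Fails if ``path`` already exists.
    """
    path = Path(path)
    arr = zarr.open_array(
        str(path),
        mode="w-",
        shape=img.shape,
        dtype=img.dtype,
        chunks=chunks if chunks is not None else img.shape,
        zarr_format=2,
    )
    arr.attrs["axes"] = AXES
    arr[:] = img.data
    return path


def write_fixture_sequence(
    img: MultiDimImage,
    directory: str | os.PathLike,
    substrings: list[str],
    encoded_dim: str = "C",
) -> list[Path]:
    """Write ``img`` as a folder of single-page TIFFs.

    One file per (encoded-dimension index, remaining plane).  Filenames embed
    the token of their encoded index plus a zero-padded numeric suffix so that
    lexicographic order equals logical order.  Tokens must be distinct and
    unambiguous (no generated filename may contain two tokens).  At most one
    non-encoded stack axis may be non-singleton so the layout is loss-free.
    """
    directory = Path(directory)
    encoded_dim = encoded_dim.upper()
    if encoded_dim not in ("T", "C", "Z"):
        raise ConfigurationError(f"encoded_dim must be T, C or Z; got {encoded_dim!r}")
    axis = {"T": 0, "C": 1, "Z": 2}[encoded_dim]
    size = img.shape[axis]
    if len(substrings) != size:
        raise ConfigurationError(
            f"need {size} substrings for {encoded_dim} of size {size}; "
            f"got {len(substrings)}"
        )
    if len(set(substrings)) != len(substrings):
        raise ConfigurationError("substring tokens must be distinct")
    # the loader stacks remaining files along Z (or T when Z is encoded),
    # so only that axis may be non-singleton among the non-encoded stack axes
    stack_axis = 0 if encoded_dim == "Z" else 2
    for a in (0, 1, 2):
        if a not in (axis, stack_axis) and img.shape[a] > 1:
            raise ConfigurationError(
                f"axis {AXES[a]} must be singleton for a file sequence "
                f"encoding {encoded_dim}; got shape {img.shape}"
            )

    moved = np.moveaxis(img.data, axis, 0)  # (encoded, rest..., Y, X)
    n_rest = moved.shape[1] * moved.shape[2]
    planes = moved.reshape(size, n_rest, *img.shape[3:])

    names = [
        f"{tok}_{j:04d}.tif" for tok in substrings for j in range(n_rest)
    ]
    for name in names:
        if sum(tok in name for tok in substrings) != 1:
            raise ConfigurationError(
                f"ambiguous token containment: filename {name!r} matches "
                "more than one substring"
            )

    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, tok in enumerate(substrings):
        for j in range(n_rest):
            p = directory / f"{tok}_{j:04d}.tif"
            tifffile.imwrite(p, planes[i, j])
            paths.append(p)
    return paths
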