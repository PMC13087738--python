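"""Independent brute-force oracles used by the test suite.

Everything here recomputes expected results by direct enumeration or via a
different library than the code under test, so the checks stay independent
of the implementation paths they verify.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from termstack.renderer import RenderFrame, parse_style


def frame_grid(frame: RenderFrame) -> list[list]:
    """Arrange a frame's styled segments into a (char_rows, char_cols) grid."""
    grid, row = [], []
    for seg in frame.segments:
        if seg.is_newline:
            grid.append(row)
            row = []
        else:
            row.append(seg)
    assert not row, "frame did not end with a newline segment"
    return grid


def pixels_from_halfblock(frame: RenderFrame, h: int, w: int) -> np.ndarray:
    """Recover the original raster from a half-block frame.

    Pixel (r, c) lives in character cell (r // 2, c): in the background when
    r is even (top pixel), in the foreground when r is odd (bottom pixel).
    """
    grid = frame_grid(frame)
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            style = parse_style(grid[r // 2][c].style)
            out[r, c] = style.background if r % 2 == 0 else style.foreground
    return out


def pixels_from_fullspace(frame: RenderFrame, h: int, w: int) -> np.ndarray:
    """Recover the raster from a legacy space frame (background of cell (r, 2c))."""
    grid = frame_grid(frame)
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            out[r, c] = parse_style(grid[r][2 * c].style).background
    return out


def read_tiff_pages_pil(path) -> list[np.ndarray]:
    """Read multi-page TIFF pages with Pillow (independent of tifffile)."""
    pages = []
    with Image.open(path) as im:
        for i in range(getattr(im, "n_frames", 1)):
            im.seek(i)
            pages.append(np.asarray(im))
    return pages


def normalize_bruteforce(s: np.ndarray, low: float, high: float) -> np.ndarray:
    """Elementwise contrast stretch by the scalar formula, no vectorization."""
    out = np.zeros(s.shape, dtype=np.uint8)
    for pos in np.ndindex(*s.shape):
        frac = (float(s[pos]) - low) / (high - low)
        frac = min(1.0, max(0.0, frac))
        out[pos] = int(np.floor(frac * 255.0 + 0.5))
    return out
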