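"""Character-based terminal rendering of RGB rasters.

Terminal cells are roughly twice as tall as they are wide, so a naive
one-cell-per-pixel display distorts the image.  Two encodings are provided:

* **half-block** (the efficient path): each terminal cell shows a pair of
  vertically adjacent pixels using U+2584 LOWER HALF BLOCK ('▄').  The
  bottom pixel colours the character's foreground (the lower half of the
  cell) and the top pixel its background (the upper half).  One character
  per two pixels — half a character per pixel.

* **fullspace** (the legacy path, kept as a correctness oracle): each pixel
  is a space character with the pixel colour as background, emitted twice
  per column so pixels come out square.  Two characters per pixel.

Colours travel as style strings in the dialect ``"rgb(R,G,B) on rgb(R,G,B)"``
(foreground first, then background after ``on``); a :class:`StyleCache`
memoizes parsing.  :func:`frame_to_ansi` turns a frame into 24-bit SGR
escape sequences for direct terminal output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Sequence

import numpy as np

from .errors import BoundsError, ConfigurationError, FormatError

HALF_BLOCK = "▄"  # '▄' LOWER HALF BLOCK

ESC = "\x1b"
RESET = ESC + "[0m"


@dataclass(frozen=True)
class StyledSegment:
    """One terminal character with its colour style.

    ``style`` is a colour string ("rgb(R,G,B) on rgb(R,G,B)", a
    foreground-only "rgb(R,G,B)", or a background-only "on rgb(R,G,B)"),
    or ``None`` for unstyled segments such as the end-of-line newline.
    """

    char: str
    style: str | None = None

    @property
    def is_newline(self) -> bool:
        return self.char == "\n"


@dataclass
class RenderFrame:
    """An ordered sequence of styled segments forming one terminal frame.

    Exactly one newline segment terminates each character row; the
    non-newline segment count equals ``char_rows * char_cols``.
    """

    segments: list[StyledSegment]
    char_rows: int
    char_cols: int

    def styled_segments(self) -> list[StyledSegment]:
        return [s for s in self.segments if not s.is_newline]


def _rgb_str(rgb: Sequence[int]) -> str:
    r, g, b = (int(v) for v in rgb)
    return f"rgb({r},{g},{b})"


def style_string(bottom_rgb: Sequence[int], top_rgb: Sequence[int]) -> str:
    """Colour string for a pixel pair: foreground = bottom, background = top.

    E.g. a red bottom pixel under a cyan top pixel gives
    ``"rgb(255,0,0) on rgb(0,255,255)"``.
    """
    return f"{_rgb_str(bottom_rgb)} on {_rgb_str(top_rgb)}"


def _as_rgb_raster(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.size == 0:
        raise ConfigurationError(
            f"expected a non-empty (H, W, 3) raster; got shape {rgb.shape}"
        )
    return rgb.astype(np.uint8, copy=False)


def render_halfblock(rgb: np.ndarray) -> RenderFrame:
    """Encode a raster as half-block characters, one per vertical pixel pair.

    For an H x W image the frame has ``ceil(H/2)`` character rows of W
    columns.  The segment at character cell (r, c) is '▄' styled with the
    bottom pixel (row 2r+1) as foreground and the top pixel (row 2r) as
    background.  Odd heights pad a virtual black bottom row.
    """
    rgb = _as_rgb_raster(rgb)
    h, w = rgb.shape[:2]
    if h % 2:
        rgb = np.concatenate([rgb, np.zeros((1, w, 3), dtype=np.uint8)])
    rows = rgb.shape[0] // 2
    segments: list[StyledSegment] = []
    for r in range(rows):
        top = rgb[2 * r]
        bottom = rgb[2 * r + 1]
        for c in range(w):
            segments.append(
                StyledSegment(HALF_BLOCK, style_string(bottom[c], top[c]))
            )
        segments.append(StyledSegment("\n"))
    return RenderFrame(segments=segments, char_rows=rows, char_cols=w)


def render_fullspace(rgb: np.ndarray) -> RenderFrame:
    """Legacy encoding: one space per pixel, doubled horizontally.

    Each pixel becomes two adjacent space characters whose background is the
    pixel colour (no foreground), so pixels render square despite the 2:1
    cell aspect ratio.  Emits ``2*H*W`` styled segments plus H newlines.
    """
    rgb = _as_rgb_raster(rgb)
    h, w = rgb.shape[:2]
    segments: list[StyledSegment] = []
    for r in range(h):
        row = rgb[r]
        for c in range(w):
            style = "on " + _rgb_str(row[c])
            seg = StyledSegment(" ", style)
            segments.append(seg)
            segments.append(seg)
        segments.append(StyledSegment("\n"))
    return RenderFrame(segments=segments, char_rows=h, char_cols=2 * w)


def make_string_lut(lut_entries: np.ndarray) -> list[str]:
    """Precompute the ``"rgb(R,G,B)"`` string for each of 256 LUT entries."""
    lut_entries = np.asarray(lut_entries)
    if lut_entries.shape != (256, 3):
        raise ConfigurationError(
            f"expected a (256, 3) LUT; got shape {lut_entries.shape}"
        )
    return [_rgb_str(e) for e in lut_entries]


def render_indexed(
    idx: np.ndarray,
    string_lut: Sequence[str],
    column_order: Iterable[int] | None = None,
) -> list[list[str]]:
    """Hot-loop style-string generation from an index raster.

    Scans the image columns two rows at a time, producing for character cell
    (r, c) the string ``string_lut[idx[2r+1, c]] + " on " + string_lut[idx[2r, c]]``
    (bottom pixel as foreground).  The result is independent of the order in
    which columns are evaluated — the contract that lets the scan be
    parallelized over columns.  Odd heights pad a virtual black bottom row.
    """
    if len(string_lut) != 256:
        raise ConfigurationError(f"string LUT must have 256 entries; got {len(string_lut)}")
    idx = np.asarray(idx)
    if idx.ndim != 2 or idx.size == 0:
        raise ConfigurationError(f"expected a non-empty 2-D index raster; got {idx.shape}")
    if idx.min() < 0 or idx.max() > 255:
        raise BoundsError("index raster values must be in 0..255")
    h, w = idx.shape
    rows = ceil(h / 2)
    top = idx[0::2]
    bottom = idx[1::2]
    black = _rgb_str((0, 0, 0))
    lut = list(string_lut)
    grid: list[list[str | None]] = [[None] * w for _ in range(rows)]
    for c in column_order if column_order is not None else range(w):
        col_top = top[:, c]
        col_bottom = bottom[:, c]
        for r in range(rows):
            fg = lut[col_bottom[r]] if r < bottom.shape[0] else black
            grid[r][c] = f"{fg} on {lut[col_top[r]]}"
    return grid  # type: ignore[return-value]


# --- style parsing and cache -------------------------------------------------

_RGB_RE = r"rgb\((0|[1-9]\d{0,2}),(0|[1-9]\d{0,2}),(0|[1-9]\d{0,2})\)"
_STYLE_RE = re.compile(
    rf"^(?:(?P<fg>{_RGB_RE})(?: on (?P<bg>{_RGB_RE}))?|on (?P<bgonly>{_RGB_RE}))$"
)


@dataclass(frozen=True)
class ParsedStyle:
    """A parsed colour style: optional foreground and background triples."""

    foreground: tuple[int, int, int] | None
    background: tuple[int, int, int] | None


def parse_style(s: str) -> ParsedStyle:
    """Parse a colour string into RGB triples; raises on malformed input."""
    m = _STYLE_RE.match(s)
    if not m:
        raise FormatError(f"malformed style string: {s!r}")

    def triple(text: str | None) -> tuple[int, int, int] | None:
        if text is None:
            return None
        vals = tuple(int(v) for v in re.findall(r"\d+", text))
        if any(v > 255 for v in vals):
            raise FormatError(f"colour component out of range in {s!r}")
        return vals  # type: ignore[return-value]

    return ParsedStyle(
        foreground=triple(m.group("fg")),
        background=triple(m.group("bg") or m.group("bgonly")),
    )


@dataclass
class StyleCache:
    """Memo from colour strings to parsed styles, with hit/miss counters.

    Keyed by the full colour string; equal strings always return the
    identical parsed object.
    """

    _memo: dict[str, ParsedStyle] = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def get(self, s: str) -> ParsedStyle:
        try:
            style = self._memo[s]
        except KeyError:
            style = parse_style(s)
            self._memo[s] = style
            self.misses += 1
            return style
        self.hits += 1
        return style

    def __len__(self) -> int:
        return len(self._memo)


def cache_get(cache: StyleCache, s: str) -> ParsedStyle:
    """Parse ``s`` through the cache (first request parses, repeats hit)."""
    return cache.get(s)


# --- ANSI emission ------------------------------------------------------------


def _sgr(style: ParsedStyle) -> str:
    parts = []
    if style.foreground is not None:
        r, g, b = style.foreground
        parts.append(f"{ESC}[38;2;{r};{g};{b}m")
    if style.background is not None:
        r, g, b = style.background
        parts.append(f"{ESC}[48;2;{r};{g};{b}m")
    return "".join(parts)


def frame_to_ansi(frame: RenderFrame, cache: StyleCache | None = None) -> str:
    """Emit a frame as 24-bit SGR truecolor text.

    Each styled segment emits its foreground code (``ESC[38;2;R;G;Bm``) and/or
    background code (``ESC[48;2;R;G;Bm``) followed by its character; a reset
    terminates each row before the bare newline.  Stripping escape codes
    leaves exactly ``char_rows`` lines of ``char_cols`` characters.
    """
    parse = cache.get if cache is not None else parse_style
    out: list[str] = []
    for seg in frame.segments:
        if seg.is_newline:
            out.append(RESET)
            out.append("\n")
        else:
            if seg.style is not None:
                out.append(_sgr(parse(seg.style)))
            out.append(seg.char)
    return "".join(out)


_ANSI_RE = re.compile(r"\x1b\[[0-9;]*m")


def strip_ansi(text: str) -> str:
    """Remove SGR escape sequences, leaving the plain characters."""
    return _ANSI_RE.sub("", text)
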