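# termstack

Browse multidimensional microscopy images in the terminal.

Confocal and light-sheet microscopes produce hyperstacks — a single array
with time, channel, Z, Y and X axes — that are easy to inspect in a GUI but
hard to look at over SSH on the storage server where they actually live.
`termstack` loads a hyperstack from disk, picks out one 2-D view of it, and
draws that view directly in the terminal as truecolor text, so you can tell
which stack is which before copying gigabytes anywhere.

## What it does

* **Canonical 5-D model.** Every image becomes a numpy array indexed
  `(t, c, z, y, x)`. Loaders exist for multi-page TIFF (pages map to Z by
  default; hints reassign them), zarr stores (an `"axes"` attribute such as
  `"CYX"` overrides positional interpretation), and folders of single-page
  TIFFs where a filename substring encodes one dimension (e.g. `GFP` / `RFP`
  files for two channels).
* **View pipeline.** A `ViewState` selects a time point, channel and
  sectioning plane (XY, XZ or YZ), applies quarter-turn rotation and
  horizontal/vertical flips, a linear contrast stretch (manual limits or
  automatic per-slice min/max), any matplotlib colormap (optionally
  inverted) through a 256-entry RGB lookup table, and finally zoom with
  nearest-neighbour or bilinear resampling. The result is an `(H, W, 3)`
  uint8 frame.
* **Half-block rendering.** Terminal cells are about twice as tall as they
  are wide. Each cell shows **two** vertically adjacent pixels using the
  lower-half-block character `▄` (U+2584): the bottom pixel colours the
  foreground, the top pixel the background, via a style string like
  `rgb(255,0,0) on rgb(0,255,255)` — a red lower half on a cyan upper half.
  That is half a character per pixel, versus two characters per pixel for
  the legacy space-character encoding (kept in the package as a correctness
  oracle). A style cache memoizes colour-string parsing, and an indexed
  hot loop generates style strings from a 256-entry string table in a way
  that is independent of column evaluation order.

## Worked example

```python
import termstack as ts

# a synthetic 3-plane stack whose intensity ramps left to right
img = ts.make_hyperstack(ts.FixtureSpec(shape=(1, 1, 3, 4, 8), pattern="ramp-x"))
rgb = ts.render_pipeline(img, ts.ViewState())      # gray, auto contrast, zoom 1
frame = ts.render_halfblock(rgb)

print(frame.char_rows, "x", frame.char_cols)       # 2 x 8
print(len(frame.styled_segments()))                # 16  (= 32 pixels / 2)
print(frame.segments[0].style)                     # rgb(0,0,0) on rgb(0,0,0)
print(frame.styled_segments()[-1].style)           # rgb(255,255,255) on rgb(255,255,255)
print(ts.frame_to_ansi(frame, cache=ts.StyleCache()))
```

The 4×8-pixel view becomes 2 character rows of 8 half-block characters
(16 styled segments for 32 pixels). Auto contrast stretches the ramp so the
leftmost column is black (`rgb(0,0,0)`) and the rightmost is white
(`rgb(255,255,255)`); the final `print` shows the actual image in any
truecolor terminal. The ANSI text begins

```
\x1b[38;2;0;0;0m\x1b[48;2;0;0;0m▄\x1b[38;2;36;36;36m\x1b[48;2;36;36;36m▄...
```

— a 24-bit foreground code (`38;2;R;G;B`), a background code
(`48;2;R;G;B`), then the character, for every cell.

From a shell, the same thing:

```sh
termstack img.tif --cmap viridis --zoom 0.5 --headless
termstack seq_folder/ --substrings GFP,RFP --dim c --plane xz --snapshot view.png
```

Exit codes: 0 success, 2 usage error, 1 runtime error.

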