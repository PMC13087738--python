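# Methods

## Image model and conventions

Images are held as one numpy array indexed `(t, c, z, y, x)` — time,
channel, Z-plane, row, column — with dtype uint8, uint16 or float32 and all
values finite. Indices are 0-based; Y increases downward, the universal
raster convention, which also makes the renderer's row pairing unambiguous
(pixel row `2r` is the top of character row `r`, row `2r+1` the bottom).

Loader conventions, chosen where the on-disk formats leave them open:

* **Multi-page TIFF.** Pages are flattened T-major, then C, then Z; with no
  hints all pages are interpreted as Z (the most common microscopy stack),
  and explicit `t=/c=/z=` hints reassign them. TIFF metadata is not used for
  axis detection — hints are explicit by design, so behaviour never depends
  on vendor-specific tags.
* **zarr.** Stores are written as zarr v2 with the canonical order recorded
  under the `"axes"` attribute (`"TCZYX"`). On read, an `"axes"` attribute
  (any permutation/subset of `TCZYX` letters) overrides positional
  interpretation; otherwise arrays with fewer than five axes are left-padded
  with singletons, preserving `(Y, X)` as the two fastest axes.
* **File sequences.** A filename substring token identifies the index along
  one encoded dimension (T, C or Z); token order defines index order. Within
  a token, files sorted lexicographically stack along Z (along T when Z
  itself is the encoded dimension) — the fixture writer zero-pads numeric
  suffixes so lexicographic order equals logical order. Every TIFF in the
  folder must match exactly one token; containment-ambiguous token sets
  (`ch1` vs `ch10`) are rejected at write time. Because the loader stacks
  all remaining planes onto a single axis, the writer requires every other
  stack axis to be singleton; this keeps the write→load round trip loss-free
  and is asserted by a property test.

## Display pipeline

The pipeline order is fixed:

    orthoslice → rotate/flip → contrast stretch → colormap LUT → zoom

Contrast comes after the geometric operations so automatic limits reflect
the plane actually displayed; the LUT is applied before zoom so colour
mapping stays a per-source-pixel table lookup.

* **Orthoslicing.** XY: rows=Y, cols=X at fixed `(t, c, z)`. XZ: rows=Z
  increasing downward, cols=X at fixed y. YZ: rows=Z, cols=Y at fixed x.
  `plane_index` always selects the coordinate orthogonal to the plane. A
  cross-plane test quantifies over all coordinates of random ≤8³ volumes to
  pin these index conventions. No voxel-anisotropy resampling is applied in
  XZ/YZ views; Z samples are displayed at unit spacing.
* **Rotation** is clockwise in quarter turns, applied before the horizontal
  flip (column reversal) and then the vertical flip (row reversal). The
  group laws (flips are involutions, four quarter turns are the identity,
  a half turn equals both flips) are asserted as properties.
* **Contrast.** Automatic limits are the per-displayed-slice min and max —
  the simplest defensible stretch, and fully testable; percentile-based
  stretches were deliberately not used. A constant slice widens to
  `(v, v + 1)` so normalization stays defined. Normalization maps value `v`
  to `floor(255 · clamp((v − low)/(high − low), 0, 1) + 0.5)` — round half
  up, pinned so tests can be bit-exact.
* **Colormaps.** The registry is matplotlib's (about 180 maps, including
  gray, viridis, cividis, magma and the other perceptually uniform maps).
  The 256-entry RGB table samples the colormap at `i/255` in float and
  rounds half-up to 8-bit; matplotlib's own byte path quantizes through its
  internal lookup table and would make `gray` deviate from the exact
  identity ramp at 24 of 256 entries. Inversion reverses entry order, so
  double inversion is the identity by construction.
* **Zoom.** Output size is `max(1, round(dim · factor))` per axis. The
  output pixel centre `i` samples source coordinate `(i + 0.5)/factor − 0.5`;
  nearest mode takes `floor(u + 0.5)` clamped to bounds, bilinear mode
  interpolates the four neighbours with edge clamping. Factor 1 is an exact
  identity in both modes (the coordinate map is then `u = i` exactly).
  Integer outputs round half up.

## Terminal rendering

A frame is an ordered list of styled segments — one character plus a colour
style — with exactly one newline segment per character row.

* **Half-block encoding.** Character cell `(r, c)` shows pixel rows `2r`
  (top, background colour) and `2r+1` (bottom, foreground colour) of column
  `c` with U+2584 LOWER HALF BLOCK. An H×W image yields `ceil(H/2)·W` styled
  segments and `ceil(H/2)` newlines — half a character per pixel. Odd
  heights pad a virtual black bottom row, keeping the one-character-per-pair
  rule total.
* **Legacy space encoding** (retained as an oracle): each pixel is a space
  with the pixel colour as background and no foreground, emitted twice per
  column so pixels render square — `2·H·W` styled segments plus `H`
  newlines. Equivalence of the two encodings on every pixel is a property
  test and part of the acceptance surface.
* **Style strings** use the dialect `rgb(R,G,B) on rgb(R,G,B)` (foreground
  before `on`, components in decimal with no padding). Foreground-only and
  background-only variants exist for the legacy encoding. A `StyleCache`
  maps full colour strings to parsed styles with hit/miss counters; cached
  and uncached ANSI emission are byte-identical, and re-rendering a frame
  adds no misses.
* **Indexed hot loop.** `render_indexed` takes a 0–255 index raster and a
  256-entry table of precomputed colour strings and scans columns two rows
  at a time, producing the style-string grid directly. Its output is
  invariant under any column evaluation order (checked by permutation
  tests) — the contract that makes the scan safe to parallelize over
  columns. The pure-Python implementation here keeps that contract without
  a compiled extension.
* **ANSI emission.** Each styled segment emits 24-bit SGR codes —
  `ESC[38;2;R;G;Bm` for foreground, `ESC[48;2;R;G;Bm` for background — then
  its character; each row ends with a reset and a bare newline. Segments are
  emitted individually (no run coalescing), which keeps output byte-
  deterministic. Stripping escape codes leaves exactly `char_rows` lines of
  `char_cols` characters.

## Controller and CLI

`handle_event` is a pure function from (view state, event, image shape) to
(new state, render-now flag). Out-of-range payloads clamp to bounds rather
than raising; switching the sectioning plane re-clamps the plane index. With
live updates enabled every state change renders; with them disabled (the
low-bandwidth mode for remote shells), slider drags mutate state silently
and only the matching release triggers a render, so a drag-drag-drag-release
sequence renders once instead of four times — and the frame after release is
identical in both modes. The command line is a thin one-shot wrapper: load,
build the initial view from the flags, write one ANSI frame to stdout,
optionally snapshot the RGB raster to PNG. Interactive widget chrome is
deliberately out of the tested contract; all browsing logic is exercised
headlessly through `handle_event`.

## Synthetic data

The fixtures module generates every input the loaders can read: intensity
ramps along X/Y/Z (clamped at the dtype maximum so they stay nondecreasing),
a parity checkerboard, constant fills, and seeded uniform noise — each a
pure function of `(spec, seed)`. These emulate the *structure* of microscopy
data (multi-page stacks, multi-channel sequences, chunked zarr arrays) but
not its content: no point-spread blur, photon noise, bleaching or axial
anisotropy. Passing tests therefore establish that indexing, I/O,
transforms and rendering are exact, not that the display is optimal for any
particular specimen.

## Problem sizes and numerical notes

Unit tests use volumes up to 8³ for exhaustive coordinate checks, rasters up
to 128×128 for count laws, and 100 random rasters up to 64×64 for the
renderer-equivalence sweep; one 512×672 frame — a typical camera field —
pins the large-frame segment counts (172,032 styled segments, 256 newlines).
The acceptance script uses the same sizes. All comparisons in the suite are
bit-exact; there are no floating-point tolerances anywhere because every
stage (normalization rounding, LUT lookup, zoom coordinate map, style
formatting) is pinned to an integer-valued contract.

## Known limitations

* No lazy or out-of-core loading; the full array is read into memory.
* No OME-TIFF metadata, BigTIFF, compressed/pyramidal TIFF, or remote
  stores.
* No per-channel composite overlays, gamma curves, histogram equalization,
  or free-angle rotation.
* The terminal output assumes a truecolor (24-bit SGR) terminal; there is
  no 256-colour or 16-colour fallback.
* Rendering throughput is that of pure Python; the design keeps the hot
  loop's order-independence contract so a compiled parallel scan could be
  substituted without changing any observable output.
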