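"""Navon compound-letter stimuli.

A Navon figure is a Global letter built from Local letters.  Here the two
letters are E and U, presented on a background matrix of '8'-shaped
placeholders (3 columns x 5 rows); a stimulus is unveiled by erasing line
segments from that matrix.  The full matrix subtends about 2.0 degrees of
visual angle (DVA) in width and 5.3 DVA in height; each placeholder is about
0.67 DVA wide and 1.05 DVA high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: placeholder geometry in DVA (40 arcmin wide, 1 deg 3 arcmin high)
CELL_W_DVA = 40.0 / 60.0
CELL_H_DVA = 1.05
GRID_COLS = 3
GRID_ROWS = 5

# seven-segment identifiers: horizontal top/mid/bottom, vertical
# upper-left/upper-right/lower-left/lower-right
_SEG_EIGHT = frozenset({"top", "mid", "bot", "ul", "ur", "ll", "lr"})
_SEG_LETTER = {
    "E": frozenset({"top", "mid", "bot", "ul", "ll"}),
    "U": frozenset({"ul", "ur", "ll", "lr", "bot"}),
}

# cells of the 3x5 grid (col, row) that are kept when the Global letter is
# drawn out of whole placeholders; row 0 is the top row
_GLOBAL_CELLS = {
    "E": {(c, r) for c in range(3) for r in range(5) if c == 0 or r in (0, 2, 4)},
    "U": {(c, r) for c in range(3) for r in range(5) if c in (0, 2) or r == 4},
}

LETTERS = ("E", "U")
LEVELS = ("Global", "Local")


@dataclass(frozen=True)
class NavonStimulus:
    """Binary luminance raster of one Navon stimulus.

    ``raster[0, 0]`` is the upper-left pixel; the grid center sits at
    ``origin`` in visual-field coordinates (DVA, fixation at the origin).
    """

    letter: str
    level: str
    raster: np.ndarray
    dva_per_pixel: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def lit_centroid_px(self) -> tuple[float, float]:
        """(row, col) centroid of lit pixels."""
        rows, cols = np.nonzero(self.raster)
        if rows.size == 0:
            raise ValueError("stimulus raster has no lit pixels")
        return float(rows.mean()), float(cols.mean())


def _segment_mask(h: int, w: int, segments: frozenset[str]) -> np.ndarray:
    """Rasterize a seven-segment glyph into an h x w cell."""
    t = max(1, round(min(h, w) / 8))
    cell = np.zeros((h, w), dtype=np.uint8)
    mid0 = (h - t) // 2
    if "top" in segments:
        cell[0:t, :] = 1
    if "mid" in segments:
        cell[mid0 : mid0 + t, :] = 1
    if "bot" in segments:
        cell[h - t : h, :] = 1
    half = mid0 + t  # verticals meet the middle bar
    if "ul" in segments:
        cell[0:half, 0:t] = 1
    if "ur" in segments:
        cell[0:half, w - t : w] = 1
    if "ll" in segments:
        cell[mid0:h, 0:t] = 1
    if "lr" in segments:
        cell[mid0:h, w - t : w] = 1
    return cell


def background_grid(dva_per_pixel: float) -> np.ndarray:
    """The full background matrix: every placeholder drawn as an '8'."""
    return _render_cells(
        {(c, r) for c in range(GRID_COLS) for r in range(GRID_ROWS)},
        _SEG_EIGHT,
        dva_per_pixel,
    )


def _cell_px(dva_per_pixel: float) -> tuple[int, int]:
    h = round(CELL_H_DVA / dva_per_pixel)
    w = round(CELL_W_DVA / dva_per_pixel)
    if h < 12 or w < 8:
        raise ValueError(
            f"resolution too coarse: placeholder spans {w}x{h} px, need >= 8x12"
        )
    return h, w


def _render_cells(
    cells: set[tuple[int, int]], segments: frozenset[str], dva_per_pixel: float
) -> np.ndarray:
    h, w = _cell_px(dva_per_pixel)
    glyph = _segment_mask(h, w, segments)
    raster = np.zeros((GRID_ROWS * h, GRID_COLS * w), dtype=np.uint8)
    for c, r in cells:
        raster[r * h : (r + 1) * h, c * w : (c + 1) * w] = glyph
    return raster


def render_navon(letter: str, level: str, dva_per_pixel: float) -> NavonStimulus:
    """Render a Navon stimulus raster.

    Global letters are drawn by keeping whole '8' placeholders in the cells
    of the letter shape and erasing the rest.  Local letters keep every
    placeholder but erase segments within each so that every placeholder
    becomes the small letter.  Both rasters are therefore subsets of the
    background '8' matrix.
    """
    if letter not in LETTERS:
        raise ValueError(f"unknown letter {letter!r}; expected one of {LETTERS}")
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if dva_per_pixel <= 0:
        raise ValueError("dva_per_pixel must be positive")
    if level == "Global":
        raster = _render_cells(_GLOBAL_CELLS[letter], _SEG_EIGHT, dva_per_pixel)
    else:
        cells = {(c, r) for c in range(GRID_COLS) for r in range(GRID_ROWS)}
        raster = _render_cells(cells, _SEG_LETTER[letter], dva_per_pixel)
    return NavonStimulus(letter, level, raster, dva_per_pixel)


def render_condition(condition: str, dva_per_pixel: float) -> NavonStimulus:
    """Render by condition code: EG, EL, UG or UL."""
    letter, lv = condition[0], condition[1]
    level = {"G": "Global", "L": "Local"}[lv]
    return render_navon(letter, level, dva_per_pixel)


def place_on_screen(
    stimulus: NavonStimulus, screen: tuple[int, int], scale: int = 1
) -> np.ndarray:
    """Paste the (optionally integer-upsampled) raster centered on a screen.

    ``screen`` is (width, height) in pixels; the returned image is
    (height, width) float in [0, 1].
    """
    width, height = screen
    raster = stimulus.raster
    if scale > 1:
        raster = np.kron(raster, np.ones((scale, scale), dtype=raster.dtype))
    h, w = raster.shape
    if h > height or w > width:
        raise ValueError("scaled stimulus does not fit on the screen")
    image = np.zeros((height, width), dtype=float)
    r0 = (height - h) // 2
    c0 = (width - w) // 2
    image[r0 : r0 + h, c0 : c0 + w] = raster
    return image
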