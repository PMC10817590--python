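"""Geometry of the en-face analysis grid.

The texture stage works on a 128 x 128 isotropic image split into a 7 x 7
grid of 18 x 18-pixel blocks anchored at the top-left corner (the trailing
two rows/columns are unused).  The central (4th) block row and column cover
the fovea and are discarded, leaving 36 blocks grouped into four 3 x 3
quadrants: Q1 temporal-superior, Q2 nasal-superior, Q3 temporal-inferior and
Q4 nasal-inferior, in the frame where the temporal side is the low-column
side (right eyes natively; left eyes after the horizontal flip) and superior
is the low-row side.
"""

from __future__ import annotations

from .constants import QUADRANTS
from .errors import ConfigurationError

BLOCK_SIZE = 18
GRID_SIZE = 7
CENTRAL_INDEX = 4  # 1-based row/column excluded (fovea)
ISO_SIZE = 128  # isotropic analysis image side
N_BLOCKS_TOTAL = GRID_SIZE * GRID_SIZE
N_BLOCKS_RETAINED = 36


def retained_tiles() -> list[tuple[int, int]]:
    """1-based (row, col) indices of the 36 non-central blocks."""
    return [
        (r, c)
        for r in range(1, GRID_SIZE + 1)
        for c in range(1, GRID_SIZE + 1)
        if r != CENTRAL_INDEX and c != CENTRAL_INDEX
    ]


def quadrant_of(tile: tuple[int, int]) -> str:
    """Quadrant of a retained 1-based (row, col) tile."""
    r, c = tile
    if r == CENTRAL_INDEX or c == CENTRAL_INDEX:
        raise ConfigurationError(f"tile {tile} is in the discarded central band")
    if not (1 <= r <= GRID_SIZE and 1 <= c <= GRID_SIZE):
        raise ConfigurationError(f"tile {tile} outside the {GRID_SIZE}x{GRID_SIZE} grid")
    if r < CENTRAL_INDEX:
        return "Q1" if c < CENTRAL_INDEX else "Q2"
    return "Q3" if c < CENTRAL_INDEX else "Q4"


def tile_pixel_slices(tile: tuple[int, int]) -> tuple[slice, slice]:
    """Pixel extent of a 1-based (row, col) tile on the 128 x 128 image."""
    r, c = tile
    return (
        slice((r - 1) * BLOCK_SIZE, r * BLOCK_SIZE),
        slice((c - 1) * BLOCK_SIZE, c * BLOCK_SIZE),
    )


def quadrant_pixel_ranges(quadrant: str) -> tuple[tuple[int, int], tuple[int, int]]:
    """(row range, col range) of a quadrant on the 128 x 128 image (pixel
    start inclusive, stop exclusive)."""
    if quadrant not in QUADRANTS:
        raise ConfigurationError(f"unknown quadrant {quadrant!r}")
    lo = (0, (CENTRAL_INDEX - 1) * BLOCK_SIZE)          # tiles 1..3 -> 0:54
    hi = (CENTRAL_INDEX * BLOCK_SIZE, GRID_SIZE * BLOCK_SIZE)  # tiles 5..7 -> 72:126
    rows = lo if quadrant in ("Q1", "Q2") else hi
    cols = lo if quadrant in ("Q1", "Q3") else hi
    return rows, cols
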