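"""Glyph rendering and conversion to transportable mass distributions.

Letters are rasterised to grayscale intensity images (8-bit values divided
by 255, so intensities lie in [0, 1]), tightly cropped to the ink bounding
box.  An image becomes a :class:`MassDistribution` by treating each pixel's
intensity as mass at its integer (row, col) position and rescaling the
masses to sum to one, which is the unit that the optimal-transport metrics
operate on.

The default typeface is DejaVu Sans, an openly licensed sans-serif resolved
from matplotlib's bundled font directory; any TrueType/OpenType file can be
supplied instead via ``font``.  Letter-shape measurements are font
dependent, so numbers quoted for one typeface will not reproduce exactly
under another.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw, ImageFont

__all__ = [
    "GERMAN_LETTERS",
    "IntensityImage",
    "MassDistribution",
    "default_font_path",
    "render_glyph",
    "render_letter_set",
    "load_glyph_png",
    "save_letter_set",
    "to_mass_distribution",
]

#: The 30 lower-case German letters in canonical RDM order: a..z then ä ö ü ß.
GERMAN_LETTERS: tuple[str, ...] = tuple("abcdefghijklmnopqrstuvwxyz") + (
    "ä",
    "ö",
    "ü",
    "ß",
)

MASS_TOL = 1e-9


class GlyphError(ValueError):
    """Raised for unrenderable glyphs or unusable font files."""


def default_font_path() -> str:
    """Path to the bundled open sans-serif (DejaVu Sans, via matplotlib)."""
    from matplotlib import get_data_path

    return os.path.join(get_data_path(), "fonts", "ttf", "DejaVuSans.ttf")


@dataclass(frozen=True)
class IntensityImage:
    """Grayscale raster of a glyph with values in [0, 1].

    Rows index y (top to bottom), columns index x; the origin is the
    top-left pixel and distances are in pixel units.
    """

    pixels: np.ndarray
    glyph_id: str = ""
    font_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if px.size == 0 or np.nanmin(px) < 0 or np.nanmax(px) > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def ink_mass(self) -> float:
        """Total intensity summed over all pixels."""
        return float(self.pixels.sum())


@dataclass(frozen=True)
class MassDistribution:
    """Discrete distribution of unit mass over integer pixel coordinates."""

    coords: np.ndarray  # (n, 2) int array of (row, col)
    masses: np.ndarray  # (n,) strictly positive, sums to 1
    total_mass: float = 1.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords)
        masses = np.asarray(self.masses, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must have shape (n, 2)")
        if masses.shape != (coords.shape[0],):
            raise ValueError("masses must align with coords")
        if coords.shape[0] == 0:
            raise ValueError("empty mass distribution")
        if np.any(masses <= 0):
            raise ValueError("masses must be strictly positive")
        if abs(masses.sum() - 1.0) > MASS_TOL:
            raise ValueError(
                f"masses must sum to 1 within {MASS_TOL:g} (got {masses.sum()!r})"
            )
        if len(np.unique(coords, axis=0)) != coords.shape[0]:
            raise ValueError("coords must be unique")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "masses", masses)

    def __len__(self) -> int:
        return self.coords.shape[0]


def _crop_to_ink(arr: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(arr.any(axis=1))
    cols = np.flatnonzero(arr.any(axis=0))
    return arr[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def render_glyph(
    char: str,
    font: str | None = None,
    max_height_px: int = 250,
) -> IntensityImage:
    """Rasterise a single character and normalise it to an intensity image.

    The glyph is drawn at a point size chosen so that, after tight cropping
    to the ink bounding box, the image height does not exceed
    ``max_height_px``.  Intensities are the rasteriser's 8-bit values
    divided by 255.

    Parameters
    ----------
    char:
        A single printable, non-whitespace character.
    font:
        Path to a TrueType/OpenType font file; defaults to the bundled
        DejaVu Sans.
    max_height_px:
        Maximum height of the cropped glyph, in pixels (>= 8).

    Raises
    ------
    GlyphError
        If the character renders to empty ink (e.g. whitespace) or the
        font file cannot be loaded.
    """
    if len(char) != 1:
        raise GlyphError(f"expected a single character, got {char!r}")
    if max_height_px < 8:
        raise ValueError("max_height_px must be >= 8")
    font_path = font if font is not None else default_font_path()
    if not os.path.exists(font_path):
        raise GlyphError(f"font file not found: {font_path}")
    try:
        probe = ImageFont.truetype(font_path, max_height_px)
    except OSError as exc:  # unreadable / not a font
        raise GlyphError(f"could not load font {font_path}: {exc}") from exc

    arr = _draw(char, probe, max_height_px)
    if arr is None:
        raise GlyphError(f"unrenderable glyph (no ink): {char!r}")
    # Descenders/umlauts can push the tight bounding box past the point
    # size; shrink the point size until the cropped height fits.
    size = max_height_px
    while arr.shape[0] > max_height_px and size > 1:
        size = int(size * max_height_px / arr.shape[0])
        arr = _draw(char, ImageFont.truetype(font_path, size), max_height_px)
        if arr is None:  # pragma: no cover - vanishes only at size ~0
            raise GlyphError(f"unrenderable glyph at size {size}: {char!r}")
    font_id = f"{os.path.basename(font_path)}@{size}px"
    return IntensityImage(pixels=arr / 255.0, glyph_id=char, font_id=font_id)


def _draw(char: str, font: ImageFont.FreeTypeFont, pad: int) -> np.ndarray | None:
    """Draw onto a generous canvas and crop to ink; None if blank."""
    canvas = Image.new("L", (4 * pad + 8, 4 * pad + 8), 0)
    ImageDraw.Draw(canvas).text((pad, pad), char, font=font, fill=255)
    arr = np.asarray(canvas, dtype=np.uint8)
    if not arr.any():
        return None
    return _crop_to_ink(arr).astype(float)


def render_letter_set(
    letters: tuple[str, ...] | list[str] = GERMAN_LETTERS,
    font: str | None = None,
    max_height_px: int = 250,
) -> dict[str, IntensityImage]:
    """Render an ordered letter set; insertion order follows ``letters``."""
    return {c: render_glyph(c, font=font, max_height_px=max_height_px) for c in letters}


def load_glyph_png(path: str, glyph_id: str = "") -> IntensityImage:
    """Read a pre-rendered 8-bit grayscale PNG as an intensity image."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    if not arr.any():
        raise GlyphError(f"image contains no ink: {path}")
    return IntensityImage(
        pixels=arr / 255.0, glyph_id=glyph_id or os.path.basename(path)
    )


def save_letter_set(images: dict[str, IntensityImage], out_dir: str) -> str:
    """Write glyph PNGs plus a JSON manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, dict] = {}
    for i, (char, img) in enumerate(images.items()):
        fname = f"glyph_{i:02d}.png"
        arr8 = np.round(img.pixels * 255).astype(np.uint8)
        Image.fromarray(arr8, mode="L").save(os.path.join(out_dir, fname))
        manifest[char] = {
            "file": fname,
            "font": img.font_id,
            "height": int(img.shape[0]),
        }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, ensure_ascii=False, indent=1)
    return path


def to_mass_distribution(
    img: IntensityImage, min_intensity: float = 0.0
) -> MassDistribution:
    """Convert an intensity image to a unit-mass distribution.

    Pixels with intensity strictly greater than ``min_intensity`` become
    support points; masses are proportional to intensity and rescaled to
    sum to one.

    Raises
    ------
    ValueError
        If thresholding leaves an empty support.
    """
    if not 0 <= min_intensity < 1:
        raise ValueError("min_intensity must lie in [0, 1)")
    rows, cols = np.nonzero(img.pixels > min_intensity)
    if rows.size == 0:
        raise ValueError(
            f"no pixels exceed min_intensity={min_intensity}; empty support"
        )
    masses = img.pixels[rows, cols].astype(float)
    masses = masses / masses.sum()
    coords = np.stack([rows, cols], axis=1).astype(np.int64)
    return MassDistribution(coords=coords, masses=masses)
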