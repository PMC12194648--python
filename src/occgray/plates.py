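"""Synthetic evaluation imagery: pseudoisochromatic plates, warm/cool cards
and colour charts.

The genuine Ishihara plates are copyrighted clinical material, so this
module generates plates that reproduce their *operative* property instead of
their appearance: a dotted disc in which a digit-shaped figure differs from
the ground in hue category (warm vs cool under the OCC dominance rule) but
not in BT.601 luminance.  A luminance-only conversion therefore erases the
figure, while a conversion sensitive to warmth/coolness keeps it legible.
Every generator is deterministic given its seed, and ground truth (figure
mask, dot table) is returned alongside the image.

Detection is quantified by :func:`separability` — the absolute difference of
mean gray level between figure dots and ground dots — with the conventional
4/255 discernibility threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .baselines import BT601_WEIGHTS, LumaWeights, bt601
from .occ import COOL, WARM, _as_rgb, dominance

__all__ = [
    "PlateSpec",
    "PlateImage",
    "Separability",
    "FONT_5X7",
    "glyph_mask",
    "match_luma",
    "make_plate",
    "separability",
    "make_warm_cool_card",
    "make_color_chart",
    "DEFAULT_FIGURE_PALETTE",
    "DEFAULT_GROUND_PALETTE",
]

logger = logging.getLogger(__name__)

# 5x7 bitmap digits, one string per row, '#' = ink.
FONT_5X7: dict[str, tuple[str, ...]] = {
    "0": (".###.", "#...#", "#..##", "#.#.#", "##..#", "#...#", ".###."),
    "1": ("..#..", ".##..", "..#..", "..#..", "..#..", "..#..", ".###."),
    "2": (".###.", "#...#", "....#", "...#.", "..#..", ".#...", "#####"),
    "3": ("#####", "...#.", "..#..", "...#.", "....#", "#...#", ".###."),
    "4": ("...#.", "..##.", ".#.#.", "#..#.", "#####", "...#.", "...#."),
    "5": ("#####", "#....", "####.", "....#", "....#", "#...#", ".###."),
    "6": ("..##.", ".#...", "#....", "####.", "#...#", "#...#", ".###."),
    "7": ("#####", "....#", "...#.", "..#..", ".#...", ".#...", ".#..."),
    "8": (".###.", "#...#", "#...#", ".###.", "#...#", "#...#", ".###."),
    "9": (".###.", "#...#", "#...#", ".####", "....#", "...#.", ".##.."),
}

# Warm (orange/red) and cool (green/teal/blue) palettes; every entry has
# BT.601 luma above the 0.5 matching target so matching only darkens.
DEFAULT_FIGURE_PALETTE: tuple[tuple[float, float, float], ...] = (
    (1.00, 0.55, 0.10),
    (1.00, 0.45, 0.20),
    (0.95, 0.60, 0.25),
)
DEFAULT_GROUND_PALETTE: tuple[tuple[float, float, float], ...] = (
    (0.30, 0.90, 0.30),
    (0.20, 0.80, 0.70),
    (0.35, 0.75, 0.95),
)


def _luma(color) -> float:
    return float(np.dot(np.asarray(color, dtype=np.float64), BT601_WEIGHTS))


def match_luma(color, target: float, *, tol: float = 1.0 / 255.0):
    """Scale a colour along its brightness direction to a BT.601 luma target.

    Multiplying all channels by ``t = target / luma`` preserves hue and the
    warm/cool category while moving luminance to ``target``.  Raises
    ``ValueError`` when the target is unreachable (black input, or a scale
    that would push a channel above 1).
    """
    arr = _as_rgb(np.asarray(color, dtype=np.float64).reshape(3))
    lum = _luma(arr)
    if lum <= 0.0:
        raise ValueError(f"colour {tuple(arr)} has zero luma; no hue to scale")
    t = target / lum
    if t * arr.max() > 1.0 + 1e-12:
        raise ValueError(
            f"luma target {target} unreachable for colour {tuple(arr)} by scaling"
        )
    out = np.clip(t * arr, 0.0, 1.0)
    if abs(_luma(out) - target) >= tol:
        raise ValueError(f"could not match luma of {tuple(arr)} to {target}")
    if dominance(out).category != dominance(arr).category:
        raise ValueError(
            f"luma matching changed the warm/cool category of {tuple(arr)}"
        )
    return tuple(float(v) for v in out)


@dataclass(frozen=True)
class PlateSpec:
    """Recipe for one pseudoisochromatic plate.

    ``coverage`` is the target dot-area fraction of the plate disc;
    dart-throwing stops once reached or after the failure budget.  With
    ``luma_matched`` every palette entry is projected to ``target_luma``
    before painting, making the figure invisible to BT.601.
    """

    size: int = 160
    glyph: str = "8"
    figure_palette: tuple = DEFAULT_FIGURE_PALETTE
    ground_palette: tuple = DEFAULT_GROUND_PALETTE
    luma_matched: bool = True
    target_luma: float = 0.5
    dot_radius_range: tuple[int, int] = (3, 7)
    # greedy non-overlapping packing saturates near 0.42 for this radius
    # spread; 0.40 is reliably reachable without a best-effort fallback
    coverage: float = 0.40
    seed: int = 0
    background: float = 1.0
    max_failures: int = 4000

    def __post_init__(self):
        if self.glyph not in FONT_5X7:
            raise ValueError(f"glyph {self.glyph!r} not in the built-in font "
                             f"(available: {sorted(FONT_5X7)})")
        if self.size < 32:
            raise ValueError("plate size must be at least 32 pixels")
        lo, hi = self.dot_radius_range
        if not (0 < lo <= hi):
            raise ValueError("dot_radius_range must satisfy 0 < lo <= hi")
        if not 0.0 < self.coverage < 0.91:
            raise ValueError("coverage must be in (0, 0.91)")
        fig = [dominance(c).category for c in self.figure_palette]
        gnd = [dominance(c).category for c in self.ground_palette]
        if len(set(fig)) != 1 or len(set(gnd)) != 1 or fig[0] == gnd[0]:
            raise ValueError(
                "figure and ground palettes must each be uniform in hue "
                "category and of opposite categories (one warm, one cool)"
            )


@dataclass
class PlateImage:
    """Generated plate: RGB raster, figure-dot mask, all-dot mask, dot table."""

    image: np.ndarray
    mask: np.ndarray
    dots: np.ndarray
    dot_table: pd.DataFrame
    spec: PlateSpec


def glyph_mask(glyph: str, size: int) -> np.ndarray:
    """Rasterize a 5x7 font glyph into the centre of a ``size`` x ``size`` mask.

    The glyph box spans roughly 60% of the plate height, nearest-neighbour
    upsampled from the bitmap.
    """
    rows = FONT_5X7[glyph]
    bitmap = np.array([[c == "#" for c in row] for row in rows], dtype=bool)
    cell = max(size * 6 // 10 // 7, 1)
    gh, gw = 7 * cell, 5 * cell
    big = np.kron(bitmap, np.ones((cell, cell), dtype=bool))
    mask = np.zeros((size, size), dtype=bool)
    r0 = (size - gh) // 2
    c0 = (size - gw) // 2
    mask[r0:r0 + gh, c0:c0 + gw] = big
    return mask


def make_plate(spec: PlateSpec) -> PlateImage:
    """Generate a dotted plate hiding the glyph in hue category only.

    Greedy dart-throwing packs non-overlapping discs inside the plate circle
    until the coverage target or the failure budget is hit (best-effort with
    a warning in the latter case).  A dot whose centre lies inside the glyph
    mask takes a figure-palette colour, others a ground-palette colour;
    palettes are luma-matched first when the spec asks for it.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    if spec.luma_matched:
        figure_pal = [match_luma(c, spec.target_luma) for c in spec.figure_palette]
        ground_pal = [match_luma(c, spec.target_luma) for c in spec.ground_palette]
    else:
        figure_pal = [tuple(map(float, c)) for c in spec.figure_palette]
        ground_pal = [tuple(map(float, c)) for c in spec.ground_palette]

    glyph = glyph_mask(spec.glyph, size)
    centre = (size - 1) / 2.0
    plate_r = 0.48 * size
    disc_area = np.pi * plate_r ** 2
    target_area = spec.coverage * disc_area

    image = np.full((size, size, 3), spec.background, dtype=np.float64)
    fig_mask = np.zeros((size, size), dtype=bool)
    dot_mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]

    centres_x: list[float] = []
    centres_y: list[float] = []
    radii: list[float] = []
    records = []
    covered = 0.0
    failures = 0
    lo, hi = spec.dot_radius_range
    while covered < target_area and failures < spec.max_failures:
        r = float(rng.uniform(lo, hi))
        x = float(rng.uniform(r, size - 1 - r))
        y = float(rng.uniform(r, size - 1 - r))
        if np.hypot(x - centre, y - centre) + r > plate_r:
            failures += 1
            continue
        if radii:
            d = np.hypot(np.array(centres_x) - x, np.array(centres_y) - y)
            if np.any(d < np.array(radii) + r + 1.0):
                failures += 1
                continue
        is_figure = bool(glyph[int(round(y)), int(round(x))])
        palette = figure_pal if is_figure else ground_pal
        pal_idx = int(rng.integers(len(palette)))
        color = palette[pal_idx]
        disc = (yy - y) ** 2 + (xx - x) ** 2 <= r ** 2
        image[disc] = color
        dot_mask |= disc
        if is_figure:
            fig_mask |= disc
        centres_x.append(x)
        centres_y.append(y)
        radii.append(r)
        records.append(
            {"x": x, "y": y, "radius": r, "figure": is_figure, "palette_index": pal_idx}
        )
        covered += np.pi * r ** 2
        failures = 0
    if covered < target_area:
        warnings.warn(
            f"plate packing reached {covered / disc_area:.2f} coverage of the "
            f"{spec.coverage:.2f} target before the failure budget",
            UserWarning,
        )
    table = pd.DataFrame.from_records(
        records, columns=["x", "y", "radius", "figure", "palette_index"]
    )
    return PlateImage(image=image, mask=fig_mask, dots=dot_mask, dot_table=table, spec=spec)


class Separability(NamedTuple):
    """Figure/ground mean-gray separation and its detection verdict."""

    statistic: float
    detected: bool


#: Gray-level separation regarded as discernible (the tau=4 convention
#: rescaled to unit gray levels).
DETECTION_THRESHOLD = 4.0 / 255.0


def separability(gray, mask, dots=None, *, threshold: float = DETECTION_THRESHOLD) -> Separability:
    """Contrast statistic between figure and ground regions of a gray raster.

    ``mask`` flags figure pixels (1); ``dots`` optionally restricts the
    computation to dot pixels (figure = mask & dots, ground = ~mask & dots)
    so the plate background is excluded.  Returns the absolute difference of
    region means and whether it reaches the discernibility threshold.
    """
    g = np.asarray(gray, dtype=np.float64)
    m = np.asarray(mask).astype(bool)
    if g.shape != m.shape:
        raise ValueError("gray and mask shapes must match")
    if dots is None:
        fig, gnd = m, ~m
    else:
        d = np.asarray(dots).astype(bool)
        if d.shape != g.shape:
            raise ValueError("dots mask shape must match the gray raster")
        fig, gnd = m & d, ~m & d
    if not fig.any() or not gnd.any():
        raise ValueError("both figure and ground regions must be non-empty")
    stat = float(abs(g[fig].mean() - g[gnd].mean()))
    return Separability(statistic=stat, detected=stat >= threshold)


def make_warm_cool_card(size: int = 96,
                        warm=(1.00, 0.55, 0.10),
                        cool=(0.30, 0.90, 0.30),
                        ground: float = 0.5,
                        *, luma_matched: bool = True):
    """Flat card with a warm disc and a cool disc on a neutral gray ground.

    With ``luma_matched`` (default) both discs are projected to the ground's
    BT.601 luma, so a luminance conversion flattens the card while a
    warmth/coolness-aware one separates the discs.  Returns
    ``(image, masks)`` where ``masks`` has boolean ``warm``, ``cool`` and
    ``ground`` regions for sweep tests.
    """
    if luma_matched:
        warm = match_luma(warm, ground)
        cool = match_luma(cool, ground)
    if dominance(warm).category != WARM or dominance(cool).category != COOL:
        raise ValueError("card colours must be warm-dominant and cool-dominant")
    image = np.full((size, size, 3), float(ground), dtype=np.float64)
    yy, xx = np.mgrid[0:size, 0:size]
    r = size * 0.2
    warm_mask = (yy - size / 2) ** 2 + (xx - size * 0.28) ** 2 <= r ** 2
    cool_mask = (yy - size / 2) ** 2 + (xx - size * 0.72) ** 2 <= r ** 2
    image[warm_mask] = warm
    image[cool_mask] = cool
    masks = {"warm": warm_mask, "cool": cool_mask, "ground": ~(warm_mask | cool_mask)}
    return image, masks


def make_color_chart(cell: int = 16) -> np.ndarray:
    """Chart of the primaries, secondaries, white, black and mid-gray.

    A 3x3 grid of flat patches (red, green, blue / yellow, cyan, magenta /
    white, gray, black), ``cell`` pixels per patch side.
    """
    colors = [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (0, 1, 1), (1, 0, 1),
        (1, 1, 1), (0.5, 0.5, 0.5), (0, 0, 0),
    ]
    chart = np.zeros((3 * cell, 3 * cell, 3), dtype=np.float64)
    for idx, c in enumerate(colors):
        r, col = divmod(idx, 3)
        chart[r * cell:(r + 1) * cell, col * cell:(col + 1) * cell] = c
    return chart
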