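"""Opponent and Complementary Colour (OCC) representation.

The OCC system models the retina's parallel ON/OFF pathways as two
complementary four-channel banks.  An RGB colour is mapped literally onto
cone-like channels (L <- R, M <- G, S <- B) plus a combined luminance-like
channel ``LM = min(L + M, 1)``; the OFF bank carries the complement of each
ON channel.  Averaging each bank yields a scalar *activity* ``A_on`` (and
*inactivity* ``A_off``), which places every colour on a single black-to-white
scale: white is full activity (1), black none (0), yellow 3/4, red and green
1/2, blue 1/4.  By construction ``A_on + A_off == 1`` for every colour.

On top of the channel bank the module defines:

* *complementary* colours — channel-wise pairs that sum to white;
* *opponent* colours — antipodes on the OCC activity sphere, whose activity
  is ``1 - A_on``;
* warm/cool *dominance* ``D = L - min(M + S, 1)`` — warm when the
  long-wavelength channel dominates (``D >= 0``), cool otherwise;
* sphere coordinates (activity as elevation, hue as azimuth with red at 0°
  and the four primaries 90° apart, saturation as radius) for visualisation.

All channel arithmetic is on floats in [0, 1]; 8-bit inputs must be divided
by 255 before use (see :mod:`occgray.raster`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WARM",
    "COOL",
    "OCCState",
    "Dominance",
    "SphereCoord",
    "to_occ",
    "occ_arrays",
    "activity",
    "dominance",
    "dominance_arrays",
    "complement_of",
    "opponent_activity",
    "sphere_coordinates",
    "occ_table",
]

WARM = "warm"
COOL = "cool"

_CHANNEL_NAMES = ("r", "g", "b")


def _as_rgb(color, *, what: str = "color") -> np.ndarray:
    """Validate an RGB colour or image and return it as a float64 array.

    Accepts anything broadcastable to shape ``(..., 3)``.  Raises
    ``ValueError`` naming the offending channel and value when a channel
    falls outside [0, 1].
    """
    arr = np.asarray(color, dtype=np.float64)
    if arr.ndim == 0 or arr.shape[-1] != 3:
        raise ValueError(
            f"{what} must have 3 trailing channels (r, g, b); got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite channel values")
    for idx, name in enumerate(_CHANNEL_NAMES):
        chan = arr[..., idx]
        lo, hi = float(chan.min()), float(chan.max())
        if lo < 0.0:
            raise ValueError(f"channel {name!r} out of range [0, 1]: {lo}")
        if hi > 1.0:
            raise ValueError(f"channel {name!r} out of range [0, 1]: {hi}")
    return arr


@dataclass(frozen=True)
class OCCState:
    """ON/OFF channel bank and activity pair for a single colour."""

    L: float
    M: float
    S: float
    LM: float
    negL: float
    negM: float
    negS: float
    negLM: float
    A_on: float
    A_off: float


@dataclass(frozen=True)
class Dominance:
    """Warm/cool dominance score ``D = L - min(M + S, 1)`` and its category."""

    D: float
    MS: float
    category: str


@dataclass(frozen=True)
class SphereCoord:
    """Position of a colour on the OCC sphere.

    ``elevation`` is the ON activity in [0, 1] (poles are black and white),
    ``azimuth`` the hue angle in degrees with red at 0°, yellow 90°, green
    180°, blue 270°, and ``radius`` the saturation (max - min channel).
    Achromatic colours sit on the polar axis and report azimuth 0 by
    convention.
    """

    elevation: float
    azimuth: float
    radius: float


def occ_arrays(image) -> dict[str, np.ndarray]:
    """Vectorised OCC transform.

    Parameters
    ----------
    image : array-like, shape (..., 3)
        RGB values in [0, 1].

    Returns
    -------
    dict
        Arrays keyed ``L, M, S, LM, negL, negM, negS, negLM, A_on, A_off``,
        each with the input's spatial shape.
    """
    arr = _as_rgb(image, what="image")
    L, M, S = arr[..., 0], arr[..., 1], arr[..., 2]
    LM = np.minimum(L + M, 1.0)
    negL, negM, negS, negLM = 1.0 - L, 1.0 - M, 1.0 - S, 1.0 - LM
    A_on = (L + M + S + LM) / 4.0
    A_off = (negL + negM + negS + negLM) / 4.0
    return {
        "L": L, "M": M, "S": S, "LM": LM,
        "negL": negL, "negM": negM, "negS": negS, "negLM": negLM,
        "A_on": A_on, "A_off": A_off,
    }


def to_occ(color) -> OCCState:
    """Map one RGB colour to its OCC state.

    >>> to_occ((1.0, 0.0, 0.0)).A_on   # red: half activity
    0.5
    """
    ch = occ_arrays(np.asarray(color, dtype=np.float64).reshape(3))
    return OCCState(**{k: float(v) for k, v in ch.items()})


def activity(image) -> np.ndarray:
    """ON-pathway activity map ``A_on`` of an RGB image."""
    return occ_arrays(image)["A_on"]


def dominance_arrays(image) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised dominance: returns ``(D, MS)`` arrays."""
    arr = _as_rgb(image, what="image")
    MS = np.minimum(arr[..., 1] + arr[..., 2], 1.0)
    return arr[..., 0] - MS, MS


def dominance(color) -> Dominance:
    """Warm/cool dominance of one colour (warm iff ``D >= 0``)."""
    D, MS = dominance_arrays(np.asarray(color, dtype=np.float64).reshape(3))
    D, MS = float(D), float(MS)
    return Dominance(D=D, MS=MS, category=WARM if D >= 0 else COOL)


def complement_of(color):
    """Channel-wise complement; the pair sums to white.

    Involutive: ``complement_of(complement_of(c)) == c`` exactly.
    """
    arr = _as_rgb(np.asarray(color, dtype=np.float64).reshape(3))
    return tuple(float(v) for v in 1.0 - arr)


def opponent_activity(state: OCCState) -> float:
    """Activity of the opponent colour: ``1 - A_on`` (sphere antipode)."""
    return 1.0 - state.A_on


def _hue_azimuth(hue_deg: np.ndarray) -> np.ndarray:
    """Remap an RGB hue angle (red 0°, yellow 60°, ...) to the OCC wheel.

    The four OCC primaries are equally spaced: red 0°, yellow 90°, green
    180°, blue 270°; hues between adjacent primaries interpolate linearly.
    """
    h = np.asarray(hue_deg, dtype=np.float64)
    az = np.empty_like(h)
    seg1 = h < 60.0          # red -> yellow
    seg2 = (h >= 60.0) & (h < 120.0)   # yellow -> green
    seg3 = (h >= 120.0) & (h < 240.0)  # green -> blue (through cyan)
    seg4 = h >= 240.0        # blue -> red (through magenta)
    az[seg1] = h[seg1] * 1.5
    az[seg2] = 90.0 + (h[seg2] - 60.0) * 1.5
    az[seg3] = 180.0 + (h[seg3] - 120.0) * 0.75
    az[seg4] = 270.0 + (h[seg4] - 240.0) * 0.75
    return np.mod(az, 360.0)


def sphere_coordinates(color) -> SphereCoord:
    """Locate a colour on the OCC sphere.

    Elevation is ``A_on``, azimuth the remapped hue (red 0°, green 180°),
    radius the channel spread ``max - min`` (a visualisation convention;
    achromatic colours report azimuth 0).
    """
    from skimage.color import rgb2hsv

    arr = _as_rgb(np.asarray(color, dtype=np.float64).reshape(3))
    elev = float(to_occ(arr).A_on)
    radius = float(arr.max() - arr.min())
    if radius == 0.0:
        return SphereCoord(elevation=elev, azimuth=0.0, radius=0.0)
    hue = float(rgb2hsv(arr.reshape(1, 1, 3))[0, 0, 0]) * 360.0
    return SphereCoord(elevation=elev, azimuth=float(_hue_azimuth(hue)), radius=radius)


def occ_table(colors) -> pd.DataFrame:
    """Tabulate OCC states and dominance for a list of colours.

    Returns a DataFrame with columns
    ``r, g, b, L, M, S, LM, A_on, A_off, D, category`` — the CSV-friendly
    inspection format.
    """
    arr = _as_rgb(np.atleast_2d(np.asarray(colors, dtype=np.float64)))
    ch = occ_arrays(arr)
    D, _ = dominance_arrays(arr)
    return pd.DataFrame(
        {
            "r": arr[..., 0], "g": arr[..., 1], "b": arr[..., 2],
            "L": ch["L"], "M": ch["M"], "S": ch["S"], "LM": ch["LM"],
            "A_on": ch["A_on"], "A_off": ch["A_off"],
            "D": D,
            "category": np.where(D >= 0, WARM, COOL),
        }
    )
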