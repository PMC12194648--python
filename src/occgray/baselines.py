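"""Reference colour-to-gray converters: BT.601 luma and PCA projection.

These are the two weighting/channel-analysis baselines the benchmark
compares DWCA against.  External converters can be plugged into the method
registry via :func:`register_method`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dwca import DWCAParams, decolorize
from .occ import _as_rgb

__all__ = [
    "LumaWeights",
    "bt601",
    "pca_decolorize",
    "DegenerateImageError",
    "get_method",
    "register_method",
    "available_methods",
]

#: ITU-R BT.601 luma coefficients for (R, G, B).
BT601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class LumaWeights:
    """Non-negative channel weights summing to 1 (default BT.601)."""

    wr: float = BT601_WEIGHTS[0]
    wg: float = BT601_WEIGHTS[1]
    wb: float = BT601_WEIGHTS[2]

    def __post_init__(self):
        if min(self.wr, self.wg, self.wb) < 0:
            raise ValueError("luma weights must be non-negative")
        if abs(self.wr + self.wg + self.wb - 1.0) > 1e-12:
            raise ValueError("luma weights must sum to 1 within 1e-12")

    def as_array(self) -> np.ndarray:
        return np.array([self.wr, self.wg, self.wb], dtype=np.float64)


class DegenerateImageError(ValueError):
    """Raised when PCA decolorization gets an image with zero colour variance."""


def bt601(image, weights: LumaWeights | None = None) -> np.ndarray:
    """Weighted-luma conversion: per pixel ``wr*R + wg*G + wb*B``."""
    arr = _as_rgb(image, what="image")
    w = (weights or LumaWeights()).as_array()
    return arr @ w


def pca_decolorize(image) -> np.ndarray:
    """Project pixels onto the first principal axis of their colour cloud.

    Pixel colours are mean-centred and projected onto the dominant
    eigenvector of the 3x3 colour covariance; the axis is oriented so the
    projection correlates non-negatively with BT.601 luma (preventing
    arbitrary polarity flips between images), then min-max rescaled to
    [0, 1].  Needs at least two distinct pixel colours.
    """
    arr = _as_rgb(image, what="image")
    pix = arr.reshape(-1, 3)
    centred = pix - pix.mean(axis=0)
    cov = centred.T @ centred / max(len(pix) - 1, 1)
    if np.allclose(cov, 0.0, atol=1e-18):
        raise DegenerateImageError(
            "image has zero colour variance; PCA is undefined — use bt601 instead"
        )
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    proj = centred @ axis
    luma = pix @ np.array(BT601_WEIGHTS)
    if np.dot(proj, luma - luma.mean()) < 0:
        proj = -proj
    lo, hi = proj.min(), proj.max()
    proj = (proj - lo) / (hi - lo)
    return proj.reshape(arr.shape[:-1])


def _dwca_method(image, params: DWCAParams | None = None, **kwargs):
    if params is None and kwargs:
        params = DWCAParams(**kwargs)
    return decolorize(image, params)


_REGISTRY = {
    "bt601": lambda image, **kw: bt601(image, **kw),
    "pca": lambda image, **kw: pca_decolorize(image),
    "dwca": _dwca_method,
}


def register_method(name: str, converter) -> None:
    """Register an external converter ``f(image, **kwargs) -> gray`` by name.

    This is the adapter point for third-party decolorization methods that
    this package deliberately does not reimplement.
    """
    _REGISTRY[name] = converter


def get_method(name: str):
    """Look up a converter by registry name; raises KeyError if unknown."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown method {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_methods() -> list[str]:
    return sorted(_REGISTRY)
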