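"""Contrast-preservation metrics for decolorization.

Given a colour image and its gray rendition, the core quantities are

* CCPR — of the sampled pixel pairs whose colour difference is at least
  ``tau`` (the set Omega), the fraction whose gray difference stays >= tau;
* CCFR — one minus the fraction of gray-contrasting pairs (difference >
  ``tau``, the set Theta) whose colour difference was <= tau, i.e. a penalty
  for contrast invented by the conversion;
* E-score — the harmonic mean of the two;
* a composite C2G-SSIM: the windowed product of SSIM-style luminance,
  contrast and structure terms between the reference lightness and the gray
  image, raised to exponents alpha, beta, gamma.  The component definitions
  here are documented SSIM stand-ins ("composite-compatible"), not the
  original C2G-SSIM component equations.

Units.  By default colour differences are CIE76 Delta-E in CIELAB (sRGB,
D65) and gray differences are CIELAB L* differences of the achromatic gray,
so a single threshold ``tau`` (4 = barely discernible, 10, 20) lives on one
perceptual-lightness scale.  ``units="byte"`` switches both to 0-255 scales
(Euclidean RGB distance and 8-bit gray levels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.color import rgb2lab

from .occ import _as_rgb

__all__ = [
    "PairSample",
    "ContrastReport",
    "C2GSSIMParams",
    "delta_e",
    "lightness",
    "gray_lightness",
    "sample_pairs",
    "ccpr",
    "ccfr",
    "e_score",
    "c2g_ssim",
    "evaluate_pair",
    "contrast_report",
    "write_report",
]

logger = logging.getLogger(__name__)

DEFAULT_TAUS = (4.0, 10.0, 20.0)
DEFAULT_N_PAIRS = 80


def lightness(image) -> np.ndarray:
    """CIELAB L* map (0-100) of an sRGB image with channels in [0, 1]."""
    arr = _as_rgb(image, what="image")
    return rgb2lab(arr.reshape(-1, 1, 3)).reshape(arr.shape)[..., 0]


def gray_lightness(gray) -> np.ndarray:
    """CIELAB L* (0-100) of an achromatic gray raster in [0, 1]."""
    g = np.asarray(gray, dtype=np.float64)
    rgb = np.stack([g, g, g], axis=-1)
    return lightness(rgb)


def delta_e(c1, c2) -> float | np.ndarray:
    """CIE76 colour difference: Euclidean distance in CIELAB (sRGB, D65).

    Black vs white is 100 (the full L* span); identical colours give 0.
    Broadcasts over leading dimensions.
    """
    a1 = _as_rgb(np.asarray(c1, dtype=np.float64))
    a2 = _as_rgb(np.asarray(c2, dtype=np.float64))
    lab1 = rgb2lab(a1.reshape(-1, 1, 3)).reshape(a1.shape)
    lab2 = rgb2lab(a2.reshape(-1, 1, 3)).reshape(a2.shape)
    d = np.sqrt(np.sum((lab1 - lab2) ** 2, axis=-1))
    return float(d) if d.ndim == 0 else d


@dataclass
class PairSample:
    """Sampled pixel pairs of one colour image plus their colour differences.

    ``pairs`` holds flat pixel indices, shape (n, 2).  ``omega`` is the
    boolean mask of pairs whose colour difference is >= ``tau``; the
    gray-dependent set Theta is derived later by :func:`ccfr` from the gray
    raster under evaluation.
    """

    pairs: np.ndarray
    color_diff: np.ndarray
    tau: float
    seed: int | None
    exhaustive: bool
    shape: tuple[int, ...]
    units: str = "lab"

    @property
    def omega(self) -> np.ndarray:
        return self.color_diff >= self.tau

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _color_distance_map(image, units: str) -> np.ndarray:
    pix = _as_rgb(image, what="image").reshape(-1, 3)
    if units == "lab":
        return rgb2lab(pix.reshape(-1, 1, 3)).reshape(-1, 3)
    if units == "byte":
        return pix * 255.0
    raise ValueError(f"units must be 'lab' or 'byte', got {units!r}")


def _gray_values(gray, units: str) -> np.ndarray:
    g = np.asarray(gray, dtype=np.float64).reshape(-1)
    if units == "lab":
        return gray_lightness(g)
    if units == "byte":
        return g * 255.0
    raise ValueError(f"units must be 'lab' or 'byte', got {units!r}")


def sample_pairs(image, n: int = DEFAULT_N_PAIRS, tau: float = 4.0,
                 seed: int | None = None, *, exhaustive: bool = False,
                 units: str = "lab") -> PairSample:
    """Draw ``n`` distinct unordered pixel pairs uniformly without replacement.

    With ``exhaustive=True`` (or when ``n`` meets or exceeds the number of
    distinct pairs, with a logged fallback) every unordered pair is used.
    A fixed seed reproduces the identical sample.
    """
    arr = _as_rgb(image, what="image")
    npix = int(np.prod(arr.shape[:-1]))
    if npix < 2:
        raise ValueError("image must have at least 2 pixels")
    total = npix * (npix - 1) // 2
    if not exhaustive and n >= total:
        logger.warning(
            "requested %d pairs but only %d distinct pairs exist; using all", n, total
        )
        exhaustive = True
    if exhaustive:
        i, j = np.triu_indices(npix, k=1)
        pairs = np.column_stack([i, j])
    else:
        rng = np.random.default_rng(seed)
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < n:
            i, j = (int(v) for v in rng.integers(0, npix, size=2))
            if i == j:
                continue
            chosen.add((i, j) if i < j else (j, i))
        pairs = np.array(sorted(chosen), dtype=np.int64)
    feats = _color_distance_map(arr, units)
    diff = np.sqrt(np.sum((feats[pairs[:, 0]] - feats[pairs[:, 1]]) ** 2, axis=-1))
    return PairSample(pairs=pairs, color_diff=diff, tau=float(tau), seed=seed,
                      exhaustive=exhaustive, shape=arr.shape[:-1], units=units)


def _check_aligned(sample: PairSample, gray) -> np.ndarray:
    g = np.asarray(gray, dtype=np.float64)
    if g.shape != sample.shape:
        raise ValueError(
            f"gray raster shape {g.shape} does not match sampled image shape {sample.shape}"
        )
    return g


def ccpr(sample: PairSample, gray, *, tau_gray: float | None = None) -> float:
    """Colour-contrast preserving ratio.

    Fraction of Omega (pairs with colour difference >= tau) whose gray
    difference is also >= the threshold.  ``tau_gray`` overrides the gray
    threshold (used to study threshold sweeps on a fixed pair set); it
    defaults to the sample's tau.  Empty Omega returns 1.0 vacuously with a
    logged notice.
    """
    g = _check_aligned(sample, gray)
    tau_g = sample.tau if tau_gray is None else float(tau_gray)
    omega = sample.omega
    if not omega.any():
        logger.info("CCPR: empty Omega (no colour-contrasting pairs); returning 1.0")
        return 1.0
    gv = _gray_values(g, sample.units)
    gdiff = np.abs(gv[sample.pairs[omega, 0]] - gv[sample.pairs[omega, 1]])
    return float(np.count_nonzero(gdiff >= tau_g) / np.count_nonzero(omega))


def ccfr(sample: PairSample, gray, *, tau_gray: float | None = None) -> float:
    """Colour-contrast fidelity ratio.

    One minus the fraction of Theta (pairs with gray difference > the
    threshold) whose colour difference was <= tau — penalising contrast the
    conversion invented.  Empty Theta returns 1.0 vacuously with a notice.
    """
    g = _check_aligned(sample, gray)
    tau_g = sample.tau if tau_gray is None else float(tau_gray)
    gv = _gray_values(g, sample.units)
    gdiff = np.abs(gv[sample.pairs[:, 0]] - gv[sample.pairs[:, 1]])
    theta = gdiff > tau_g
    if not theta.any():
        logger.info("CCFR: empty Theta (no gray-contrasting pairs); returning 1.0")
        return 1.0
    bad = np.count_nonzero(sample.color_diff[theta] <= sample.tau)
    return float(1.0 - bad / np.count_nonzero(theta))


def e_score(ccpr_value: float, ccfr_value: float) -> float:
    """Harmonic mean of CCPR and CCFR (0 when both are 0)."""
    if not (0.0 <= ccpr_value <= 1.0 and 0.0 <= ccfr_value <= 1.0):
        raise ValueError("ccpr and ccfr must lie in [0, 1]")
    if ccpr_value + ccfr_value == 0.0:
        return 0.0
    return 2.0 * ccpr_value * ccfr_value / (ccpr_value + ccfr_value)


@dataclass(frozen=True)
class C2GSSIMParams:
    """Exponents and window of the composite C2G-SSIM."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    window: int = 11

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative exponent")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


def c2g_ssim(color_image, gray, params: C2GSSIMParams | None = None) -> float:
    """Composite structural-similarity score between colour and gray images.

    The reference signal is the CIELAB lightness of the colour image scaled
    to [0, 1].  Within each sliding window, SSIM-style luminance, contrast
    and structure terms are formed and combined as
    ``mean(L**alpha * C**beta * S**gamma)``.  Structure is clipped at zero
    before exponentiation so fractional exponents stay real.  Equals 1 when
    the gray image reproduces the reference lightness exactly, and 1
    trivially when all exponents are 0.
    """
    params = params or C2GSSIMParams()
    ref = lightness(color_image) / 100.0
    g = np.asarray(gray, dtype=np.float64)
    if g.shape != ref.shape:
        raise ValueError("gray raster must match the colour image's spatial shape")
    if params.window > min(g.shape):
        raise ValueError(
            f"window {params.window} exceeds smallest image dimension {min(g.shape)}"
        )
    # SSIM regularizers for unit data range
    c1, c2 = 0.01 ** 2, 0.03 ** 2
    c3 = c2 / 2.0
    w = params.window
    mu_x = uniform_filter(ref, size=w)
    mu_y = uniform_filter(g, size=w)
    var_x = np.maximum(uniform_filter(ref * ref, size=w) - mu_x ** 2, 0.0)
    var_y = np.maximum(uniform_filter(g * g, size=w) - mu_y ** 2, 0.0)
    cov = uniform_filter(ref * g, size=w) - mu_x * mu_y
    sx, sy = np.sqrt(var_x), np.sqrt(var_y)
    lum = (2 * mu_x * mu_y + c1) / (mu_x ** 2 + mu_y ** 2 + c1)
    con = (2 * sx * sy + c2) / (var_x + var_y + c2)
    struct = np.clip((cov + c3) / (sx * sy + c3), 0.0, 1.0)
    lum = np.clip(lum, 0.0, 1.0)
    con = np.clip(con, 0.0, 1.0)
    # restrict to fully valid window centres
    half = w // 2
    core = (slice(half, ref.shape[0] - half), slice(half, ref.shape[1] - half))
    q = lum[core] ** params.alpha * con[core] ** params.beta * struct[core] ** params.gamma
    return float(q.mean())


@dataclass(frozen=True)
class ContrastReport:
    """CCPR/CCFR/E-score at one threshold for one (colour, gray) pair."""

    tau: float
    ccpr: float
    ccfr: float
    e_score: float
    n_pairs: int
    n_omega: int
    n_theta: int
    c2g_ssim: float | None = None


def evaluate_pair(color_image, gray, tau: float, *, n_pairs: int = DEFAULT_N_PAIRS,
                  seed: int | None = None, exhaustive: bool = False,
                  units: str = "lab",
                  ssim_params: C2GSSIMParams | None = None,
                  with_ssim: bool = False) -> ContrastReport:
    """Compute all contrast metrics for one image pair at one threshold."""
    sample = sample_pairs(color_image, n=n_pairs, tau=tau, seed=seed,
                          exhaustive=exhaustive, units=units)
    p = ccpr(sample, gray)
    f = ccfr(sample, gray)
    gv = _gray_values(np.asarray(gray, dtype=np.float64), units)
    gdiff = np.abs(gv[sample.pairs[:, 0]] - gv[sample.pairs[:, 1]])
    return ContrastReport(
        tau=float(tau), ccpr=p, ccfr=f, e_score=e_score(p, f),
        n_pairs=sample.n_pairs,
        n_omega=int(np.count_nonzero(sample.omega)),
        n_theta=int(np.count_nonzero(gdiff > tau)),
        c2g_ssim=c2g_ssim(color_image, gray, ssim_params) if with_ssim else None,
    )


def contrast_report(color_image, gray, taus=DEFAULT_TAUS, **kwargs) -> pd.DataFrame:
    """Tabulate :func:`evaluate_pair` over several thresholds."""
    rows = [evaluate_pair(color_image, gray, tau, **kwargs) for tau in taus]
    return pd.DataFrame([r.__dict__ for r in rows])


def write_report(frame: pd.DataFrame, path, fmt: str = "csv") -> None:
    """Persist a metrics report as CSV or JSON."""
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        frame.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"report format must be 'csv' or 'json', got {fmt!r}")
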