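"""Focus-metric response maps.

Each operator turns a grayscale image into a per-pixel *response map* (or,
for the perceptual-blur metric, a list of edge widths) that is later reduced
by simple aggregations (sum, mean, std, ...).  Conventions, frozen as this
package's contract:

* ``x`` indexes columns, ``y`` rows; origin top-left, row-major.
* Derivative-style maps are computed on the *valid* region only (no padding),
  so borders never inflate gradient energy.  Map shapes therefore shrink by
  the operator footprint; aggregations only see the values.
* Population (not sample) statistics everywhere.

Families
--------
Gradient based:   GRAE (gradient energy), GRAS (squared gradient),
                  TENG (Tenengrad, squared Sobel magnitude).
Laplacian based:  LAPE (energy of Laplacian), LAPSM (sum-modified Laplacian),
                  LAPD (diagonal Laplacian), LAPV (raw Laplacian response,
                  whose VAR aggregation is the classic variance-of-Laplacian),
                  LAPG (Laplacian of Gaussian, 5x5, sigma = 1).
Statistical:      GLVA (7x7 local gray-level variance map), GLVN (global
                  normalised variance), HISE (histogram entropy), HISR
                  (histogram range).
Spectral:         DCT (orthonormal type-II), DFT; magnitudes, DC excluded
                  at aggregation time.
Other principles: BREN (Brenner), CURV (image curvature), SPFQ (spatial
                  frequency), VOLA (Vollath autocorrelation), PRCB
                  (Marziliano perceptual blur edge widths).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import correlate
from skimage.filters import threshold_otsu

__all__ = [
    "SOBEL_X",
    "SOBEL_Y",
    "LAPLACIAN_3",
    "log_kernel",
    "grae_map",
    "gras_map",
    "teng_map",
    "lape_map",
    "lapv_map",
    "lapsm_map",
    "lapd_map",
    "lapg_map",
    "glva_map",
    "glvn_value",
    "histogram_entropy",
    "histogram_range",
    "dct_map",
    "dft_map",
    "bren_map",
    "curv_map",
    "spfq_map",
    "vola_map",
    "marziliano_widths",
    "aggregate",
    "GLVA_WINDOW",
]

SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T
LAPLACIAN_3 = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])

GLVA_WINDOW = 7


def _valid_correlate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Cross-correlation restricted to fully-supported (valid) pixels."""
    kh, kw = kernel.shape
    mh, mw = kh // 2, kw // 2
    out = correlate(np.asarray(img, dtype=np.float64), kernel, mode="constant")
    return out[mh : img.shape[0] - mh, mw : img.shape[1] - mw]


def _check_min_side(img: np.ndarray, side: int, family: str) -> np.ndarray:
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2 or min(a.shape) < side:
        raise ValueError(f"{family} needs a 2-D image with side >= {side}, got {a.shape}")
    return a


# ---------------------------------------------------------------- gradients

def grae_map(img: np.ndarray) -> np.ndarray:
    """Gradient energy: Ix^2 + Iy^2 with forward differences."""
    a = _check_min_side(img, 3, "GRAE")
    dx = a[:-1, 1:] - a[:-1, :-1]
    dy = a[1:, :-1] - a[:-1, :-1]
    return dx * dx + dy * dy


def gras_map(img: np.ndarray) -> np.ndarray:
    """Squared horizontal gradient: (I(x+1, y) - I(x, y))^2."""
    a = _check_min_side(img, 3, "GRAS")
    d = a[:, 1:] - a[:, :-1]
    return d * d


def teng_map(img: np.ndarray) -> np.ndarray:
    """Tenengrad: Sx^2 + Sy^2 with 3x3 Sobel operators."""
    a = _check_min_side(img, 3, "TENG")
    sx = _valid_correlate(a, SOBEL_X)
    sy = _valid_correlate(a, SOBEL_Y)
    return sx * sx + sy * sy


# ---------------------------------------------------------------- laplacians

def lape_map(img: np.ndarray) -> np.ndarray:
    """Energy of Laplacian: (3x3 Laplacian response)^2."""
    a = _check_min_side(img, 3, "LAPE")
    lap = _valid_correlate(a, LAPLACIAN_3)
    return lap * lap


def lapv_map(img: np.ndarray) -> np.ndarray:
    """Raw 3x3 Laplacian response (variance-of-Laplacian under VAR)."""
    a = _check_min_side(img, 3, "LAPV")
    return _valid_correlate(a, LAPLACIAN_3)


def lapsm_map(img: np.ndarray) -> np.ndarray:
    """Sum-modified Laplacian: |2I - left - right| + |2I - up - down|."""
    a = _check_min_side(img, 3, "LAPSM")
    c = a[1:-1, 1:-1]
    horiz = np.abs(2.0 * c - a[1:-1, :-2] - a[1:-1, 2:])
    vert = np.abs(2.0 * c - a[:-2, 1:-1] - a[2:, 1:-1])
    return horiz + vert


def lapd_map(img: np.ndarray) -> np.ndarray:
    """Diagonal Laplacian: LAPSM plus both diagonal terms scaled 1/sqrt(2)."""
    a = _check_min_side(img, 3, "LAPD")
    c = a[1:-1, 1:-1]
    d1 = np.abs(2.0 * c - a[:-2, :-2] - a[2:, 2:]) / np.sqrt(2.0)
    d2 = np.abs(2.0 * c - a[:-2, 2:] - a[2:, :-2]) / np.sqrt(2.0)
    return lapsm_map(img) + d1 + d2


def log_kernel(size: int = 5, sigma: float = 1.0) -> np.ndarray:
    """Sampled Laplacian-of-Gaussian kernel, adjusted to zero sum."""
    ax = np.arange(size, dtype=np.float64) - size // 2
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx * xx + yy * yy
    k = (r2 - 2.0 * sigma**2) / sigma**4 * np.exp(-r2 / (2.0 * sigma**2))
    return k - k.mean()


_LOG_5 = log_kernel(5, 1.0)


def lapg_map(img: np.ndarray) -> np.ndarray:
    """Laplacian-of-Gaussian response (5x5 kernel, sigma = 1)."""
    a = _check_min_side(img, 5, "LAPG")
    return _valid_correlate(a, _LOG_5)


# ---------------------------------------------------------------- statistics

def glva_map(img: np.ndarray, window: int = GLVA_WINDOW) -> np.ndarray:
    """Local gray-level variance over a sliding window (population)."""
    a = _check_min_side(img, window, "GLVA")
    a = a - a.mean()  # variance is shift-invariant; centring avoids cancellation
    box = np.full((window, window), 1.0 / window**2)
    m = _valid_correlate(a, box)
    m2 = _valid_correlate(a * a, box)
    return np.maximum(m2 - m * m, 0.0)


def glvn_value(img: np.ndarray) -> float:
    """Normalised gray-level variance: global variance / global mean.

    NaN sentinel when the mean is zero with non-zero variance (undefined);
    an all-zero image maps to 0.
    """
    a = np.asarray(img, dtype=np.float64)
    mu = a.mean()
    var = a.var()
    if mu == 0.0:
        return 0.0 if var == 0.0 else float("nan")
    return float(var / mu)


def histogram_entropy(channel: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin intensity histogram."""
    a = np.clip(np.asarray(channel, dtype=np.float64), 0.0, 255.0)
    hist, _ = np.histogram(a, bins=256, range=(0.0, 256.0))
    p = hist[hist > 0] / a.size
    return float(-(p * np.log2(p)).sum())


def histogram_range(channel: np.ndarray) -> float:
    """Max minus min intensity."""
    a = np.asarray(channel, dtype=np.float64)
    return float(a.max() - a.min())


# ---------------------------------------------------------------- spectral

def dct_map(img: np.ndarray) -> np.ndarray:
    """Magnitude of the orthonormal type-II 2-D DCT."""
    a = _check_min_side(img, 8, "DCT")
    return np.abs(sp_fft.dctn(a, type=2, norm="ortho"))


def dft_map(img: np.ndarray) -> np.ndarray:
    """Magnitude of the 2-D DFT (DC at index (0, 0))."""
    a = _check_min_side(img, 8, "DFT")
    return np.abs(np.fft.fft2(a))


def spectral_values(mag: np.ndarray) -> np.ndarray:
    """Flatten a spectral magnitude map, excluding the DC coefficient."""
    return np.asarray(mag, dtype=np.float64).ravel()[1:]


# ---------------------------------------------------------------- other

def bren_map(img: np.ndarray) -> np.ndarray:
    """Brenner's measure: (I(x+2, y) - I(x, y))^2."""
    a = _check_min_side(img, 5, "BREN")
    d = a[:, 2:] - a[:, :-2]
    return d * d


# Least-squares fit of c0 + c1*x + c2*y + a*x^2 + b*y^2 over a 3x3 patch;
# rows of pinv(design) give the convolution kernels for each coefficient.
def _curv_kernels() -> tuple[np.ndarray, np.ndarray]:
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 0), (0, 1), (1, -1), (1, 0), (1, 1)]
    design = np.array([[1.0, x, y, x * x, y * y] for (y, x) in offsets])
    pinv = np.linalg.pinv(design)
    return pinv[3].reshape(3, 3), pinv[4].reshape(3, 3)


_CURV_A, _CURV_B = _curv_kernels()


def curv_map(img: np.ndarray) -> np.ndarray:
    """Curvature magnitude |a| + |b| from a 3x3 quadratic surface fit."""
    a = _check_min_side(img, 5, "CURV")
    ca = _valid_correlate(a, _CURV_A)
    cb = _valid_correlate(a, _CURV_B)
    return np.abs(ca) + np.abs(cb)


def spfq_map(img: np.ndarray) -> np.ndarray:
    """Spatial frequency: sqrt(row difference^2 + column difference^2)."""
    a = _check_min_side(img, 5, "SPFQ")
    rd = a[1:, :-1] - a[:-1, :-1]
    cd = a[:-1, 1:] - a[:-1, :-1]
    return np.sqrt(rd * rd + cd * cd)


def vola_map(img: np.ndarray) -> np.ndarray:
    """Vollath autocorrelation: I(x,y) I(x+1,y) - I(x,y) I(x+2,y)."""
    a = _check_min_side(img, 5, "VOLA")
    return a[:, :-2] * a[:, 1:-1] - a[:, :-2] * a[:, 2:]


# ------------------------------------------------------- perceptual blur

def _marziliano_x(a: np.ndarray) -> np.ndarray:
    """Edge widths along x: distance between the luminance extrema that
    bracket each Sobel edge pixel (global Otsu threshold on |Sobel_x|)."""
    gx = correlate(a, SOBEL_X, mode="reflect")
    mag = np.abs(gx)
    if mag.max() <= 0.0 or np.unique(mag).size < 2:
        return np.empty(0, dtype=np.float64)
    thr = threshold_otsu(mag)
    edges = mag > thr
    if not edges.any():
        return np.empty(0, dtype=np.float64)

    h, w = a.shape
    cols = np.arange(w)
    d = np.diff(a, axis=1)  # d[:, j] = a[:, j+1] - a[:, j]

    def run_bounds(rising: bool) -> tuple[np.ndarray, np.ndarray]:
        # Left bound: largest j <= c with j == 0 or step j-1 not strictly in
        # the edge direction; right bound mirrors it.  Equivalent to walking
        # outwards from c while the profile keeps strictly rising/falling.
        cont = d > 0 if rising else d < 0
        blocked_left = np.ones((h, w), dtype=bool)
        blocked_left[:, 1:] = ~cont
        left = np.maximum.accumulate(np.where(blocked_left, cols, 0), axis=1)
        blocked_right = np.ones((h, w), dtype=bool)
        blocked_right[:, :-1] = ~cont
        right = np.minimum.accumulate(
            np.where(blocked_right, cols, w - 1)[:, ::-1], axis=1
        )[:, ::-1]
        return left, right

    lpos, rpos = run_bounds(rising=True)
    lneg, rneg = run_bounds(rising=False)

    rr, cc = np.nonzero(edges)
    sgn = np.sign(gx[rr, cc])
    widths = np.where(
        sgn >= 0, rpos[rr, cc] - lpos[rr, cc], rneg[rr, cc] - lneg[rr, cc]
    ).astype(np.float64)
    return widths


def marziliano_widths(img: np.ndarray, axis: str) -> np.ndarray:
    """Perceptual-blur edge widths along ``axis`` ('x' or 'y').

    Returns a 1-D array (possibly empty) of per-edge-pixel widths in pixels.
    """
    a = _check_min_side(img, 5, "PRCB")
    if axis == "x":
        return _marziliano_x(a)
    if axis == "y":
        return _marziliano_x(np.ascontiguousarray(a.T))
    raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")


# ------------------------------------------------------------- aggregation

_AGGS = {
    "SUM": np.sum,
    "MEAN": np.mean,
    "STD": np.std,   # population
    "VAR": np.var,   # population
    "MIN": np.min,
    "MAX": np.max,
}


def aggregate(values: np.ndarray, aggregation: str, *, allow_empty: bool = False) -> float:
    """Reduce a response map / width list with a named aggregation.

    ``allow_empty`` enables the no-edge fallback used by the perceptual-blur
    metric (SUM and MEAN of an empty width list are defined as 0).
    """
    agg = aggregation.upper()
    if agg not in _AGGS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        if allow_empty and agg in ("SUM", "MEAN"):
            warnings.warn("empty response; falling back to 0", stacklevel=2)
            return 0.0
        raise ValueError("cannot aggregate an empty response map")
    return float(_AGGS[agg](v))
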