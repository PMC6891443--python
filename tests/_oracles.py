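"""Independent brute-force oracles for the focus-metric response maps.

Everything here is written from the mathematical definitions with explicit
Python loops (or naive matrix products for the transforms), deliberately
sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

_SX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SY = _SX.T
_LAP = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def mean_filter(a: np.ndarray, k: int) -> np.ndarray:
    """k x k mean with symmetric (edge-mirrored) padding, by direct loops."""
    r = k // 2
    p = np.pad(np.asarray(a, dtype=np.float64), r, mode="symmetric")
    h, w = a.shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = p[i : i + k, j : j + k].mean()
    return out


def kernel_size(width: int, height: int) -> int:
    m = min(width, height)
    k = m // 75
    return k if k % 2 == 1 else k + 1


def _corr_valid(a: np.ndarray, kern: np.ndarray) -> np.ndarray:
    kh, kw = kern.shape
    h, w = a.shape
    out = np.empty((h - kh + 1, w - kw + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = (a[i : i + kh, j : j + kw] * kern).sum()
    return out


def grae(a):
    h, w = a.shape
    out = np.empty((h - 1, w - 1))
    for i in range(h - 1):
        for j in range(w - 1):
            out[i, j] = (a[i, j + 1] - a[i, j]) ** 2 + (a[i + 1, j] - a[i, j]) ** 2
    return out


def gras(a):
    h, w = a.shape
    out = np.empty((h, w - 1))
    for i in range(h):
        for j in range(w - 1):
            out[i, j] = (a[i, j + 1] - a[i, j]) ** 2
    return out


def teng(a):
    return _corr_valid(a, _SX) ** 2 + _corr_valid(a, _SY) ** 2


def lape(a):
    return _corr_valid(a, _LAP) ** 2


def lapv(a):
    return _corr_valid(a, _LAP)


def lapsm(a):
    h, w = a.shape
    out = np.empty((h - 2, w - 2))
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            out[i - 1, j - 1] = abs(2 * a[i, j] - a[i, j - 1] - a[i, j + 1]) + abs(
                2 * a[i, j] - a[i - 1, j] - a[i + 1, j]
            )
    return out


def lapd(a):
    h, w = a.shape
    out = np.empty((h - 2, w - 2))
    s2 = np.sqrt(2.0)
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            out[i - 1, j - 1] = (
                abs(2 * a[i, j] - a[i, j - 1] - a[i, j + 1])
                + abs(2 * a[i, j] - a[i - 1, j] - a[i + 1, j])
                + abs(2 * a[i, j] - a[i - 1, j - 1] - a[i + 1, j + 1]) / s2
                + abs(2 * a[i, j] - a[i - 1, j + 1] - a[i + 1, j - 1]) / s2
            )
    return out


def lapg(a, sigma=1.0):
    ax = np.arange(5.0) - 2.0
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    k = (r2 - 2 * sigma**2) / sigma**4 * np.exp(-r2 / (2 * sigma**2))
    k = k - k.mean()
    return _corr_valid(a, k)


def glva(a, window=7):
    r = window // 2
    h, w = a.shape
    out = np.empty((h - 2 * r, w - 2 * r))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            win = a[i : i + window, j : j + window]
            out[i, j] = ((win - win.mean()) ** 2).mean()
    return out


def glvn(a):
    mu = a.mean()
    var = ((a - mu) ** 2).mean()
    if mu == 0:
        return 0.0 if var == 0 else float("nan")
    return var / mu


def hist_entropy(a):
    counts = np.zeros(256)
    for v in np.clip(np.asarray(a, dtype=float).ravel(), 0, 255):
        counts[min(int(v), 255)] += 1
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def dct_ortho(a):
    """Orthonormal type-II 2-D DCT via explicit basis matrices."""
    def cmat(n):
        m = np.zeros((n, n))
        for u in range(n):
            alpha = np.sqrt(1.0 / n) if u == 0 else np.sqrt(2.0 / n)
            for x in range(n):
                m[u, x] = alpha * np.cos(np.pi * (2 * x + 1) * u / (2 * n))
        return m

    h, w = a.shape
    return np.abs(cmat(h) @ a @ cmat(w).T)


def dft_mag(a):
    h, w = a.shape
    eu = np.exp(-2j * np.pi * np.outer(np.arange(h), np.arange(h)) / h)
    ev = np.exp(-2j * np.pi * np.outer(np.arange(w), np.arange(w)) / w)
    return np.abs(eu @ a @ ev.T)


def bren(a):
    h, w = a.shape
    out = np.empty((h, w - 2))
    for i in range(h):
        for j in range(w - 2):
            out[i, j] = (a[i, j + 2] - a[i, j]) ** 2
    return out


def curv(a):
    """|a2| + |b2| of the least-squares quadratic fit on each 3x3 patch."""
    h, w = a.shape
    offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    design = np.array([[1.0, dx, dy, dx * dx, dy * dy] for dy, dx in offsets])
    out = np.empty((h - 2, w - 2))
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            z = np.array([a[i + dy, j + dx] for dy, dx in offsets])
            coef, *_ = np.linalg.lstsq(design, z, rcond=None)
            out[i - 1, j - 1] = abs(coef[3]) + abs(coef[4])
    return out


def spfq(a):
    h, w = a.shape
    out = np.empty((h - 1, w - 1))
    for i in range(h - 1):
        for j in range(w - 1):
            rd = a[i + 1, j] - a[i, j]
            cd = a[i, j + 1] - a[i, j]
            out[i, j] = np.sqrt(rd * rd + cd * cd)
    return out


def vola(a):
    h, w = a.shape
    out = np.empty((h, w - 2))
    for i in range(h):
        for j in range(w - 2):
            out[i, j] = a[i, j] * a[i, j + 1] - a[i, j] * a[i, j + 2]
    return out


def _corr_reflect(a, kern):
    r = kern.shape[0] // 2
    p = np.pad(a, r, mode="symmetric")
    h, w = a.shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = (p[i : i + 2 * r + 1, j : j + 2 * r + 1] * kern).sum()
    return out


def marziliano_x(a):
    """Per-edge-pixel widths along x, by walking to the bracketing extrema."""
    a = np.asarray(a, dtype=np.float64)
    gx = _corr_reflect(a, _SX)
    mag = np.abs(gx)
    if mag.max() <= 0 or np.unique(mag).size < 2:
        return np.empty(0)
    thr = threshold_otsu(mag)
    h, w = a.shape
    widths = []
    for i in range(h):
        for j in range(w):
            if mag[i, j] > thr:
                s = 1.0 if gx[i, j] > 0 else -1.0
                c1 = j
                while c1 > 0 and s * (a[i, c1] - a[i, c1 - 1]) > 0:
                    c1 -= 1
                c2 = j
                while c2 < w - 1 and s * (a[i, c2 + 1] - a[i, c2]) > 0:
                    c2 += 1
                widths.append(float(c2 - c1))
    return np.asarray(widths)


def marziliano_y(a):
    return marziliano_x(np.asarray(a, dtype=np.float64).T)


def tree_predict_paths(nodes, features):
    """Predict by enumerating all root-to-leaf paths and their constraints."""
    paths = []

    def walk(idx, constraints):
        node = nodes[idx]
        if "label" in node:
            paths.append((constraints, node["label"]))
        else:
            walk(node["left"], constraints + [(node["feature"], node["threshold"], True)])
            walk(node["right"], constraints + [(node["feature"], node["threshold"], False)])

    walk(0, [])
    matches = [
        label
        for constraints, label in paths
        if all(
            (features[f] <= t) if le else (features[f] > t) for f, t, le in constraints
        )
    ]
    assert len(matches) == 1, "input must satisfy exactly one root-to-leaf path"
    return matches[0]
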