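"""Feature catalogue and blur-reference feature extraction.

Every base metric from the metric bank is computed twice — on the luma crop
``IGray`` and on its mean-filtered blur reference ``IBlur`` — and two
relative variants are derived per base metric:

* ``DIFF  = GRAY - BLUR``   (large for sharp images, near zero for blurred)
* ``RATIO = BLUR / GRAY``   (near 1 for blurred images)

Feature names follow ``{FAMILY}_{AGG}[_{AXIS|CHANNEL}]_{VARIANT}`` with
``VARIANT`` in ``{GRAY, BLUR, DIFF, RATIO}``, e.g. ``GLVA_SUM_DIFF`` or
``PRCB_MEAN_Y_GRAY``.  The catalogue enumerates 77 base metrics, hence 308
features, and is identical for every image.

RATIO conventions for degenerate inputs: when both the GRAY and BLUR values
are 0 the ratio is defined as 1 (a featureless image behaves like a maximally
blurred one); when only the GRAY value is 0 the ratio is a NaN sentinel that
classifiers refuse to consume silently.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import metrics as M
from .image import (
    DEFAULT_CROP_FRACTION,
    GrayImage,
    ImagePair,
    RawImage,
    load_image,
    mean_filter,
    preprocess,
)

__all__ = [
    "VARIANTS",
    "base_metric_names",
    "feature_catalogue",
    "extract_features",
    "extract_features_image",
    "FocusFeatureExtractor",
    "write_feature_table",
    "read_feature_table",
    "write_catalogue_manifest",
    "METADATA_COLUMNS",
]

VARIANTS = ("GRAY", "BLUR", "DIFF", "RATIO")

#: (family, aggregations, axes-or-channels) in catalogue order.
_FAMILY_PLAN: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = [
    ("GRAE", ("SUM", "MEAN", "STD", "MAX"), ()),
    ("GRAS", ("SUM", "MEAN", "STD", "MAX"), ()),
    ("TENG", ("SUM", "MEAN", "STD", "MAX", "VAR"), ()),
    ("LAPE", ("SUM", "MEAN", "STD", "MAX"), ()),
    ("LAPSM", ("SUM", "MEAN", "STD", "MAX"), ()),
    ("LAPD", ("SUM", "MEAN", "STD", "MAX"), ()),
    ("LAPV", ("MEAN", "STD", "MAX", "VAR"), ()),
    ("LAPG", ("SUM", "MEAN", "STD", "MAX"), ()),
    ("GLVA", ("SUM", "MEAN", "STD", "MIN", "MAX"), ()),
    ("GLVN", ("NORM",), ()),
    ("HISE", ("SUM",), ("R", "G", "B", "GRAY")),
    ("HISR", ("RANGE",), ("R", "G", "B", "GRAY")),
    ("DCT", ("SUM", "MEAN", "STD", "MIN", "MAX"), ()),
    ("DFT", ("SUM", "MEAN", "STD", "MIN", "MAX"), ()),
    ("BREN", ("SUM", "MEAN", "STD"), ()),
    ("CURV", ("SUM", "MEAN", "STD", "MIN", "MAX"), ()),
    ("SPFQ", ("SUM", "MEAN", "STD", "MAX"), ()),
    ("VOLA", ("SUM", "MEAN", "STD", "MAX"), ()),
    ("PRCB", ("SUM", "MEAN"), ("X", "Y")),
]

#: Non-feature columns of a feature table.
METADATA_COLUMNS = ("image_id", "label", "subject_id", "role", "split")

_MAP_FUNCS = {
    "GRAE": M.grae_map,
    "GRAS": M.gras_map,
    "TENG": M.teng_map,
    "LAPE": M.lape_map,
    "LAPSM": M.lapsm_map,
    "LAPD": M.lapd_map,
    "LAPV": M.lapv_map,
    "LAPG": M.lapg_map,
    "GLVA": M.glva_map,
    "BREN": M.bren_map,
    "CURV": M.curv_map,
    "SPFQ": M.spfq_map,
    "VOLA": M.vola_map,
}


def base_metric_names() -> list[str]:
    """Ordered names of the 77 base metrics (variant suffix excluded)."""
    names: list[str] = []
    for family, aggs, axes in _FAMILY_PLAN:
        for agg in aggs:
            if axes:
                names.extend(f"{family}_{agg}_{ax}" for ax in axes)
            else:
                names.append(f"{family}_{agg}")
    return names


def feature_catalogue() -> list[str]:
    """The full, deterministic feature-name catalogue (308 names)."""
    return [f"{base}_{var}" for base in base_metric_names() for var in VARIANTS]


def _base_metrics(gray: np.ndarray, color: np.ndarray) -> dict[str, float]:
    """All 77 base metrics for one (gray image, colour image) realisation."""
    out: dict[str, float] = {}
    for family, aggs, axes in _FAMILY_PLAN:
        if family in _MAP_FUNCS:
            resp = _MAP_FUNCS[family](gray)
            for agg in aggs:
                out[f"{family}_{agg}"] = M.aggregate(resp, agg)
        elif family == "GLVN":
            out["GLVN_NORM"] = M.glvn_value(gray)
        elif family in ("HISE", "HISR"):
            func = M.histogram_entropy if family == "HISE" else M.histogram_range
            agg = aggs[0]
            for idx, ch in enumerate(("R", "G", "B")):
                out[f"{family}_{agg}_{ch}"] = func(color[:, :, idx])
            out[f"{family}_{agg}_GRAY"] = func(gray)
        elif family in ("DCT", "DFT"):
            mag = M.dct_map(gray) if family == "DCT" else M.dft_map(gray)
            vals = M.spectral_values(mag)
            for agg in aggs:
                out[f"{family}_{agg}"] = M.aggregate(vals, agg)
        elif family == "PRCB":
            for ax in ("X", "Y"):
                widths = M.marziliano_widths(gray, ax.lower())
                for agg in aggs:
                    out[f"PRCB_{agg}_{ax}"] = M.aggregate(widths, agg, allow_empty=True)
        else:  # pragma: no cover
            raise AssertionError(family)
    return out


def _ratio(g: float, b: float) -> float:
    if math.isnan(g) or math.isnan(b):
        return float("nan")
    if g == 0.0:
        return 1.0 if b == 0.0 else float("nan")
    return b / g


def extract_features(pair: ImagePair, color: RawImage) -> dict[str, float]:
    """Full absolute + relative feature vector for a preprocessed image.

    ``color`` must be the cropped RGB source matching ``pair`` (the
    channel-histogram metrics need it); its blur-reference counterpart is
    built by mean-filtering each channel with the pair's kernel.
    """
    if color.pixels.shape[:2] != pair.gray.pixels.shape:
        raise ValueError("color crop dimensions must match the gray image")
    cpx = color.pixels.astype(np.float64)
    color_blur = np.stack(
        [mean_filter(GrayImage(cpx[:, :, i]), pair.kernel_size).pixels for i in range(3)],
        axis=2,
    )
    g = _base_metrics(pair.gray.pixels, cpx)
    b = _base_metrics(pair.blur.pixels, color_blur)
    out: dict[str, float] = {}
    for base in base_metric_names():
        vg, vb = g[base], b[base]
        out[f"{base}_GRAY"] = vg
        out[f"{base}_BLUR"] = vb
        out[f"{base}_DIFF"] = vg - vb
        out[f"{base}_RATIO"] = _ratio(vg, vb)
    return out


def extract_features_image(
    image: RawImage, crop_fraction: float = DEFAULT_CROP_FRACTION
) -> dict[str, float]:
    """Convenience: preprocess a raw frame and extract the full vector."""
    pair, cropped = preprocess(image, crop_fraction)
    return extract_features(pair, cropped)


class FocusFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform raw RGB frames into the named focus-feature space.

    A stateless scikit-learn transformer: ``transform`` accepts an iterable
    of ``RawImage``, ``H x W x 3`` arrays or file paths and returns a
    :class:`pandas.DataFrame` whose columns are the fixed feature catalogue.

    Parameters
    ----------
    crop_fraction : float, default 0.7
        Side of the central square crop as a fraction of the smaller image
        dimension.
    """

    def __init__(self, crop_fraction: float = DEFAULT_CROP_FRACTION):
        self.crop_fraction = crop_fraction

    def fit(self, X=None, y=None):
        if not (0.0 < self.crop_fraction <= 1.0):
            raise ValueError("crop_fraction must be in (0, 1]")
        self.feature_names_out_ = feature_catalogue()
        return self

    def transform(self, X: Iterable) -> pd.DataFrame:
        self.fit()
        rows = [extract_features_image(self._coerce(item), self.crop_fraction) for item in X]
        return pd.DataFrame(rows, columns=self.feature_names_out_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_catalogue(), dtype=object)

    @staticmethod
    def _coerce(item) -> RawImage:
        if isinstance(item, RawImage):
            return item
        if isinstance(item, (str, Path)):
            return load_image(item)
        return RawImage(np.asarray(item))


# ------------------------------------------------------------------ tables

def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (metadata columns first, then catalogue order)."""
    meta = [c for c in METADATA_COLUMNS if c in df.columns]
    feats = [c for c in feature_catalogue() if c in df.columns]
    df.loc[:, meta + feats].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"feature table {path} is empty")
    return df


def write_catalogue_manifest(path: str | Path) -> None:
    """Plain-text manifest of the feature catalogue, one name per line."""
    Path(path).write_text("\n".join(feature_catalogue()) + "\n")
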