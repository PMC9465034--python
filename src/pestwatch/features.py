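"""The 30-dimensional hand-crafted descriptor and GBDT feature selection.

Each insect ROI yields 30 named features in a fixed order:

* 9 color features — mean, standard deviation and skewness of each RGB
  channel over the body (masked) pixels;
* 16 texture features — contrast, correlation, energy (angular second
  moment) and homogeneity of the gray-level co-occurrence matrix at the four
  angles 0, 45, 90 and 135 degrees (distance 1, 16 gray levels, symmetric,
  body pixels only);
* 5 shape features — area, perimeter, circularity (4*pi*A/P^2), eccentricity
  and extent of the body mask.

Feature selection fits a gradient-boosted tree ensemble (CART weak learners,
log-loss) and keeps every feature whose gain importance reaches the mean
importance — the mean is the salience threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import perimeter_crofton, regionprops

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "glcm_stats",
    "extract",
    "SelectionResult",
    "select_features",
]

GLCM_ANGLES_DEG = (0, 45, 90, 135)
GLCM_STATS = ("contrast", "correlation", "energy", "homogeneity")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"color_{s}_{c}" for s in ("mean", "std", "skew") for c in "RGB"]
    + [f"glcm_{s}_{a}deg" for a in GLCM_ANGLES_DEG for s in GLCM_STATS]
    + ["shape_area", "shape_perimeter", "shape_circularity",
       "shape_eccentricity", "shape_extent"]
)
assert len(FEATURE_NAMES) == 30


@dataclass
class FeatureVector:
    """A named 30-vector of color/texture/shape descriptors for one ROI."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("feature vector length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("features must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------

def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Map a uint8/float image in [0, 255] onto integer levels 0..levels-1."""
    g = np.asarray(gray, dtype=float)
    return np.minimum((g / 256.0 * levels).astype(np.intp), levels - 1)


def glcm_stats(gray_roi: np.ndarray, mask: np.ndarray | None = None,
               levels: int = 16, distance: int = 1) -> np.ndarray:
    """Co-occurrence statistics at 0/45/90/135 degrees.

    Returns 16 values ordered angle-major: for each angle, contrast,
    correlation, energy (= angular second moment, the summed squared
    probability mass) and homogeneity of the symmetric, normalized
    co-occurrence matrix. Pixels outside ``mask`` contribute to no pair:
    they are coded as a sentinel level whose rows/columns are dropped before
    normalization. Angle 0 pairs horizontally, 90 vertically.
    """
    gray_roi = np.asarray(gray_roi)
    if gray_roi.ndim != 2:
        raise ValueError("gray_roi must be 2-D")
    if min(gray_roi.shape) <= distance:
        raise ValueError("ROI smaller than the co-occurrence distance")
    q = quantize(gray_roi, levels)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != q.shape:
            raise ValueError("mask and ROI sizes differ")
        if not mask.any():
            raise ValueError("empty mask")
        q = np.where(mask, q, levels)  # sentinel
    angles = [np.deg2rad(a) for a in GLCM_ANGLES_DEG]
    P = graycomatrix(q.astype(np.uint8), distances=[distance], angles=angles,
                     levels=levels + (mask is not None), symmetric=True,
                     normed=False).astype(float)
    P = P[:levels, :levels]  # drop sentinel pairs
    sums = P.sum(axis=(0, 1), keepdims=True)
    if (sums == 0).any():
        raise ValueError("mask leaves no pixel pairs at some angle")
    P /= sums

    out = np.empty(16)
    for j in range(4):
        Pa = P[:, :, :, j:j + 1]
        out[4 * j + 0] = graycoprops(Pa, "contrast")[0, 0]
        out[4 * j + 1] = graycoprops(Pa, "correlation")[0, 0]
        out[4 * j + 2] = graycoprops(Pa, "ASM")[0, 0]
        out[4 * j + 3] = graycoprops(Pa, "homogeneity")[0, 0]
    return out


# ---------------------------------------------------------------------------
# full descriptor
# ---------------------------------------------------------------------------

def _skew(x: np.ndarray) -> float:
    # skewness of a (near-)constant sample is 0 by convention
    if x.size < 2 or np.ptp(x) == 0:
        return 0.0
    return float(stats.skew(x))


def extract(roi: np.ndarray, mask: np.ndarray,
            levels: int = 16, distance: int = 1) -> FeatureVector:
    """Extract the 30-feature descriptor from an RGB ROI and its body mask."""
    roi = np.asarray(roi)
    mask = np.asarray(mask, dtype=bool)
    if roi.ndim != 3 or roi.shape[2] != 3:
        raise ValueError("roi must be an RGB image")
    if roi.shape[:2] != mask.shape:
        raise ValueError("roi and mask sizes differ")
    if not mask.any():
        raise ValueError("empty mask")

    pix = roi[mask].astype(float)                       # (n, 3)
    color = np.concatenate([
        pix.mean(axis=0),
        pix.std(axis=0),
        [_skew(pix[:, c]) for c in range(3)],
    ])

    gray = roi.astype(float).mean(axis=-1)
    texture = glcm_stats(gray, mask, levels=levels, distance=distance)

    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perim = float(perimeter_crofton(mask, directions=4))
    circularity = 4 * np.pi * area / perim ** 2 if perim > 0 else 0.0
    shape = np.array([area, perim, circularity,
                      float(props.eccentricity), float(props.extent)])

    return FeatureVector(values=np.concatenate([color, texture, shape]))


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Gain importances, the mean-importance threshold and the surviving
    feature indices (original order). Zero-importance features never pass."""

    importances: np.ndarray
    threshold: float
    selected: np.ndarray
    names: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "importances": self.importances.tolist(),
            "threshold": self.threshold,
            "selected": self.selected.tolist(),
            "selected_names": ([self.names[i] for i in self.selected]
                               if self.names else None),
        }


def select_features(X: np.ndarray, y: np.ndarray, *, n_estimators: int = 200,
                    max_depth: int = 3, learning_rate: float = 0.1,
                    seed: int = 0,
                    names: tuple[str, ...] | None = None) -> SelectionResult:
    """Rank features with a gradient-boosted CART ensemble (log-loss) and keep
    those whose importance reaches the mean importance."""
    from sklearn.ensemble import GradientBoostingClassifier

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes disagree")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to rank features")

    gbdt = GradientBoostingClassifier(
        loss="log_loss", n_estimators=n_estimators, max_depth=max_depth,
        learning_rate=learning_rate, random_state=seed)
    gbdt.fit(X, y)
    imp = gbdt.feature_importances_.astype(float)
    threshold = float(imp.mean())
    selected = np.flatnonzero((imp >= threshold) & (imp > 0))
    return SelectionResult(importances=imp, threshold=threshold,
                           selected=selected, names=names)
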