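"""Per-pixel Gaussian-mixture background modeling and capture quality control.

The acquisition device photographs insects falling through a lit channel; the
background is static, so everything a mixture of per-pixel Gaussians cannot
explain is foreground (the insect). The model follows the classic adaptive
mixture formulation: each pixel keeps K weighted Gaussians sorted by
weight/sigma; an observation within ``match_threshold`` standard deviations of
a component updates that component, otherwise the least probable component is
replaced; the most probable components whose cumulative weight first exceeds
the background fraction T form the background model.

On top of the raw masks sit the quality-control rules used to assemble
datasets: each capture is placed in exactly one of six categories (clean,
removable noise, non-removable noise, out of view, background not removed,
blurred) and a seeded selector picks the clean captures kept per sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import sobel

__all__ = [
    "MixtureConfig",
    "QCConfig",
    "QCCategory",
    "PixelMixture",
    "update_pixel",
    "subtract",
    "SubtractionResult",
    "classify_capture",
    "select_clean",
    "SelectionOutcome",
]


# ---------------------------------------------------------------------------
# mixture model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureConfig:
    """Gaussian-mixture background model parameters.

    Defaults follow the standard adaptive-mixture conventions: K=5 components,
    learning rate 0.01, a 2.5-sigma match gate and background fraction 0.7.
    """

    n_components: int = 5
    learning_rate: float = 0.01
    match_threshold: float = 2.5
    background_fraction: float = 0.7
    initial_variance: float = 225.0  # sigma 15 for a fresh component
    variance_floor: float = 4.0
    new_component_weight: float = 0.05
    burn_in: int = 30
    morphology: bool = True  # 3x3 opening then closing on each mask

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("need at least one component")
        if not 0 < self.background_fraction <= 1:
            raise ValueError("background_fraction in (0, 1]")
        if self.variance_floor <= 0:
            raise ValueError("variance floor must be positive")


@dataclass
class PixelMixture:
    """Mixture state over an array of pixels.

    ``weights``, ``means``, ``variances`` all have shape ``pixel_shape + (K,)``
    and are kept sorted along the last axis by decreasing weight/sigma.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    config: MixtureConfig

    @classmethod
    def initialize(cls, first_frame: np.ndarray,
                   config: MixtureConfig = MixtureConfig()) -> "PixelMixture":
        """Seed component 1 with the first observed frame, weight 1."""
        shape = np.shape(first_frame) + (config.n_components,)
        w = np.zeros(shape)
        mu = np.zeros(shape)
        var = np.full(shape, config.initial_variance)
        w[..., 0] = 1.0
        mu[..., 0] = first_frame
        return cls(weights=w, means=mu, variances=var, config=config)

    def background_count(self) -> np.ndarray:
        """Per-pixel number B of top components forming the background model:
        the smallest prefix whose cumulative weight exceeds T."""
        csum = np.cumsum(self.weights, axis=-1)
        return 1 + np.sum(csum < self.config.background_fraction, axis=-1)


def _observe(mix: PixelMixture, frame: np.ndarray,
             learn: bool = True) -> np.ndarray:
    """Classify ``frame`` against the current model, then (optionally) update.

    Returns the boolean foreground mask: pixels whose observation matched no
    component inside the background prefix.
    """
    cfg = mix.config
    frame = np.asarray(frame, dtype=float)
    d = frame[..., None] - mix.means
    matched = d * d <= (cfg.match_threshold ** 2) * mix.variances
    any_match = matched.any(axis=-1)
    # first matching component in sorted (most-probable-first) order
    first = np.argmax(matched, axis=-1)

    n_bg = mix.background_count()
    foreground = ~(any_match & (first < n_bg))

    if learn and cfg.learning_rate > 0:
        a = cfg.learning_rate
        k = np.arange(cfg.n_components)
        onehot = first[..., None] == k  # matched component indicator
        upd = onehot & any_match[..., None]

        # matched pixels: weights decay toward the match indicator,
        # matched component's mean/variance move toward the observation
        w = np.where(any_match[..., None],
                     mix.weights + a * (onehot.astype(float) - mix.weights),
                     mix.weights)
        mu = np.where(upd, mix.means + a * d, mix.means)
        var = np.where(upd, mix.variances + a * (d * d - mix.variances),
                       mix.variances)

        # unmatched pixels: replace the least probable (last) component
        last = np.zeros_like(onehot)
        last[..., -1] = True
        miss = ~any_match[..., None]
        w = np.where(miss & last, cfg.new_component_weight, w)
        mu = np.where(miss & last, frame[..., None], mu)
        var = np.where(miss & last, cfg.initial_variance, var)

        w /= w.sum(axis=-1, keepdims=True)
        var = np.maximum(var, cfg.variance_floor)

        # keep components sorted by w / sigma, most probable first
        key = w / np.sqrt(var)
        order = np.argsort(-key, axis=-1, kind="stable")
        mix.weights = np.take_along_axis(w, order, axis=-1)
        mix.means = np.take_along_axis(mu, order, axis=-1)
        mix.variances = np.take_along_axis(var, order, axis=-1)

    return foreground


def update_pixel(mix: PixelMixture, value) -> PixelMixture:
    """Feed one observation (scalar per pixel) through the mixture update."""
    _observe(mix, value, learn=True)
    return mix


# ---------------------------------------------------------------------------
# sequence subtraction
# ---------------------------------------------------------------------------

@dataclass
class SubtractionResult:
    """Masks plus the background-removed frames (both kinds are saved by the
    device). Mask entries during burn-in are all-background."""

    masks: np.ndarray      # bool (N, H, W)
    removed: np.ndarray    # uint8 (N, H, W), frame where mask else 0
    burn_in: int


def subtract(frames: np.ndarray,
             config: MixtureConfig = MixtureConfig()) -> SubtractionResult:
    """Run the mixture model over a frame stack and emit foreground masks."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) == 0:
        raise ValueError("frames must be a nonempty (N, H, W) stack")
    mix = PixelMixture.initialize(frames[0].astype(float), config)
    masks = np.zeros(frames.shape, dtype=bool)
    selem = np.ones((3, 3), dtype=bool)
    for t, frame in enumerate(frames):
        fg = _observe(mix, frame, learn=True)
        if t < config.burn_in:
            continue
        if config.morphology:
            fg = ndimage.binary_closing(
                ndimage.binary_opening(fg, structure=selem), structure=selem)
        masks[t] = fg
    removed = np.where(masks, frames, 0).astype(np.uint8)
    return SubtractionResult(masks=masks, removed=removed,
                             burn_in=config.burn_in)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

class QCCategory(enum.Enum):
    """The six capture categories used when screening acquired images."""

    CLEAN = "clean"
    REMOVABLE_NOISE = "removable_noise"
    NONREMOVABLE_NOISE = "nonremovable_noise"
    OUT_OF_VIEW = "out_of_view"
    BACKGROUND_NOT_REMOVED = "background_not_removed"
    BLURRED = "blurred"


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the rule-based capture categorization.

    ``min_blob_px``: blobs below this size count as removable specks.
    ``max_residual_fraction``: image fraction of non-principal foreground
    tolerated before the background is declared not removed.
    ``min_gradient_energy``: mean Sobel gradient magnitude over the principal
    blob below which the target is declared blurred (intensity units / px).
    """

    min_blob_px: int = 20
    max_residual_fraction: float = 0.01
    min_gradient_energy: float = 2.0


def classify_capture(image: np.ndarray, mask: np.ndarray,
                     config: QCConfig = QCConfig()) -> QCCategory:
    """Assign exactly one QC category to a capture.

    Rule order: no foreground -> out of view; principal blob cut by the frame
    border -> out of view; low gradient energy on the principal blob ->
    blurred; a large secondary blob -> non-removable noise; diffuse residual
    foreground above the tolerated fraction -> background not removed; small
    secondary specks only -> removable noise; otherwise clean.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask sizes differ")
    if not mask.any():
        return QCCategory.OUT_OF_VIEW

    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    principal = int(np.argmax(sizes)) + 1
    blob = labels == principal

    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (blob & border).any():
        return QCCategory.OUT_OF_VIEW

    gray = image if image.ndim == 2 else image.mean(axis=-1)
    grad = sobel(gray.astype(float))
    # dilate so the blob's boundary gradient is included
    region = ndimage.binary_dilation(blob, iterations=1)
    if grad[region].mean() < config.min_gradient_energy:
        return QCCategory.BLURRED

    secondary = np.delete(sizes, principal - 1)
    if secondary.size and secondary.max() >= config.min_blob_px:
        return QCCategory.NONREMOVABLE_NOISE
    residual = int(mask.sum() - sizes[principal - 1])
    if residual > config.max_residual_fraction * mask.size:
        return QCCategory.BACKGROUND_NOT_REMOVED
    if residual > 0:
        return QCCategory.REMOVABLE_NOISE
    return QCCategory.CLEAN


@dataclass
class SelectionOutcome:
    """Indices of kept captures; ``shortfall`` > 0 when fewer clean captures
    existed than requested (all clean ones are then returned)."""

    indices: np.ndarray
    shortfall: int


def select_clean(images: np.ndarray, masks: np.ndarray, keep_n: int,
                 seed: int = 0, config: QCConfig = QCConfig(),
                 categories=None) -> SelectionOutcome:
    """Seeded selection of ``keep_n`` clean captures from a sample's stack.

    ``categories`` may pass precomputed QC categories to avoid re-screening.
    """
    if keep_n < 0:
        raise ValueError("keep_n must be nonnegative")
    if categories is None:
        categories = [classify_capture(im, m, config)
                      for im, m in zip(images, masks)]
    clean = np.flatnonzero(np.array([c is QCCategory.CLEAN
                                     for c in categories]))
    if keep_n >= clean.size:
        return SelectionOutcome(indices=clean,
                                shortfall=keep_n - clean.size)
    rng = np.random.default_rng(seed)
    picked = rng.choice(clean, size=keep_n, replace=False)
    return SelectionOutcome(indices=np.sort(picked), shortfall=0)
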