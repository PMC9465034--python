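"""ROI extraction, augmentation, stratified splitting, and the dataset
construction rules used when updating models with new field data.

The three update-oriented constructions are:

* ``build_dataset2_1`` — a field dataset whose oversized fourth
  (non-target/noise) category is randomly downsampled to a fixed quota so the
  class balance becomes workable;
* ``filling_mix`` — pad the three target classes of the field training set
  with lab-dataset images until each matches the fourth category's size;
* ``symmetric_mix`` — double every class by mixing equal quantities from the
  lab and field training sets (the fourth class takes its second half from a
  pool outside the downsampled field set).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import AffineTransform, warp

__all__ = [
    "LabeledImageSet",
    "crop_roi",
    "AugmentParams",
    "sample_augment",
    "apply_augment",
    "augment",
    "split",
    "build_dataset2_1",
    "filling_mix",
    "symmetric_mix",
    "ROI_SIZE",
]

ROI_SIZE = 140


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class LabeledImageSet:
    """Images with class labels, stable identities and provenance.

    ``ids`` are unique per underlying image and survive subsetting and
    mixing, so duplicate-identity checks across mixed sets are exact.
    """

    images: np.ndarray                 # (N, H, W, 3) uint8
    labels: np.ndarray                 # (N,) int64
    class_names: list[str]
    ids: np.ndarray                    # (N,) str
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels) or len(self.ids) != len(self.labels):
            raise ValueError("images, labels and ids must align")
        if len(self.labels) and (self.labels.min() < 0
                                 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels must index class_names")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices, provenance: str | None = None) -> "LabeledImageSet":
        idx = np.asarray(indices)
        return LabeledImageSet(images=self.images[idx], labels=self.labels[idx],
                               class_names=list(self.class_names),
                               ids=self.ids[idx],
                               provenance=provenance or self.provenance)

    @staticmethod
    def concatenate(parts: list["LabeledImageSet"],
                    provenance: str) -> "LabeledImageSet":
        names = parts[0].class_names
        for p in parts:
            if p.class_names != names:
                raise ValueError("class name sets differ")
        return LabeledImageSet(
            images=np.concatenate([p.images for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            class_names=list(names),
            ids=np.concatenate([p.ids for p in parts]),
            provenance=provenance)


# ---------------------------------------------------------------------------
# ROI cropping
# ---------------------------------------------------------------------------

def crop_roi(image: np.ndarray, mask: np.ndarray,
             size: int = ROI_SIZE) -> np.ndarray:
    """Crop a ``size`` x ``size`` window centered on the mask centroid.

    When the window overruns the frame the image border is expanded by edge
    replication first, so the output is always exactly ``size`` square.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask sizes differ")
    if not mask.any():
        raise ValueError("empty mask: no insect body to center on")
    rr, cc = np.nonzero(mask)
    cy, cx = int(round(rr.mean())), int(round(cc.mean()))
    half = size // 2
    r0, c0 = cy - half, cx - half
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bottom = max(0, r0 + size - image.shape[0])
    pad_right = max(0, c0 + size - image.shape[1])
    pads = ((pad_top, pad_bottom), (pad_left, pad_right))
    if image.ndim == 3:
        pads = pads + ((0, 0),)
    padded = np.pad(image, pads, mode="edge")
    r0 += pad_top
    c0 += pad_left
    return padded[r0:r0 + size, c0:c0 + size]


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """One draw of the online augmentation: quarter-turn count, shear factor
    (0–0.5), and horizontal/vertical flips. All off -> identity."""

    k_rot90: int = 0
    shear: float = 0.0
    flip_h: bool = False
    flip_v: bool = False


def sample_augment(rng: np.random.Generator,
                   max_shear: float = 0.5) -> AugmentParams:
    return AugmentParams(k_rot90=int(rng.integers(0, 4)),
                         shear=float(rng.uniform(0.0, max_shear)),
                         flip_h=bool(rng.integers(0, 2)),
                         flip_v=bool(rng.integers(0, 2)))


def apply_augment(image: np.ndarray, params: AugmentParams) -> np.ndarray:
    """Apply an augmentation draw; output has the input's size and dtype."""
    img = np.asarray(image)
    if img.shape[0] != img.shape[1]:
        raise ValueError("augmentation expects square images")
    out = np.rot90(img, k=params.k_rot90)
    if params.flip_h:
        out = out[:, ::-1]
    if params.flip_v:
        out = out[::-1]
    if params.shear:
        c = out.shape[0] / 2.0
        # centered horizontal shear, edge-replicated fill
        m = np.array([[1.0, params.shear, -params.shear * c],
                      [0.0, 1.0, 0.0],
                      [0.0, 0.0, 1.0]])
        tf = AffineTransform(matrix=m)
        warped = warp(out.astype(float), tf.inverse, mode="edge", order=1,
                      preserve_range=True)
        out = warped.round().astype(img.dtype) if np.issubdtype(
            img.dtype, np.integer) else warped.astype(img.dtype)
    return np.ascontiguousarray(out)


def augment(image: np.ndarray, seed: int,
            max_shear: float = 0.5) -> np.ndarray:
    """Seeded single-image augmentation (rotation, shear, flips)."""
    rng = np.random.default_rng(seed)
    return apply_augment(image, sample_augment(rng, max_shear))


# ---------------------------------------------------------------------------
# stratified splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, shares: np.ndarray) -> np.ndarray:
    """Apportion n items to shares by largest remainder; ties favor the
    earliest bucket (train before val before test)."""
    exact = n * shares / shares.sum()
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = n - base.sum()
    # stable sort on -remainder keeps bucket order on ties
    order = np.argsort(-rem, kind="stable")
    base[order[:short]] += 1
    return base


def split(dataset: LabeledImageSet, ratios=(7, 1.5, 1.5), seed: int = 0
          ) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Stratified train/val/test split at the given ratios.

    Per class, counts follow the largest-remainder rule (ties to train), so
    e.g. 9000 images at 7:1.5:1.5 give exactly 6300/1350/1350.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (3,) or (ratios < 0).any() or ratios.sum() == 0:
        raise ValueError("need three nonnegative ratios, not all zero")
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for k in range(dataset.n_classes):
        idx = dataset.class_indices(k)
        if idx.size < 3:
            raise ValueError(
                f"class {dataset.class_names[k]} has {idx.size} images; "
                "need at least 3 to split")
        idx = rng.permutation(idx)
        counts = _largest_remainder(idx.size, ratios)
        parts[0].append(idx[:counts[0]])
        parts[1].append(idx[counts[0]:counts[0] + counts[1]])
        parts[2].append(idx[counts[0] + counts[1]:])
    out = []
    for name, chunks in zip(("train", "val", "test"), parts):
        sel = np.sort(np.concatenate(chunks)).astype(int)
        out.append(dataset.subset(sel, provenance=f"{dataset.provenance}/{name}"))
    return tuple(out)


# ---------------------------------------------------------------------------
# update-strategy dataset constructions
# ---------------------------------------------------------------------------

def build_dataset2_1(dataset2: LabeledImageSet, n_fourth: int = 70,
                     seed: int = 0) -> LabeledImageSet:
    """Downsample the fourth (non-target) class to ``n_fourth`` images,
    keeping the three target classes whole."""
    if dataset2.n_classes != 4:
        raise ValueError("expected a 4-class field dataset")
    fourth = dataset2.class_indices(3)
    if fourth.size < n_fourth:
        raise ValueError(
            f"fourth class has {fourth.size} images, fewer than {n_fourth}")
    rng = np.random.default_rng(seed)
    keep4 = rng.choice(fourth, size=n_fourth, replace=False)
    keep = np.sort(np.concatenate([
        np.flatnonzero(dataset2.labels < 3), keep4]))
    return dataset2.subset(keep, provenance="dataset2_1")


def filling_mix(ds1_train: LabeledImageSet, ds2_train: LabeledImageSet,
                seed: int = 0) -> LabeledImageSet:
    """Pad the field training set's target classes with lab images until each
    matches the fourth class's size; the fourth class is left as is."""
    if ds2_train.n_classes != 4:
        raise ValueError("field training set must have 4 classes")
    target = int(ds2_train.class_counts()[3])
    if target == 0:
        raise ValueError("fourth class is empty; nothing to fill toward")
    rng = np.random.default_rng(seed)
    parts = [ds2_train]
    for k in range(3):
        need = target - int(ds2_train.class_counts()[k])
        if need < 0:
            raise ValueError(
                f"class {k} already exceeds the fourth class's size")
        if need == 0:
            continue
        pool = ds1_train.class_indices(k)
        if pool.size < need:
            raise ValueError(
                f"lab dataset has {pool.size} class-{k} images; {need} needed")
        take = rng.choice(pool, size=need, replace=False)
        fill = ds1_train.subset(np.sort(take))
        fill = LabeledImageSet(images=fill.images,
                               labels=np.full(need, k, dtype=np.int64),
                               class_names=list(ds2_train.class_names),
                               ids=fill.ids, provenance="fill")
        parts.append(fill)
    mixed = LabeledImageSet.concatenate(parts, provenance="filled_mix")
    _check_no_duplicates(mixed)
    return mixed


def symmetric_mix(ds1_train: LabeledImageSet, ds2_1_train: LabeledImageSet,
                  extra_fourth_pool: LabeledImageSet,
                  seed: int = 0) -> LabeledImageSet:
    """Double every class: target classes take equal quantities from the lab
    and field training sets; the fourth class mixes the field images with an
    equal quantity from a pool outside the downsampled field set."""
    if ds2_1_train.n_classes != 4:
        raise ValueError("field training set must have 4 classes")
    counts = ds2_1_train.class_counts()
    if (counts[:3] == 0).any() or counts[3] == 0:
        raise ValueError("every field class must be nonempty to mix")
    if np.intersect1d(extra_fourth_pool.ids,
                      ds2_1_train.ids).size:
        raise ValueError("extra fourth-class pool overlaps the field set")
    rng = np.random.default_rng(seed)
    parts = [ds2_1_train]
    for k in range(3):
        n_c = int(counts[k])
        pool = ds1_train.class_indices(k)
        if pool.size < n_c:
            raise ValueError(
                f"lab dataset has {pool.size} class-{k} images; {n_c} needed")
        take = rng.choice(pool, size=n_c, replace=False)
        part = ds1_train.subset(np.sort(take))
        parts.append(LabeledImageSet(
            images=part.images, labels=np.full(n_c, k, dtype=np.int64),
            class_names=list(ds2_1_train.class_names), ids=part.ids,
            provenance="lab_half"))
    n_4 = int(counts[3])
    pool4 = np.arange(len(extra_fourth_pool))
    if pool4.size < n_4:
        raise ValueError(
            f"external fourth-class pool has {pool4.size} images; {n_4} needed")
    take4 = rng.choice(pool4, size=n_4, replace=False)
    part4 = extra_fourth_pool.subset(np.sort(take4))
    parts.append(LabeledImageSet(
        images=part4.images, labels=np.full(n_4, 3, dtype=np.int64),
        class_names=list(ds2_1_train.class_names), ids=part4.ids,
        provenance="extra_fourth"))
    mixed = LabeledImageSet.concatenate(parts, provenance="symmetric_mix")
    _check_no_duplicates(mixed)
    return mixed


def _check_no_duplicates(ds: LabeledImageSet) -> None:
    if len(np.unique(ds.ids)) != len(ds.ids):
        raise ValueError("mixed set contains duplicate image identities")
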