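"""Synthetic inputs emulating a light-trap insect image acquisition device.

Three generators cover everything the downstream pipeline consumes, each with
exact ground truth:

* :func:`render_sequence` — grayscale frame sequences of a small dark object
  falling across a static noisy background (what the device's camera sees
  while an insect drops through the acquisition channel), with per-frame
  ground-truth foreground masks.
* :func:`make_insect_dataset` — small labeled RGB image datasets in the
  CIFAR-10 style, with 3–4 classes whose color, texture, elongation and size
  statistics differ (stand-ins for cotton bollworm moth, borer moth and
  *Spodoptera litura*, plus an optional non-target/noise class).
* :func:`make_count_series` — daily moth-count time series with controllable
  geometric growth and optional Poisson dispersion, feeding the outbreak
  warning engine.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneSpec",
    "ClassSpec",
    "CountSeriesSpec",
    "DEFAULT_CLASSES",
    "parabolic_trajectory",
    "render_sequence",
    "make_insect_dataset",
    "make_count_series",
    "write_sequence",
    "write_count_series",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a falling-insect frame sequence.

    Parameters
    ----------
    frame_size : (height, width) in pixels.
    background_mean : mean background intensity (0–255); the device channel is
        a bright, LED-lit surface, so the default is light gray.
    background_noise_sigma : per-pixel Gaussian sensor-noise std, intensity units.
    object_axes : (semi-major, semi-minor) of the elliptical insect body, px.
    object_orientation : body orientation, radians.
    object_intensity : body intensity (dark against the lit background).
    trajectory : per-frame (row, col) centroid positions; its length fixes the
        maximum number of renderable frames.
    blur_sigma : Gaussian optical blur applied after compositing, px.
    clutter_rate : probability per frame of a spurious transient small blob
        (debris crossing the channel), exercising the "removable noise" QC path.
    """

    frame_size: tuple[int, int] = (200, 200)
    background_mean: float = 180.0
    background_noise_sigma: float = 8.0
    object_axes: tuple[float, float] = (14.0, 7.0)
    object_orientation: float = 0.4
    object_intensity: float = 40.0
    trajectory: tuple[tuple[float, float], ...] = ()
    blur_sigma: float = 0.8
    clutter_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.object_axes) <= 0:
            raise ValueError("object axes must be positive")
        for v in (self.background_mean, self.object_intensity):
            if not 0 <= v <= 255:
                raise ValueError("intensities must lie in [0, 255]")
        if self.background_noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("sigmas must be nonnegative")
        if not 0 <= self.clutter_rate <= 1:
            raise ValueError("clutter_rate is a probability")


@dataclass(frozen=True)
class ClassSpec:
    """Appearance statistics of one synthetic insect class.

    ``texture_period`` is the stripe period on the body in pixels (0 disables
    striping); ``shape_elongation`` is the body axis ratio (>= 1);
    ``size_px`` is the mean body area in pixels.
    """

    class_name: str
    body_color_mean: tuple[float, float, float]
    body_color_sigma: tuple[float, float, float] = (12.0, 12.0, 12.0)
    texture_period: float = 0.0
    shape_elongation: float = 2.0
    size_px: float = 260.0
    distorted: bool = False  # non-target/noise class: clutter + warped blobs

    def __post_init__(self) -> None:
        if self.shape_elongation < 1:
            raise ValueError("shape_elongation must be >= 1")
        if self.size_px <= 0:
            raise ValueError("size_px must be positive")


#: Default class set: three separable target species plus a non-target/noise
#: class. Colors are far apart (tens of intensity units vs sigma ~12) so a
#: nearest-centroid rule on mean RGB alone solves the 3-class task; texture
#: period and elongation add non-color structure for the texture features.
DEFAULT_CLASSES: tuple[ClassSpec, ...] = (
    ClassSpec("bollworm_moth", (190.0, 160.0, 110.0), texture_period=6.0,
              shape_elongation=2.2, size_px=300.0),
    ClassSpec("borer_moth", (120.0, 90.0, 60.0), texture_period=3.0,
              shape_elongation=3.0, size_px=220.0),
    ClassSpec("spodoptera_litura", (90.0, 110.0, 150.0), texture_period=0.0,
              shape_elongation=1.6, size_px=360.0),
    ClassSpec("non_target", (140.0, 140.0, 140.0), body_color_sigma=(40.0, 40.0, 40.0),
              texture_period=0.0, shape_elongation=1.2, size_px=150.0,
              distorted=True),
)


@dataclass(frozen=True)
class CountSeriesSpec:
    """Daily moth-count series: ``count(d) = round(base * growth**d)`` plus
    optional Poisson dispersion around that deterministic trajectory."""

    n_days: int = 14
    base_count: float = 10.0
    daily_growth: float = 1.0
    noise: float = 0.0  # 0 → exact; > 0 → Poisson around the trajectory
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.base_count < 0:
            raise ValueError("base_count must be nonnegative")
        if self.daily_growth < 0:
            raise ValueError("daily_growth must be nonnegative")


# ---------------------------------------------------------------------------
# frame sequences
# ---------------------------------------------------------------------------

def parabolic_trajectory(frame_size: tuple[int, int], n_frames: int,
                         entry_col: float | None = None,
                         horizontal_speed: float = 0.6,
                         gravity: float = 0.12) -> tuple[tuple[float, float], ...]:
    """Centroid path of a body entering at the top and falling in a parabola.

    Vertical position accelerates with ``gravity`` px/frame² from just above
    the frame; horizontal drift is constant. The body enters, accelerates
    through the view in a few dozen frames and exits below; any remaining
    frames observe background only, as between captures on the device.
    """
    h, w = frame_size
    if entry_col is None:
        entry_col = 0.3 * w
    t = np.arange(n_frames, dtype=float)
    rows = -12.0 + 0.5 * gravity * t ** 2
    cols = entry_col + horizontal_speed * t
    cols = np.clip(cols, -5, w + 5)
    return tuple((float(r), float(c)) for r, c in zip(rows, cols))


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], theta: float) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dc * ct + dr * st
    v = -dc * st + dr * ct
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_sequence(spec: SceneSpec, n_frames: int, seed: int,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Render a grayscale frame stack and its ground-truth foreground masks.

    Returns
    -------
    frames : uint8 array (n_frames, H, W)
    truth_masks : bool array (n_frames, H, W), marking exactly the object
        pixels *before* optical blur. Clutter blobs are not ground truth.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if len(spec.trajectory) and len(spec.trajectory) < n_frames:
        raise ValueError(
            f"trajectory has {len(spec.trajectory)} positions but "
            f"{n_frames} frames were requested")
    rng = np.random.default_rng(seed)
    h, w = spec.frame_size
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    masks = np.zeros((n_frames, h, w), dtype=bool)

    # transient clutter persists 1–2 frames
    clutter: list[tuple[int, np.ndarray]] = []  # (remaining frames, mask)
    for t in range(n_frames):
        frame = spec.background_mean * np.ones((h, w), dtype=float)
        if spec.background_noise_sigma > 0:
            frame += rng.normal(0.0, spec.background_noise_sigma, size=(h, w))

        if len(spec.trajectory):
            m = _ellipse_mask((h, w), spec.trajectory[t], spec.object_axes,
                              spec.object_orientation)
            masks[t] = m
            frame[m] = spec.object_intensity

        clutter = [(n - 1, cm) for n, cm in clutter if n > 0]
        if spec.clutter_rate > 0 and rng.random() < spec.clutter_rate:
            r = rng.uniform(1.0, 1.8)  # area ~ pi r^2 in 3–10 px
            center = (rng.uniform(0, h), rng.uniform(0, w))
            cm = _ellipse_mask((h, w), center, (r, r), 0.0)
            clutter.append((int(rng.integers(1, 3)), cm))
        for _, cm in clutter:
            frame[cm] = spec.object_intensity

        if spec.blur_sigma > 0:
            frame = gaussian_filter(frame, spec.blur_sigma)
        frames[t] = np.clip(frame, 0, 255).round().astype(np.uint8)
    return frames, masks


# ---------------------------------------------------------------------------
# labeled image datasets
# ---------------------------------------------------------------------------

def _render_insect_image(cls: ClassSpec, image_size: int,
                         rng: np.random.Generator) -> np.ndarray:
    """One RGB image: a textured elliptical body on a dark vignetted background."""
    s = image_size
    img = np.empty((s, s, 3), dtype=float)
    bg = rng.uniform(20, 45)
    img[...] = bg + rng.normal(0, 6, size=(s, s, 3))

    area = max(cls.size_px * rng.uniform(0.8, 1.25), 20.0)
    elong = cls.shape_elongation * rng.uniform(0.85, 1.15)
    b = np.sqrt(area / (np.pi * elong))
    a = elong * b
    a = min(a, 0.45 * s)
    theta = rng.uniform(0, np.pi)
    center = (s / 2 + rng.uniform(-s * 0.08, s * 0.08),
              s / 2 + rng.uniform(-s * 0.08, s * 0.08))
    body = _ellipse_mask((s, s), center, (a, b), theta)

    color = np.asarray(cls.body_color_mean) + rng.normal(
        0, np.asarray(cls.body_color_sigma))
    rr, cc = np.nonzero(body)
    pix = color[None, :] + rng.normal(0, 8, size=(rr.size, 3))
    if cls.texture_period > 0:
        # stripes along the major axis
        u = (cc - center[1]) * np.cos(theta) + (rr - center[0]) * np.sin(theta)
        stripes = 25.0 * np.sin(2 * np.pi * u / cls.texture_period)
        pix += stripes[:, None]
    img[rr, cc] = pix

    if cls.distorted:
        # non-target/noise class: extra clutter blobs and intensity streaks
        for _ in range(rng.integers(2, 6)):
            r = rng.uniform(1.5, 4.0)
            cm = _ellipse_mask((s, s), (rng.uniform(0, s), rng.uniform(0, s)),
                               (r, r), 0.0)
            img[cm] = rng.uniform(0, 255, size=3)
        row = int(rng.integers(0, s))
        img[row:row + 2] += rng.uniform(-60, 60)

    img = gaussian_filter(img, (0.6, 0.6, 0))
    return np.clip(img, 0, 255).round().astype(np.uint8)


def make_insect_dataset(classes=DEFAULT_CLASSES[:3], n_per_class=300,
                        image_size: int = 32, seed: int = 0):
    """Build a :class:`~pestwatch.preprocess.LabeledImageSet` of rendered insects.

    ``classes`` may include a fourth, ``distorted`` spec to emulate the
    non-target/noise category collected in the field. ``n_per_class`` is an
    int or a per-class sequence (field data is usually unbalanced, with the
    non-target class far larger than the targets).
    """
    from .preprocess import LabeledImageSet  # local import avoids a cycle

    classes = tuple(classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    names = [c.class_name for c in classes]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate class names: {names}")
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    counts = ([int(n_per_class)] * len(classes)
              if np.isscalar(n_per_class) else list(map(int, n_per_class)))
    if len(counts) != len(classes):
        raise ValueError("one count per class required")

    rng = np.random.default_rng(seed)
    total = sum(counts)
    images = np.empty((total, image_size, image_size, 3), dtype=np.uint8)
    labels = np.empty(total, dtype=np.int64)
    i = 0
    for k, (cls, n) in enumerate(zip(classes, counts)):
        for _ in range(n):
            images[i] = _render_insect_image(cls, image_size, rng)
            labels[i] = k
            i += 1
    ids = np.array([f"synth-{seed}-{j}" for j in range(i)])
    return LabeledImageSet(images=images, labels=labels, class_names=names,
                           ids=ids, provenance="synthetic")


# ---------------------------------------------------------------------------
# count series
# ---------------------------------------------------------------------------

def make_count_series(spec: CountSeriesSpec) -> np.ndarray:
    """Daily insect counts, length ``spec.n_days``, nonnegative integers."""
    d = np.arange(spec.n_days, dtype=float)
    mean = spec.base_count * spec.daily_growth ** d
    if spec.noise == 0:
        return np.round(mean).astype(np.int64)
    rng = np.random.default_rng(spec.seed)
    return rng.poisson(mean).astype(np.int64)


# ---------------------------------------------------------------------------
# disk output (device-format emulation)
# ---------------------------------------------------------------------------

def write_sequence(outdir: str | Path, frames: np.ndarray, masks: np.ndarray,
                   metadata: dict | None = None) -> Path:
    """Write PNG frames + PNG truth masks + a JSON manifest, mirroring the
    capture device's on-disk layout ({name, location, time} metadata)."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)
    (outdir / "truth_masks").mkdir(parents=True, exist_ok=True)
    for t, (f, m) in enumerate(zip(frames, masks)):
        iio.imwrite(outdir / "frames" / f"frame_{t:05d}.png", f)
        iio.imwrite(outdir / "truth_masks" / f"mask_{t:05d}.png",
                    (m.astype(np.uint8) * 255))
    manifest = {
        "n_frames": int(len(frames)),
        "frame_size": [int(frames.shape[1]), int(frames.shape[2])],
        "metadata": metadata or {
            "device_name": "synthetic-trap-0",
            "location": {"lat": 44.316, "lon": 86.06},
            "timestamp": "2019-08-03T22:00:00",
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def write_count_series(path: str | Path, counts: np.ndarray,
                       start_date: str = "2019-08-03") -> Path:
    """Write a (date, count) CSV as the identification stage would log it."""
    import pandas as pd

    dates = pd.date_range(start_date, periods=len(counts), freq="D")
    pd.DataFrame({"date": dates.strftime("%Y-%m-%d"),
                  "count": np.asarray(counts, dtype=int)}
                 ).to_csv(path, index=False)
    return Path(path)
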