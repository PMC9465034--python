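"""Shared fixtures: small synthetic datasets and sequences, generated once
per session."""

from __future__ import annotations

import numpy as np
import pytest

from pestwatch.synthgen import (DEFAULT_CLASSES, SceneSpec,
                                make_insect_dataset, parabolic_trajectory,
                                render_sequence)


@pytest.fixture(scope="session")
def small_dataset3():
    """Three separable classes, 30 images each, 32 px."""
    return make_insect_dataset(DEFAULT_CLASSES[:3], n_per_class=30,
                               image_size=32, seed=11)


@pytest.fixture(scope="session")
def small_dataset4():
    """Four classes including the distorted non-target class."""
    return make_insect_dataset(DEFAULT_CLASSES, n_per_class=30,
                               image_size=32, seed=12)


@pytest.fixture(scope="session")
def short_sequence():
    """120-frame falling-object sequence with clutter, plus truth masks."""
    traj = parabolic_trajectory((160, 160), 120)
    spec = SceneSpec(frame_size=(160, 160), trajectory=traj,
                     clutter_rate=0.05)
    frames, truth = render_sequence(spec, 120, seed=7)
    return spec, frames, truth


def in_view(truth_mask: np.ndarray) -> bool:
    """Object fully inside the frame (nonempty mask touching no border)."""
    m = truth_mask
    return bool(m.any()) and not (m[0].any() or m[-1].any()
                                  or m[:, 0].any() or m[:, -1].any())
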