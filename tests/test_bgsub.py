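"""Mixture background model: update recursion, oracle equivalence, QC rules."""

import numpy as np
import pytest

from conftest import in_view
from pestwatch.bgsub import (MixtureConfig, PixelMixture, QCCategory,
                             QCConfig, SelectionOutcome, classify_capture,
                             select_clean, subtract, update_pixel)
from pestwatch.synthgen import SceneSpec, parabolic_trajectory, render_sequence


class TestUpdatePixel:
    def test_constant_stream_converges_to_fixed_point(self):
        mix = PixelMixture.initialize(np.array(100.0),
                                      MixtureConfig(learning_rate=0.05))
        for _ in range(500):
            update_pixel(mix, np.array(100.0))
        assert mix.weights[..., 0] > 0.99
        assert abs(mix.means[..., 0] - 100.0) < 1e-6

    def test_zero_learning_rate_is_identity(self):
        mix = PixelMixture.initialize(np.array(50.0),
                                      MixtureConfig(learning_rate=0.0))
        w, m, v = (mix.weights.copy(), mix.means.copy(),
                   mix.variances.copy())
        update_pixel(mix, np.array(120.0))
        assert (mix.weights == w).all() and (mix.means == m).all() \
            and (mix.variances == v).all()

    def test_alternating_stream_grows_two_components(self):
        mix = PixelMixture.initialize(np.array(50.0), MixtureConfig())
        for t in range(600):
            update_pixel(mix, np.array(50.0 if t % 2 == 0 else 200.0))
        means = np.sort(mix.means[mix.weights > 0.1])
        assert abs(means[0] - 50) < 10
        assert abs(means[-1] - 200) < 10


def _oracle_masks(frames, cfg):
    """Scalar re-implementation of the per-pixel match/update recursion."""
    n, h, w = frames.shape
    out = np.zeros((n, h, w), dtype=bool)
    K, a, thr = cfg.n_components, cfg.learning_rate, cfg.match_threshold
    for r in range(h):
        for c in range(w):
            wts = [0.0] * K
            mus = [0.0] * K
            vrs = [cfg.initial_variance] * K
            wts[0] = 1.0
            mus[0] = float(frames[0, r, c])
            for t in range(n):
                v = float(frames[t, r, c])
                # components already sorted most-probable-first
                match = next((k for k in range(K)
                              if (v - mus[k]) ** 2 <= thr ** 2 * vrs[k]), None)
                csum, n_bg = 0.0, K
                for k in range(K):
                    csum += wts[k]
                    if csum >= cfg.background_fraction:
                        n_bg = k + 1
                        break
                fg = match is None or match >= n_bg
                if a > 0:
                    if match is not None:
                        for k in range(K):
                            wts[k] += a * ((1.0 if k == match else 0.0) - wts[k])
                        d = v - mus[match]
                        mus[match] += a * d
                        vrs[match] += a * (d * d - vrs[match])
                    else:
                        wts[K - 1] = cfg.new_component_weight
                        mus[K - 1] = v
                        vrs[K - 1] = cfg.initial_variance
                    s = sum(wts)
                    wts = [x / s for x in wts]
                    vrs = [max(x, cfg.variance_floor) for x in vrs]
                    order = sorted(range(K),
                                   key=lambda k: -wts[k] / np.sqrt(vrs[k]))
                    wts = [wts[k] for k in order]
                    mus = [mus[k] for k in order]
                    vrs = [vrs[k] for k in order]
                if t >= cfg.burn_in:
                    out[t, r, c] = fg
    return out


class TestSubtract:
    def test_matches_bruteforce_oracle_on_toy_stack(self):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 256, size=(20, 3, 3)).astype(np.uint8)
        cfg = MixtureConfig(burn_in=5, morphology=False)
        res = subtract(frames, cfg)
        assert (res.masks == _oracle_masks(frames, cfg)).all()

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            subtract(np.zeros((0, 4, 4)))

    def test_static_scene_all_background_after_burn_in(self):
        spec = SceneSpec(frame_size=(50, 50), trajectory=())
        frames, _ = render_sequence(spec, 60, seed=2)
        res = subtract(frames)
        assert not res.masks[res.burn_in:].any()

    def test_moving_object_mask_overlaps_truth(self, short_sequence):
        _, frames, truth = short_sequence
        res = subtract(frames)
        ious = []
        for t in range(res.burn_in, len(frames)):
            if not in_view(truth[t]):
                continue
            inter = (res.masks[t] & truth[t]).sum()
            union = (res.masks[t] | truth[t]).sum()
            ious.append(inter / union)
        assert np.median(ious) >= 0.7

    def test_clean_fraction_not_increased_by_noise(self):
        """More sensor noise never yields a higher clean fraction."""
        fractions = []
        for sigma in (4.0, 16.0, 48.0):
            total = clean = 0
            for seed in (0, 1):
                traj = parabolic_trajectory((100, 100), 80)
                spec = SceneSpec(frame_size=(100, 100), trajectory=traj,
                                 background_noise_sigma=sigma)
                frames, truth = render_sequence(spec, 80, seed=seed)
                res = subtract(frames)
                for t in range(res.burn_in, 80):
                    if in_view(truth[t]):
                        total += 1
                        cat = classify_capture(frames[t], res.masks[t])
                        clean += cat is QCCategory.CLEAN
            fractions.append(clean / total)
        assert fractions[0] >= fractions[1] >= fractions[2]


class TestClassifyCapture:
    def _blob(self, shape=(80, 80), center=(40, 40), r=8):
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r * r

    def _image_for(self, mask, fg=40, bg=180):
        return np.where(mask, fg, bg).astype(np.uint8)

    def test_empty_mask_is_out_of_view(self):
        m = np.zeros((40, 40), dtype=bool)
        assert classify_capture(self._image_for(m), m) is QCCategory.OUT_OF_VIEW

    def test_single_compact_blob_is_clean(self):
        m = self._blob()
        assert classify_capture(self._image_for(m), m) is QCCategory.CLEAN

    def test_blob_plus_transient_speck_is_removable(self):
        m = self._blob()
        m[5:7, 60:62] = True  # 4-px speck, below the removable threshold
        assert classify_capture(self._image_for(m), m) \
            is QCCategory.REMOVABLE_NOISE

    def test_second_large_blob_is_nonremovable(self):
        m = self._blob() | self._blob(center=(15, 65), r=5)
        assert classify_capture(self._image_for(m), m) \
            is QCCategory.NONREMOVABLE_NOISE

    def test_border_touching_blob_is_out_of_view(self):
        m = self._blob(center=(0, 40))
        assert classify_capture(self._image_for(m), m) \
            is QCCategory.OUT_OF_VIEW

    def test_widespread_residual_is_background_not_removed(self):
        rng = np.random.default_rng(4)
        m = self._blob()
        speck = rng.random((80, 80)) < 0.05
        speck[0, :] = speck[-1, :] = speck[:, 0] = speck[:, -1] = False
        m |= speck
        assert classify_capture(self._image_for(m), m) \
            is QCCategory.BACKGROUND_NOT_REMOVED

    def test_low_contrast_blob_is_blurred(self):
        m = self._blob()
        img = np.full((80, 80), 100, dtype=np.uint8)
        img[m] = 99  # nearly no gradient anywhere
        assert classify_capture(img, m) is QCCategory.BLURRED

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_capture(np.zeros((10, 10)), np.zeros((9, 9), dtype=bool))


class TestSelectClean:
    def _captures(self, n_clean, n_dirty):
        rr, cc = np.mgrid[0:60, 0:60]
        blob = (rr - 30) ** 2 + (cc - 30) ** 2 <= 64
        imgs, masks = [], []
        for _ in range(n_clean):
            imgs.append(np.where(blob, 40, 180).astype(np.uint8))
            masks.append(blob)
        empty = np.zeros((60, 60), dtype=bool)
        for _ in range(n_dirty):
            imgs.append(np.full((60, 60), 180, dtype=np.uint8))
            masks.append(empty)
        return np.stack(imgs), np.stack(masks)

    def test_keeps_requested_count_of_clean(self):
        imgs, masks = self._captures(8, 4)
        out = select_clean(imgs, masks, keep_n=5, seed=1)
        assert len(out.indices) == 5 and out.shortfall == 0
        assert (out.indices < 8).all()

    def test_keep_zero_returns_empty(self):
        imgs, masks = self._captures(3, 0)
        assert len(select_clean(imgs, masks, keep_n=0).indices) == 0

    def test_all_clean_keep_all_is_identity(self):
        imgs, masks = self._captures(4, 0)
        out = select_clean(imgs, masks, keep_n=4)
        assert (out.indices == np.arange(4)).all()

    def test_shortfall_reported_when_too_few_clean(self):
        imgs, masks = self._captures(2, 3)
        out = select_clean(imgs, masks, keep_n=5)
        assert out.shortfall == 3 and len(out.indices) == 2

    def test_selection_is_seed_deterministic(self):
        imgs, masks = self._captures(10, 0)
        a = select_clean(imgs, masks, keep_n=4, seed=9)
        b = select_clean(imgs, masks, keep_n=4, seed=9)
        assert (a.indices == b.indices).all()
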