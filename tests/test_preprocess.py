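import numpy as np
import pytest

from memclust.preprocess import (
    MaskStack,
    TopographyMovie,
    align_frames,
    flatten_frame,
    isodata_threshold,
    select_isolated_clusters,
    surface_coverage,
    walking_average,
)


def intermeans_oracle(values, t0=None):
    """Brute-force intermeans iteration, independent of the implementation."""
    values = np.asarray(values, dtype=float)
    t = t0 if t0 is not None else 0.5 * (values.min() + values.max())
    for _ in range(1000):
        lo, hi = values[values <= t], values[values > t]
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < 1e-12:
            return t_new
        t = t_new
    return t


class TestIsodata:
    def test_two_level_image(self):
        frame = np.array([[0.0, 10.0], [0.0, 10.0]])
        assert isodata_threshold(frame) == pytest.approx(5.0)

    def test_four_pixel_fixed_point(self):
        values = [0.0, 0.0, 8.0, 10.0]
        expected = intermeans_oracle(values)  # = 4.5
        assert expected == pytest.approx(4.5)
        assert isodata_threshold(np.array(values)) == pytest.approx(expected, abs=1e-6)

    def test_bimodal_gaussians(self, rng):
        lo = rng.normal(0.0, 0.3, 2000)
        hi = rng.normal(4.0, 0.3, 2000)
        frame = np.concatenate([lo, hi]).reshape(40, 100)
        t = isodata_threshold(frame)
        assert 1.5 < t < 2.5

    def test_constant_frame_rejected(self):
        with pytest.raises(ValueError):
            isodata_threshold(np.full((8, 8), 3.0))

    def test_fixed_point_property(self, rng):
        frame = rng.normal(0, 1, (30, 30)) + (rng.uniform(size=(30, 30)) > 0.7) * 5.0
        t = isodata_threshold(frame)
        lo, hi = frame[frame <= t], frame[frame > t]
        assert t == pytest.approx(0.5 * (lo.mean() + hi.mean()), abs=1e-5)

    def test_affine_equivariance(self, rng):
        frame = rng.normal(0, 1, (20, 20)) + (rng.uniform(size=(20, 20)) > 0.5) * 6.0
        t = isodata_threshold(frame)
        t2 = isodata_threshold(2.5 * frame + 3.0)
        assert t2 == pytest.approx(2.5 * t + 3.0, abs=1e-4)


def _membrane_with_blob(h=60, w=80, blob_height=5.0):
    frame = np.zeros((h, w))
    yy, xx = np.indices((h, w))
    frame[(yy - h // 2) ** 2 + (xx - w // 2) ** 2 <= 100] = blob_height
    return frame


class TestFlattenFrame:
    def test_plane_tilt_removed(self):
        base = _membrane_with_blob()
        yy, xx = np.indices(base.shape)
        tilted = base + 0.01 * xx + 0.5
        assert np.allclose(flatten_frame(tilted), flatten_frame(base), atol=1e-6)

    def test_constant_frame_zeroed(self):
        out = flatten_frame(np.full((10, 10), 7.0))
        assert np.allclose(out, 0.0)

    def test_known_line_offsets_recovered(self, rng):
        base = _membrane_with_blob()
        offsets = rng.normal(0.0, 0.3, base.shape[0])
        noisy = base + offsets[:, None]
        out = flatten_frame(noisy)
        ref = flatten_frame(base)
        rms_err = np.sqrt(np.mean((out - ref) ** 2))
        assert rms_err < 0.01 * np.sqrt(np.mean(offsets**2))


class TestAlignFrames:
    def test_identical_frames_zero_shift(self, rng):
        frame = rng.normal(0, 1, (40, 40))
        movie = TopographyMovie(np.stack([frame] * 4), 1.0, 1.0)
        _, drift = align_frames(movie)
        assert np.allclose(drift, 0.0)

    def test_single_frame_identity(self, rng):
        frame = rng.normal(0, 1, (30, 30))
        movie = TopographyMovie(frame[None], 1.0, 1.0)
        aligned, drift = align_frames(movie)
        assert np.array_equal(aligned.frames[0], frame)
        assert drift.shape == (1, 2)

    def test_linear_drift_recovered(self):
        base = _membrane_with_blob(80, 80)
        frames = [np.roll(base, (0, t // 2), axis=(0, 1)) for t in range(8)]
        # 1 px every 2 frames = 0.5 px/frame along x
        movie = TopographyMovie(np.stack(frames), 1.0, 1.0)
        _, drift = align_frames(movie)
        rate = (drift[-1] - drift[0]) / (len(frames) - 1)
        assert abs(rate[1] - 0.5) < 0.1
        assert abs(rate[0]) < 0.1


class TestWalkingAverage:
    def _disk_stack(self, n=6):
        yy, xx = np.indices((40, 40))
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 81
        return np.stack([disk] * n)

    def test_salt_pixel_removed(self):
        stack = self._disk_stack()
        stack[3, 2, 2] = True  # single-frame noise pixel far from the disk
        out = walking_average(MaskStack(stack))
        assert not out.masks[3, 2, 2]

    def test_idempotent_on_constant_stack(self):
        stack = MaskStack(self._disk_stack())
        out = walking_average(stack)
        assert np.array_equal(out.masks, stack.masks)
        again = walking_average(out)
        assert np.array_equal(again.masks, out.masks)

    def test_flicker_noise_cleaned(self, rng):
        stack = self._disk_stack(12)
        truth = stack[0]
        # 5% of mask pixels drop out independently per frame
        flicker = (rng.uniform(size=stack.shape) < 0.05) & stack
        noisy = stack ^ flicker
        out = walking_average(MaskStack(noisy))
        inner = out.masks[3:-3]
        jaccard = np.min(
            [
                (m & truth).sum() / (m | truth).sum() if (m | truth).sum() else 1.0
                for m in inner
            ]
        )
        assert jaccard > 0.99

    def test_hole_filling(self):
        stack = self._disk_stack()
        stack[:, 20, 20] = False  # persistent interior gap pixel
        out = walking_average(MaskStack(stack))
        assert out.masks[:, 20, 20].all()

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            walking_average(MaskStack(self._disk_stack(2)))


class TestSurfaceCoverage:
    def test_painted_fractions_recovered(self, rng):
        # ~11% protein at 8 nm, ~15% lipid at 4 nm, ~74% mica at 0 nm
        n = 200 * 200
        labels = rng.permutation(
            np.concatenate(
                [np.full(int(0.11 * n), 2), np.full(int(0.15 * n), 1),
                 np.full(n - int(0.11 * n) - int(0.15 * n), 0)]
            )
        )
        heights = np.choose(labels, [0.0, 4.0, 8.0]) + rng.normal(0, 0.2, n)
        frame = heights.reshape(200, 200)
        frac = surface_coverage(frame)
        assert frac["protein"] == pytest.approx(0.11, abs=0.01)
        assert frac["lipid"] == pytest.approx(0.15, abs=0.01)
        assert frac["mica"] == pytest.approx(0.74, abs=0.01)

    def test_uniform_membrane(self):
        with pytest.warns(UserWarning):
            frac = surface_coverage(np.full((20, 20), 4.0))
        assert frac == {"mica": 0.0, "lipid": 1.0, "protein": 0.0}

    def test_fractions_sum_to_one(self, rng):
        for _ in range(5):
            frame = rng.normal(0, 1, (30, 30)) + rng.choice([0, 4, 8], (30, 30))
            frac = surface_coverage(frame)
            assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)

    def test_configured_levels(self):
        frame = np.array([[0.1, 3.9], [8.2, 0.0]])
        frac = surface_coverage(frame, levels={"mica": 0, "lipid": 4, "protein": 8})
        assert frac == {"mica": 0.5, "lipid": 0.25, "protein": 0.25}


def _disk(shape, cy, cx, r):
    yy, xx = np.indices(shape)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestSelectIsolatedClusters:
    def test_stable_disk_accepted(self):
        stack = np.stack([_disk((60, 60), 30, 30, 10)] * 5)
        traces = select_isolated_clusters(MaskStack(stack))
        assert len(traces) == 1
        assert traces[0].shape == stack.shape

    def test_merging_disks_rejected(self):
        frames = []
        for t in range(5):
            gap = 14 - 3 * t  # disks drift together and touch by t=4
            m = _disk((80, 80), 40, 25 + 3 * t, 10) | _disk((80, 80), 40, 55, 10)
            frames.append(m)
        with pytest.warns(UserWarning):
            traces = select_isolated_clusters(MaskStack(np.stack(frames)))
        assert traces == []

    def test_splitting_disk_rejected(self):
        whole = _disk((80, 80), 40, 40, 12)
        split = _disk((80, 80), 40, 25, 8) | _disk((80, 80), 40, 55, 8)
        stack = np.stack([whole] * 3 + [split] * 2)
        with pytest.warns(UserWarning):
            traces = select_isolated_clusters(MaskStack(stack))
        assert traces == []

    def test_border_touching_rejected(self):
        stack = np.stack([_disk((40, 40), 5, 5, 8)] * 4)  # clipped at border
        with pytest.warns(UserWarning):
            traces = select_isolated_clusters(MaskStack(stack))
        assert traces == []


class TestTopographyMovie:
    def test_timestamp_validation(self):
        with pytest.raises(ValueError):
            TopographyMovie(np.zeros((3, 4, 4)), 1.0, 1.0, timestamps=np.array([0.0, 2.0, 1.0]))

    def test_default_timestamps(self):
        m = TopographyMovie(np.zeros((3, 4, 4)), 1.0, 0.5)
        assert np.allclose(m.timestamps, [0.0, 0.5, 1.0])
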