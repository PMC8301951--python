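import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sphereloc.volume import (
    DegenerateInputError,
    Volume,
    VolumeIOError,
    find_local_maxima,
    load_volume,
    normalize_intensity,
    resample_isotropic,
    save_volume,
)


def brute_force_maxima(v: Volume, min_distance: float, threshold: float):
    """Independent O(n*k) oracle for find_local_maxima (Euclidean-ball
    neighbourhood, greedy suppression in descending value / lex order)."""
    data = v.data
    spacing = np.asarray(v.spacing)
    cands = []
    for idx in np.ndindex(data.shape):
        val = data[idx]
        if val <= threshold:
            continue
        is_max = True
        for nb in np.ndindex(data.shape):
            d = np.linalg.norm((np.asarray(nb) - np.asarray(idx)) * spacing)
            if d <= min_distance and data[nb] > val:
                is_max = False
                break
        if is_max:
            cands.append((idx, val))
    cands.sort(key=lambda t: (-t[1], t[0]))
    kept = []
    for idx, val in cands:
        pos = v.voxel_to_physical(idx)
        if all(np.linalg.norm(pos - k) > min_distance for k, _ in kept):
            kept.append((pos, val))
    return kept


class TestVolume:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Volume(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            Volume(np.zeros((4, 4, 4)), spacing=(1, 0, 1))

    def test_voxel_physical_round_trip_identity(self, rng):
        v = Volume(np.zeros((5, 6, 7)), spacing=(0.7, 1.1, 2.0), origin=(-3, 4, 0.5))
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in v.shape], indexing="ij"), -1)
        back = v.physical_to_voxel(v.voxel_to_physical(idx))
        assert np.allclose(back, idx)


class TestIO:
    def test_nifti_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(6, 7, 8)), spacing=(0.8, 1.0, 1.2), origin=(1, 2, 3))
        path = tmp_path / "vol.nii.gz"
        save_volume(v, path)
        w = load_volume(path)
        assert np.allclose(w.data, v.data, atol=1e-6)
        assert np.allclose(w.spacing, v.spacing)
        assert np.allclose(w.origin, v.origin)

    def test_raw_fixture_with_sidecar(self, tmp_path):
        arr = np.arange(27.0).reshape(3, 3, 3)
        np.save(tmp_path / "vol.npy", arr)
        (tmp_path / "vol.json").write_text(json.dumps({"spacing_mm": [1, 1, 1]}))
        v = load_volume(tmp_path / "vol.npy")
        assert v.spacing == (1.0, 1.0, 1.0)
        assert np.array_equal(v.data, arr)

    def test_invalid_spacing_rejected(self, tmp_path):
        np.save(tmp_path / "bad.npy", np.zeros((3, 3, 3)))
        (tmp_path / "bad.json").write_text(json.dumps({"spacing_mm": [1, 0, 1]}))
        with pytest.raises(VolumeIOError):
            load_volume(tmp_path / "bad.npy")

    def test_missing_file(self, tmp_path):
        with pytest.raises(VolumeIOError):
            load_volume(tmp_path / "nope.nii.gz")


class TestResample:
    def test_isotropic_identity(self, rng):
        v = Volume(rng.normal(size=(10, 10, 10)), spacing=(1, 1, 1))
        w = resample_isotropic(v, 1.0)
        assert w.spacing == (1.0, 1.0, 1.0)
        assert np.allclose(w.data, v.data)

    def test_constant_preserved(self):
        v = Volume(np.full((8, 8, 12), 3.7), spacing=(1, 1, 0.5))
        w = resample_isotropic(v, 1.0)
        assert np.allclose(w.data, 3.7)
        # physical extent preserved to within one voxel
        assert abs(w.shape[2] * 1.0 - 12 * 0.5) <= 1.0

    def test_anisotropic_sphere_centroid_preserved(self):
        # ball painted on a (1,1,2) grid; resampled centroid within 0.5*target
        v = Volume(np.zeros((40, 40, 20)), spacing=(1, 1, 2))
        center = np.array([19.3, 20.2, 18.9])
        grids = np.meshgrid(*[np.arange(n) for n in v.shape], indexing="ij")
        pos = np.stack(grids, -1) * np.asarray(v.spacing)
        v.data[np.linalg.norm(pos - center, axis=-1) <= 6.0] = 1.0

        def centroid(vol):
            g = np.meshgrid(*[np.arange(n) for n in vol.shape], indexing="ij")
            p = np.stack(g, -1) * np.asarray(vol.spacing)
            w = vol.data
            return (p * w[..., None]).sum((0, 1, 2)) / w.sum()

        w = resample_isotropic(v, 1.0)
        assert np.linalg.norm(centroid(w) - centroid(v)) < 0.5


class TestNormalize:
    def test_mean_zero_sd_one_and_idempotent(self, rng):
        v = Volume(rng.normal(3, 5, size=(9, 9, 9)))
        w = normalize_intensity(v)
        assert abs(w.data.mean()) < 1e-6 and abs(w.data.std() - 1) < 1e-6
        w2 = normalize_intensity(w)
        assert np.allclose(w2.data, w.data, atol=1e-6)

    def test_constant_raises(self):
        with pytest.raises(DegenerateInputError):
            normalize_intensity(Volume(np.ones((4, 4, 4))))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        scale=st.floats(0.01, 100), offset=st.floats(-50, 50),
        seed=st.integers(0, 100),
    )
    def test_affine_rescale_invariance(self, scale, offset, seed):
        data = np.random.default_rng(seed).normal(size=(6, 6, 6))
        a = normalize_intensity(Volume(data))
        b = normalize_intensity(Volume(scale * data + offset))
        assert np.allclose(a.data, b.data, atol=1e-6)


class TestLocalMaxima:
    def test_single_impulse(self):
        data = np.zeros((12, 12, 12))
        data[5, 5, 5] = 2.0
        pos, vals = find_local_maxima(Volume(data), min_distance=2.0, threshold=0.5)
        assert len(pos) == 1
        assert np.allclose(pos[0], (5, 5, 5)) and vals[0] == 2.0

    def test_two_close_impulses_keep_larger_then_lex(self):
        data = np.zeros((12, 12, 12))
        data[5, 5, 5] = 1.0
        data[5, 5, 7] = 2.0
        pos, _ = find_local_maxima(Volume(data), min_distance=3.0, threshold=0.0)
        assert len(pos) == 1 and np.allclose(pos[0], (5, 5, 7))
        data[5, 5, 7] = 1.0  # tie -> lexicographically smallest voxel wins
        pos, _ = find_local_maxima(Volume(data), min_distance=3.0, threshold=0.0)
        assert len(pos) == 1 and np.allclose(pos[0], (5, 5, 5))

    def test_all_zero_empty(self):
        pos, _ = find_local_maxima(Volume(np.zeros((8, 8, 8))), 2.0, 0.0)
        assert len(pos) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("spacing", [(1, 1, 1), (0.5, 1, 1.5)])
    def test_matches_brute_force_oracle(self, seed, spacing):
        rng = np.random.default_rng(seed)
        data = np.round(rng.uniform(0, 10, size=(9, 10, 8)), 1)
        v = Volume(data, spacing=spacing)
        got_pos, got_vals = find_local_maxima(v, min_distance=2.2, threshold=4.0)
        expected = brute_force_maxima(v, 2.2, 4.0)
        assert len(got_pos) == len(expected)
        for (pos, val), gp, gv in zip(expected, got_pos, got_vals):
            assert np.allclose(gp, pos) and gv == val
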