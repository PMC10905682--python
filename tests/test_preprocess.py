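"""Intensity normalization, VOI cropping, prior planes, flips, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lvifusion.cohort import PRIOR_FEATURE_NAMES, CohortSpec, build_cohort
from lvifusion.preprocess import (
    PriorFeatureScaler,
    SplitConfig,
    assemble_input,
    case_to_input,
    crop_voi_patch,
    encode_prior_planes,
    flip_tensor,
    normalize_intensity,
    random_flip,
    scale_prior_features,
    stratified_split,
)


class TestNormalizeIntensity:
    def test_clips_then_scales_to_unit_range(self, rng):
        vol = rng.uniform(-5, 10, size=(8, 8, 8))
        vol.flat[0], vol.flat[1] = -5.0, 10.0
        out = normalize_intensity(vol)
        assert out.min() == 0.0 and out.max() == pytest.approx(1.0)

    def test_all_zero_volume_unchanged(self):
        assert not normalize_intensity(np.zeros((4, 4, 4))).any()

    def test_idempotent(self, rng):
        vol = rng.normal(size=(6, 6, 6))
        once = normalize_intensity(vol)
        assert np.allclose(normalize_intensity(once), once, atol=1e-7)

    def test_nonfinite_rejected(self):
        vol = np.zeros((4, 4, 4))
        vol[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            normalize_intensity(vol)

    def test_normalize_before_crop_is_the_fixed_order(self, rng):
        """Per-volume scaling does not commute with cropping unless the patch
        contains the volume max; the pipeline normalizes first."""
        vol = rng.uniform(0, 1, size=(40, 40, 40))
        vol[2, 2, 2] = 50.0  # max far outside the patch window
        center = (30, 30, 30)
        a = crop_voi_patch(normalize_intensity(vol), center, 8)
        b = normalize_intensity(crop_voi_patch(vol, center, 8))
        assert not np.allclose(a, b)


class TestCropVoiPatch:
    def test_interior_window_indices(self, rng):
        vol = rng.normal(size=(64, 64, 64))
        patch = crop_voi_patch(vol, (32, 32, 32), 32)
        assert np.array_equal(patch, vol[16:48, 16:48, 16:48])

    def test_corner_zero_padding(self, rng):
        vol = rng.uniform(1, 2, size=(64, 64, 64))
        patch = crop_voi_patch(vol, (0, 0, 0), 32)
        assert np.array_equal(patch[16:, 16:, 16:], vol[:16, :16, :16])
        assert (patch > 0).sum() == 16**3  # exactly one octant from the volume

    def test_center_outside_rejected(self):
        with pytest.raises(IndexError):
            crop_voi_patch(np.zeros((8, 8, 8)), (8, 0, 0), 4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        c=st.tuples(*[st.integers(0, 19)] * 3),
        size=st.sampled_from([4, 8]),
        seed=st.integers(0, 10_000),
    )
    def test_matches_index_oracle(self, c, size, seed):
        vol = np.random.default_rng(seed).normal(size=(20, 20, 20))
        patch = crop_voi_patch(vol, c, size)
        half = size // 2
        for idx in [(0, 0, 0), (half, half, half), (size - 1, 1, half)]:
            src = tuple(cc - half + i for cc, i in zip(c, idx))
            want = vol[src] if all(0 <= s < 20 for s in src) else 0.0
            assert patch[idx] == want


class TestPriorScaling:
    def test_binary_features_unchanged(self):
        df = pd.DataFrame({"b": [0, 1, 0, 1]})
        scaled, _ = scale_prior_features(df)
        assert np.array_equal(scaled["b"].to_numpy(), [0, 1, 0, 1])

    def test_minmax_arithmetic_and_clipping(self):
        train = pd.DataFrame({"age": [25.0, 85.0, 55.0]})
        scaled, scaler = scale_prior_features(train)
        assert scaled["age"].iloc[2] == pytest.approx(0.5)
        val = scaler.transform(pd.DataFrame({"age": [90.0, 20.0]}))
        assert val["age"].tolist() == [1.0, 0.0]

    def test_constant_feature_maps_to_zero(self):
        train = pd.DataFrame({"c": [3.0, 3.0, 3.0]})
        scaled, _ = scale_prior_features(train)
        assert not scaled["c"].to_numpy().any()

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            PriorFeatureScaler().fit(pd.DataFrame({"a": []}))


class TestPriorPlanes:
    def test_planes_are_spatially_constant(self, rng):
        vals = rng.uniform(0, 1, size=16)
        planes = encode_prior_planes(vals, size=8)
        assert planes.shape == (16, 8, 8, 8)
        assert np.all(np.ptp(planes.reshape(16, -1), axis=1) == 0.0)
        assert np.allclose(planes.mean(axis=(1, 2, 3)), vals, atol=1e-7)

    def test_zero_value_gives_zero_plane(self):
        planes = encode_prior_planes(np.zeros(16), size=4)
        assert not planes.any()

    def test_unscaled_input_rejected(self):
        bad = np.zeros(16)
        bad[3] = 1.5
        with pytest.raises(ValueError):
            encode_prior_planes(bad)


class TestAssembleInput:
    def test_full_and_ablated_channel_counts(self, rng):
        patches = [rng.uniform(0, 1, (8, 8, 8)) for _ in range(3)]
        planes = encode_prior_planes(rng.uniform(0, 1, 16), size=8)
        full = assemble_input(patches, planes)
        assert full.shape == (19, 8, 8, 8)
        ablated = assemble_input(patches)
        assert ablated.shape == (3, 8, 8, 8)

    def test_round_trip_slices(self, rng):
        patches = [rng.uniform(0, 1, (4, 4, 4)).astype(np.float32) for _ in range(3)]
        planes = encode_prior_planes(rng.uniform(0, 1, 16), size=4)
        x = assemble_input(patches, planes)
        for c in range(3):
            assert np.array_equal(x[c], patches[c])
        assert np.array_equal(x[3:], planes)
        assert np.array_equal(assemble_input([x[0], x[1], x[2]], x[3:]), x)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            assemble_input([np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), np.zeros((8, 8, 8))])


class TestRandomFlip:
    def test_involution(self, rng):
        x = rng.normal(size=(19, 6, 6, 6)).astype(np.float32)
        assert np.array_equal(flip_tensor(flip_tensor(x, (1, 1, 1)), (1, 1, 1)), x)

    def test_voxel_multiset_preserved_per_channel(self, rng):
        x = rng.normal(size=(4, 6, 6, 6)).astype(np.float32)
        y, _ = random_flip(x, rng=3)
        for c in range(4):
            assert np.array_equal(np.sort(y[c].ravel()), np.sort(x[c].ravel()))

    def test_mask_reproducible_given_seed(self, rng):
        x = rng.normal(size=(3, 4, 4, 4)).astype(np.float32)
        y1, m1 = random_flip(x, rng=42)
        y2, m2 = random_flip(x, rng=42)
        assert m1 == m2 and np.array_equal(y1, y2)

    def test_constant_planes_invariant(self):
        planes = encode_prior_planes(np.linspace(0, 1, 16), size=4)
        flipped, _ = random_flip(planes, rng=0)
        assert np.array_equal(flipped, planes)


class TestStratifiedSplit:
    def test_reference_cohort_sizes(self):
        labels = np.array([0] * 256 + [1] * 85)
        tr, va = stratified_split(labels, SplitConfig(seed=1, allocation_rule="floor_validation"))
        assert len(tr) + len(va) == 341 and not np.intersect1d(tr, va).size
        assert (labels[va] == 0).sum() == 76
        assert (labels[va] == 1).sum() == 25
        tr2, va2 = stratified_split(labels, SplitConfig(seed=1, allocation_rule="largest_remainder"))
        assert len(va2) == 102
        assert (labels[va2] == 0).sum() in (76, 77)
        assert (labels[va2] == 1).sum() in (25, 26)

    def test_balanced_small_cohort(self):
        labels = np.array([0] * 5 + [1] * 5)
        tr, va = stratified_split(labels, SplitConfig(seed=0, allocation_rule="largest_remainder"))
        assert len(tr) == 7 and len(va) == 3
        assert abs((labels[va] == 0).sum() - (labels[va] == 1).sum()) <= 1

    def test_deterministic_given_seed(self):
        labels = (np.arange(50) % 3 == 0).astype(int)
        a = stratified_split(labels, SplitConfig(seed=7))
        b = stratified_split(labels, SplitConfig(seed=7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([], dtype=int), SplitConfig())


def test_case_to_input_bounds_and_constant_planes(small_spec):
    cases, table = build_cohort(small_spec)
    feats = table[list(PRIOR_FEATURE_NAMES)]
    scaled, _ = scale_prior_features(feats)
    x = case_to_input(cases[0], scaled.iloc[0].to_numpy(), size=32)
    assert x.data.shape == (19, 32, 32, 32)
    assert x.data.min() >= 0.0 and x.data.max() <= 1.0
    assert np.all(np.ptp(x.data[3:].reshape(16, -1), axis=1) == 0.0)
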