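"""Distance metrics, centroid extraction and feature assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdstages.geometry import (
    MissingStructureError,
    Point3,
    assemble_feature_table,
    cosine_distance,
    euclidean_distance,
    extract_subject_features,
    measure_structure,
    minkowski_distance,
    voxel_to_ras,
)
from pdstages.registry import default_registry, feature_columns
from pdstages.volume import LabeledVolume

finite = st.floats(min_value=-100, max_value=100, allow_nan=False)
points = st.tuples(finite, finite, finite)


class TestMinkowski:
    @pytest.mark.parametrize(
        "a, b, p, expected",
        [
            ((0, 0, 0), (3, 4, 0), 2, 5.0),  # 3-4-5 triangle
            ((0, 0, 0), (3, 4, 0), 1, 7.0),  # Manhattan
            ((1, 2, 3), (1, 2, 3), 2, 0.0),
            ((1, 2, 3), (1, 2, 3), 7, 0.0),
        ],
    )
    def test_known_values(self, a, b, p, expected):
        assert minkowski_distance(a, b, p) == pytest.approx(expected)

    def test_order_below_one_rejected(self):
        with pytest.raises(ValueError):
            minkowski_distance((0, 0, 0), (1, 1, 1), p=0.5)

    @settings(max_examples=100, derandomize=True)
    @given(a=points, b=points, c=points, p=st.floats(min_value=1, max_value=5))
    def test_metric_axioms(self, a, b, c, p):
        dab = minkowski_distance(a, b, p)
        assert dab == pytest.approx(minkowski_distance(b, a, p))
        assert minkowski_distance(a, a, p) == 0.0
        assert dab <= minkowski_distance(a, c, p) + minkowski_distance(c, b, p) + 1e-9

    def test_p2_equals_euclidean(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=3), rng.normal(size=3)
            assert minkowski_distance(a, b, 2) == pytest.approx(euclidean_distance(a, b), abs=1e-12)


class TestCosine:
    def test_identical_vectors_exactly_zero(self, rng):
        for _ in range(20):
            v = rng.normal(size=3) * rng.uniform(0.01, 1e4)
            assert cosine_distance(v, v) == 0.0

    def test_opposed_vectors_exactly_two(self, rng):
        for _ in range(20):
            v = rng.normal(size=3) * rng.uniform(0.01, 1e4)
            assert cosine_distance(v, -v) == 2.0

    def test_orthogonal_unit_vectors(self):
        assert cosine_distance((1, 0, 0), (0, 1, 0)) == pytest.approx(1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance((0, 0, 0), (1, 2, 3))

    @settings(max_examples=150, derandomize=True)
    @given(a=points, b=points, s=st.floats(min_value=0.01, max_value=100))
    def test_bounds_and_scale_invariance(self, a, b, s):
        av, bv = np.asarray(a), np.asarray(b)
        if np.linalg.norm(av) == 0 or np.linalg.norm(bv) == 0:
            return
        d = cosine_distance(av, bv)
        assert 0.0 <= d <= 2.0
        assert cosine_distance(s * av, bv) == pytest.approx(d, abs=1e-9)


class TestVoxelToRas:
    def test_identity_and_translation(self):
        vol = LabeledVolume(labels=np.zeros((5, 6, 7), dtype=np.int16), affine=np.eye(4))
        assert voxel_to_ras(vol, (2, 3, 4)).as_array() == pytest.approx([2, 3, 4])
        aff = np.eye(4)
        aff[:3, 3] = (-10.0, 5.0, 2.5)
        vol_t = LabeledVolume(labels=vol.labels, affine=aff)
        assert voxel_to_ras(vol_t, (0, 0, 0)).as_array() == pytest.approx([-10, 5, 2.5])

    def test_matches_matrix_product_oracle(self, rng):
        aff = np.eye(4)
        aff[:3, :3] = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        aff[:3, 3] = rng.normal(size=3)
        vol = LabeledVolume(labels=np.zeros((4, 4, 4), dtype=np.int16), affine=aff)
        idx = (1, 2, 3)
        expected = (aff @ np.array([1, 2, 3, 1.0]))[:3]
        assert voxel_to_ras(vol, idx).as_array() == pytest.approx(expected, abs=1e-12)

    def test_out_of_bounds(self):
        vol = LabeledVolume(labels=np.zeros((3, 3, 3), dtype=np.int16), affine=np.eye(4))
        with pytest.raises(IndexError):
            voxel_to_ras(vol, (3, 0, 0))


def _brute_force_geometry(vol: LabeledVolume, codes):
    """Independent voxel-scan oracle: plain loops, explicit affine product."""
    n = 0
    acc = np.zeros(3)
    for i in range(vol.labels.shape[0]):
        for j in range(vol.labels.shape[1]):
            for k in range(vol.labels.shape[2]):
                if int(vol.labels[i, j, k]) in codes:
                    n += 1
                    acc += (vol.affine @ np.array([i, j, k, 1.0]))[:3]
    return n, acc / n


class TestMeasureStructure:
    def _volume_with(self, voxels, code=17, shape=(6, 6, 6)):
        labels = np.zeros(shape, dtype=np.int16)
        for v in voxels:
            labels[v] = code
        return LabeledVolume(labels=labels, affine=np.eye(4))

    def test_single_voxel(self):
        reg = default_registry()
        vol = self._volume_with([(2, 3, 4)])
        g = measure_structure(vol, "Left-Hippocampus", reg)
        assert g.centroid.as_array() == pytest.approx([2, 3, 4])
        assert g.volume_mm3 == pytest.approx(1.0)

    def test_two_voxel_symmetry(self):
        vol = self._volume_with([(0, 0, 0), (4, 0, 0)])
        g = measure_structure(vol, "Left-Hippocampus")
        assert g.centroid.as_array() == pytest.approx([2, 0, 0])

    def test_merged_labels_pool_one_cloud(self):
        labels = np.zeros((6, 6, 6), dtype=np.int16)
        labels[1, 1, 1] = 10
        labels[5, 1, 1] = 49
        vol = LabeledVolume(labels=labels, affine=np.eye(4))
        g = measure_structure(vol, "Thalamus")
        assert g.n_voxels == 2
        assert g.centroid.as_array() == pytest.approx([3, 1, 1])

    def test_absent_structure_raises(self):
        vol = self._volume_with([(0, 0, 0)], code=17)
        with pytest.raises(MissingStructureError):
            measure_structure(vol, "Right-Hippocampus")

    def test_matches_brute_force_oracle(self, rng):
        labels = (rng.random((12, 12, 12)) < 0.2).astype(np.int16) * 17
        aff = np.diag([1.0, 2.0, 0.5, 1.0])
        aff[:3, 3] = (-4.0, 1.0, 7.0)
        vol = LabeledVolume(labels=labels, affine=aff)
        g = measure_structure(vol, "Left-Hippocampus")
        n, cen = _brute_force_geometry(vol, {17})
        assert g.n_voxels == n
        assert g.centroid.as_array() == pytest.approx(cen, abs=1e-9)
        assert g.volume_mm3 == pytest.approx(n * 1.0, abs=1e-9)


class TestSubjectFeatures:
    def test_normalisation_arithmetic(self, small_phantom):
        sid = small_phantom.manifest["subject_id"].iloc[0]
        row = small_phantom.manifest.iloc[0].to_dict()
        vol = small_phantom.volumes[sid]
        feats = extract_subject_features(vol, row)
        reg = default_registry()
        thal = measure_structure(vol, "Thalamus", reg)
        assert feats.thalamus_volume == pytest.approx(thal.volume_mm3)
        hip = measure_structure(vol, "Left-Hippocampus", reg)
        assert feats.norm_volume["Left-Hippocampus"] == pytest.approx(hip.volume_mm3 / thal.volume_mm3)
        assert feats.euclidean_mm["Left-Hippocampus"] == pytest.approx(
            euclidean_distance(hip.centroid, thal.centroid)
        )
        # The reference structure appears only as its raw volume.
        assert "Thalamus" not in feats.norm_volume

    def test_matches_ground_truth_within_voxelization(self, small_phantom):
        reg = default_registry()
        gt = small_phantom.ground_truth
        for sid, vol in small_phantom.volumes.items():
            row = small_phantom.manifest.set_index("subject_id").loc[sid]
            feats = extract_subject_features(vol, {"subject_id": sid, **row.to_dict()})
            sub = gt[gt.subject_id == sid].set_index("structure")
            thal_true = sub.loc["Thalamus", "vol_mm3"]
            for name in reg.non_reference:
                true_norm = sub.loc[name, "vol_mm3"] / thal_true
                assert feats.norm_volume[name] == pytest.approx(true_norm, rel=0.06)
                true_d = euclidean_distance(
                    sub.loc[name, ["cx", "cy", "cz"]].to_numpy(float),
                    sub.loc["Thalamus", ["cx", "cy", "cz"]].to_numpy(float),
                )
                assert feats.euclidean_mm[name] == pytest.approx(true_d, abs=0.5)

    def test_scaling_and_translation_properties(self, small_phantom):
        """Uniform scaling preserves volume ratios and scales distances;
        translation changes cosine but not Euclidean features."""
        sid = small_phantom.manifest["subject_id"].iloc[0]
        demo = small_phantom.manifest.iloc[0].to_dict()
        vol = small_phantom.volumes[sid]
        base = extract_subject_features(vol, demo)

        scaled_aff = vol.affine.copy()
        scaled_aff[:3, :] *= 2.0
        scaled = extract_subject_features(LabeledVolume(vol.labels, scaled_aff), demo)
        shifted_aff = vol.affine.copy()
        shifted_aff[:3, 3] += (50.0, -30.0, 20.0)
        shifted = extract_subject_features(LabeledVolume(vol.labels, shifted_aff), demo)

        for name in default_registry().non_reference:
            assert scaled.norm_volume[name] == pytest.approx(base.norm_volume[name], rel=1e-9)
            assert scaled.euclidean_mm[name] == pytest.approx(2 * base.euclidean_mm[name], rel=1e-9)
            assert shifted.euclidean_mm[name] == pytest.approx(base.euclidean_mm[name], rel=1e-9)
        cos_changes = [
            abs(shifted.cosine[n] - base.cosine[n]) for n in default_registry().non_reference
        ]
        assert max(cos_changes) > 1e-3  # origin sensitivity of the cosine metric


class TestFeatureTable:
    def test_57_feature_columns(self, small_phantom):
        feats = [
            extract_subject_features(vol, small_phantom.manifest.set_index("subject_id").loc[sid].to_dict() | {"subject_id": sid})
            for sid, vol in small_phantom.volumes.items()
        ]
        table = assemble_feature_table(feats)
        assert table.drop(columns=["group"]).shape[1] == 57
        assert list(table.columns[:-1]) == feature_columns()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            assemble_feature_table([])

    def test_column_order_deterministic(self):
        assert feature_columns() == feature_columns()
        assert feature_columns()[0] == "Thalamus_vol"
        assert feature_columns()[-2:] == ["Sex", "Age"]
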