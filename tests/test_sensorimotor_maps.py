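"""Conjunction, segment-specific maps, and the motor/tactile partition."""

import numpy as np
import pytest

from emomap import glm, sensorimotor_maps as sm
from emomap.types import GridSpec, MODALITIES, SEGMENTS, StatMap, binary_map


def tmap(data, df=19, affine=None):
    return StatMap(np.asarray(data, dtype=float), affine if affine is not None else np.eye(4), "tstat", df=df)


SHAPE = (10, 10, 8)


class TestConjunction:
    def test_identical_maps_idempotent(self, rng):
        t = rng.normal(size=SHAPE) * 3
        single = glm.threshold_cluster(tmap(t), 0.01)
        conj = sm.conjunction([tmap(t), tmap(t)], 0.01)
        assert np.array_equal(conj.data, single.data)

    def test_disjoint_suprathreshold_sets_empty(self):
        a = np.zeros(SHAPE)
        b = np.zeros(SHAPE)
        a[:3] = 10.0
        b[5:] = 10.0
        conj = sm.conjunction([tmap(a), tmap(b)], 0.001)
        assert conj.count() == 0

    def test_shared_roi_recovered_exactly(self):
        """Eight planted-ROI t-maps sharing one common ROI: the conjunction is
        exactly that ROI (set-intersection oracle)."""
        common = np.zeros(SHAPE, dtype=bool)
        common[4:6, 4:6, 3:5] = True
        maps = []
        for i in range(8):
            t = np.zeros(SHAPE)
            t[i, i % 8, :2] = 10.0  # private ROI per contrast
            t[common] = 10.0
            maps.append(tmap(t))
        conj = sm.conjunction(maps, 0.001)
        assert np.array_equal(conj.data.astype(bool), common)

    def test_subset_of_each_thresholded_input(self, rng):
        maps = [tmap(rng.normal(size=SHAPE) * 2) for _ in range(4)]
        conj = sm.conjunction(maps, 0.05)
        for m in maps:
            single = glm.threshold_cluster(m, 0.05)
            assert np.all(single.data.astype(bool) | ~conj.data.astype(bool))

    def test_monotone_in_voxel_p(self, rng):
        maps = [tmap(rng.normal(size=SHAPE) * 2) for _ in range(3)]
        small = sm.conjunction(maps, 0.01)
        large = sm.conjunction(maps, 0.10)
        assert np.all(large.data.astype(bool) | ~small.data.astype(bool))

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="at least two"):
            sm.conjunction([tmap(np.zeros(SHAPE))], 0.01)
        with pytest.raises(ValueError, match="df policy"):
            sm.conjunction([tmap(np.zeros(SHAPE), df=10), tmap(np.zeros(SHAPE), df=20)], 0.01)


def _subject_betas(rng, amplitudes, n_subjects=20, noise=0.2, shape=SHAPE):
    """Per-subject contrast images with planted per-(segment, modality) ROI
    amplitudes; ROIs are disjoint 2x2x2 blocks."""
    rois = {}
    for i, seg in enumerate(SEGMENTS):
        for j, mod in enumerate(MODALITIES):
            m = np.zeros(shape, dtype=bool)
            m[2 * i : 2 * i + 2, 4 * j : 4 * j + 2, 2:4] = True
            rois[(seg, mod)] = m
    betas = {}
    for key, roi in rois.items():
        signal = np.where(roi, amplitudes.get(key, 0.0), 0.0)
        betas[key] = [
            StatMap(signal + rng.normal(0, noise, size=shape), np.eye(4), "beta") for _ in range(n_subjects)
        ]
    return betas, rois


class TestSegmentSpecific:
    def test_identical_signal_cancels(self, rng):
        """When all eight contrast maps are identical per subject, the
        target-minus-others contrast is exactly zero and the map is empty."""
        shared = [StatMap(rng.normal(1.0, 0.5, size=SHAPE), np.eye(4), "beta") for _ in range(8)]
        betas = {(s, m): list(shared) for s in SEGMENTS for m in MODALITIES}
        binary, _ = sm.segment_specific_map("hands", betas, 0.001, None)
        assert binary.count() == 0

    def test_planted_dominant_segment_recovered(self, rng):
        amplitudes = {(s, m): 1.0 for s in SEGMENTS for m in MODALITIES}
        for m in MODALITIES:
            amplitudes[("hands", m)] = 2.0
        betas, rois = _subject_betas(rng, amplitudes, n_subjects=20)
        binary, _ = sm.segment_specific_map("hands", betas, 0.001, 0.05, n_permutations=200,
                                            rng=np.random.default_rng(0))
        hand_roi = rois[("hands", "motor")] | rois[("hands", "tactile")]
        got = binary.data.astype(bool)
        # cluster-extent inference may admit the odd boundary voxel adjacent
        # to the true cluster, but essentially everything lies in the ROI
        assert np.count_nonzero(got & ~hand_roi) <= 2
        assert np.count_nonzero(got & hand_roi) >= 0.9 * hand_roi.sum()

    def test_negated_data_yields_empty_one_sided_map(self, rng):
        amplitudes = {("hands", m): 2.0 for m in MODALITIES}
        betas, rois = _subject_betas(rng, amplitudes, n_subjects=10)
        negated = {k: [StatMap(-m.data, m.affine, "beta") for m in v] for k, v in betas.items()}
        binary, _ = sm.segment_specific_map("hands", negated, 0.001, None)
        hand_roi = rois[("hands", "motor")] | rois[("hands", "tactile")]
        # one-sided: the (negative) planted effect never survives; anything
        # left is the expected p<0.001 false-positive trickle in pure noise
        assert not np.any(binary.data.astype(bool) & hand_roi)
        assert binary.count() <= 2

    def test_missing_contrast_rejected(self, rng):
        betas, _ = _subject_betas(rng, {}, n_subjects=4)
        del betas[("feet", "tactile")]
        with pytest.raises(ValueError, match="missing"):
            sm.segment_specific_map("hands", betas, 0.001, None)


class TestMotorTactilePartition:
    def test_equal_modalities_give_empty_partition(self, rng):
        """With motor data identical to tactile data the difference contrast
        is exactly zero, so both partition maps are empty."""
        per_seg = {s: [StatMap(rng.normal(1.0, 0.5, size=SHAPE), np.eye(4), "beta") for _ in range(10)]
                   for s in SEGMENTS}
        betas = {(s, m): list(per_seg[s]) for s in SEGMENTS for m in MODALITIES}
        whole = StatMap(np.ones(SHAPE, dtype=np.uint8), np.eye(4), "binary")
        motor, tactile = sm.motor_tactile_partition(betas, whole, 0.001)
        assert motor.count() == 0 and tactile.count() == 0

    def test_planted_motor_roi_lands_in_motor_map(self, rng):
        amplitudes = {(s, "motor"): 1.0 for s in SEGMENTS}
        betas, rois = _subject_betas(rng, amplitudes, n_subjects=20, noise=0.1)
        whole = StatMap(np.ones(SHAPE, dtype=np.uint8), np.eye(4), "binary")
        motor, tactile = sm.motor_tactile_partition(betas, whole, 0.001)
        motor_rois = np.zeros(SHAPE, dtype=bool)
        for s in SEGMENTS:
            motor_rois |= rois[(s, "motor")]
        assert np.count_nonzero(motor.data.astype(bool) & motor_rois) >= 0.9 * motor_rois.sum()
        assert not np.any(tactile.data.astype(bool) & motor_rois)

    def test_outputs_disjoint_and_match_sign_oracle(self, rng):
        amplitudes = {(s, m): rng.uniform(0.5, 2.0) for s in SEGMENTS for m in MODALITIES}
        betas, _ = _subject_betas(rng, amplitudes, n_subjects=15)
        whole = StatMap(np.ones(SHAPE, dtype=np.uint8), np.eye(4), "binary")
        motor, tactile = sm.motor_tactile_partition(betas, whole, 0.01)
        assert not np.any(motor.data.astype(bool) & tactile.data.astype(bool))
        # voxelwise oracle: sign of the mean difference decides the side
        dmaps = sm.motor_minus_tactile_maps(betas)
        mean_diff = np.mean([m.data for m in dmaps], axis=0)
        assert np.all(mean_diff[motor.data.astype(bool)] > 0)
        assert np.all(mean_diff[tactile.data.astype(bool)] < 0)


class TestOverlapResolution:
    def test_shared_voxels_assigned_to_larger_t(self):
        a = np.zeros(SHAPE)
        b = np.zeros(SHAPE)
        a[0:4] = 5.0
        b[2:6] = 7.0  # overlap in rows 2:4, where b wins
        bin_a = StatMap((a > 0).astype(np.uint8), np.eye(4), "binary")
        bin_b = StatMap((b > 0).astype(np.uint8), np.eye(4), "binary")
        out = sm.resolve_segment_overlaps(
            {"face": bin_a, "hands": bin_b}, {"face": tmap(a), "hands": tmap(b)}
        )
        assert not np.any(out["face"].data.astype(bool) & out["hands"].data.astype(bool))
        assert np.all(out["hands"].data[2:4].astype(bool))
        assert not np.any(out["face"].data[2:4].astype(bool))
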