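"""Dice / HD95 oracles, empty-mask conventions, ET post-processing."""

import numpy as np
import pytest

from wfseg.errors import InvalidLabelError
from wfseg.io_pipeline import MultimodalVolume, save_case
from wfseg.metrics import (
    EMPTY_SENTINEL,
    dice_score,
    evaluate_cases,
    evaluate_pair,
    hd95,
    postprocess_et,
    surface_voxels,
)


def brute_force_hd(pred, truth, spacing=(1.0, 1.0, 1.0), percentile=95.0):
    """All-pairs Euclidean oracle on surface voxel coordinates."""
    p = np.argwhere(surface_voxels(pred)) * np.asarray(spacing)
    q = np.argwhere(surface_voxels(truth)) * np.asarray(spacing)
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(-1))
    return max(
        np.percentile(d.min(axis=1), percentile),
        np.percentile(d.min(axis=0), percentile),
    )


def random_blob(rng, shape=(20, 20, 20), n_seeds=3, radius=3.0):
    grid = np.indices(shape).transpose(1, 2, 3, 0)
    mask = np.zeros(shape, dtype=bool)
    margin = radius + 2
    for _ in range(n_seeds):
        c = rng.uniform(margin, np.array(shape) - margin)
        mask |= ((grid - c) ** 2).sum(-1) <= radius**2
    return mask


class TestDiceScore:
    def test_identical_nonempty(self, rng):
        m = random_blob(rng)
        assert dice_score(m, m) == 1.0

    def test_disjoint_nonempty(self):
        a = np.zeros((5, 5, 5), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, 0] = b[4, 4, 4] = True
        assert dice_score(a, b) == 0.0

    def test_confusion_count_substitution(self):
        pred = np.zeros((4, 4, 4), dtype=bool)
        truth = np.zeros_like(pred)
        truth.ravel()[:5] = True  # TP=3, FN=2
        pred.ravel()[2:6] = True  # overlap 3 (idx 2,3,4), FP=1 (idx 5)
        assert dice_score(pred, truth) == pytest.approx(6 / 9)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), dtype=bool)
        assert dice_score(z, z) == 1.0

    def test_symmetry_and_monotonicity(self, rng):
        a, b = random_blob(rng), random_blob(rng)
        assert dice_score(a, b) == dice_score(b, a)
        # adding a true-positive voxel never decreases the score
        missing = np.argwhere(b & ~a)
        if len(missing):
            a2 = a.copy()
            a2[tuple(missing[0])] = True
            assert dice_score(a2, b) >= dice_score(a, b)


class TestHd95:
    def test_identical_masks_zero(self, rng):
        m = random_blob(rng)
        assert hd95(m, m) == 0.0

    def test_two_voxels_axis_distance(self):
        a = np.zeros((9, 9, 9), dtype=bool)
        b = np.zeros_like(a)
        a[4, 4, 2] = True
        b[4, 4, 5] = True
        assert hd95(a, b) == pytest.approx(3.0)

    def test_empty_conventions(self, rng):
        z = np.zeros((5, 5, 5), dtype=bool)
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        assert hd95(z, z) == 0.0
        assert hd95(m, z) == EMPTY_SENTINEL
        assert hd95(z, m) == EMPTY_SENTINEL

    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (1.0, 0.5, 2.0)])
    def test_matches_all_pairs_oracle(self, rng, spacing):
        for _ in range(5):
            a, b = random_blob(rng), random_blob(rng)
            assert hd95(a, b, spacing) == pytest.approx(
                brute_force_hd(a, b, spacing), abs=1e-6
            )

    def test_symmetry_and_translation_invariance(self, rng):
        a, b = random_blob(rng), random_blob(rng)
        assert hd95(a, b) == hd95(b, a)
        shift = (1, 1, 1)
        a2, b2 = np.roll(a, shift, (0, 1, 2)), np.roll(b, shift, (0, 1, 2))
        # blobs stay interior, so rolling is a rigid translation
        assert hd95(a2, b2) == pytest.approx(hd95(a, b), abs=1e-9)

    def test_percentile_100_is_classic_hausdorff(self, rng):
        a, b = random_blob(rng), random_blob(rng)
        assert hd95(a, b, percentile=100) == pytest.approx(
            brute_force_hd(a, b, percentile=100), abs=1e-6
        )


class TestPostprocessEt:
    def make_labels(self, n_et):
        labels = np.zeros((20, 20, 20), dtype=np.int16)
        labels[:10] = 2
        labels[:5, :5] = 1
        flat = np.argwhere(labels == 2)
        for i in range(n_et):
            labels[tuple(flat[i])] = 4
        return labels

    def test_small_et_relabeled_to_necrosis(self):
        labels = self.make_labels(199)
        out = postprocess_et(labels, threshold=200)
        assert (out == 4).sum() == 0
        assert (out == 1).sum() == (labels == 1).sum() + 199

    def test_threshold_is_strict(self):
        labels = self.make_labels(200)
        np.testing.assert_array_equal(postprocess_et(labels, threshold=200), labels)

    def test_no_et_is_identity(self):
        labels = self.make_labels(0)
        np.testing.assert_array_equal(postprocess_et(labels), labels)

    def test_wt_and_tc_membership_preserved(self):
        labels = self.make_labels(150)
        out = postprocess_et(labels, threshold=200)
        from wfseg.io_pipeline import encode_regions

        before, after = encode_regions(labels), encode_regions(out)
        np.testing.assert_array_equal(before.wt, after.wt)
        np.testing.assert_array_equal(before.tc, after.tc)

    def test_per_component_mode(self):
        labels = np.zeros((20, 20, 20), dtype=np.int16)
        labels[1:3, 1:3, 1:3] = 4  # 8 voxels
        labels[10:16, 10:16, 10:16] = 4  # 216 voxels
        out = postprocess_et(labels, threshold=100, per_component=True)
        assert (out[1:3, 1:3, 1:3] == 1).all()
        assert (out[10:16, 10:16, 10:16] == 4).all()

    def test_invalid_labels_rejected(self):
        labels = np.full((4, 4, 4), 5, dtype=np.int16)
        with pytest.raises(InvalidLabelError):
            postprocess_et(labels)


class TestEvaluateCases:
    def _write(self, directory, case_id, labels, suffix="seg"):
        import nibabel as nib

        directory.mkdir(parents=True, exist_ok=True)
        nib.save(
            nib.Nifti1Image(labels.astype(np.int16), np.eye(4)),
            directory / f"{case_id}_{suffix}.nii.gz",
        )

    def _labels(self, rng):
        labels = np.zeros((16, 16, 16), dtype=np.int16)
        labels[4:12, 4:12, 4:12] = 2
        labels[6:10, 6:10, 6:10] = 1
        labels[7:9, 7:9, 7:9] = 4
        return labels

    def test_truth_vs_itself_is_perfect(self, tmp_path, rng):
        labels = self._labels(rng)
        self._write(tmp_path / "truth", "caseA", labels)
        self._write(tmp_path / "pred", "caseA", labels, suffix="pred")
        report = evaluate_cases(tmp_path / "pred", tmp_path / "truth")
        for region in ("wt", "tc", "et"):
            assert report.per_case["caseA"][region]["dice"] == 1.0
            assert report.per_case["caseA"][region]["hd95"] == 0.0

    def test_single_case_equals_scalar_ops(self, tmp_path, rng):
        truth = self._labels(rng)
        pred = truth.copy()
        pred[4:6] = 0  # degrade
        self._write(tmp_path / "truth", "c", truth)
        self._write(tmp_path / "pred", "c", pred, suffix="pred")
        report = evaluate_cases(tmp_path / "pred", tmp_path / "truth")
        expected = evaluate_pair(pred, truth)
        assert report.per_case["c"] == expected

    def test_aggregate_mean_matches_hand_average(self, tmp_path, rng):
        truths, preds = [], []
        for i in range(3):
            t = self._labels(rng)
            p = t.copy()
            p[4 : 6 + i] = 0
            self._write(tmp_path / "truth", f"c{i}", t)
            self._write(tmp_path / "pred", f"c{i}", p, suffix="pred")
            truths.append(t)
            preds.append(p)
        report = evaluate_cases(tmp_path / "pred", tmp_path / "truth")
        manual = np.mean([evaluate_pair(p, t)["wt"]["dice"] for p, t in zip(preds, truths)])
        assert report.aggregate["wt"]["dice"]["mean"] == pytest.approx(manual)

    def test_missing_prediction_listed_not_fatal(self, tmp_path, rng):
        self._write(tmp_path / "truth", "present", self._labels(rng))
        self._write(tmp_path / "truth", "absent", self._labels(rng))
        self._write(tmp_path / "pred", "present", self._labels(rng), suffix="pred")
        report = evaluate_cases(tmp_path / "pred", tmp_path / "truth")
        assert report.missing == ["absent"]
        assert not report.complete
        assert "present" in report.per_case

    def test_report_serialization(self, tmp_path, rng):
        labels = self._labels(rng)
        self._write(tmp_path / "truth", "c", labels)
        self._write(tmp_path / "pred", "c", labels, suffix="pred")
        report = evaluate_cases(tmp_path / "pred", tmp_path / "truth")
        report.to_json(tmp_path / "r.json")
        report.to_csv(tmp_path / "r.csv")
        assert (tmp_path / "r.json").exists()
        assert "case" in (tmp_path / "r.csv").read_text().splitlines()[0]
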