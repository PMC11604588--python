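"""Confusion-based metrics, AVD, surface extraction, ASSD, cohort
aggregation — each against an independent brute-force oracle where one
exists."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fusionnet3d.metrics import (ConfusionCounts, VolumePair, confusion,
                                 recall, precision, dice, lfpr, avd, surface,
                                 assd, subject_metrics, evaluate_cohort)


def _loop_confusion(pred, truth, c):
    """Per-voxel Python loop oracle."""
    tp = fp = tn = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p == c and t == c:
            tp += 1
        elif p == c:
            fp += 1
        elif t == c:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


class TestConfusion:
    def test_matches_per_voxel_loop_on_random_volumes(self, rng):
        pred = rng.integers(0, 4, size=(4, 4, 4))
        truth = rng.integers(0, 4, size=(4, 4, 4))
        for c in range(4):
            cc = confusion(pred, truth, c)
            assert (cc.tp, cc.fp, cc.tn, cc.fn) == _loop_confusion(pred, truth, c)
            assert cc.total == pred.size

    def test_perfect_prediction_has_no_errors(self, rng):
        t = rng.integers(0, 4, size=(4, 4, 4))
        cc = confusion(t, t, 2)
        assert cc.fp == 0 and cc.fn == 0

    def test_all_background_prediction_counts_misses(self):
        truth = np.zeros((4, 4, 4), dtype=int)
        truth[:2, 0, 0] = 1  # k = 2 voxels of class 1
        cc = confusion(np.zeros_like(truth), truth, 1)
        assert cc.tp == 0 and cc.fn == 2

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="grid"):
            confusion(np.zeros((2, 2, 2), int), np.zeros((3, 3, 3), int), 0)


class TestRatios:
    def test_hand_computed_counts(self):
        cc = ConfusionCounts(tp=2, fp=1, tn=10, fn=1)
        assert recall(cc) == pytest.approx(2 / 3)
        assert precision(cc) == pytest.approx(2 / 3)
        assert dice(cc) == pytest.approx(4 / 6)

    def test_perfect_prediction_extremes(self):
        cc = ConfusionCounts(tp=5, fp=0, tn=20, fn=0)
        assert (recall(cc), precision(cc), dice(cc), lfpr(cc)) == (1, 1, 1, 0)

    def test_empty_prediction_nonempty_truth_scores_zero(self):
        cc = ConfusionCounts(tp=0, fp=0, tn=20, fn=5)
        assert recall(cc) == 0.0
        assert precision(cc) == 0.0
        assert dice(cc) == 0.0

    def test_undefined_denominators_give_nan(self):
        assert np.isnan(recall(ConfusionCounts(0, 3, 5, 0)))   # truth empty
        assert np.isnan(dice(ConfusionCounts(0, 0, 8, 0)))     # both empty
        assert np.isnan(lfpr(ConfusionCounts(2, 0, 0, 6)))     # truth everywhere
        assert precision(ConfusionCounts(0, 0, 8, 2)) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_dice_is_harmonic_mean_of_precision_and_recall(self, tp, fp, fn):
        cc = ConfusionCounts(tp=tp, fp=fp, tn=5, fn=fn)
        p, r = precision(cc), recall(cc)
        if np.isnan(r) or p + r == 0:
            return
        assert dice(cc) == pytest.approx(2 * p * r / (p + r), abs=1e-12)


class TestAVD:
    def test_matching_volumes_give_zero(self):
        assert avd([VolumePair(100, 100), VolumePair(7, 7)]) == 0.0

    def test_hand_computed_values(self):
        assert avd([VolumePair(150, 100)]) == pytest.approx(0.5)
        assert avd([(50, 100), (200, 100)]) == pytest.approx(0.75)

    def test_zero_truth_pairs_excluded_and_empty_undefined(self):
        assert avd([(5, 0), (150, 100)]) == pytest.approx(0.5)
        assert np.isnan(avd([]))
        assert np.isnan(avd([(5, 0)]))


class TestSurface:
    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        s = surface(m)
        np.testing.assert_array_equal(s.points, [[1, 1, 1]])

    def test_solid_cubes_shed_their_interior(self):
        cube3 = np.ones((3, 3, 3), bool)
        assert len(surface(cube3).points) == 26
        cube5 = np.ones((5, 5, 5), bool)
        assert len(surface(cube5).points) == 5 ** 3 - 3 ** 3

    def test_volume_border_counts_as_outside(self):
        # a full volume's surface is its outer shell, not empty
        m = np.ones((4, 4, 4), bool)
        assert len(surface(m).points) == 4 ** 3 - 2 ** 3

    def test_empty_mask_gives_marked_empty_set(self):
        s = surface(np.zeros((3, 3, 3), bool))
        assert s.empty and s.points.shape == (0, 3)

    def test_spacing_scales_coordinates(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 2, 1] = True
        np.testing.assert_allclose(surface(m, (2.0, 0.5, 1.0)).points,
                                   [[2.0, 1.0, 1.0]])


def _random_mask(rng, shape, p=0.3):
    return rng.random(shape) < p


class TestASSD:
    def test_identical_masks_give_zero(self, rng):
        m = _random_mask(rng, (5, 5, 5))
        m[2, 2, 2] = True
        assert assd(m, m) == 0.0

    def test_two_voxels_three_apart(self):
        a = np.zeros((8, 4, 4), bool)
        b = np.zeros((8, 4, 4), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        assert assd(a, b) == pytest.approx(3.0)

    def test_empty_prediction_is_undefined(self, rng):
        t = _random_mask(rng, (4, 4, 4))
        t[0, 0, 0] = True
        assert np.isnan(assd(np.zeros((4, 4, 4), bool), t))

    def test_symmetry_and_bruteforce_agreement(self, rng):
        for _ in range(10):
            a = _random_mask(rng, (8, 8, 8))
            b = _random_mask(rng, (8, 8, 8))
            if not a.any() or not b.any():
                continue
            sp = tuple(rng.uniform(0.5, 2.0, 3))
            fast = assd(a, b, sp)
            assert fast == pytest.approx(assd(b, a, sp), abs=1e-12)
            assert fast == pytest.approx(assd(a, b, sp, method="brute"),
                                         abs=1e-9)

    def test_doubling_spacing_doubles_assd_only(self, rng):
        a = _random_mask(rng, (6, 6, 6))
        b = _random_mask(rng, (6, 6, 6))
        a[3, 3, 3] = b[2, 2, 2] = True
        assert assd(a, b, (2, 2, 2)) == pytest.approx(2 * assd(a, b, (1, 1, 1)))
        # overlap metrics are spacing-free by construction (voxel counts)
        pred = a.astype(int)
        truth = b.astype(int)
        m1 = subject_metrics(pred, truth, (1, 1, 1), classes=(1,))
        m2 = subject_metrics(pred, truth, (2, 2, 2), classes=(1,))
        for key in ("recall", "precision", "dice", "lfpr", "avd"):
            assert m1[1][key] == pytest.approx(m2[1][key], nan_ok=True)
        assert m2[1]["assd"] == pytest.approx(2 * m1[1]["assd"])

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            assd(np.ones((2, 2, 2), bool), np.ones((3, 3, 3), bool))


class TestCohort:
    def test_single_subject_mean_is_value_sd_zero(self, rng):
        truth = rng.integers(0, 4, size=(6, 6, 6))
        rep = subject_metrics(truth, truth)
        report = evaluate_cohort([rep])
        assert report.summary.loc["ED", "dice_mean"] == pytest.approx(1.0)
        assert report.summary.loc["ED", "dice_sd"] == 0.0

    def test_population_sd_formula(self):
        reps = []
        for val in (0.5, 0.7):
            # synthesize a report with a known dice value
            reps.append({1: {"recall": val, "precision": val, "dice": val,
                             "lfpr": 0.0, "avd": 0.0, "assd": 0.0}})
        rep = evaluate_cohort(reps)
        assert rep.summary.loc["NC", "dice_mean"] == pytest.approx(0.6)
        assert rep.summary.loc["NC", "dice_sd"] == pytest.approx(0.1)

    def test_undefined_entries_excluded_not_contaminating(self):
        reps = [
            {1: {"recall": 0.8, "precision": 0.8, "dice": 0.8, "lfpr": 0.01,
                 "avd": 0.1, "assd": 1.5}},
            {1: {"recall": 0.0, "precision": 0.0, "dice": 0.0, "lfpr": 0.0,
                 "avd": 1.0, "assd": float("nan")}},
        ]
        rep = evaluate_cohort(reps)
        assert rep.summary.loc["NC", "assd_mean"] == pytest.approx(1.5)
        assert rep.summary.loc["NC", "assd_excluded"] == 1
        assert rep.summary.loc["NC", "dice_mean"] == pytest.approx(0.4)

    def test_all_undefined_metric_aggregates_to_nan(self):
        reps = [{1: {"recall": 1.0, "precision": 1.0, "dice": 1.0,
                     "lfpr": 0.0, "avd": 0.0, "assd": float("nan")}}]
        rep = evaluate_cohort(reps)
        assert np.isnan(rep.summary.loc["NC", "assd_mean"])

    def test_csv_export_shape_and_columns(self, tmp_path, rng):
        truth = rng.integers(0, 4, size=(6, 6, 6))
        report = evaluate_cohort([subject_metrics(truth, truth)])
        frame = report.to_csv(tmp_path / "m.csv", method="FusionNet-A")
        assert list(frame["subregion"]) == ["NC", "ED", "ET"]
        assert {"dice", "dice_mean", "dice_sd", "assd"} <= set(frame.columns)
        assert (tmp_path / "m.csv").exists()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            evaluate_cohort([])


def test_ranges_on_random_predictions(rng):
    pred = rng.integers(0, 4, size=(8, 8, 8))
    truth = rng.integers(0, 4, size=(8, 8, 8))
    rep = subject_metrics(pred, truth)
    for c, vals in rep.items():
        for key in ("recall", "precision", "dice", "lfpr"):
            assert np.isnan(vals[key]) or 0.0 <= vals[key] <= 1.0
        for key in ("avd", "assd"):
            assert np.isnan(vals[key]) or vals[key] >= 0.0
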