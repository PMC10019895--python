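import numpy as np
import pytest

from imcseg.io import ChannelStack
from imcseg.metrics import (
    MetricsReport,
    double_positive_rate,
    evaluate,
    jaccard,
    mean_patch_iou,
    nuclei_positivity_threshold,
    real_cell_fraction,
)
from imcseg.postprocessing import remove_anucleate_cells
from imcseg.quantify import cell_intensities
from imcseg.synthetic import default_panel, generate_scene
from tests.conftest import tiny_scene_params


def brute_force_mean_iou(pred, truth):
    """All-pairs overlap computation with explicit pixel sets."""
    truth_ids = sorted(set(truth.ravel()) - {0})
    pred_sets = {
        pid: set(zip(*np.nonzero(pred == pid))) for pid in set(pred.ravel()) - {0}
    }
    ious = []
    for tid in truth_ids:
        t_set = set(zip(*np.nonzero(truth == tid)))
        best_pid, best_inter = None, 0
        for pid in sorted(pred_sets):
            inter = len(t_set & pred_sets[pid])
            if inter > best_inter:
                best_pid, best_inter = pid, inter
        if best_pid is None:
            ious.append(0.0)
        else:
            ious.append(best_inter / len(t_set | pred_sets[best_pid]))
    return float(np.mean(ious))


class TestJaccard:
    def test_identity_is_one(self):
        a = {(0, 0), (1, 1)}
        assert jaccard(a, a) == 1.0

    def test_disjoint_is_zero(self):
        assert jaccard({(0, 0)}, {(5, 5)}) == 0.0

    def test_half_overlap(self):
        a = {(0, 0), (0, 1), (1, 0)}
        b = {(0, 0), (0, 1), (2, 2)}
        assert jaccard(a, b) == 0.5

    def test_symmetry(self, rng):
        for _ in range(10):
            a = (rng.random((8, 8)) > 0.5)
            b = (rng.random((8, 8)) > 0.5)
            if not (a.any() or b.any()):
                continue
            assert jaccard(a, b) == jaccard(b, a)

    def test_accepts_boolean_masks(self):
        a = np.zeros((3, 3), dtype=bool)
        a[0, 0] = True
        assert jaccard(a, a) == 1.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())

    def test_monotone_under_growing_intersection(self):
        # fixed union of 4 pixels, growing intersection
        union = [(0, 0), (0, 1), (1, 0), (1, 1)]
        prev = -1.0
        for k in range(1, 5):
            a = set(union[:k]) | {union[0]}
            b = set(union)
            val = jaccard(a, b)
            assert val >= prev
            prev = val


class TestMeanPatchIoU:
    def test_perfect_prediction(self):
        truth = np.zeros((8, 8), dtype=int)
        truth[1:4, 1:4] = 1
        truth[5:8, 5:8] = 2
        assert mean_patch_iou(truth, truth) == 1.0

    def test_empty_prediction_total_miss(self):
        truth = np.zeros((8, 8), dtype=int)
        truth[1:4, 1:4] = 1
        assert mean_patch_iou(np.zeros_like(truth), truth) == 0.0

    def test_half_matched_fixture(self):
        truth = np.zeros((6, 12), dtype=int)
        truth[0:2, 0:5] = 1    # 10 px, matched at IoU 0.8 below
        truth[4:6, 4:8] = 2    # missed entirely
        pred = np.zeros_like(truth)
        pred[0:2, 0:4] = 1     # 8 px inside cell 1 -> IoU 8/10
        assert mean_patch_iou(pred, truth) == pytest.approx((0.8 + 0.0) / 2)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            mean_patch_iou(np.zeros((4, 4), dtype=int), np.zeros((4, 4), dtype=int))

    def test_agrees_with_brute_force_all_pairs(self, rng):
        from imcseg.postprocessing import label_cells
        for trial in range(10):
            truth = label_cells((rng.random((32, 32)) > 0.7).astype(np.uint8))
            pred = label_cells((rng.random((32, 32)) > 0.7).astype(np.uint8))
            if truth.max() == 0:
                continue
            assert mean_patch_iou(pred, truth) == pytest.approx(
                brute_force_mean_iou(pred, truth), abs=1e-12
            )

    def test_one_iff_identical_partitions(self, rng):
        from imcseg.postprocessing import label_cells
        truth = label_cells((rng.random((16, 16)) > 0.7).astype(np.uint8))
        if truth.max() > 0:
            # same partition, permuted labels
            perm = np.concatenate([[0], rng.permutation(truth.max()) + 1])
            assert mean_patch_iou(perm[truth], truth) == 1.0
            # a merged partition scores below 1
            merged = (truth > 0).astype(int)
            if truth.max() > 1:
                assert mean_patch_iou(merged, truth) < 1.0


def nuclei_fixture(n_cells=10, weak=1):
    """Cells on a strong nuclei field except `weak` cells with none."""
    h = 10 * n_cells
    labels = np.zeros((h, 12), dtype=np.int64)
    nuclei = np.zeros((h, 12))
    for k in range(n_cells):
        labels[10 * k + 2:10 * k + 8, 3:9] = k + 1
        if k >= weak:
            nuclei[10 * k + 2:10 * k + 8, 3:9] = 80.0
    nuclei[0, 0] = 100.0  # sets the grayscale range
    stack = ChannelStack(np.stack([nuclei]).astype(np.uint16), ["DNA"])
    return labels, nuclei, stack


class TestRealCellFraction:
    def test_all_strong_nuclei_is_100(self):
        labels, nuclei, stack = nuclei_fixture(weak=0)
        table = cell_intensities(labels, stack)
        n, pct = real_cell_fraction(table, nuclei, "DNA")
        assert n == 10 and pct == 100.0

    def test_one_of_ten_anucleate_is_90(self):
        labels, nuclei, stack = nuclei_fixture(weak=1)
        table = cell_intensities(labels, stack)
        n, pct = real_cell_fraction(table, nuclei, "DNA")
        assert n == 10 and pct == pytest.approx(90.0)

    def test_uniform_field_counts_all_real(self):
        labels = np.zeros((8, 8), dtype=np.int64)
        labels[1:4, 1:4] = 1
        nuclei = np.full((8, 8), 5.0)
        stack = ChannelStack(np.stack([nuclei]).astype(np.uint16), ["DNA"])
        table = cell_intensities(labels, stack)
        _, pct = real_cell_fraction(table, nuclei, "DNA")
        assert pct == 100.0

    def test_empty_table_rejected(self):
        labels, nuclei, stack = nuclei_fixture()
        table = cell_intensities(np.zeros_like(labels), stack)
        with pytest.raises(ValueError):
            real_cell_fraction(table, nuclei, "DNA")

    def test_removing_anucleate_cells_never_lowers_pct(self, rng):
        for seed in range(3):
            scene = generate_scene(tiny_scene_params(seed=50 + seed,
                                                     anucleate_fraction=0.3))
            nuclei = scene.stack.channel("DNA").astype(float)
            before_tab = cell_intensities(scene.truth, scene.stack)
            _, before = real_cell_fraction(before_tab, nuclei, "DNA")
            from imcseg.postprocessing import otsu_nuclei_threshold
            cleaned = remove_anucleate_cells(scene.truth, nuclei,
                                             otsu_nuclei_threshold(nuclei))
            if cleaned.max() == 0:
                continue
            after_tab = cell_intensities(cleaned, scene.stack)
            _, after = real_cell_fraction(after_tab, nuclei, "DNA")
            assert after >= before


def gating_fixture(n_cells=20, n_double=1):
    """Cells expressing CD3 xor CD20, except `n_double` expressing both."""
    h = 8 * n_cells
    labels = np.zeros((h, 10), dtype=np.int64)
    cd3 = np.zeros((h, 10))
    cd20 = np.zeros((h, 10))
    for k in range(n_cells):
        sl = (slice(8 * k + 1, 8 * k + 7), slice(2, 8))
        labels[sl] = k + 1
        if k < n_double:
            cd3[sl] = 40.0
            cd20[sl] = 40.0
        elif k % 2:
            cd3[sl] = 40.0
        else:
            cd20[sl] = 40.0
    stack = ChannelStack(np.stack([cd3, cd20]).astype(np.uint16), ["CD3", "CD20"])
    return labels, stack


class TestDoublePositive:
    def test_no_cell_above_thresholds(self):
        labels, stack = gating_fixture(n_double=0)
        table = cell_intensities(labels, stack)
        rate = double_positive_rate(table, ("CD3", "CD20"),
                                    {"CD3": 100.0, "CD20": 100.0})
        assert rate == 0.0

    def test_one_in_twenty_is_5pct(self):
        labels, stack = gating_fixture(n_cells=20, n_double=1)
        table = cell_intensities(labels, stack)
        rate = double_positive_rate(table, ("CD3", "CD20"),
                                    {"CD3": 10.0, "CD20": 10.0})
        assert rate == pytest.approx(5.0)

    def test_zero_thresholds_with_signal_everywhere(self):
        labels, stack = gating_fixture(n_cells=4, n_double=4)
        table = cell_intensities(labels, stack)
        rate = double_positive_rate(table, ("CD3", "CD20"),
                                    {"CD3": 0.0, "CD20": 0.0})
        assert rate == 100.0

    def test_otsu_gating_on_bimodal_means(self):
        labels, stack = gating_fixture(n_cells=20, n_double=2)
        table = cell_intensities(labels, stack)
        rate = double_positive_rate(table, ("CD3", "CD20"), "otsu")
        assert rate == pytest.approx(10.0)

    def test_unknown_marker_rejected(self):
        labels, stack = gating_fixture()
        table = cell_intensities(labels, stack)
        with pytest.raises(KeyError):
            double_positive_rate(table, ("CD3", "CD8"))


class TestEvaluate:
    def test_perfect_synthetic_prediction(self):
        scene = generate_scene(tiny_scene_params(seed=21))
        report = evaluate(scene.truth, scene.truth, scene.stack,
                          default_panel(scene.params))
        assert report.mean_iou == 1.0
        assert report.pct_real_cells == 100.0
        assert report.n_cells == scene.n_cells

    def test_anucleate_contamination_lowers_pct_real_and_cleanup_raises_it(self):
        scene = generate_scene(tiny_scene_params(seed=22, n_cells=8,
                                                 anucleate_fraction=0.25))
        panel = default_panel(scene.params)
        raw_report = evaluate(scene.truth, None, scene.stack, panel)
        assert raw_report.pct_real_cells < 100.0
        from imcseg.postprocessing import otsu_nuclei_threshold
        nuclei = scene.stack.channel("DNA").astype(float)
        cleaned = remove_anucleate_cells(scene.truth, nuclei,
                                         otsu_nuclei_threshold(nuclei))
        clean_report = evaluate(cleaned, None, scene.stack, panel)
        assert clean_report.pct_real_cells > raw_report.pct_real_cells

    def test_report_serialization(self, tmp_path):
        report = MetricsReport(n_cells=5, pct_real_cells=80.0,
                               pct_double_positive={("CD3", "CD20"): 0.0},
                               mean_iou=0.9)
        path = tmp_path / "report.txt"
        report.save(path)
        text = path.read_text()
        assert "n_cells\t5" in text
        assert "mean_iou\t0.9" in text
        assert "pct_double_positive_CD3_CD20" in text

    def test_percentage_bounds_enforced(self):
        with pytest.raises(ValueError):
            MetricsReport(n_cells=1, pct_real_cells=120.0)
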