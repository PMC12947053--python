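"""Segmentation metrics and paired Wilcoxon comparison protocol."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import binary_erosion, generate_binary_structure

from sphereseg import (
    bonferroni_threshold,
    compare_methods,
    confusion_metrics,
    dice,
    evaluate_case,
    hd95,
    wilcoxon_signed_rank,
)


def brute_force_hd95(a, b, spacing=(1.0, 1.0, 1.0)):
    """All-pairs surface-distance oracle (max of directed 95th pctiles)."""
    struct = generate_binary_structure(3, 1)

    def surface_points(m):
        surf = m & ~binary_erosion(m, structure=struct, border_value=0)
        return np.argwhere(surf) * np.asarray(spacing)

    pa, pb = surface_points(a.astype(bool)), surface_points(b.astype(bool))
    d_ab = [min(np.linalg.norm(p - q) for q in pb) for p in pa]
    d_ba = [min(np.linalg.norm(q - p) for p in pa) for q in pb]
    return max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))


def blob(shape, center, r):
    g = np.ogrid[: shape[0], : shape[1], : shape[2]]
    m = sum((gi - c) ** 2 for gi, c in zip(g, center)) <= r**2
    return m.astype(np.uint8)


class TestDice:
    def test_identical_and_disjoint(self):
        a = blob((10, 10, 10), (4, 4, 4), 2)
        assert dice(a, a) == 1.0
        b = np.zeros_like(a)
        b[8, 8, 8] = 1
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0, 0, :4] = 1
        b[0, 0, 2:4] = 1
        b[0, 1, :2] = 1
        assert dice(a, b) == pytest.approx(0.5)  # |A|=|B|=4, overlap 2

    def test_symmetry_and_empty_convention(self, rng):
        a = (rng.random((6, 6, 6)) > 0.5).astype(np.uint8)
        b = (rng.random((6, 6, 6)) > 0.5).astype(np.uint8)
        assert dice(a, b) == dice(b, a)
        empty = np.zeros((4, 4, 4), dtype=np.uint8)
        assert dice(empty, empty) == 1.0

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)))


class TestHD95:
    def test_identical_masks_zero(self):
        a = blob((12, 12, 12), (6, 6, 6), 3)
        assert hd95(a, a) == 0.0

    def test_two_voxels_direct_distance(self):
        a = np.zeros((16, 16, 16), dtype=np.uint8)
        b = np.zeros_like(a)
        a[2, 8, 8] = 1
        b[12, 8, 8] = 1
        assert hd95(a, b) == pytest.approx(10.0)

    def test_spacing_aware(self):
        a = np.zeros((8, 8, 8), dtype=np.uint8)
        b = np.zeros_like(a)
        a[2, 4, 4] = 1
        b[6, 4, 4] = 1
        assert hd95(a, b, spacing=(2.0, 1.0, 1.0)) == pytest.approx(8.0)

    def test_matches_all_pairs_oracle(self, rng):
        a = blob((12, 12, 12), (5, 5, 6), 3)
        b = blob((12, 12, 12), (7, 6, 5), 4)
        assert hd95(a, b) == pytest.approx(brute_force_hd95(a, b), abs=1e-9)
        # symmetric under the max-of-directed convention
        assert hd95(a, b) == pytest.approx(hd95(b, a))

    def test_random_blobs_vs_oracle(self, rng):
        a = (rng.random((10, 10, 10)) > 0.7).astype(np.uint8)
        b = (rng.random((10, 10, 10)) > 0.7).astype(np.uint8)
        assert hd95(a, b) == pytest.approx(brute_force_hd95(a, b), abs=1e-9)

    def test_empty_mask_undefined(self):
        a = blob((8, 8, 8), (4, 4, 4), 2)
        assert math.isnan(hd95(a, np.zeros_like(a)))
        assert math.isnan(hd95(np.zeros_like(a), a))


class TestConfusion:
    def test_perfect_prediction(self):
        a = blob((8, 8, 8), (4, 4, 4), 2)
        m = confusion_metrics(a, a)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0
        assert m["accuracy"] == 1.0

    def test_all_ones_prediction(self):
        ref = blob((8, 8, 8), (4, 4, 4), 2)
        m = confusion_metrics(np.ones_like(ref), ref)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_counts_match_voxel_loop_oracle(self, rng):
        a = (rng.random((6, 6, 6)) > 0.5).astype(np.uint8)
        b = (rng.random((6, 6, 6)) > 0.5).astype(np.uint8)
        tp = fp = tn = fn = 0
        for idx in itertools.product(range(6), repeat=3):
            if a[idx] and b[idx]:
                tp += 1
            elif a[idx] and not b[idx]:
                fp += 1
            elif not a[idx] and b[idx]:
                fn += 1
            else:
                tn += 1
        m = confusion_metrics(a, b)
        assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        assert m["specificity"] == pytest.approx(tn / (tn + fp))
        assert m["accuracy"] == pytest.approx((tp + tn) / 216)
        assert tp + fp + tn + fn == a.size

    def test_evaluate_case_bundles_all_metrics(self, rng):
        a = blob((8, 8, 8), (4, 4, 4), 2)
        out = evaluate_case(a, a)
        assert set(out) == {"dsc", "hd95", "sensitivity", "specificity", "accuracy"}
        assert out["dsc"] == 1.0 and out["hd95"] == 0.0


class TestComparison:
    def test_bonferroni_threshold(self):
        assert bonferroni_threshold(0.05, 2) == 0.025
        assert bonferroni_threshold(0.05, 1) == 0.05
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_identical_samples_no_signal(self):
        x = [0.8, 0.7, 0.9, 0.6, 0.75]
        assert wilcoxon_signed_rank(x, x) == 1.0

    def test_all_positive_differences_exact_tail(self):
        """With n strictly positive differences the two-sided exact
        signed-rank p-value is 2 / 2^n."""
        for n in (6, 8, 10):
            x = [1.0 + 0.1 * (i + 1) for i in range(n)]
            y = [1.0] * n
            assert wilcoxon_signed_rank(x, y) == pytest.approx(2.0 / 2**n)

    def test_underpowered_warning(self):
        with pytest.warns(UserWarning, match="underpowered"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.5, 1.0, 2.0])

    def test_compare_methods_table(self):
        idx = pd.Index([f"case{i}" for i in range(8)], name="case")
        base = pd.DataFrame({"dsc": np.linspace(0.6, 0.8, 8)}, index=idx)
        better = base + 0.05
        table = compare_methods({"fused": better, "2d": base, "3d": base}, "fused")
        assert len(table) == 2
        assert np.allclose(table["threshold"], 0.025)
        assert table["p_value"].iloc[0] == pytest.approx(2.0 / 2**8)
        assert bool(table["significant"].iloc[0]) is True

    def test_identical_methods_not_significant(self):
        idx = pd.Index(range(10))
        df = pd.DataFrame({"dsc": np.linspace(0.5, 0.9, 10)}, index=idx)
        table = compare_methods({"fused": df, "2d": df.copy()}, "fused")
        assert not table["significant"].any()
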