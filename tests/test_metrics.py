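"""DSC, HD95, volume statistics, jackknife CIs and Welch testing."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from spectralseg.core import CSF, GM, WM, TissueLabelMap
from spectralseg.metrics import (
    MetricsRecord,
    UndefinedMetricError,
    absolute_avd_summary,
    bland_altman_points,
    bonferroni,
    compare_models,
    dsc,
    evaluate_case,
    hd95,
    jackknife_ci,
    signed_avd,
    summarize,
    volume_of_class,
    welch_test,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def border_oracle(mask):
    """Border voxels via explicit 6-neighbour checks (treats the array edge
    as outside), independent of the erosion-based implementation."""
    border = np.zeros_like(mask, dtype=bool)
    idx = np.argwhere(mask)
    shape = mask.shape
    for i, j, k in idx:
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                border[i, j, k] = True
                break
            if not mask[ni, nj, nk]:
                border[i, j, k] = True
                break
    return border


def hd95_oracle(a, b, spacing):
    """All-pairs brute-force 95th percentile of the pooled bidirectional
    border-to-border distance set."""
    pa = np.argwhere(border_oracle(a)) * np.asarray(spacing)
    pb = np.argwhere(border_oracle(b)) * np.asarray(spacing)
    d = cdist(pa, pb)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95))


def random_mask_pair(rng, max_side=16):
    shape = tuple(int(rng.integers(4, max_side + 1)) for _ in range(3))
    while True:
        a = rng.random(shape) < rng.uniform(0.05, 0.5)
        b = rng.random(shape) < rng.uniform(0.05, 0.5)
        if a.any() and b.any():
            return a, b


# ---------------------------------------------------------------------------
# DSC
# ---------------------------------------------------------------------------

class TestDsc:
    def test_analytic_cases(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[:2] = True
        assert dsc(a, a.copy()) == 1.0
        assert dsc(a, ~a) == 0.0
        assert dsc(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 2), bool)) == 1.0

    def test_counted_overlap(self):
        a = np.zeros(10, dtype=bool)
        b = np.zeros(10, dtype=bool)
        a[[0, 1, 2]] = True
        b[[1, 2, 5]] = True
        assert dsc(a, b) == pytest.approx(2 * 2 / 6)

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_mask_pair(rng, max_side=8)
            assert dsc(a, b) == dsc(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dsc(np.ones((2, 2, 2), bool), np.ones((3, 3, 3), bool))

    def test_perfect_only_for_equal_nonempty_masks(self, rng):
        a, b = random_mask_pair(rng, max_side=6)
        if not np.array_equal(a, b):
            assert dsc(a, b) < 1.0


# ---------------------------------------------------------------------------
# HD95
# ---------------------------------------------------------------------------

class TestHd95:
    def test_identical_masks_give_zero(self, rng):
        a, _ = random_mask_pair(rng)
        assert hd95(a, a.copy(), (1.0, 1.0, 1.0)) == 0.0

    def test_two_single_voxels_five_apart(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[1, 1, 1] = True
        b[6, 1, 1] = True
        assert hd95(a, b, (1.0, 1.0, 1.0)) == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            a, b = random_mask_pair(rng)
            got = hd95(a, b, (1.0, 1.5, 2.0))
            want = hd95_oracle(a, b, (1.0, 1.5, 2.0))
            assert got == pytest.approx(want, abs=1e-9)

    def test_linear_in_spacing(self, rng):
        a, b = random_mask_pair(rng)
        one = hd95(a, b, (1.0, 1.0, 1.0))
        two = hd95(a, b, (2.0, 2.0, 2.0))
        assert two == pytest.approx(2 * one, abs=1e-9)

    def test_symmetry(self, rng):
        a, b = random_mask_pair(rng)
        assert hd95(a, b, (1, 1, 1)) == pytest.approx(hd95(b, a, (1, 1, 1)), abs=1e-12)

    def test_empty_mask_is_undefined(self):
        full = np.ones((4, 4, 4), dtype=bool)
        empty = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(UndefinedMetricError):
            hd95(full, empty, (1, 1, 1))


# ---------------------------------------------------------------------------
# volumes and AVD
# ---------------------------------------------------------------------------

class TestVolumes:
    def test_unit_conversion(self):
        data = np.zeros((10, 10, 10), dtype=np.int16)
        data.ravel()[:1000] = WM
        labels = TissueLabelMap(data, (1.0, 1.0, 1.0))
        assert volume_of_class(labels, WM) == pytest.approx(1.0)  # 1 mL
        assert volume_of_class(labels, CSF) == 0.0

    def test_class_volumes_conserve_grid_volume(self, rng):
        data = rng.integers(0, 4, size=(6, 6, 6)).astype(np.int16)
        labels = TissueLabelMap(data, (2.0, 3.0, 4.0))
        total = sum(volume_of_class(labels, c) for c in range(4))
        assert total == pytest.approx(6 * 6 * 6 * 24 / 1000.0)

    @pytest.mark.parametrize("v_gt,v_model,expected", [
        (100.0, 100.0, 0.0),
        (100.0, 110.0, -10.0),
        (80.0, 60.0, 25.0),
    ])
    def test_signed_avd_substitution(self, v_gt, v_model, expected):
        assert signed_avd(v_gt, v_model) == pytest.approx(expected)

    def test_signed_avd_sign_flips_with_direction(self):
        assert signed_avd(100.0, 90.0) == -signed_avd(100.0, 110.0)

    def test_zero_ground_truth_undefined(self):
        with pytest.raises(UndefinedMetricError):
            signed_avd(0.0, 10.0)


class TestSummaries:
    def records(self, signed):
        return [MetricsRecord(case_id=f"c{i}", tissue="WM", dsc=0.8, hd95_mm=1.0,
                              v_gt_ml=100.0, v_model_ml=100.0 * (1 - s / 100.0),
                              avd_signed_pct=s, avd_abs_pct=abs(s))
                for i, s in enumerate(signed)]

    def test_mean_absolute_avd(self):
        frame = absolute_avd_summary(self.records([10.0, 20.0]))
        wm = frame[frame.tissue == "WM"].iloc[0]
        assert wm.mean_abs_avd_pct == pytest.approx(15.0)
        assert frame[frame.tissue == "all"].iloc[0].mean_abs_avd_pct == pytest.approx(15.0)

    def test_negating_signed_values_leaves_summary_unchanged(self):
        a = absolute_avd_summary(self.records([10.0, -20.0]))
        b = absolute_avd_summary(self.records([-10.0, 20.0]))
        assert a.mean_abs_avd_pct.tolist() == b.mean_abs_avd_pct.tolist()

    def test_single_record_is_its_own_mean(self):
        frame = absolute_avd_summary(self.records([7.5]))
        assert frame[frame.tissue == "WM"].iloc[0].mean_abs_avd_pct == pytest.approx(7.5)

    def test_bland_altman_plot_draws_all_points(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from spectralseg.metrics import plot_bland_altman
        ax = plot_bland_altman(self.records([5.0, -10.0, 2.0]))
        assert sum(len(c.get_offsets()) for c in ax.collections) == 3

    def test_bland_altman_points(self):
        recs = self.records([0.0, 20.0])
        pts = bland_altman_points(recs)
        assert len(pts) == 2
        assert pts.iloc[0].mean_volume_ml == pytest.approx(100.0)
        assert pts.iloc[0].avd_signed_pct == pytest.approx(0.0)
        assert pts.iloc[1].mean_volume_ml == pytest.approx((100.0 + 80.0) / 2)
        assert pts.attrs["mean_line"] == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class TestJackknife:
    def test_constant_sample_gives_zero_width(self):
        lo, hi = jackknife_ci([0.8] * 5)
        assert lo == hi == pytest.approx(0.8)

    def test_interval_contains_mean(self, rng):
        values = rng.normal(size=10)
        lo, hi = jackknife_ci(values)
        assert lo <= values.mean() <= hi

    def test_hand_computed_five_value_sample(self):
        values = [0.8, 0.82, 0.84, 0.86, 0.88]
        # independent hand computation of the delete-one jackknife SE
        n = len(values)
        loo = [(sum(values) - v) / (n - 1) for v in values]
        mbar = sum(loo) / n
        se = math.sqrt((n - 1) / n * sum((m - mbar) ** 2 for m in loo))
        z = 1.959963984540054
        lo, hi = jackknife_ci(values)
        assert lo == pytest.approx(np.mean(values) - z * se, abs=1e-12)
        assert hi == pytest.approx(np.mean(values) + z * se, abs=1e-12)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            jackknife_ci([0.8, 0.9])


class TestWelch:
    def test_identical_samples(self):
        t, dof, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swap_negates_t_keeps_p(self):
        t1, _, p1 = welch_test([1, 2, 3, 4], [2, 3, 4, 6])
        t2, _, p2 = welch_test([2, 3, 4, 6], [1, 2, 3, 4])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_textbook_formula_oracle(self):
        from scipy import stats
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        va, vb = np.var(a, ddof=1) / 4, np.var(b, ddof=1) / 4
        t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(va + vb)
        dof_hand = (va + vb) ** 2 / (va ** 2 / 3 + vb ** 2 / 3)
        p_hand = 2 * stats.t.sf(abs(t_hand), dof_hand)
        t, dof, p = welch_test(a, b)
        assert t == pytest.approx(t_hand, abs=1e-9)
        assert dof == pytest.approx(dof_hand, abs=1e-9)
        assert p == pytest.approx(p_hand, abs=1e-9)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


class TestBonferroni:
    @pytest.mark.parametrize("p,expected", [(0.01, 0.07), (0.2, 1.0), (0.0, 0.0)])
    def test_correction(self, p, expected):
        assert bonferroni(p, m=7) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(1.5)

    def test_corrected_bounds(self, rng):
        for p in rng.uniform(0, 1, size=20):
            corr = bonferroni(float(p))
            assert p <= corr <= 1.0


class TestCompareModels:
    def test_reports_against_reference(self):
        results = {
            "ref": {"WM": [0.84, 0.85, 0.83, 0.86]},
            "other": {"WM": [0.80, 0.81, 0.79, 0.82]},
        }
        reports = compare_models(results, reference="ref")
        assert len(reports) == 1
        r = reports[0]
        assert r.p_corrected == pytest.approx(min(1.0, 7 * r.p_raw))
        assert r.p_corrected >= r.p_raw


# ---------------------------------------------------------------------------
# per-case evaluation
# ---------------------------------------------------------------------------

class TestEvaluateCase:
    def test_perfect_prediction(self, rng):
        data = rng.integers(0, 4, size=(8, 8, 4)).astype(np.int16)
        truth = TissueLabelMap(data, (1.0, 1.0, 2.0))
        records = evaluate_case(TissueLabelMap(data.copy(), truth.spacing), truth,
                                case_id="c0")
        assert [r.tissue for r in records] == ["WM", "GM", "CSF"]
        for r in records:
            assert r.dsc == 1.0
            assert r.hd95_mm == 0.0
            assert r.avd_signed_pct == 0.0
            assert r.v_gt_ml == r.v_model_ml

    def test_missing_class_yields_missing_hd95(self):
        truth_data = np.zeros((6, 6, 4), dtype=np.int16)
        truth_data[2:4, 2:4] = GM
        truth_data[0, 0, 0] = WM
        truth_data[5, 5, 3] = CSF
        pred_data = truth_data.copy()
        pred_data[pred_data == CSF] = 0  # CSF absent from the prediction
        records = evaluate_case(TissueLabelMap(pred_data, (1, 1, 1)),
                                TissueLabelMap(truth_data, (1, 1, 1)))
        csf = [r for r in records if r.tissue == "CSF"][0]
        assert csf.hd95_mm is None
        assert csf.dsc == 0.0

    def test_summarize_has_ci_columns(self, rng):
        data = rng.integers(0, 4, size=(8, 8, 4)).astype(np.int16)
        truth = TissueLabelMap(data, (1.0, 1.0, 1.0))
        records = []
        for i in range(4):
            records.extend(evaluate_case(truth, truth, case_id=f"c{i}"))
        frame = summarize(records)
        assert set(frame.tissue) == {"WM", "GM", "CSF"}
        row = frame[frame.tissue == "WM"].iloc[0]
        assert row.dsc_ci_lo <= row.mean_dsc <= row.dsc_ci_hi
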