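import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atacshift.differential import (
    bh_adjust,
    differential_test,
    global_shift,
    paired_eye_shift,
    three_group_test,
    DifferentialResult,
)
from atacshift.matrix import (
    CountMatrix,
    NormalizedMatrix,
    SampleMeta,
    demo_peaks,
    normalize_counts,
)
from atacshift.simulate import CohortConfig, simulate_cohort


def brute_force_bh(p):
    """Textbook step-up BH: q_i = min_{j>=i} m*p_(j)/j, clipped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust(np.array([0.01])).tolist() == [0.01]

    def test_hand_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert bh_adjust(np.ones(5)).tolist() == [1.0] * 5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(bh_adjust(np.array(pvals)), brute_force_bh(pvals))


def make_counts(raw, library_sizes, stage_codes=None):
    raw = np.asarray(raw)
    stage_codes = stage_codes or [0] * raw.shape[1]
    samples = [
        SampleMeta(sample_id=f"s{i}", library_size=float(sl), stage_code=int(st_))
        for i, (sl, st_) in enumerate(zip(library_sizes, stage_codes))
    ]
    return CountMatrix(demo_peaks(raw.shape[0]), samples, raw)


class TestDifferentialTest:
    def test_identical_groups_have_zero_fold_change(self):
        raw = np.column_stack([[10, 40, 90]] * 4)
        counts = make_counts(raw, [1e7] * 4)
        res = differential_test(counts, ["s0", "s1"], ["s2", "s3"])
        np.testing.assert_allclose(res.log2fc, 0.0, atol=1e-12)
        assert not res.significant.any()

    def test_doubled_counts_give_unit_fold_change_with_pseudocount(self):
        a = np.array([100, 1000])
        raw = np.column_stack([a, a, 2 * a, 2 * a])
        counts = make_counts(raw, [1e7] * 4)
        res = differential_test(counts, ["s0", "s1"], ["s2", "s3"])
        expected = np.log2((2 * a + 0.5) / (a + 0.5))
        np.testing.assert_allclose(res.log2fc, expected, rtol=1e-12)

    def test_antisymmetric_in_group_order(self, small_cohort):
        counts, _ = small_cohort
        ga = [s.sample_id for s in counts.samples if s.stage_code == 0]
        gb = [s.sample_id for s in counts.samples if s.stage_code == 2]
        ab = differential_test(counts, ga, gb)
        ba = differential_test(counts, gb, ga)
        np.testing.assert_allclose(ab.log2fc, -ba.log2fc, atol=1e-10)
        np.testing.assert_allclose(ab.pvalue, ba.pvalue, atol=1e-10)

    def test_type_i_error_on_null_cohort(self, null_cohort):
        counts, _ = null_cohort
        ga = [s.sample_id for s in counts.samples if s.stage_code == 0]
        gb = [s.sample_id for s in counts.samples if s.stage_code > 0]
        res = differential_test(counts, ga, gb)
        rate = float((res.pvalue < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / len(res.pvalue))
        assert abs(rate - 0.05) < 3 * se

    @pytest.mark.parametrize(
        "ga,gb", [([], ["s1"]), (["s0"], []), (["s0", "s1"], ["s1", "s2"])]
    )
    def test_bad_groups_rejected(self, ga, gb):
        counts = make_counts(np.ones((2, 4), dtype=int), [1e7] * 4)
        with pytest.raises(ValueError):
            differential_test(counts, ga, gb)

    def test_planted_effects_are_detected(self, small_cohort):
        counts, truth = small_cohort
        ga = [s.sample_id for s in counts.samples if s.stage_code == 0]
        gb = [s.sample_id for s in counts.samples if s.stage_code == 2]
        res = differential_test(counts, ga, gb)
        strong = truth.alpha1 < -0.5  # two-stage shift > 1 in log2
        assert res.significant[strong].mean() > 0.5
        assert (res.log2fc[strong] < 0).mean() > 0.95


class TestThreeGroupTest:
    def test_identical_groups_not_significant(self):
        raw = np.column_stack([[10, 40]] * 6)
        counts = make_counts(raw, [1e7] * 6, stage_codes=[0, 0, 1, 1, 2, 2])
        df = three_group_test(counts, [["s0", "s1"], ["s2", "s3"], ["s4", "s5"]])
        assert not df["significant"].any()

    def test_constructed_gradient_peak_is_found(self):
        rng = np.random.default_rng(3)
        values = np.full((20, 9), 8.0) + rng.normal(0, 0.05, size=(20, 9))
        values[0, 0:3] = 10.0
        values[0, 3:6] = 8.0
        values[0, 6:9] = 6.0
        samples = [SampleMeta(sample_id=f"s{i}") for i in range(9)]
        norm = NormalizedMatrix(demo_peaks(20), samples, values)
        groups = [["s0", "s1", "s2"], ["s3", "s4", "s5"], ["s6", "s7", "s8"]]
        df = three_group_test(norm, groups)
        assert df["significant"].tolist() == [True] + [False] * 19
        assert df.loc[0, "contrast_1_vs_0"] == "decreased"
        assert df.loc[0, "contrast_2_vs_1"] == "decreased"

    def test_label_permutation_on_null_yields_no_hits(self, null_cohort):
        counts, _ = null_cohort
        rng = np.random.default_rng(9)
        ids = [s.sample_id for s in counts.samples]
        perm = list(rng.permutation(ids))
        groups = [perm[:8], perm[8:16], perm[16:]]
        df = three_group_test(counts, groups)
        assert df["significant"].sum() <= len(df) * 0.005

    def test_empty_group_rejected(self):
        counts = make_counts(np.ones((2, 3), dtype=int), [1e7] * 3)
        with pytest.raises(ValueError):
            three_group_test(counts, [["s0"], [], ["s1"]])


def make_result(log2fc, mean_signal=None):
    log2fc = np.asarray(log2fc, float)
    if mean_signal is None:
        mean_signal = np.linspace(5, 9, len(log2fc))
    return DifferentialResult(
        peak=[f"p{i}" for i in range(len(log2fc))],
        mean_signal=np.asarray(mean_signal, float),
        log2fc=log2fc,
        pvalue=np.full(len(log2fc), 0.5),
        fdr=np.full(len(log2fc), 0.5),
    )


class TestGlobalShift:
    def test_all_negative_gives_one(self):
        assert global_shift(make_result([-0.1, -2.0, -0.5])).frac_reduced == 1.0

    def test_tie_convention(self):
        summary = global_shift(make_result([-1.0, -1.0, 1.0, 0.0]))
        assert summary.n_reduced == 2
        assert summary.n_ties == 1
        assert summary.frac_reduced == 0.5

    def test_order_invariance(self, rng):
        fc = rng.normal(size=200)
        a = global_shift(make_result(fc))
        perm = rng.permutation(200)
        b = global_shift(make_result(fc[perm]))
        assert a.frac_reduced == b.frac_reduced

    def test_curve_tracks_binned_means(self):
        fc = np.array([-1.0, -1.0, 2.0, 2.0])
        summary = global_shift(make_result(fc, mean_signal=[1, 1, 9, 9]), n_bins=2)
        np.testing.assert_allclose(summary.mean_fc_curve["mean_log2fc"], [-1.0, 2.0])

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            global_shift(make_result([1.0]), n_bins=0)


class TestPairedEyeShift:
    def make_norm(self, values):
        values = np.asarray(values, float)
        samples = [SampleMeta(sample_id=f"s{i}") for i in range(values.shape[1])]
        return NormalizedMatrix(demo_peaks(values.shape[0]), samples, values)

    def test_identical_sample_gives_only_ties(self):
        norm = self.make_norm(np.column_stack([[5.0, 6.0], [5.0, 6.0]]).T)
        summary = paired_eye_shift(norm, "s0", "s0")
        assert summary.n_reduced == 0
        assert summary.n_ties == summary.n_peaks

    def test_uniform_decrease_gives_one(self):
        right = np.array([5.0, 6.0, 7.0])
        norm = self.make_norm(np.column_stack([right - 1.0, right]))
        assert paired_eye_shift(norm, "s0", "s1").frac_reduced == 1.0

    def test_unknown_sample_rejected(self):
        norm = self.make_norm(np.zeros((2, 2)))
        with pytest.raises(KeyError):
            paired_eye_shift(norm, "s0", "nope")

    def test_symmetric_replicates_split_evenly(self):
        from atacshift.simulate import paired_eye_meta

        meta = paired_eye_meta(0, 0, seed=5)
        cfg = CohortConfig(n_peaks=2000, samples=meta, fraction_affected=0.0, seed=14)
        counts, _ = simulate_cohort(cfg)
        norm = normalize_counts(counts)
        ids = norm.sample_ids
        frac = paired_eye_shift(norm, ids[0], ids[1]).frac_reduced
        assert 0.45 <= frac <= 0.55
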