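"""Hand-enumerated examples and brute-force oracle agreement for the
evaluation protocol."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hfsnet import metrics as M
import oracles


def _tally(tp, fn, fp=0, slices=None):
    """Minimal CaseTally with one synthetic slice record."""
    recs = slices or [{"slice": 0, "tp": tp, "fn": fn, "fp": fp,
                       "n_pred": tp + fp, "n_ref": tp + fn,
                       "detected_ids": []}]
    return M.CaseTally("c", recs, 1.0, 1, 1, 1, 2.0, 2.0, 1)


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((2, 4, 4), bool)
        a[0, 1:3, 1:3] = True
        assert M.dice(a, a) == 1.0
        assert M.dice(a, np.roll(a, 2, axis=1) & ~a) == 0.0

    def test_counted_example(self):
        a = np.zeros((1, 4, 4), bool)
        b = np.zeros((1, 4, 4), bool)
        a[0, 0, :4] = True   # |A| = 4
        b[0, 0, :2] = True   # |B| = 2, overlap 2
        assert M.dice(a, b) == pytest.approx(2 * 2 / 6)

    def test_symmetric_and_empty_empty(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=(2, 5, 5)) < 0.4
        b = rng.uniform(size=(2, 5, 5)) < 0.4
        assert M.dice(a, b) == M.dice(b, a)
        z = np.zeros((1, 3, 3), bool)
        assert M.dice(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            M.dice(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))


class TestCaseAggregates:
    def test_per_case_mean_and_bounds(self):
        a = np.ones((1, 2, 2), bool)
        z = np.zeros((1, 2, 2), bool)
        cases = [(a, a), (z, a)]
        assert M.dice_per_case(cases) == 0.5
        assert M.dice_per_case([(a, a)]) == 1.0

    def test_global_pooled_example(self):
        # (|A|,|B|,∩) = (4,2,2) and (10,10,10) -> 2*12/26
        a1 = np.zeros((1, 4, 4), bool); a1[0, 0, :4] = True
        b1 = np.zeros((1, 4, 4), bool); b1[0, 0, :2] = True
        a2 = np.zeros((1, 2, 5), bool); a2[0] = True
        cases = [(a1, b1), (a2, a2)]
        assert M.dice_global(cases) == pytest.approx(24 / 26)
        assert M.dice_global(cases) != M.dice_per_case(cases)

    def test_single_case_global_equals_dice(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(size=(3, 6, 6)) < 0.3
        b = rng.uniform(size=(3, 6, 6)) < 0.3
        assert M.dice_global([(a, b)]) == pytest.approx(M.dice(a, b))

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError):
            M.dice_per_case([])
        with pytest.raises(ValueError):
            M.dice_global([])


class TestMatching:
    def test_overlap_above_theta_detected(self):
        ref = np.zeros((1, 6, 6), int)
        ref[0, 1:5, 1:3] = 1          # 8 px
        pred = np.zeros((1, 6, 6), int)
        pred[0, 1, 1] = 1             # dice 2/9 ≈ 0.22 > 0.2
        rec = M.match_instances(pred, ref, 0.2)[0]
        assert rec["tp"] == 1 and rec["fn"] == 0 and rec["fp"] == 0

    def test_overlap_below_theta_is_fn_and_fp(self):
        ref = np.zeros((1, 8, 8), int)
        ref[0, 1:7, 1:5] = 1          # 24 px
        pred = np.zeros((1, 8, 8), int)
        pred[0, 1, 1] = 1             # dice 2/25 = 0.08
        rec = M.match_instances(pred, ref, 0.2)[0]
        assert rec["tp"] == 0 and rec["fn"] == 1 and rec["fp"] == 1

    def test_one_pred_two_refs_matches_higher_dice(self):
        ref = np.zeros((1, 8, 8), int)
        ref[0, 1:4, 1:4] = 1          # 9 px
        ref[0, 5:7, 1:4] = 2          # 6 px
        pred = np.zeros((1, 8, 8), int)
        pred[0, 2:7, 1:4] = 1         # overlaps ref1 (6) and ref2 (6)
        rec = M.match_instances(pred, ref, 0.2)[0]
        # dice with ref2 = 12/21 > dice with ref1 = 12/24
        assert rec["detected_ids"] == [2]
        assert rec["tp"] == 1 and rec["fn"] == 1 and rec["fp"] == 0

    def test_theta_bounds(self):
        z = np.zeros((1, 2, 2), int)
        with pytest.raises(ValueError):
            M.match_instances(z, z, 0.0)
        with pytest.raises(ValueError):
            M.match_instances(z, z, 1.0)


class TestGranularities:
    def test_perfect_prediction_all_ones(self):
        ref = np.zeros((2, 8, 8), int)
        ref[0, 1:4, 1:4] = 1
        ref[1, 2:5, 2:5] = 1
        t = M.tally_case(ref > 0, ref, (2.5, 1.4, 1.4))
        for g in M.GRANULARITIES:
            s, p, f = M.detection_metrics([t], g)
            assert (s, p, f) == (1.0, 1.0, 1.0)

    def test_slice_vs_patient_example(self):
        # slice 0 tumor detected, slice 1 tumor missed
        recs = [{"slice": 0, "tp": 1, "fn": 0, "fp": 0, "n_pred": 1,
                 "n_ref": 1, "detected_ids": [1]},
                {"slice": 1, "tp": 0, "fn": 1, "fp": 0, "n_pred": 0,
                 "n_ref": 1, "detected_ids": []}]
        t = _tally(0, 0, slices=recs)
        assert M.detection_metrics([t], "per_slice")[0] == 0.5
        assert M.detection_metrics([t], "per_patient")[0] == 1.0

    def test_pooled_vs_averaged_example(self):
        tallies = [_tally(10, 0), _tally(0, 10)]
        assert M.detection_metrics(tallies, "per_tumor_volume")[0] == 0.5
        assert M.detection_metrics(tallies, "per_tumor_cut")[0] == 0.5
        tallies.append(_tally(1, 0))
        assert M.detection_metrics(
            tallies, "per_tumor_volume")[0] == pytest.approx(11 / 21)
        assert M.detection_metrics(
            tallies, "per_tumor_cut")[0] == pytest.approx(2 / 3)

    def test_empty_prediction_zero_sensitivity(self):
        ref = np.zeros((2, 8, 8), int)
        ref[0, 1:4, 1:4] = 1
        t = M.tally_case(np.zeros_like(ref), ref, (2.5, 1.4, 1.4))
        for g in M.GRANULARITIES:
            assert M.detection_metrics([t], g)[0] == 0.0


class TestF1:
    def test_equal_inputs(self):
        assert M.f1(0.6, 0.6) == pytest.approx(0.6)

    def test_zero_zero_defined_zero(self):
        assert M.f1(0.0, 0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            M.f1(1.2, 0.5)


class TestMtd:
    def test_identical_zero(self):
        ref = np.zeros((2, 10, 10), int)
        ref[0, 2:8, 4] = 1
        assert M.mtd_mae(ref, ref, (2.5, 1.4, 1.4)) == 0.0

    def test_single_case_difference(self):
        sp = (2.5, 1.4, 1.4)
        ref = np.zeros((1, 64, 64), int)
        ref[0, 10, 10:46] = 1     # 35 px axis = 4.9 cm
        pred = np.zeros((1, 64, 64), int)
        pred[0, 10, 10:31] = 1    # 20 px axis = 2.8 cm
        assert M.mtd_mae(pred, ref, sp) == pytest.approx(
            (35 - 20) * 0.14, abs=1e-9)

    def test_missed_largest_tumor(self):
        sp = (2.5, 1.4, 1.4)
        ref = np.zeros((1, 64, 64), int)
        ref[0, 5, 5:41] = 1       # 35 px ≈ 5 cm
        ref[0, 30, 5:20] = 2      # 14 px ≈ 2 cm
        pred = np.zeros((1, 64, 64), int)
        pred[0, 30, 5:20] = 1     # finds only the small one
        assert M.mtd_mae(pred, ref, sp) == pytest.approx(21 * 0.14, abs=1e-9)

    def test_reference_without_tumor_rejected(self):
        z = np.zeros((1, 4, 4), int)
        with pytest.raises(ValueError):
            M.mtd_mae(z, z, (2.5, 1.4, 1.4))


class TestStratify:
    def _tally_with_mtd(self, mtd, n_tumors=1):
        t = _tally(1, 0)
        t.ref_mtd_cm = mtd
        t.n_ref_tumors = n_tumors
        return t

    def test_boundary_two_cm_goes_to_middle_bin(self):
        strata = M.stratify([self._tally_with_mtd(2.0)], "size_bin")
        assert strata["2-3cm"]["n_cases"] == 1
        assert strata["<2cm"]["n_cases"] == 0

    def test_counts_sum_to_total(self):
        tallies = [self._tally_with_mtd(m) for m in (1.0, 2.5, 3.1, 6.0, 4.9)]
        strata = M.stratify(tallies, "size_bin")
        assert sum(s["n_cases"] for s in strata.values()) == len(tallies)

    def test_single_tumor_only_cohort_flags_empty_stratum(self):
        strata = M.stratify([self._tally_with_mtd(3.0, 1)], "tumor_count")
        assert strata[">1 tumors"]["n_cases"] == 0
        assert np.isnan(strata[">1 tumors"]["dice_global"])
        assert strata["1 tumor"]["n_cases"] == 1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_matching_counts_partition_instances(seed):
    """tp+fn equals the number of reference instances and tp+fp the number
    of predicted components, in every slice."""
    rng = np.random.default_rng(seed)
    from skimage import measure
    ref = measure.label(rng.uniform(size=(3, 10, 10)) < 0.25)
    pred = rng.uniform(size=(3, 10, 10)) < 0.25
    for rec in M.match_instances(pred, ref, 0.2):
        assert rec["tp"] + rec["fn"] == rec["n_ref"]
        assert rec["tp"] + rec["fp"] >= rec["n_pred"] - rec["fp"]


def test_oracle_agreement_small_battery():
    """Spot agreement with the naive implementations (the exhaustive
    50-volume battery runs in the acceptance suite)."""
    rng = np.random.default_rng(42)
    from skimage import measure
    for _ in range(5):
        ref = measure.label(rng.uniform(size=(4, 12, 12)) < 0.2)
        pred = rng.uniform(size=(4, 12, 12)) < 0.2
        mine = M.match_instances(pred, ref, 0.2)
        theirs = oracles.match_slices_bf(pred, ref, 0.2)
        for a, b in zip(mine, theirs):
            assert (a["tp"], a["fp"], a["fn"]) == (b["tp"], b["fp"], b["fn"])
        assert M.dice(pred, ref > 0) == pytest.approx(
            oracles.dice_bf(pred, ref > 0), abs=1e-12)
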