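import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyntac.curves import TacCurve
from dyntac.errors import InvalidInputError, OutOfRangeError
from dyntac.features import (
    CONVENTIONAL_FEATURE_NAMES,
    KINETIC_FEATURE_NAMES,
    auc_t,
    component_features,
    conventional_features,
    extract_feature_vector,
    peak_features,
    roi_mean_tac,
    slope_between,
)
from dyntac.kinetics import decompose

# frozen naming contract: 14 per ROI (6 C_f, 6 C_b, 2 C_m), tumor block first
GOLDEN_NAMES = (
    "T_Cf_Slope_10_30", "T_Cf_AUC_T", "T_Cf_Slope_0_max", "T_Cf_Slope_max_60",
    "T_Cf_Time_TM", "T_Cf_TAC_max",
    "T_Cb_Slope_10_30", "T_Cb_AUC_T", "T_Cb_Slope_0_max", "T_Cb_Slope_max_60",
    "T_Cb_Time_TM", "T_Cb_TAC_max",
    "T_Cm_Slope_0_max", "T_Cm_TAC_max",
    "BM_Cf_Slope_10_30", "BM_Cf_AUC_T", "BM_Cf_Slope_0_max", "BM_Cf_Slope_max_60",
    "BM_Cf_Time_TM", "BM_Cf_TAC_max",
    "BM_Cb_Slope_10_30", "BM_Cb_AUC_T", "BM_Cb_Slope_0_max", "BM_Cb_Slope_max_60",
    "BM_Cb_Time_TM", "BM_Cb_TAC_max",
    "BM_Cm_Slope_0_max", "BM_Cm_TAC_max",
)


def tent_curve():
    """Rise 0->4 over [0,20], fall to 1 at 65."""
    return TacCurve([0.0, 20.0, 65.0], [0.0, 4.0, 1.0])


class TestRoiMeanTac:
    def test_identical_voxels_unchanged(self):
        c = tent_curve()
        out = roi_mean_tac([c, c, c])
        np.testing.assert_array_equal(out.values, c.values)

    def test_two_voxel_average(self):
        a = TacCurve([0, 1], [0.0, 0.0])
        b = TacCurve([0, 1], [2.0, 2.0])
        assert roi_mean_tac([a, b]).values == pytest.approx([1.0, 1.0])

    def test_random_voxels_match_direct_summation(self):
        rng = np.random.default_rng(0)
        t = np.arange(28.0)
        curves = [TacCurve(t, rng.normal(size=28)) for _ in range(50)]
        out = roi_mean_tac(curves)
        brute = sum(c.values for c in curves) / 50.0
        np.testing.assert_allclose(out.values, brute, rtol=0, atol=1e-12)

    def test_mismatched_grids_raise(self):
        with pytest.raises(InvalidInputError):
            roi_mean_tac([TacCurve([0, 1], [1, 1]), TacCurve([0, 2], [1, 1])])


class TestSlopeBetween:
    def test_constant_curve_zero_slope(self):
        c = TacCurve([0.0, 65.0], [2.0, 2.0])
        assert slope_between(c) == 0.0

    def test_affine_curve_exact(self):
        c = TacCurve([0.0, 65.0], [1.0, 1.0 + 0.3 * 65])
        assert slope_between(c, 10, 30) == pytest.approx(0.3)

    def test_declining_curve_negative_sign(self):
        # sign convention must match a negative published-style cutoff
        c = TacCurve([0.0, 65.0], [5.0, 5.0 - 0.02 * 65])
        assert slope_between(c, 10, 30) < 0

    def test_out_of_support_anchor_raises(self):
        c = TacCurve([15.0, 65.0], [1.0, 2.0])
        with pytest.raises(OutOfRangeError):
            slope_between(c, 10, 30)


class TestAucT:
    def test_constant_curve(self):
        c = TacCurve([0.0, 65.0], [3.0, 3.0])
        assert auc_t(c) == pytest.approx(195.0)

    def test_two_samples(self):
        assert auc_t(TacCurve([0.0, 1.0], [0.0, 2.0])) == pytest.approx(1.0)

    def test_matches_interval_accumulation_oracle(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 65, 28))
        v = rng.uniform(0, 10, 28)
        c = TacCurve(t, v)
        brute = sum((v[i] + v[i + 1]) / 2 * (t[i + 1] - t[i]) for i in range(27))
        assert auc_t(c) == pytest.approx(brute, rel=1e-14)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 65, 28)
        a = TacCurve(t, rng.normal(size=28))
        b = TacCurve(t, rng.normal(size=28))
        s = TacCurve(t, a.values + b.values)
        assert auc_t(s) == pytest.approx(auc_t(a) + auc_t(b), rel=1e-12)


class TestPeakFeatures:
    def test_monotone_curve_peaks_at_end(self):
        t = np.linspace(0, 65, 28)
        pf = peak_features(TacCurve(t, t**1.5))
        assert pf["Time_TM"] == pytest.approx(65.0)
        assert pf["Slope_max_60"] == 0.0  # peak at/after the 60-min anchor

    def test_tent_curve_closed_form(self):
        pf = peak_features(tent_curve())
        assert pf["TAC_max"] == 4.0
        assert pf["Time_TM"] == 20.0
        assert pf["Slope_0_max"] == pytest.approx(0.2)
        v60 = 4.0 + (1.0 - 4.0) * (60.0 - 20.0) / (65.0 - 20.0)
        assert pf["Slope_max_60"] == pytest.approx((v60 - 4.0) / 40.0)

    def test_peak_at_first_sample_gives_zero_rise(self):
        c = TacCurve([0.0, 30.0, 65.0], [5.0, 1.0, 0.5])
        assert peak_features(c)["Slope_0_max"] == 0.0

    def test_peak_tie_earliest_wins(self):
        c = TacCurve([0.0, 10.0, 20.0, 65.0], [0.0, 3.0, 3.0, 1.0])
        assert peak_features(c)["Time_TM"] == 10.0

    def test_short_curve_raises_for_max60(self):
        with pytest.raises(OutOfRangeError):
            peak_features(TacCurve([0.0, 10.0, 50.0], [0.0, 2.0, 1.0]))

    def test_dense_grid_oracle(self):
        t = np.linspace(0, 65, 6501)
        v = t * np.exp(-t / 15.0)
        c = TacCurve(t, v)
        pf = peak_features(c)
        i = np.argmax(v)  # brute-force dense re-computation
        assert pf["TAC_max"] == v[i]
        assert pf["Time_TM"] == t[i]
        assert pf["Slope_0_max"] == pytest.approx((v[i] - v[0]) / (t[i] - t[0]))


class TestResamplingInvariance:
    def test_operators_stable_under_denser_sampling(self):
        t280 = np.linspace(0.1, 65, 280)
        t2800 = np.linspace(0.1, 65, 2800)
        f = lambda t: 8 * t * np.exp(-t / 12.0) + 0.5
        coarse = component_features(TacCurve(t280, f(t280)))
        fine = component_features(TacCurve(t2800, f(t2800)))
        for k in ("Slope_10_30", "AUC_T", "TAC_max", "Slope_0_max", "Slope_max_60"):
            assert coarse[k] == pytest.approx(fine[k], rel=5e-3, abs=1e-4)


class TestExtractFeatureVector:
    def _components_from(self, cohort, fits, pid):
        comp = {}
        for roi, fit in fits[pid].items():
            cb, cf, cm = decompose(fit)
            comp[roi] = {"Cf": cf, "Cb": cb, "Cm": cm}
        return comp

    def test_frozen_names_and_count(self, small_cohort, small_cohort_fits):
        pid = small_cohort.patients[0].patient_id
        vec = extract_feature_vector(self._components_from(small_cohort,
                                                           small_cohort_fits, pid))
        assert tuple(vec.index) == GOLDEN_NAMES
        assert tuple(KINETIC_FEATURE_NAMES) == GOLDEN_NAMES
        assert len(vec) == 28
        assert sum(n.startswith("T_") for n in vec.index) == 14
        assert sum(n.startswith("BM_") for n in vec.index) == 14

    def test_all_zero_components_give_zero_features(self):
        t = np.linspace(0.1, 65, 28)
        zero = TacCurve(t, np.zeros(28))
        comp = {roi: {"Cf": zero, "Cb": zero, "Cm": zero}
                for roi in ("tumor", "bone_marrow")}
        vec = extract_feature_vector(comp)
        slopes = [n for n in vec.index if "Slope" in n or "AUC" in n or "max" in n]
        assert all(vec[n] == 0 for n in slopes if "Time" not in n)

    def test_missing_component_named_in_error(self):
        t = np.linspace(0.1, 65, 28)
        zero = TacCurve(t, np.zeros(28))
        comp = {"tumor": {"Cf": zero, "Cb": zero, "Cm": zero},
                "bone_marrow": {"Cf": zero, "Cb": zero}}
        with pytest.raises(InvalidInputError, match="Cm"):
            extract_feature_vector(comp)

    def test_bm_slope_feature_tracks_generator_truth(self, small_cohort, small_cohort_fits):
        got, truth = [], []
        for p in small_cohort.patients:
            vec = extract_feature_vector(
                self._components_from(small_cohort, small_cohort_fits, p.patient_id)
            )
            got.append(vec["BM_Cf_Slope_10_30"])
            truth.append(p.true_slope)
        rho = np.corrcoef(got, truth)[0, 1]
        assert rho > 0.9


class TestConventionalFeatures:
    def test_uniform_phantom(self):
        s = conventional_features([3.0] * 10, [1.0] * 5, voxel_volume_ml=1.0)
        assert s["MTV"] == 10.0
        assert s["TLG"] == pytest.approx(30.0)
        assert tuple(s.index) == CONVENTIONAL_FEATURE_NAMES

    def test_all_subthreshold(self):
        s = conventional_features([1.0, 2.0], [0.5], voxel_volume_ml=2.0)
        assert s["MTV"] == 0.0 and s["TLG"] == 0.0

    def test_random_phantom_matches_count_oracle(self):
        rng = np.random.default_rng(4)
        tv = rng.uniform(0, 8, 200)
        mv = rng.uniform(0, 3, 100)
        s = conventional_features(tv, mv, voxel_volume_ml=0.25)
        n_above = int(np.sum(tv >= 2.5))
        assert s["MTV"] == pytest.approx(n_above * 0.25)
        assert s["TLG"] == pytest.approx(s["MTV"] * tv[tv >= 2.5].mean())
        assert s["T_SUVmin"] <= s["T_SUVmean"] <= s["T_SUVmax"]

    def test_empty_roi_raises(self):
        with pytest.raises(InvalidInputError):
            conventional_features([], [1.0], 1.0)


@settings(max_examples=30, deadline=None)
@given(a=st.floats(-10, 10), s=st.floats(-1, 1))
def test_slope_affine_identity_property(a, s):
    t = np.linspace(0, 65, 66)
    c = TacCurve(t, a + s * t)
    assert slope_between(c, 10, 30) == pytest.approx(s, abs=1e-9)
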