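"""Expression ratios, binned distributions, landmarks and K-S comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneutx import (
    KaryotypeSpec,
    assign_cis_trans,
    build_ratio_distribution,
    classify_dosage_response,
    cpm_normalize,
    dosage_landmarks,
    expression_ratio,
    filter_low_expression,
    find_distribution_peaks,
    ks_compare,
    simulate_landmark_dataset,
    varied_arms,
)

from _oracles import ks_statistic_bruteforce
from conftest import make_matrix


class TestCisTrans:
    def test_varied_arm_is_cis(self, trisomy_pair):
        case, control = trisomy_pair
        loc = assign_cis_trans(["2L", "X", "3R"], case, control)
        assert list(loc) == ["cis", "trans", "trans"]

    def test_unknown_arm_errors(self, trisomy_pair):
        case, control = trisomy_pair
        with pytest.raises(ValueError, match="Y"):
            assign_cis_trans(["Y"], case, control)

    def test_all_cis_when_every_arm_varied(self):
        control = KaryotypeSpec("c", {"2L": 2, "X": 2})
        case = KaryotypeSpec("t", {"2L": 3, "X": 3}, control_genotype="c")
        assert set(assign_cis_trans(["2L", "X"], case, control)) == {"cis"}


class TestExpressionRatio:
    def _cpm(self, case_vals, ctrl_vals, features):
        vals = {}
        for i, col in enumerate(zip(*case_vals)):
            vals[f"case{i}"] = list(col)
        for i, col in enumerate(zip(*ctrl_vals)):
            vals[f"ctrl{i}"] = list(col)
        genos = {k: ("case" if k.startswith("case") else "ctrl") for k in vals}
        return make_matrix(vals, features, genos, unit="cpm")

    def test_identity(self):
        m = self._cpm([[10.0, 10.0]], [[10.0, 10.0]], ["f"])
        rt = expression_ratio(m, ["case0", "case1"], ["ctrl0", "ctrl1"])
        assert rt.table["ratio"].iloc[0] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        m = self._cpm([[30.0, 30.0, 30.0]], [[20.0, 20.0, 20.0]], ["f"])
        rt = expression_ratio(m, ["case0", "case1", "case2"], ["ctrl0", "ctrl1", "ctrl2"])
        assert rt.table["ratio"].iloc[0] == pytest.approx(1.5)

    def test_zero_control_dropped_and_counted(self):
        m = self._cpm([[5.0], [5.0]], [[0.0], [10.0]], ["dead", "ok"])
        rt = expression_ratio(m, ["case0"], ["ctrl0"])
        assert rt.n_dropped == 1
        assert list(rt.table["feature_id"]) == ["ok"]

    def test_empty_group_errors(self):
        m = self._cpm([[1.0]], [[1.0]], ["f"])
        with pytest.raises(ValueError):
            expression_ratio(m, [], ["ctrl0"])

    def test_requires_normalized_unit(self):
        m = make_matrix({"a": [1.0], "b": [1.0]}, ["f"])
        with pytest.raises(ValueError, match="normalized"):
            expression_ratio(m, ["a"], ["b"])


class TestRatioDistribution:
    def test_exact_one_falls_in_right_open_bin(self):
        d = build_ratio_distribution([1.0, 1.0, 1.0])
        i = int(np.floor(1.0 / 0.1))
        assert d.percent[i] == 100.0

    def test_hand_binning(self):
        d = build_ratio_distribution([0.05, 0.15, 0.15, 0.95])
        assert d.percent[0] == 25.0 and d.percent[1] == 50.0 and d.percent[9] == 25.0

    def test_overflow_pooled_at_cap(self):
        d = build_ratio_distribution([0.5, 3.0, 7.2], cap=3.0)
        assert d.percent[-1] == pytest.approx(100 * 2 / 3)

    def test_empty_and_nonpositive_error(self):
        with pytest.raises(ValueError):
            build_ratio_distribution([])
        with pytest.raises(ValueError):
            build_ratio_distribution([1.0, -0.5])

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_percent_sums_to_100(self, ratios):
        d = build_ratio_distribution(ratios)
        assert np.isclose(d.percent.sum(), 100.0)


class TestKS:
    def test_identical_samples(self):
        r = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert ks_compare([1, 2], [3, 4]).statistic == 1.0

    def test_undersized_errors(self):
        with pytest.raises(ValueError):
            ks_compare([1.0], [1.0, 2.0])

    def test_matches_bruteforce_ecdf_oracle(self, rng):
        """D equals exhaustive ECDF evaluation for many small sample pairs."""
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 7))
            b = rng.normal(size=rng.integers(2, 7))
            assert ks_compare(a, b).statistic == pytest.approx(
                ks_statistic_bruteforce(a, b), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        a, b = rng.normal(size=30), rng.normal(loc=0.4, size=25)
        d1 = ks_compare(a, b).statistic
        d2 = ks_compare(np.exp(a), np.exp(b)).statistic
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestLandmarks:
    def test_trisomy_values(self, trisomy_pair):
        case, control = trisomy_pair
        lm = dosage_landmarks(case, control)["2L"]
        assert lm.dosage_effect == pytest.approx(1.5)
        assert round(lm.inverse, 2) == 0.67
        assert lm.compensation == 1.0

    def test_monosomy(self):
        control = KaryotypeSpec("c", {"2L": 2})
        case = KaryotypeSpec("m", {"2L": 1}, control_genotype="c")
        lm = dosage_landmarks(case, control)["2L"]
        assert (lm.dosage_effect, lm.inverse) == (0.5, 2.0)

    def test_not_aneuploid_errors(self):
        k = KaryotypeSpec("c", {"2L": 2})
        with pytest.raises(ValueError, match="not aneuploid"):
            dosage_landmarks(k, k)

    @given(st.integers(1, 6), st.integers(1, 6))
    @settings(derandomize=True)
    def test_effect_times_inverse_is_one(self, case_dose, control_dose):
        if case_dose == control_dose:
            return
        control = KaryotypeSpec("c", {"A": control_dose})
        case = KaryotypeSpec("t", {"A": case_dose}, control_genotype="c")
        lm = dosage_landmarks(case, control)["A"]
        assert lm.dosage_effect * lm.inverse == pytest.approx(1.0)


class TestClassifyDosageResponse:
    @pytest.fixture
    def lm(self, trisomy_pair):
        return dosage_landmarks(*trisomy_pair)["2L"]

    def test_exact_landmarks(self, lm):
        assert classify_dosage_response(1.0, "cis", lm) == "compensated"
        assert classify_dosage_response(1.0, "trans", lm) == "unchanged"
        assert classify_dosage_response(1.5, "cis", lm) == "dosage_effect"
        assert classify_dosage_response(1.5, "trans", lm) == "direct"

    def test_nearest_landmark_on_log_scale(self, lm):
        # |log(0.68/0.667)| = 0.020 < |log(0.68/1.0)| = 0.386
        assert classify_dosage_response(0.68, "trans", lm) == "inverse"

    def test_outside_all_windows_is_other(self, lm):
        assert classify_dosage_response(1.22, "cis", lm, rel_tol=0.10) == "other"

    def test_nonpositive_ratio_errors(self, lm):
        with pytest.raises(ValueError):
            classify_dosage_response(0.0, "cis", lm)


class TestPeaks:
    def test_unimodal_planted_peak(self):
        # 30 ratios at 0.7-0.8, 10 spread elsewhere
        ratios = [0.75] * 30 + [0.35] * 5 + [1.25] * 5
        pk = find_distribution_peaks(build_ratio_distribution(ratios))
        assert pk.iloc[0]["bin_center"] == pytest.approx(0.75)
        assert bool(pk.iloc[0]["distinct"])

    def test_flat_distribution_flagged(self):
        ratios = [0.05, 0.15, 0.25, 0.35]  # one per bin: no local max
        pk = find_distribution_peaks(build_ratio_distribution(ratios, cap=0.4))
        assert not bool(pk.iloc[0]["distinct"])

    def test_bimodal_tie_prefers_smaller_ratio(self):
        ratios = [0.75] * 40 + [1.05] * 40 + [0.45] * 10 + [1.45] * 10
        pk = find_distribution_peaks(build_ratio_distribution(ratios))
        assert pk.iloc[0]["bin_center"] == pytest.approx(0.75)
        assert pk.iloc[1]["bin_center"] == pytest.approx(1.05)


class TestLandmarkConvergence:
    """Planted-class medians converge to the analytic landmarks."""

    @pytest.mark.parametrize(
        "klass, location, landmark",
        [("inverse", "trans", 2 / 3), ("dosage_effect", "cis", 1.5),
         ("compensated", "cis", 1.0)],
    )
    def test_median_within_001_of_landmark(self, klass, location, landmark):
        # the per-run median has sampling SD ~0.004-0.008 under these
        # conditions, so the 0.01 band is checked on the mean of the medians
        # of eight independent simulations (SE ~0.002)
        meds, pooled = [], []
        for seed in range(8):
            counts, cs, ct, tids, _ = simulate_landmark_dataset(
                klass, location, n_features=2000, seed=seed
            )
            cpm = cpm_normalize(filter_low_expression(counts, 5.0))
            rt = expression_ratio(cpm, cs, ct)
            ratios = rt.table.set_index("feature_id").loc[tids, "ratio"]
            meds.append(float(np.median(ratios)))
            pooled.append(ratios.to_numpy())
        assert abs(np.mean(meds) - landmark) < 0.01
        # the modal bin of the pooled histogram sits at (or, for a landmark on
        # a bin edge, one bin below — ratio distributions are right-skewed so
        # the mode lies slightly left of the median) the landmark
        top = find_distribution_peaks(
            build_ratio_distribution(np.concatenate(pooled))
        ).iloc[0]
        assert abs(top["bin_center"] - landmark) <= 0.1
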