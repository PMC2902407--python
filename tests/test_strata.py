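import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirqc import (
    Stratum,
    assign_strata,
    assign_stratum,
    duplicate_agreement,
    fit_smoothing_spline,
    stratum_counts,
)
from mirqc.errors import DomainError, FitError

from conftest import make_matrix

ABUNDANCE_RANK = {"high": 2, "medium": 1, "low": 0}


class TestAssignStratum:
    @pytest.mark.parametrize(
        "ct,expected",
        [
            (29.99, Stratum.HIGH),
            (30.0, Stratum.MEDIUM),   # medium is closed: [30, 35]
            (35.0, Stratum.MEDIUM),
            (35.01, Stratum.LOW),
            (40.0, Stratum.LOW),      # censored ceiling lands in low
            (0.5, Stratum.HIGH),
        ],
    )
    def test_boundary_placement(self, ct, expected):
        assert assign_stratum(ct) is expected

    @pytest.mark.parametrize("ct", [0.0, -1.0, 40.5])
    def test_out_of_range_is_domain_error(self, ct):
        with pytest.raises(DomainError):
            assign_stratum(ct)

    @settings(max_examples=100, derandomize=True)
    @given(
        ct1=st.floats(0.01, 40.0),
        ct2=st.floats(0.01, 40.0),
    )
    def test_monotone_in_abundance(self, ct1, ct2):
        if ct1 > ct2:
            ct1, ct2 = ct2, ct1
        s1, s2 = assign_stratum(ct1), assign_stratum(ct2)
        assert ABUNDANCE_RANK[s1.value] >= ABUNDANCE_RANK[s2.value]

    def test_vectorised_matches_scalar_and_keeps_nan(self):
        vals = [25.0, 30.0, 36.0, np.nan]
        out = assign_strata(vals)
        assert list(out[:3]) == ["high", "medium", "low"]
        assert out[3] is None


class TestDuplicateAgreement:
    def test_point_arithmetic_and_ceiling_exclusion(self):
        frame = pd.DataFrame(
            {"r1": [25.0, 40.0, 33.0], "r2": [25.4, 33.0, 40.0]},
            index=["miR-1", "miR-2", "miR-3"],
        )
        res = duplicate_agreement(make_matrix(frame), "r1", "r2")
        assert len(res) == 1
        pt = res.points.iloc[0]
        assert pt["mean_ct"] == pytest.approx(25.2)
        assert pt["abs_diff"] == pytest.approx(0.4)
        assert res.n_dropped == 2

    def test_symmetric_in_plates(self, conc_study):
        matrix, _ = conc_study
        ab = duplicate_agreement(matrix, "conc200-r1", "conc200-r2")
        ba = duplicate_agreement(matrix, "conc200-r2", "conc200-r1")
        pd.testing.assert_frame_equal(ab.points, ba.points)

    def test_identical_plates_have_zero_differences(self):
        frame = pd.DataFrame(
            {"r1": [25.0, 33.0], "r2": [25.0, 33.0]}, index=["miR-1", "miR-2"]
        )
        res = duplicate_agreement(make_matrix(frame), "r1", "r2")
        assert (res.points["abs_diff"] == 0).all()


class TestSmoothingSpline:
    def test_reproduces_noise_free_linear_trend(self):
        x = np.linspace(20, 40, 60)
        pts = pd.DataFrame({"mean_ct": x, "abs_diff": 0.01 * x})
        fit = fit_smoothing_spline(pts)
        assert np.allclose(fit.predict(x), 0.01 * x, atol=1e-3)

    def test_constant_data_gives_constant_curve(self):
        x = np.linspace(22, 38, 40)
        pts = pd.DataFrame({"mean_ct": x, "abs_diff": np.full_like(x, 0.7)})
        fit = fit_smoothing_spline(pts)
        assert np.allclose(fit.predict(x), 0.7, atol=1e-6)

    def test_rising_variability_above_the_knee(self, conc_study):
        # Ct-dependent duplicate noise: fitted |dCt| at mean Ct 37 must
        # exceed the fitted value at mean Ct 25.
        matrix, _ = conc_study
        res = duplicate_agreement(matrix, "conc200-r1", "conc200-r2")
        fit = fit_smoothing_spline(res.points)
        lo, hi = fit.predict([25.0, 37.0])
        assert hi > lo

    def test_too_few_points_or_narrow_span_raise(self):
        few = pd.DataFrame({"mean_ct": [25.0, 26.0, 27.0], "abs_diff": [0.1] * 3})
        with pytest.raises(FitError):
            fit_smoothing_spline(few)
        narrow = pd.DataFrame(
            {"mean_ct": np.linspace(30, 31.5, 20), "abs_diff": np.zeros(20)}
        )
        with pytest.raises(FitError):
            fit_smoothing_spline(narrow)


class TestStratumCounts:
    def test_single_condition_direct_counts(self):
        frame = pd.DataFrame({"s1": [25.0, 32.0, 38.0]}, index=list("abc"))
        counts = stratum_counts(make_matrix(frame), {"g": ["s1"]})
        assert counts["g"].tolist() == [1, 1, 1]  # low, medium, high

    def test_two_identical_conditions_average_to_the_same(self):
        frame = pd.DataFrame(
            {"s1": [25.0, 32.0, 38.0], "s2": [25.0, 32.0, 38.0]},
            index=list("abc"),
        )
        m = make_matrix(frame)
        one = stratum_counts(m, {"g": ["s1"]})
        both = stratum_counts(m, {"g": ["s1", "s2"]})
        assert one["g"].tolist() == both["g"].tolist()

    def test_half_counts_round_half_up(self):
        # high counts 3 and 4 across the group's two conditions -> 3.5 -> 4
        frame = pd.DataFrame(
            {
                "s1": [25.0, 26.0, 27.0, 36.0],
                "s2": [25.0, 26.0, 27.0, 28.0],
            },
            index=list("abcd"),
        )
        counts = stratum_counts(make_matrix(frame), {"g": ["s1", "s2"]})
        assert counts.at["high", "g"] == 4

    def test_partition_into_strata_is_complete(self, clinical_study):
        matrix, _ = clinical_study
        counts = stratum_counts(
            matrix, {c: [c] for c in matrix.condition_ids}
        )
        assert (counts.sum(axis=0) == len(matrix.mir_ids)).all()

    def test_mean_ct_aggregation_stratifies_the_assay_mean(self):
        # one assay at 29 and 33: mean 31 -> medium only
        frame = pd.DataFrame({"s1": [29.0], "s2": [33.0]}, index=["miR-1"])
        counts = stratum_counts(
            make_matrix(frame), {"g": ["s1", "s2"]}, aggregation="mean_ct"
        )
        assert counts["g"].tolist() == [0, 1, 0]

    def test_ordered_median_agreement_across_strata(self, conc_study):
        # duplicate spread medians must order low > medium > high
        matrix, _ = conc_study
        res = duplicate_agreement(matrix, "conc200-r1", "conc200-r2")
        strata = assign_strata(res.points["mean_ct"])
        med = res.points.groupby(strata.to_numpy())["abs_diff"].median()
        assert med["low"] > med["medium"] > med["high"]
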