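"""Rb+ efflux quantification, Hill fitting, and group comparisons."""

import numpy as np
import pytest
from scipy import stats

from katpscreenlab.efflux import (
    compare_to_control,
    fit_hill,
    fractional_efflux,
    hill_curve,
    ic50_with_sem,
    preprocess,
)
from katpscreenlab.synthetic import PlateSpec, gen_plate


class TestFractionalEfflux:
    @pytest.mark.parametrize(
        "e, l, expected", [(0, 100, 0.0), (50, 50, 0.5), (100, 0, 1.0)]
    )
    def test_definition(self, e, l, expected):
        assert fractional_efflux(e, l) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            fractional_efflux([10.0, 0.0], [10.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fractional_efflux(-1.0, 5.0)


class TestPreprocess:
    def test_noiseless_plate_recovers_hill_over_top(self):
        """After background subtraction and vehicle normalization, fractions
        equal the planted inhibition curve divided by its top plateau."""
        spec = PlateSpec(noise_cv=0.0, seed=0)
        wells, truth = gen_plate(spec)
        table = preprocess(wells, "WT")
        t = truth["hill_truth"]
        for _, row in table.data.iterrows():
            expected = hill_curve(
                row["dose_uM"], t["top"], t["bottom"], t["ic50_uM"], t["slope"]
            ) / t["top"]
            assert row["fraction"] == pytest.approx(expected, abs=1e-12)

    def test_reference_vehicle_normalizes_to_one(self):
        wells, _ = gen_plate(PlateSpec(noise_cv=0.0, seed=1))
        table = preprocess(wells, "WT")
        ref = table.data[
            (table.data["condition"] == "WT") & (table.data["dose_uM"] == 0)
        ]
        assert ref["fraction"].mean() == pytest.approx(1.0)

    def test_background_equal_sample_maps_to_zero(self):
        # a dose so high the channel is fully inhibited: fraction == background
        spec = PlateSpec(
            hill_truth=(0.7, 0.0, 1e-6, 3.0), noise_cv=0.0,
            doses=(0.0, 1.0, 3.0, 10.0, 200.0), seed=2,
        )
        wells, _ = gen_plate(spec)
        table = preprocess(wells, "WT")
        top_dose = table.data[table.data["dose_uM"] == 200.0]
        assert top_dose["fraction"].abs().max() < 1e-9

    def test_missing_untransfected_rejected(self):
        wells, _ = gen_plate(PlateSpec(seed=3))
        with pytest.raises(ValueError, match="untransfected"):
            preprocess(wells[~wells["is_untransfected"]], "WT")

    def test_missing_reference_rejected(self):
        wells, _ = gen_plate(PlateSpec(seed=3))
        with pytest.raises(ValueError, match="reference"):
            preprocess(wells, "not_a_condition")

    def test_second_application_refused(self):
        wells, _ = gen_plate(PlateSpec(seed=4))
        table = preprocess(wells, "WT")
        with pytest.raises(ValueError, match="second application"):
            preprocess(table, "WT")


class TestFitHill:
    DOSES = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0])

    def test_noiseless_parameter_recovery(self):
        y = hill_curve(self.DOSES, 1.0, 0.0, 10.0, 1.0)
        fit = fit_hill(self.DOSES, y)
        assert fit.converged
        assert fit.top == pytest.approx(1.0, rel=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.ic50 == pytest.approx(10.0, rel=1e-6)
        assert fit.slope == pytest.approx(1.0, rel=1e-6)

    def test_midpoint_identity(self):
        fit = fit_hill(self.DOSES, hill_curve(self.DOSES, 0.9, 0.1, 20.0, 1.5))
        assert fit.predict(fit.ic50) == pytest.approx((fit.top + fit.bottom) / 2)

    def test_flat_responses_flagged_nonconverged(self):
        fit = fit_hill(self.DOSES, np.full_like(self.DOSES, 0.8))
        assert not fit.converged

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_hill([1.0, 1.0, 10.0, 10.0, 0.0], [0.9, 0.9, 0.4, 0.4, 1.0])

    @pytest.mark.parametrize("c", [0.1, 3.0, 1000.0])
    def test_dose_scale_equivariance(self, c):
        """Multiplying every dose by c multiplies the fitted IC50 by c."""
        y = hill_curve(self.DOSES, 1.0, 0.05, 12.0, 1.3)
        base = fit_hill(self.DOSES, y)
        scaled = fit_hill(self.DOSES * c, y)
        assert scaled.ic50 == pytest.approx(base.ic50 * c, rel=1e-6)

    def test_vehicle_points_anchor_top(self):
        doses = np.concatenate([[0.0, 0.0], self.DOSES])
        y = hill_curve(doses, 0.95, 0.0, 15.0, 1.0)
        fit = fit_hill(doses, y)
        assert fit.converged and fit.top == pytest.approx(0.95, rel=1e-6)


class TestIc50WithSem:
    DOSES = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0])

    def _replicate(self, ic50):
        return self.DOSES, hill_curve(self.DOSES, 1.0, 0.0, ic50, 1.0)

    def test_identical_replicates_sem_zero(self):
        summary = ic50_with_sem([self._replicate(10.0)] * 3)
        assert summary.sem_ic50 == pytest.approx(0.0, abs=1e-9)

    def test_mean_and_sem_arithmetic(self):
        summary = ic50_with_sem([self._replicate(8.0), self._replicate(12.0)])
        assert summary.mean_ic50 == pytest.approx(10.0, rel=1e-6)
        assert summary.sem_ic50 == pytest.approx(2.0, rel=1e-6)

    def test_nonconvergent_replicate_excluded_with_warning(self):
        flat = (self.DOSES, np.full_like(self.DOSES, 0.5))
        with pytest.warns(UserWarning, match="excluded"):
            summary = ic50_with_sem(
                [self._replicate(8.0), self._replicate(12.0), flat]
            )
        assert summary.excluded == [2] and summary.n_replicates == 2

    def test_fewer_than_two_convergent_rejected(self):
        flat = (self.DOSES, np.full_like(self.DOSES, 0.5))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="fewer than 2"):
                ic50_with_sem([self._replicate(8.0), flat])

    def test_monte_carlo_recovery_from_synthetic_plates(self):
        """Mean estimated IC50 across simulated triplicate experiments lies
        within 10% of the planted 9.23 µM."""
        estimates = []
        for seed in range(30):
            wells, truth = gen_plate(
                PlateSpec(noise_cv=0.05, n_biological=3, seed=seed)
            )
            table = preprocess(wells, "WT")
            reps = [
                (g["dose_uM"].to_numpy(), g["fraction"].to_numpy())
                for _, g in table.data.groupby("biological_rep")
            ]
            estimates.append(ic50_with_sem(reps).mean_ic50)
        assert np.mean(estimates) == pytest.approx(9.23, rel=0.10)


class TestCompareToControl:
    def test_identical_constants_flagged_with_unit_pvalues(self):
        groups = {"ctrl": [1.0, 1.0, 1.0], "a": [1.0, 1.0, 1.0]}
        res = compare_to_control(groups, "ctrl")
        assert res["degenerate"]
        assert (res["comparisons"]["p_adj"] == 1.0).all()

    def test_two_group_dunnett_matches_t_test(self):
        rng = np.random.default_rng(42)
        groups = {
            "ctrl": rng.normal(0, 1, 12),
            "treat": rng.normal(0.8, 1, 12),
        }
        res = compare_to_control(groups, "ctrl", method="dunnett")
        t = stats.ttest_ind(groups["treat"], groups["ctrl"])
        assert res["comparisons"]["p_adj"].iloc[0] == pytest.approx(
            t.pvalue, abs=1e-3
        )

    def test_tukey_all_pairs(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(0, 1, 6) for k in ("ctrl", "a", "b")}
        res = compare_to_control(groups, "ctrl", method="tukey")
        assert len(res["comparisons"]) == 3  # all pairs of 3 groups

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_to_control({"ctrl": [1.0, 2.0], "a": [1.0]}, "ctrl")

    def test_unknown_method_and_missing_control(self):
        groups = {"ctrl": [1.0, 2.0], "a": [1.0, 2.0]}
        with pytest.raises(ValueError):
            compare_to_control(groups, "ctrl", method="bonferroni")
        with pytest.raises(ValueError):
            compare_to_control(groups, "nope")
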