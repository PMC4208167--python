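"""Dynamic S/N statistic and the screening workflow built on it."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from lfaquant.design import assign_factors, get_array
from lfaquant.exceptions import (
    ConfoundedInteractionWarning,
    DegenerateDataError,
    InputError,
)
from lfaquant.taguchi import (
    TaguchiModel,
    anova,
    best_levels,
    fit_dynamic,
    interaction_cells,
    response_table,
    run_response,
    select_optimal,
    significant_factors,
    sn_dynamic,
)

from conftest import CAMERA_LEVEL1, CAMERA_LEVEL2

STANDARDS = np.array([247.0, 249.0, 251.0, 253.0, 255.0])


def brute_force_slope(M, y):
    """Independent oracle: numerically minimize the residual sum of squares."""
    res = minimize_scalar(
        lambda b: float(((y - b * M) ** 2).sum()),
        bracket=(0.0, 2.0),
        method="brent",
        options={"xtol": 1e-14},
    )
    return res.x


# ---------------------------------------------------------------------------
# per-run statistic


class TestFitDynamic:
    def test_identity_data_gives_unit_slope_zero_spread(self):
        beta, sd = fit_dynamic(STANDARDS, STANDARDS)
        assert beta == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_perturbed_standards_match_closed_form_and_grid_oracle(self):
        y = STANDARDS + np.array([1.0, -1.0, 1.0, -1.0, 0.0])
        beta, sd = fit_dynamic(STANDARDS, y)
        assert beta == pytest.approx(0.999987, abs=1e-6)
        assert sd == pytest.approx(1.0000, abs=1e-4)
        assert beta == pytest.approx(brute_force_slope(STANDARDS, y), abs=1e-9)

    def test_exact_proportionality(self):
        beta, sd = fit_dynamic([1.0, 2.0], [2.0, 4.0])
        assert beta == pytest.approx(2.0)
        assert sd == pytest.approx(0.0)

    def test_input_errors(self):
        with pytest.raises(InputError):
            fit_dynamic([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(InputError):
            fit_dynamic([1.0], [1.0])
        with pytest.raises(DegenerateDataError):
            fit_dynamic([0.0, 0.0], [1.0, 2.0])

    def test_intercept_form_recovers_offset_line(self):
        y = 0.9 * STANDARDS + 20.0
        beta, sd = fit_dynamic(STANDARDS, y, through_origin=False)
        assert beta == pytest.approx(0.9)
        assert sd == pytest.approx(0.0, abs=1e-9)


class TestSnDynamic:
    @pytest.mark.parametrize(
        "beta,sd,expected",
        [
            (1.0, 0.1, 20.0),
            # confirmation-run slope/spread pairs evaluated directly
            (1.0037, 0.0063, 44.045),
            (1.0004, 0.0035, 49.122),
        ],
    )
    def test_direct_evaluation(self, beta, sd, expected):
        assert sn_dynamic(beta, sd) == pytest.approx(expected, abs=5e-3)

    def test_perfect_fit_is_unbounded(self):
        assert sn_dynamic(1.0, 0.0) == math.inf
        assert sn_dynamic(2.0, 0.0) == math.inf

    def test_zero_slope_is_an_error(self):
        with pytest.raises(DegenerateDataError):
            sn_dynamic(0.0, 0.1)
        with pytest.raises(InputError):
            sn_dynamic(1.0, -0.1)

    @settings(max_examples=100, derandomize=True)
    @given(
        beta=st.floats(0.1, 10.0),
        sd=st.floats(1e-4, 10.0),
        c=st.floats(0.01, 100.0),
    )
    def test_invariant_under_joint_scaling(self, beta, sd, c):
        assert sn_dynamic(c * beta, c * sd) == pytest.approx(
            sn_dynamic(beta, sd), abs=1e-8
        )

    @settings(max_examples=50, derandomize=True)
    @given(k=st.floats(0.05, 20.0))
    def test_exact_proportionality_is_perfect_fit(self, k):
        beta, sd = fit_dynamic(STANDARDS, k * STANDARDS)
        assert sn_dynamic(beta, sd) == math.inf

    def test_normalized_scale_shifts_sn_by_constant(self):
        y = STANDARDS + np.array([1.0, -1.0, 1.0, -1.0, 0.0])
        raw = run_response(1, STANDARDS, y)
        norm = run_response(1, STANDARDS, y, scale=255.0)
        assert norm.sn_db - raw.sn_db == pytest.approx(20 * math.log10(255), abs=1e-9)
        assert norm.beta == pytest.approx(raw.beta)


# ---------------------------------------------------------------------------
# response table


class TestResponseTable:
    def test_reproduces_published_camera_study(self, l12, camera_run_sn):
        table = response_table(l12, camera_run_sn)
        for label in "ABCDEFGHIJK":
            row = table.table.loc[label]
            assert row["level1_mean"] == pytest.approx(CAMERA_LEVEL1[label], abs=5e-4)
            assert row["level2_mean"] == pytest.approx(CAMERA_LEVEL2[label], abs=5e-4)
        f_row = table.table.loc["F"]
        assert f_row["effect"] == pytest.approx(-7.3609, abs=5e-4)
        assert f_row["range"] == pytest.approx(7.3609, abs=5e-4)
        assert f_row["rank"] == 1
        ranks = {lab: int(table.table.loc[lab, "rank"]) for lab in "AFIK"}
        assert ranks == {"F": 1, "I": 2, "A": 3, "K": 11}

    def test_level_mean_averages_equal_grand_mean(self, l12, camera_run_sn):
        table = response_table(l12, camera_run_sn)
        for label in table.labels:
            mid = (table.level_mean(label, 1) + table.level_mean(label, 2)) / 2
            assert mid == pytest.approx(table.grand_mean, abs=1e-9)
        assert table.grand_mean == pytest.approx(43.3180, abs=5e-4)

    def test_constant_runs_give_zero_effects(self, l12):
        table = response_table(l12, np.full(12, 37.0))
        assert (table.table["effect"] == 0).all()
        assert (table.table["range"] == 0).all()
        assert list(table.table["rank"]) == list(range(1, 12))  # ties keep column order

    def test_length_mismatch_rejected(self, l12):
        with pytest.raises(InputError):
            response_table(l12, np.ones(11))

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_grand_mean_identity_on_random_runs(self, seed):
        array = get_array("L12")
        sn = np.random.default_rng(seed).normal(40.0, 5.0, size=12)
        table = response_table(array, sn)
        for label in table.labels:
            mid = (table.level_mean(label, 1) + table.level_mean(label, 2)) / 2
            assert mid == pytest.approx(table.grand_mean, abs=1e-9)


class TestBestLevels:
    def test_published_best_levels(self, l12, camera_run_sn):
        table = response_table(l12, camera_run_sn)
        best = best_levels(table)
        assert best == {
            "A": 2, "B": 1, "C": 1, "D": 2, "E": 1, "F": 1,
            "G": 1, "H": 2, "I": 2, "J": 2, "K": 1,
        }

    def test_tie_goes_to_level_one(self, l12):
        best = best_levels(response_table(l12, np.zeros(12)))
        assert set(best.values()) == {1}

    def test_single_column_larger_mean_wins(self):
        array = get_array("L4")
        sn = np.where(array.column(0) == 2, 2.0, 1.0)
        assert best_levels(response_table(array, sn))["A"] == 2


# ---------------------------------------------------------------------------
# ANOVA and screening


class TestAnova:
    def test_column_a_sum_of_squares(self, l12, camera_run_sn, camera_assignment):
        table = anova(l12, camera_run_sn, camera_assignment)
        # SS = (n_runs/4) * effect^2 = 3 * 3.1489^2
        assert table.table.loc["A", "sum_sq"] == pytest.approx(29.75, abs=0.01)

    def test_decomposition_factor_plus_error_equals_total(
        self, l12, camera_run_sn, camera_assignment
    ):
        table = anova(l12, camera_run_sn, camera_assignment, pooling="none")
        ss_sum = table.table["sum_sq"].sum() + table.error_ss
        assert ss_sum == pytest.approx(table.total_ss, rel=1e-6)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_decomposition_on_random_runs(self, seed):
        array = get_array("L12")
        assignment = assign_factors(
            [{"id": c, "level1": 1, "level2": 2} for c in "ABCDEFGHIJ"], array
        )
        sn = np.random.default_rng(seed).normal(40.0, 3.0, size=12)
        table = anova(array, sn, assignment, pooling="none")
        assert table.table["sum_sq"].sum() + table.error_ss == pytest.approx(
            table.total_ss, rel=1e-6
        )

    def test_constant_runs_give_zero_ss(self, l12, camera_assignment):
        table = anova(l12, np.full(12, 40.0), camera_assignment)
        assert (table.table["sum_sq"] == 0).all()

    def test_injected_effect_exceeds_95_confidence(self, l12, camera_assignment):
        rng = np.random.default_rng(42)
        x = np.where(l12.column(0) == 2, 0.5, -0.5)
        sn = 40.0 + 8.0 * x + rng.normal(0, 0.5, 12)
        table = anova(l12, sn, camera_assignment)
        assert table.table.loc["A", "confidence"] > 95.0
        assert significant_factors(table)[0] == "A"

    def test_no_error_dof_instructs_pooling(self):
        array = get_array("L4")
        assignment = assign_factors(
            [{"id": c, "level1": 1, "level2": 2} for c in "ABC"], array
        )
        with pytest.raises(InputError, match="pool"):
            anova(array, [1.0, 2.0, 3.0, 4.0], assignment, pooling="none")

    def test_prescreen_pooling_reproduces_published_screening(
        self, l12, camera_run_sn, camera_assignment
    ):
        """Pooling sub-3 dB factors before the F test singles out the
        backlight-compensation, gamma and sharpness factors at >95%."""
        table = anova(l12, camera_run_sn, camera_assignment, pooling=("range-below", 3.0))
        assert set(significant_factors(table)) == {"A", "F", "I"}
        assert significant_factors(table)[0] == "F"  # ordered by descending F


class TestSignificantFactors:
    def test_threshold_filter_and_ordering(self, l12, camera_assignment):
        rng = np.random.default_rng(7)
        xa = np.where(l12.column(0) == 2, 0.5, -0.5)
        xf = np.where(l12.column(5) == 2, 0.5, -0.5)
        sn = 40.0 + 5.0 * xa - 9.0 * xf + rng.normal(0, 0.3, 12)
        table = anova(l12, sn, camera_assignment)
        sig = significant_factors(table, threshold=95.0)
        assert sig[0] == "F" and "A" in sig

    def test_nothing_significant_on_pure_noise_threshold_100(
        self, l12, camera_run_sn, camera_assignment
    ):
        table = anova(l12, camera_run_sn, camera_assignment)
        assert significant_factors(table, threshold=100.0) == []


class TestSelectOptimal:
    def test_published_baseline_preserving_selection(self, l12, camera_run_sn):
        table = response_table(l12, camera_run_sn)
        baseline = {c: 1 for c in "ABCDEFGHIJ"}
        sel = select_optimal(table, ["A", "F", "I"], baseline)
        assert sel.chosen_levels == {
            "A": 2, "B": 1, "C": 1, "D": 1, "E": 1, "F": 1,
            "G": 1, "H": 1, "I": 2, "J": 1,
        }

    def test_additive_prediction_close_to_measured_confirmation(
        self, l12, camera_run_sn
    ):
        table = response_table(l12, camera_run_sn)
        sel = select_optimal(table, ["A", "F", "I"], {c: 1 for c in "ABCDEFGHIJ"})
        assert sel.predicted_sn == pytest.approx(50.5, abs=0.1)

    def test_empty_significant_set_keeps_baseline(self, l12, camera_run_sn):
        table = response_table(l12, camera_run_sn)
        baseline = {c: 1 for c in "ABCDEFGHIJ"}
        sel = select_optimal(table, [], baseline)
        assert sel.chosen_levels == baseline
        assert sel.predicted_sn == pytest.approx(table.grand_mean)

    def test_unknown_factor_rejected(self, l12, camera_run_sn):
        table = response_table(l12, camera_run_sn)
        with pytest.raises(InputError):
            select_optimal(table, ["Z"], {c: 1 for c in "ABCDEFGHIJ"})


class TestInteractionCells:
    def test_additive_runs_have_zero_nonparallelism(self, l12):
        xa = np.where(l12.column(0) == 2, 0.5, -0.5)
        xi = np.where(l12.column(8) == 2, 0.5, -0.5)
        sn = 40.0 + 3.0 * xa + 4.0 * xi
        with pytest.warns(ConfoundedInteractionWarning):
            summary = interaction_cells(l12, sn, 0, 8)
        assert summary.nonparallelism == pytest.approx(0.0, abs=1e-9)

    def test_injected_product_term_recovered(self, l12):
        # brute-force over the four cells: sn = c*xa*xb with +/-1 contrasts
        # puts +/-c in the cells, so the nonparallelism statistic equals 4c
        xa = np.where(l12.column(0) == 2, 1.0, -1.0)
        xb = np.where(l12.column(5) == 2, 1.0, -1.0)
        c = 1.7
        with pytest.warns(ConfoundedInteractionWarning):
            summary = interaction_cells(l12, 40.0 + c * xa * xb, 0, 5)
        assert summary.nonparallelism == pytest.approx(4 * c, abs=1e-9)
        assert summary.confounded

    def test_cell_counts_and_best_cell(self, l12, camera_run_sn):
        with pytest.warns(ConfoundedInteractionWarning):
            summary = interaction_cells(l12, camera_run_sn, 0, 5)
        for la in (1, 2):
            for lb in (1, 2):
                count = ((l12.column(0) == la) & (l12.column(5) == lb)).sum()
                assert count == 3
        # A at its better level 2, gamma (F) at its better level 1
        assert summary.best_cell == (2, 1)

    def test_regular_design_does_not_warn(self):
        import warnings

        array = get_array("L8")
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            interaction_cells(array, np.arange(8.0), 0, 1)

    def test_same_column_rejected(self, l12, camera_run_sn):
        with pytest.raises(InputError):
            interaction_cells(l12, camera_run_sn, 3, 3)


# ---------------------------------------------------------------------------
# model wrapper


class TestTaguchiModel:
    def test_fit_from_measurements_reports_summary(self, l12, camera_assignment):
        rng = np.random.default_rng(0)
        y = STANDARDS + rng.normal(0, 1.0, size=(12, 5))
        model = TaguchiModel.from_measurements(
            l12, STANDARDS, y, camera_assignment, scale=255.0
        )
        results = model.fit()
        assert len(model.run_sn) == 12
        text = results.summary()
        assert "Response table" in text and "ANOVA" in text
        assert results.anova.error_dof >= 1

    def test_response_graph_renders(self, l12, camera_run_sn, camera_assignment):
        import matplotlib

        matplotlib.use("Agg")
        results = TaguchiModel(l12, camera_run_sn, camera_assignment).fit()
        ax = results.plot_response()
        assert len(ax.lines) >= 11  # one segment per column plus grand-mean line

    def test_round_trip_through_results(self, l12, camera_run_sn, camera_assignment):
        results = TaguchiModel(l12, camera_run_sn, camera_assignment).fit()
        sel = results.select_optimal()
        assert set(sel.chosen_levels) == set("ABCDEFGHIJ")
        with pytest.warns(ConfoundedInteractionWarning):
            inter = results.interaction("A", "I")
        assert inter.factor_pair == ("A", "I")
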