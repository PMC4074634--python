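"""Wald intervals, the three prevalence estimators, and verification sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from claimprev import (
    CRITERIA,
    DataError,
    PatternTable,
    PPVEstimate,
    SimulationConfig,
    attach_population,
    deduplicate,
    draw_sample,
    estimate_ppv,
    exact_ci,
    generate_claims,
    generate_verification,
    make_sampling_plan,
    per_100k,
    population_range_for_rate,
    regional_prevalence,
    scale_estimate,
    subgroup_estimate,
    truncate,
    wald_ci,
)
from claimprev.estimation import _largest_remainder


def _verification_frame(confirmed: int, total: int) -> pd.DataFrame:
    flags = np.zeros((total, len(CRITERIA)), dtype=int)
    flags[:confirmed, :5] = 1  # 5 criteria -> confirmed
    frame = pd.DataFrame(flags, columns=list(CRITERIA))
    frame.insert(0, "patient_id", [f"P{i}" for i in range(total)])
    return frame


class TestWaldCI:
    def test_random_sampling_arm_bounds(self):
        low, high = wald_ci(0.6715, 2000)
        assert round(low, 4) == 0.6509
        assert round(high, 4) == 0.6921
        assert truncate(high) == 0.6920  # the 4-decimal truncation convention

    def test_census_arm_bounds(self):
        low, high = wald_ci(0.6983, 3504)
        assert round(low, 4) == 0.6831
        assert round(high, 4) == 0.7135

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_proportion_gives_zero_width(self, p):
        assert wald_ci(p, 57) == (p, p)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0.5, 0)
        with pytest.raises(ValueError):
            wald_ci(1.2, 10)

    @given(k=st.integers(0, 200), n=st.integers(1, 200))
    @settings(derandomize=True, max_examples=50)
    def test_interval_brackets_p_and_stays_in_unit_range(self, k, n):
        k = min(k, n)
        low, high = wald_ci(k / n, n)
        assert 0.0 <= low <= k / n <= high <= 1.0

    def test_exact_interval_option_brackets_the_point_estimate(self):
        low, high = exact_ci(1343, 2000)
        assert low < 1343 / 2000 < high
        # Exact interval is wider than Wald here but close at this n.
        wlow, whigh = wald_ci(1343 / 2000, 2000)
        assert abs(low - wlow) < 0.005 and abs(high - whigh) < 0.005


class TestEstimatePPV:
    def test_counts_give_exact_proportion(self):
        est = estimate_ppv(_verification_frame(1343, 2000))
        assert est.p == 0.6715
        assert est.verified_true == 1343 and est.n == 2000

    def test_all_confirmed_gives_unit_ppv_with_degenerate_ci(self):
        est = estimate_ppv(_verification_frame(50, 50))
        assert (est.p, est.ci_low, est.ci_high) == (1.0, 1.0, 1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError, match="empty"):
            estimate_ppv(_verification_frame(0, 0))

    def test_recovers_design_ppv_within_binomial_error(self, window):
        # Binomial oracle: verification of a simulated sample drawn at a
        # known homogeneous PPV lands within 3 standard errors of it.
        config = SimulationConfig(
            n_patients=4000, count_mode="weights", ppv_mode="homogeneous",
            homogeneous_ppv=0.7, seed=21,
        )
        claims, truth = generate_claims(config)
        patients = deduplicate(claims, window)
        plan = make_sampling_plan(patients, total_override=1500)
        sample = draw_sample(patients, plan, 4)
        est = estimate_ppv(generate_verification(sample, truth, config, seed=5))
        assert abs(est.p - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 1500)


class TestScaleEstimate:
    def test_random_sampling_worked_example(self):
        ppv = PPVEstimate.from_counts(1343, 2000)
        est = scale_estimate(13652, ppv)
        assert est.cases == 9167
        assert est.cases_ci == (8886, 9448)
        truncated = scale_estimate(13652, ppv, ci_digits_mode="truncate")
        assert truncated.cases_ci == (8886, 9447)

    def test_census_worked_example_from_reported_proportion(self):
        ppv = PPVEstimate.from_proportion(0.6983, 3504)
        est = scale_estimate(13652, ppv, method="all_registered")
        assert est.cases == 9533
        assert est.cases_ci == (9326, 9741)

    def test_unit_ppv_is_identity(self):
        ppv = PPVEstimate.from_counts(100, 100)
        assert scale_estimate(4321, ppv).cases == 4321

    def test_monotone_in_p_and_total(self):
        lo = scale_estimate(10000, PPVEstimate.from_counts(60, 100))
        hi = scale_estimate(10000, PPVEstimate.from_counts(70, 100))
        assert lo.cases <= hi.cases
        assert scale_estimate(20000, PPVEstimate.from_counts(60, 100)).cases >= lo.cases


class TestSubgroupEstimate:
    def _table(self, counts, ppv):
        return PatternTable(counts=counts, ppv=ppv)

    def test_published_coefficients_worked_example(self):
        table = self._table(
            {"abc": 7842, "bc": 1672, "ac": 260, "c": 3878},
            {"abc": 0.90, "bc": 0.76, "ac": 0.36, "c": 0.57},
        )
        est = subgroup_estimate(table)
        assert est.cases == 10633
        assert est.cases_ci is None  # no variance available for group PPVs

    def test_unit_ppvs_recover_included_total(self):
        table = self._table(
            {"abc": 10, "bc": 20, "ac": 30, "c": 40, "a": 99},
            {g: 1.0 for g in ("abc", "bc", "ac", "c")},
        )
        assert subgroup_estimate(table).cases == 100  # group "a" excluded

    def test_missing_ppv_for_included_group_rejected(self):
        table = self._table({"abc": 10, "bc": 5, "ac": 2, "c": 1}, {"abc": 0.9})
        with pytest.raises(ValueError, match="bc"):
            subgroup_estimate(table)

    @given(
        counts=st.lists(st.integers(0, 5000), min_size=4, max_size=4),
        p=st.floats(0.0, 1.0, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=50)
    def test_homogeneous_ppv_collapses_to_scaled_total(self, counts, p):
        # Algebraic identity: equal group PPVs make the subgroup estimator
        # a plain PPV scaling of the included-group total.
        total = sum(counts)
        if total == 0:
            return
        table = self._table(
            dict(zip(("abc", "bc", "ac", "c"), counts)),
            {g: p for g in ("abc", "bc", "ac", "c")},
        )
        expected = scale_estimate(total, PPVEstimate.from_proportion(p, 1000)).cases
        assert subgroup_estimate(table).cases == expected


class TestRates:
    def test_per_100k_basics(self):
        assert per_100k(20_000, 100_000_000) == 20.0
        assert per_100k(0, 1_000) == 0.0
        with pytest.raises(ValueError):
            per_100k(1, 0)

    def test_population_back_solving_inverts_rounding(self):
        low, high = population_range_for_rate(9167, 18.8)
        for population in (int(low) + 1, int((low + high) / 2), int(high)):
            assert round(per_100k(9167, population), 1) == 18.8

    def test_attach_population_scales_ci(self):
        est = scale_estimate(13652, PPVEstimate.from_counts(1343, 2000))
        with_pop = attach_population(est, 48_890_000)
        assert round(with_pop.per_100k, 1) == 18.8
        assert with_pop.per_100k_ci[0] < with_pop.per_100k < with_pop.per_100k_ci[1]


class TestSamplingPlan:
    def _patients(self, sizes: dict) -> pd.DataFrame:
        rows = []
        i = 0
        for (region, hospital), size in sizes.items():
            for _ in range(size):
                rows.append((f"P{i}", frozenset({2004}), "a", region, hospital,
                             "rheumatology", "female", 35))
                i += 1
        return pd.DataFrame(rows, columns=[
            "patient_id", "years_billed", "visit_pattern", "region",
            "hospital_type", "department", "sex", "age_at_first_claim"])

    def test_equal_strata_split_evenly(self):
        patients = self._patients({
            ("Seoul", "university_hospital"): 600,
            ("Seoul", "general_hospital"): 600,
            ("Pusan", "university_hospital"): 600,
            ("Pusan", "general_hospital"): 600,
        })
        plan = make_sampling_plan(patients, total_override=2000)
        assert set(plan.targets.values()) == {500}

    def test_hospital_mix_allocation_matches_design(self):
        # Strata proportional to the national hospital mix; a 2000-chart
        # budget allocates (1308, 358, 18, 316) across hospital types.
        patients = self._patients({
            ("Seoul", "university_hospital"): 6540,
            ("Seoul", "general_hospital"): 1790,
            ("Seoul", "local_hospital"): 90,
            ("Seoul", "private_clinic"): 1580,
        })
        plan = make_sampling_plan(patients, total_override=2000)
        by_hospital = {k[1]: v for k, v in plan.targets.items()}
        assert by_hospital == {
            "university_hospital": 1308, "general_hospital": 358,
            "local_hospital": 18, "private_clinic": 316,
        }

    def test_default_fraction_targets_15_percent(self):
        patients = self._patients({("Seoul", "university_hospital"): 1000})
        assert make_sampling_plan(patients).total == 150

    @given(
        sizes=st.lists(st.integers(1, 400), min_size=1, max_size=12),
        fraction=st.floats(0.05, 1.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_largest_remainder_accounting(self, sizes, fraction):
        arr = np.array(sizes, dtype=np.int64)
        total = int(np.floor(fraction * arr.sum()))
        if total == 0:
            return
        alloc = _largest_remainder(arr, total)
        assert alloc.sum() == total
        assert (alloc <= arr).all()
        assert (alloc >= 0).all()

    def test_requested_total_beyond_cohort_rejected(self):
        patients = self._patients({("Seoul", "university_hospital"): 10})
        with pytest.raises(ValueError, match="exceeds"):
            make_sampling_plan(patients, total_override=11)


class TestDrawSample:
    def test_fixed_seed_reproduces_the_sample(self, study_cohort, window):
        patients = deduplicate(study_cohort[0], window)
        plan = make_sampling_plan(patients, total_override=500)
        first = draw_sample(patients, plan, 99)
        second = draw_sample(patients, plan, 99)
        pd.testing.assert_frame_equal(first, second)

    def test_full_stratum_target_returns_whole_stratum(self):
        patients = TestSamplingPlan()._patients({("Jeju", "general_hospital"): 25})
        plan = make_sampling_plan(patients, total_override=25)
        sample = draw_sample(patients, plan, 1)
        assert set(sample["patient_id"]) == set(patients["patient_id"])

    def test_inclusion_frequency_tracks_target_over_size(self):
        # Uniform-sampling oracle: marginal inclusion probability within a
        # stratum is target/size.
        patients = TestSamplingPlan()._patients({("Seoul", "university_hospital"): 100})
        plan = make_sampling_plan(patients, total_override=30)
        hits = np.zeros(100)
        n_draws = 300
        for i in range(n_draws):
            sample = draw_sample(patients, plan, 1000 + i)
            hits[[int(p[1:]) for p in sample["patient_id"]]] += 1
        freq = hits / n_draws
        se = np.sqrt(0.3 * 0.7 / n_draws)
        assert (np.abs(freq - 0.3) < 4 * se).all()


class TestRegionalValidation:
    def test_zero_coded_patients_give_zero_rate(self):
        ppv = PPVEstimate.from_counts(1, 2)
        est = regional_prevalence(0, ppv, 500_000)
        assert est.cases == 0 and est.per_100k == 0.0

    def test_perfect_code_on_whole_population_gives_full_rate(self):
        ppv = PPVEstimate.from_counts(10, 10)
        est = regional_prevalence(500_000, ppv, 500_000)
        assert est.per_100k == 100_000.0

    def test_simulated_island_recovers_truth_within_ci(self, window):
        # Simulation oracle: the regional interval covers the realised
        # true-case rate in most replicates.
        covered = 0
        n_rep = 40
        for rep in range(n_rep):
            config = SimulationConfig(
                n_patients=800, count_mode="weights", ppv_mode="homogeneous",
                homogeneous_ppv=0.72, seed=500 + rep,
            )
            claims, truth = generate_claims(config)
            patients = deduplicate(claims, window)
            plan = make_sampling_plan(patients, total_override=400)
            sample = draw_sample(patients, plan, rep)
            ppv = estimate_ppv(generate_verification(sample, truth, config, seed=rep))
            est = regional_prevalence(len(patients), ppv, 300_000)
            true_rate = truth["true_sle"].sum() / 300_000 * 1e5
            if est.per_100k_ci[0] <= true_rate <= est.per_100k_ci[1]:
                covered += 1
        assert covered >= int(0.85 * n_rep)
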