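import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from biomoneq.population import (
    AgeGroup,
    BmiCategory,
    PopulationSpec,
    Stratum,
    bmi_category,
    generate_population,
    individual_chemical_params,
    resample_to_match,
    yamane_sample_size,
    _ANTHROPOMETRY,
)


class TestYamane:
    def test_eu_population_gives_400(self):
        assert yamane_sample_size(508_000_000, 0.05) == 400

    def test_hand_value(self):
        # 100 / (1 + 100·0.0025) = 80
        assert yamane_sample_size(100, 0.05) == 80

    def test_asymptote_is_inverse_e_squared(self):
        assert yamane_sample_size(1e15, 0.05) == 400

    @given(st.integers(1, 10**9))
    def test_monotone_and_bounded(self, n):
        e = 0.05
        assert yamane_sample_size(n, e) <= yamane_sample_size(n + 1, e)
        assert yamane_sample_size(n, e) <= min(n, math.ceil(1 / e**2))

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValueError):
            yamane_sample_size(1000, 0.0)
        with pytest.raises(ValueError):
            yamane_sample_size(1000, 1.5)


class TestBmiCategory:
    @pytest.mark.parametrize(
        "bmi,group,expected",
        [
            (25.0, AgeGroup.ADULT, BmiCategory.OVERWEIGHT),  # boundary inclusive
            (30.0, AgeGroup.ADULT, BmiCategory.OBESE),
            (24.9, AgeGroup.ADULT, BmiCategory.NORMAL),
            (17.0, AgeGroup.ADULT, BmiCategory.UNDERWEIGHT),
            (16.0, AgeGroup.CHILD, BmiCategory.NORMAL),
            (22.0, AgeGroup.CHILD, BmiCategory.OVERWEIGHT),
            (25.0, AgeGroup.CHILD, BmiCategory.OBESE),
        ],
    )
    def test_boundaries(self, bmi, group, expected):
        assert bmi_category(bmi, group) is expected

    def test_positive_required(self):
        with pytest.raises(ValueError):
            bmi_category(0.0, AgeGroup.ADULT)


class TestGeneratePopulation:
    def test_seeded_determinism(self):
        spec = PopulationSpec(n=25, seed=7)
        a, b = generate_population(spec), generate_population(spec)
        assert [i.bw_kg for i in a] == [i.bw_kg for i in b]
        assert [i.age_years for i in a] == [i.age_years for i in b]

    def test_adult_female_strata(self):
        pop = generate_population(
            PopulationSpec(n=60, stratum=Stratum.ADULT_FEMALE, age_range=(32, 56), seed=1)
        )
        assert len(pop) == 60
        assert all(32 <= i.age_years <= 56 for i in pop)
        assert all(i.sex == "F" for i in pop)
        assert all(i.daily_urine_volume_ml == 1600.0 for i in pop)

    def test_flows_sum_to_cardiac_output(self, adult_pop):
        for ind in adult_pop:
            assert sum(ind.blood_flows_lh.values()) == pytest.approx(
                ind.cardiac_output_lh, abs=1e-6
            )
            assert ind.bmi == pytest.approx(
                ind.bw_kg / (ind.height_cm / 100) ** 2, rel=1e-12
            )

    def test_weight_category_restriction(self):
        pop = generate_population(
            PopulationSpec(
                n=30, stratum=Stratum.ADULT_FEMALE,
                weight_categories=[BmiCategory.OBESE], seed=3,
            )
        )
        assert all(i.bmi >= 30.0 for i in pop)

    def test_child_bw_median_matches_distribution(self):
        """Empirical child BW median vs an independent 200k-draw oracle, 2%."""
        pop = generate_population(
            PopulationSpec(n=10_000, stratum=Stratum.CHILD, age_range=(6, 11),
                           sex_mix={"F": 0.5, "M": 0.5}, seed=11)
        )
        med = np.median([i.bw_kg for i in pop])
        rng = np.random.default_rng(123456)
        a = _ANTHROPOMETRY[Stratum.CHILD]
        h = rng.normal(a["height_mean"], a["height_sd"], 200_000) / 100.0
        bmi = np.exp(rng.normal(np.log(a["bmi_gm"]), np.log(a["bmi_gsd"]), 200_000))
        oracle = np.median(bmi * h**2)
        assert med == pytest.approx(oracle, rel=0.02)

    def test_child_urine_volume_default(self, child_pop):
        assert all(i.daily_urine_volume_ml == 820.0 for i in child_pop)


class TestIndividualChemicalParams:
    def test_identity_multiplier(self, chems, reference_individual):
        merged = individual_chemical_params(reference_individual, chems["BPA"])
        assert merged.clint == chems["BPA"].clint

    def test_multiplier_scales_clint_and_vmax(self, chems, reference_individual):
        reference_individual.clearance_multiplier = 2.0
        merged = individual_chemical_params(reference_individual, chems["BPA"])
        assert merged.clint == pytest.approx(2 * chems["BPA"].clint)
        assert merged.metabolic_steps[0].vmax_invitro == pytest.approx(
            2 * chems["BPA"].metabolic_steps[0].vmax_invitro
        )

    def test_poor_metaboliser_below_median(self, chems, reference_individual):
        merged = individual_chemical_params(
            reference_individual, chems["BPA"], poor_metaboliser=True
        )
        assert merged.clint <= chems["BPA"].clint  # 5th quantile < GM = median

    def test_clearance_quantile_override(self, chems, reference_individual):
        # e.g. a distribution parameter of 0.06 for a poorly cleared phenol
        merged = individual_chemical_params(
            reference_individual, chems["TCS"], poor_metaboliser=True,
            poor_metaboliser_quantile=0.06,
        )
        default = individual_chemical_params(
            reference_individual, chems["TCS"], poor_metaboliser=True
        )
        assert merged.clint > default.clint  # 6th quantile above the 5th


class TestResampleToMatch:
    def test_self_targets_full_population(self, adult_pop):
        bws = np.array([i.bw_kg for i in adult_pop])
        targets = {"min": bws.min(), "max": bws.max(),
                   "median": float(np.median(bws)), "mean": float(bws.mean())}
        subset = resample_to_match(adult_pop, targets, k=len(adult_pop), seed=0)
        assert sorted(i.id for i in subset) == sorted(i.id for i in adult_pop)

    def test_single_individual_retrievable(self, adult_pop):
        target = adult_pop[3].bw_kg
        subset = resample_to_match(
            adult_pop, {"min": target, "max": target, "mean": target}, k=1,
            seed=5, tolerance=1e-9,
        )
        assert subset[0].bw_kg == target

    def test_cohort_style_matching(self):
        pop = generate_population(PopulationSpec(n=500, seed=9))
        bws = np.array([i.bw_kg for i in pop])
        subset = resample_to_match(
            pop, {"mean": float(bws.mean()), "median": float(np.median(bws))},
            k=43, seed=2, tolerance=0.10,
        )
        assert len(subset) == 43
        assert np.mean([i.bw_kg for i in subset]) == pytest.approx(bws.mean(), rel=0.10)

    def test_not_found_is_explicit(self, adult_pop):
        with pytest.raises(LookupError, match="NOT_FOUND"):
            resample_to_match(adult_pop, {"mean": 500.0}, k=5, seed=1, max_attempts=50)
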