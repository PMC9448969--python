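"""Breeder/adult classification, liveness rules and population aggregation."""

import pytest

from pedpop.demography import (
    Bounds,
    DemographicEstimator,
    DemographyConfig,
    ParentCategoryCounts,
    adult_population_bounds,
    apply_liveness_rules,
    breeding_bounds_from_counts,
    classify_adults_no_record,
    classify_breeders,
    density,
    hypothetical_parent_age,
    lineal_descendant_depth,
    minimum_population,
    survival_weight,
)
from pedpop.individuals import AgeEvidence, Individual, Sex
from pedpop.parentage import ParentageAssignment
from pedpop.sibship import HypotheticalParent

CFG = DemographyConfig()


class TestSurvivalWeight:
    def test_female_two_years_unseen(self):
        w = survival_weight(2017, Sex.FEMALE, CFG)
        assert w == pytest.approx(0.8836)
        assert round(w, 2) == 0.88

    def test_seen_in_reference_year(self):
        assert survival_weight(2019, Sex.MALE, CFG) == 1.0

    def test_male_one_year_unseen(self):
        assert survival_weight(2018, Sex.MALE, CFG) == pytest.approx(0.89)

    def test_future_identification_rejected(self):
        with pytest.raises(ValueError):
            survival_weight(2020, Sex.FEMALE, CFG)


class TestHypotheticalAge:
    def test_oldest_offspring_2012(self):
        assert hypothetical_parent_age(2012, CFG) == pytest.approx(14.3)

    def test_offspring_in_reference_year(self):
        assert hypothetical_parent_age(2019, CFG) == pytest.approx(7.3)

    def test_old_anchor_crosses_senescence(self):
        age = hypothetical_parent_age(1996, CFG)
        assert age == pytest.approx(30.3)
        assert age >= CFG.senescence_age_f


class TestBreedingBounds:
    def test_female_aggregation(self):
        b = breeding_bounds_from_counts(ParentCategoryCounts(125, 1, 2, 9.3, 36))
        assert (b.min, b.max) == (128, 173)

    def test_male_aggregation(self):
        b = breeding_bounds_from_counts(ParentCategoryCounts(65, 0, 1, 5.3, 20))
        assert (b.min, b.max) == (66, 91)

    def test_no_extra_parents_collapses_bounds(self):
        b = breeding_bounds_from_counts(ParentCategoryCounts(10, 0, 0, 0.0, 0))
        assert (b.min, b.max) == (10, 10)

    def test_adult_bounds_shift_by_no_record_adults(self):
        breeding = {Sex.FEMALE: Bounds(128, 173), Sex.MALE: Bounds(66, 91)}
        adults = adult_population_bounds(
            breeding,
            {Sex.FEMALE: {f"f{i}" for i in range(27)}, Sex.MALE: {f"m{i}" for i in range(18)}},
        )
        assert (adults[Sex.FEMALE].min, adults[Sex.FEMALE].max) == (155, 200)
        assert (adults[Sex.MALE].min, adults[Sex.MALE].max) == (84, 109)

    def test_empty_no_record_set_leaves_bounds(self):
        breeding = {Sex.FEMALE: Bounds(5, 7), Sex.MALE: Bounds(2, 3)}
        adults = adult_population_bounds(breeding, {})
        assert adults[Sex.FEMALE] == Bounds(5, 7)


class TestDensity:
    @pytest.mark.parametrize(
        "count, area, expected",
        [(449, 1760, 25.5), (449, 1378, 32.6), (0, 1760, 0.0)],
    )
    def test_per_100km2(self, count, area, expected):
        assert round(density(count, area), 1) == expected


def _ind(iid, sex, **kw):
    kw.setdefault("identified_2019_20", True)
    return Individual(id=iid, sex=sex, **kw)


class TestClassification:
    def test_breeder_requires_offspring_and_survey_identification(self):
        mom = _ind("m", Sex.FEMALE, id_years={2019})
        childless = _ind("x", Sex.MALE, id_years={2020})
        off = _ind("o", Sex.FEMALE, birth_year=2015, id_years={2019})
        assignments = [ParentageAssignment("o", mother_id="m")]
        breeders = classify_breeders([mom, childless, off], assignments)
        assert breeders[Sex.FEMALE] == {"m"}
        assert breeders[Sex.MALE] == set()

    def test_adult_from_early_first_identification(self):
        ind = _ind("a", Sex.FEMALE, first_id_year=2014, id_years={2014, 2019})
        adults = classify_adults_no_record([ind], {Sex.FEMALE: set(), Sex.MALE: set()}, CFG)
        assert "a" in adults[Sex.FEMALE]

    def test_adult_from_parent_death_bound(self):
        # father dead 2014 => born at latest 2015 => at least 4 in 2019
        ind = _ind(
            "b", Sex.MALE, max_birth_year=2015, first_id_year=2019, id_years={2019},
            age_evidence=AgeEvidence.PARENT_DEATH,
        )
        adults = classify_adults_no_record([ind], {Sex.FEMALE: set(), Sex.MALE: set()}, CFG)
        assert "b" in adults[Sex.MALE]

    def test_recent_first_identification_insufficient(self):
        ind = _ind("c", Sex.FEMALE, first_id_year=2018, id_years={2018, 2019})
        adults = classify_adults_no_record([ind], {Sex.FEMALE: set(), Sex.MALE: set()}, CFG)
        assert "c" not in adults[Sex.FEMALE]


class TestLivenessRules:
    def test_mother_of_surviving_yearling_counted_minimum(self):
        # cub born 2018, sampled dead at age 1 in 2019: its mother lived to separation
        cub = _ind("cub", Sex.MALE, birth_year=2018, death_year=2019, id_years={2019})
        hyp = HypotheticalParent(id="HYP-F-001", sex=Sex.FEMALE, offspring_ids=("cub",))
        assignments = [ParentageAssignment("cub", mother_id="HYP-F-001")]
        (status,) = apply_liveness_rules([], [hyp], assignments, [cub], CFG)
        assert status.liveness == "counted-minimum"

    def test_father_of_next_year_cub_counted_minimum(self):
        cub = _ind("cub", Sex.FEMALE, birth_year=2020, id_years={2020})
        hyp = HypotheticalParent(id="HYP-M-001", sex=Sex.MALE, offspring_ids=("cub",))
        assignments = [ParentageAssignment("cub", father_id="HYP-M-001")]
        (status,) = apply_liveness_rules([], [hyp], assignments, [cub], CFG)
        assert status.liveness == "counted-minimum"

    def test_senescent_hypothetical_mother_is_dead(self):
        old = _ind("o", Sex.FEMALE, birth_year=1996, id_years={2019})
        hyp = HypotheticalParent(
            id="HYP-F-002", sex=Sex.FEMALE, offspring_ids=("o",),
            anchor_offspring_birth_year=1996,
        )
        assignments = [ParentageAssignment("o", mother_id="HYP-F-002")]
        (status,) = apply_liveness_rules([], [hyp], assignments, [old], CFG)
        assert status.liveness == "dead-senescence"

    def test_deep_matriline_hits_generation_limit(self):
        # living chain of four below the hypothetical mother: she would be a
        # great-great-grandmother and is treated as dead
        chain = []
        assignments = []
        prev = None
        for i, birth in enumerate((2001, 2006, 2011, 2016)):
            iid = f"g{i}"
            chain.append(_ind(iid, Sex.FEMALE, birth_year=birth, id_years={2019}))
            assignments.append(
                ParentageAssignment(iid, mother_id=prev if prev else "HYP-F-003")
            )
            prev = iid
        hyp = HypotheticalParent(
            id="HYP-F-003", sex=Sex.FEMALE, offspring_ids=("g0",),
            anchor_offspring_birth_year=2001,
        )
        (status,) = apply_liveness_rules([], [hyp], assignments, chain, CFG)
        assert status.liveness == "dead-generation-limit"

    def test_monitoring_override(self):
        kid = _ind("k", Sex.FEMALE, birth_year=2010, id_years={2019})
        mom = Individual(id="mom", sex=Sex.FEMALE, last_id_year=2007, first_id_year=2005)
        assignments = [ParentageAssignment("k", mother_id="mom")]
        (status,) = apply_liveness_rules(
            [mom], [], assignments, [kid, mom], CFG, monitoring_dead={"mom"}
        )
        assert status.liveness == "dead-monitoring"

    def test_confirmed_dead_existing_parent_excluded(self):
        kid = _ind("k", Sex.FEMALE, birth_year=2010, id_years={2019})
        mom = Individual(
            id="mom", sex=Sex.FEMALE, first_id_year=2005, last_id_year=2012,
            death_year=2012,
        )
        assignments = [ParentageAssignment("k", mother_id="mom")]
        (status,) = apply_liveness_rules([mom], [], assignments, [kid, mom], CFG)
        assert status.liveness == "dead-confirmed"
        assert status.weight == 0.0


class TestMinimumPopulation:
    def test_death_during_reference_year_still_counts(self):
        ind = _ind("d", Sex.FEMALE, birth_year=2010, death_year=2019, id_years={2019})
        counts, breakdown, audit = minimum_population([ind], [], CFG)
        assert counts[Sex.FEMALE] == 1
        assert breakdown[Sex.FEMALE][">=4"] == 1

    def test_next_year_bear_without_age_evidence_excluded(self):
        ind = _ind("n", Sex.MALE, id_years={2020}, first_id_year=2020, last_id_year=2020)
        counts, _, _ = minimum_population([ind], [], CFG)
        assert counts[Sex.MALE] == 0

    def test_next_year_yearling_with_pedigree_birth_year_included(self):
        ind = _ind(
            "y", Sex.MALE, birth_year=2018, id_years={2020},
            first_id_year=2020, last_id_year=2020,
        )
        counts, breakdown, _ = minimum_population([ind], [], CFG)
        assert counts[Sex.MALE] == 1
        assert breakdown[Sex.MALE]["1"] == 1

    def test_monotone_in_hypothetical_parents(self):
        """Adding an alive hypothetical parent never lowers the maximum."""
        from pedpop.demography import breeding_population_bounds, parent_category_counts
        from pedpop.demography import ParentStatus

        confirmed = {Sex.FEMALE: {"a"}, Sex.MALE: set()}
        base = [ParentStatus("h1", Sex.FEMALE, "hypothetical", "alive", 1.0)]
        more = base + [ParentStatus("h2", Sex.FEMALE, "hypothetical", "alive", 1.0)]
        b0 = breeding_population_bounds(confirmed, base)[Sex.FEMALE]
        b1 = breeding_population_bounds(confirmed, more)[Sex.FEMALE]
        assert b1.max >= b0.max


def test_estimator_front_end_composes_all_stages():
    mom = _ind("m", Sex.FEMALE, birth_year=2008, id_years={2019})
    kid = _ind("k", Sex.MALE, birth_year=2015, id_years={2019})
    norec = _ind("n", Sex.FEMALE, first_id_year=2013, id_years={2013, 2019})
    assignments = [
        ParentageAssignment("k", mother_id="m", route="dyad-mother"),
        ParentageAssignment("m"),
        ParentageAssignment("n"),
    ]
    est = DemographicEstimator().fit([mom, kid, norec], assignments, [])
    assert est.breeders_[Sex.FEMALE] == {"m"}
    assert est.adults_no_record_[Sex.FEMALE] == {"n"}
    assert est.breeding_bounds_[Sex.FEMALE].min == 1
    assert est.adult_bounds_[Sex.FEMALE].min == 2
    assert est.estimate_.minimum_population[Sex.FEMALE] == 2
    assert est.estimate_.minimum_population[Sex.MALE] == 1
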