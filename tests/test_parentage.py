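"""Parentage likelihoods, Δ calibration and the assignment cascade."""

import itertools
import math

import numpy as np
import pytest

from pedpop.genotypes import (
    AlleleFrequencyTable,
    Genotype,
    LocusPanel,
    genotypes_to_array,
)
from pedpop.individuals import Individual, Sex
from pedpop.parentage import (
    AssignmentConfig,
    DeltaThresholds,
    ParentageAssigner,
    assign_parent_pair,
    calibrate_delta,
    candidate_fathers,
    candidate_mothers,
    dyad_lod_vector,
    lod_score,
    run_cascade,
    transition_prob,
    trio_lod_matrix,
)
from pedpop.simulate import SimulationParams, perturbed_truth_catalogue, simulate_population


@pytest.fixture(scope="module")
def ftab():
    return AlleleFrequencyTable({"L1": {1: 0.5, 2: 0.5}})


class TestTransitionProb:
    def test_known_mother_homozygous_offspring(self, ftab):
        # mother transmits allele 1 surely; the unknown father contributes at p1
        assert transition_prob("L1", (1, 1), (1, 1), ftab, 0.0) == pytest.approx(0.5)

    def test_exclusion_is_zero_without_error(self, ftab):
        assert transition_prob("L1", (1, 1), (2, 2), ftab, 0.0) == 0.0

    def test_error_absorbs_exclusion(self, ftab):
        assert transition_prob("L1", (1, 1), (2, 2), ftab, 0.01) > 0.0


class TestLodScore:
    def test_closed_form_single_locus(self, ftab):
        lod = lod_score(Genotype({"L1": (1, 1)}), ftab, 0.0, mother=Genotype({"L1": (1, 1)}))
        assert lod == pytest.approx(math.log(2.0))

    def test_all_missing_candidate_scores_zero(self, ftab):
        lod = lod_score(Genotype({"L1": (1, 1)}), ftab, 0.0, mother=Genotype({"L1": None}))
        assert lod == 0.0

    def test_true_parent_tops_random_nonparents(self):
        """At 21 informative loci the true parent wins nearly always."""
        rng = np.random.default_rng(11)
        n_loci, n_rand = 21, 1000
        freq_dict, alleles, probs = {}, [], []
        for l in range(n_loci):
            p = rng.dirichlet(np.ones(5) * 2)
            freq_dict[f"L{l:02d}"] = {a: float(x) for a, x in enumerate(p)}
            alleles.append(np.arange(5))
            probs.append(p)
        panel = LocusPanel(tuple(freq_dict))
        ftab = AlleleFrequencyTable(freq_dict)
        fmat = ftab.freq_matrix(panel.loci)

        def hwe(n):
            out = np.empty((n, n_loci, 2), dtype=np.int64)
            for l in range(n_loci):
                out[:, l, :] = rng.choice(alleles[l], size=(n, 2), p=probs[l])
            return out

        wins = 0
        reps = 100
        for _ in range(reps):
            mom, dad = hwe(1)[0], hwe(1)[0]
            pick = rng.integers(0, 2, size=(n_loci, 2))
            off = np.stack(
                [mom[np.arange(n_loci), pick[:, 0]], dad[np.arange(n_loci), pick[:, 1]]],
                axis=1,
            )
            cands = np.concatenate([mom[None], hwe(n_rand)], axis=0)
            lod, _ = dyad_lod_vector(off, cands, fmat, 0.0)
            wins += int(np.argmax(lod) == 0)
        assert wins / reps >= 0.95


class TestScalarVectorAgreement:
    def test_dyad_and_trio_kernels_match_scalar_reference(self):
        rng = np.random.default_rng(5)
        loci = [f"L{l}" for l in range(6)]
        freqs = {}
        for l in loci:
            p = rng.dirichlet(np.ones(4))
            freqs[l] = {a: float(x) for a, x in enumerate(p)}
        ftab = AlleleFrequencyTable(freqs)
        panel = LocusPanel(tuple(loci))
        fmat = ftab.freq_matrix(panel.loci)

        def rand_geno():
            return Genotype(
                {l: tuple(sorted(rng.integers(0, 4, size=2))) for l in loci}
            )

        e = 0.01
        for _ in range(25):
            off, mom, dad = rand_geno(), rand_geno(), rand_geno()
            o = genotypes_to_array([off], panel)[0]
            m = genotypes_to_array([mom], panel)
            f = genotypes_to_array([dad], panel)
            lod_vec, _ = dyad_lod_vector(o, m, fmat, e)
            assert lod_vec[0] == pytest.approx(
                lod_score(off, ftab, e, mother=mom), rel=1e-9
            )
            lod_mat, _ = trio_lod_matrix(o, m, f, fmat, e)
            assert lod_mat[0, 0] == pytest.approx(
                lod_score(off, ftab, e, mother=mom, father=dad), rel=1e-9
            )


@pytest.fixture(scope="module")
def freqs():
    rng = np.random.default_rng(2)
    out = {}
    for l in range(10):
        p = rng.dirichlet(np.ones(5) * 2)
        out[f"L{l}"] = {a: float(x) for a, x in enumerate(p)}
    return AlleleFrequencyTable(out)


class TestCalibration:
    CFG = AssignmentConfig(
        n_simulation_cycles=400, n_candidates_per_offspring=30, error_rate=0.01
    )

    def test_same_seed_identical_thresholds(self, freqs):
        panel = LocusPanel(tuple(freqs.freqs))
        a = calibrate_delta(self.CFG, freqs, panel, seed=4)
        b = calibrate_delta(self.CFG, freqs, panel, seed=4)
        assert a == b

    def test_strict_threshold_at_least_relaxed(self, freqs):
        panel = LocusPanel(tuple(freqs.freqs))
        th = calibrate_delta(self.CFG, freqs, panel, seed=4)
        assert th.trio_strict >= th.trio_relaxed >= 0.0
        assert th.dyad_strict >= th.dyad_relaxed >= 0.0

    def test_reduced_and_larger_runs_agree_in_scale(self, freqs):
        panel = LocusPanel(tuple(freqs.freqs))
        small = calibrate_delta(self.CFG, freqs, panel, seed=4)
        big_cfg = AssignmentConfig(
            n_simulation_cycles=1600, n_candidates_per_offspring=30, error_rate=0.01
        )
        big = calibrate_delta(big_cfg, freqs, panel, seed=4)
        assert abs(small.dyad_relaxed - big.dyad_relaxed) < 5.0


from _oracles import brute_force_consistent_pairs


class TestExclusionOracle:
    def test_cascade_exclusions_match_enumeration(self):
        """On tiny instances the likelihood cascade excludes exactly the
        parent sets a brute-force Mendelian enumeration excludes (e = 0)."""
        rng = np.random.default_rng(21)
        loci = ["L1", "L2", "L3", "L4"]
        for rep in range(40):
            freqs = {}
            for l in loci:
                p = rng.dirichlet(np.ones(3))
                freqs[l] = {a: float(x) for a, x in enumerate(p)}
            ftab = AlleleFrequencyTable(freqs)
            panel = LocusPanel(tuple(loci))
            fmat = ftab.freq_matrix(panel.loci)

            def rand_geno():
                return Genotype(
                    {l: tuple(sorted(rng.integers(0, 3, size=2))) for l in loci}
                )

            off = rand_geno()
            mothers = [rand_geno() for _ in range(3)]
            fathers = [rand_geno() for _ in range(3)]
            oracle = brute_force_consistent_pairs(off, mothers, fathers)
            o = genotypes_to_array([off], panel)[0]
            lods, _ = trio_lod_matrix(
                o,
                genotypes_to_array(mothers, panel),
                genotypes_to_array(fathers, panel),
                fmat,
                0.0,
            )
            likelihood_ok = {
                (i, j)
                for i in range(3)
                for j in range(3)
                if math.isfinite(lods[i, j])
            }
            assert likelihood_ok == oracle


def _mk(ind_id, sex, geno, **kw):
    return Individual(id=ind_id, sex=sex, genotype=geno, **kw)


class TestCandidateFilters:
    CFG = AssignmentConfig()

    def test_mt_haplotype_filter_blocks_foreign_mothers(self):
        off = _mk("o", Sex.MALE, Genotype({"L1": (1, 1)}), mt_haplotype="HB-02")
        moms = [
            _mk("m1", Sex.FEMALE, Genotype({"L1": (1, 1)}), mt_haplotype="HB-11"),
            _mk("m2", Sex.FEMALE, Genotype({"L1": (1, 1)}), mt_haplotype="HB-10"),
        ]
        assert candidate_mothers(off, moms, self.CFG) == []

    def test_unknown_sex_never_a_candidate(self):
        off = _mk("o", Sex.FEMALE, Genotype({"L1": (1, 1)}))
        other = _mk("u", Sex.UNKNOWN, Genotype({"L1": (1, 1)}))
        assert candidate_mothers(off, [other], self.CFG) == []
        assert candidate_fathers(off, [other], self.CFG) == []

    def test_dead_mother_cannot_bear_later_offspring(self):
        off = _mk("o", Sex.FEMALE, Genotype({"L1": (1, 1)}), birth_year=2018)
        mom = _mk(
            "m", Sex.FEMALE, Genotype({"L1": (1, 1)}), birth_year=2010, death_year=2016
        )
        assert candidate_mothers(off, [mom], self.CFG) == []

    def test_father_alive_at_conception_passes(self):
        off = _mk("o", Sex.FEMALE, Genotype({"L1": (1, 1)}), birth_year=2018)
        dad = _mk(
            "f", Sex.MALE, Genotype({"L1": (1, 1)}), birth_year=2008, death_year=2017
        )
        assert candidate_fathers(off, [dad], self.CFG) == [dad]


class TestTrioRules:
    def test_two_mismatch_trio_never_accepted(self):
        loci = {f"L{l}": (1, 1) for l in range(6)}
        off = _mk("o", Sex.FEMALE, Genotype(loci))
        # two loci where the mother carries no offspring allele
        mom_geno = dict(loci)
        mom_geno["L0"] = (2, 2)
        mom_geno["L1"] = (2, 2)
        mom = _mk("m", Sex.FEMALE, Genotype(mom_geno))
        dad = _mk("f", Sex.MALE, Genotype(loci))
        freqs = AlleleFrequencyTable(
            {l: {1: 0.5, 2: 0.5} for l in loci}
        )
        panel = LocusPanel(tuple(loci))
        th = DeltaThresholds(-1.0, -1.0, -1.0, -1.0)  # accept anything by Δ
        res = assign_parent_pair(
            off, [mom], [dad], th, AssignmentConfig(error_rate=0.01), freqs, panel
        )
        assert res is None


@pytest.fixture(scope="module")
def truth():
    return simulate_population(
        SimulationParams(
            seed=5,
            initial_size=70,
            start_year=2007,
            genotyping_error=0.0,
            locus_missing_prob=0.0,
            monitored_fraction=1.0,
        )
    )


@pytest.fixture(scope="module")
def cascade_result(truth):
    cat = perturbed_truth_catalogue(truth, error=0.0)
    cfg = AssignmentConfig(
        n_simulation_cycles=500, n_candidates_per_offspring=50, error_rate=0.0
    )
    assigner = ParentageAssigner(panel=truth.panel, config=cfg, seed=5).fit(cat)
    return cat, assigner, assigner.predict(cat)


class TestCascade:
    def test_full_sampling_zero_error_yields_triads(self, truth, cascade_result):
        cat, _, assignments = cascade_result
        ids = {i.id for i in cat}
        eligible = [
            a
            for a in assignments
            if not truth.individuals[a.offspring_id].immigrant
            and truth.true_parents(a.offspring_id)[0] in ids
            and truth.true_parents(a.offspring_id)[1] in ids
        ]
        triads = [a for a in eligible if a.route.startswith("trio")]
        assert len(triads) / len(eligible) >= 0.95

    def test_rerun_same_seed_is_identical(self, truth, cascade_result):
        cat, assigner, assignments = cascade_result
        again = run_cascade(
            cat,
            assigner.config_,
            5,
            truth.panel,
            thresholds=assigner.thresholds_,
            freqs=assigner.frequencies_,
        )
        assert again == assignments

    def test_every_individual_gets_one_assignment(self, cascade_result):
        cat, _, assignments = cascade_result
        assert sorted(a.offspring_id for a in assignments) == sorted(i.id for i in cat)

    def test_accepted_links_respect_liveness(self, cascade_result):
        cat, _, assignments = cascade_result
        by_id = {i.id: i for i in cat}
        for a in assignments:
            off = by_id[a.offspring_id]
            if a.mother_id and a.mother_id in by_id:
                mom = by_id[a.mother_id]
                if mom.death_year is not None and off.birth_year is not None:
                    assert mom.death_year >= off.birth_year
            if a.father_id and a.father_id in by_id:
                dad = by_id[a.father_id]
                if dad.death_year is not None and off.birth_year is not None:
                    assert dad.death_year >= off.birth_year - 1

    def test_duplicate_ids_raise(self, truth):
        ind = _mk("dup", Sex.FEMALE, Genotype({"L01": (1, 1)}))
        with pytest.raises(ValueError):
            run_cascade(
                [ind, ind],
                AssignmentConfig(),
                0,
                truth.panel,
                thresholds=DeltaThresholds(0, 0, 0, 0),
                freqs=AlleleFrequencyTable({"L01": {1: 1.0}}),
            )
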