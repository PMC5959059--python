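import numpy as np
import pytest
from scipy import stats

from pigeonblup.microsat import summarize
from pigeonblup.pedigree import relationship_matrix, validate_and_sort, PedigreeRecord
from pigeonblup.phenotypes import encode_race_traits
from pigeonblup.simulate import (
    DEFAULT_ALLELE_FREQS,
    SimulationConfig,
    _liability_cutpoints,
    gene_drop_breeding_values,
    simulate_genotypes,
    simulate_pedigree,
    simulate_study,
)


def small_config(**kwargs):
    defaults = dict(
        n_founders=10,
        n_generations=4,
        n_matings=5,
        offspring_per_mating=4,
        n_phenotyped=None,
        n_genotyped=None,
        seed=0,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestSimulatePedigree:
    def test_zero_generations_founders_only(self):
        ped = simulate_pedigree(small_config(n_generations=0), np.random.default_rng(0))
        assert len(ped) == 10
        assert ped.is_founder.all()

    def test_animal_count_arithmetic(self):
        ped = simulate_pedigree(small_config(), np.random.default_rng(1))
        assert len(ped) == 10 + 4 * 5 * 4

    def test_deterministic_given_seed(self):
        a = simulate_pedigree(small_config(), np.random.default_rng(3))
        b = simulate_pedigree(small_config(), np.random.default_rng(3))
        assert a.ids == b.ids
        assert a.sexes() == b.sexes()
        assert np.array_equal(a.sire_idx, b.sire_idx)

    def test_both_sexes_required(self):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_pedigree(small_config(n_founders=1), np.random.default_rng(0))

    def test_default_scale_matches_study(self):
        cfg = SimulationConfig()
        ped = simulate_pedigree(cfg, np.random.default_rng(0))
        assert len(ped) == 2037


class TestGeneDrop:
    def test_zero_variance_all_zero(self, random_pedigree):
        u = gene_drop_breeding_values(random_pedigree, 0.0, np.random.default_rng(0))
        assert (u == 0).all()

    def test_founder_variance(self):
        ped = validate_and_sort([PedigreeRecord(f"f{i}") for i in range(5)])
        u = gene_drop_breeding_values(
            ped, 0.7, np.random.default_rng(1), n_replicates=100_000
        )
        assert u.var(axis=1) == pytest.approx(np.full(5, 0.7), rel=0.05)

    def test_covariance_matches_relationship_matrix(self, full_sib_mating):
        """Gene-dropped u has covariance sigma2_u * A (the A-matrix cross-oracle)."""
        s2u = 0.5
        u = gene_drop_breeding_values(
            full_sib_mating, s2u, np.random.default_rng(2), n_replicates=200_000
        )
        emp = u @ u.T / u.shape[1]
        target = s2u * relationship_matrix(full_sib_mating).A
        se = np.sqrt(
            (np.outer(np.diag(target), np.diag(target)) + target**2) / u.shape[1]
        )
        assert (np.abs(emp - target) <= 3 * se + 1e-12).all()


class TestSimulateGenotypes:
    def test_fixed_allele(self):
        ped = simulate_pedigree(small_config(), np.random.default_rng(0))
        genos = simulate_genotypes(ped, {"A": 1.0}, np.random.default_rng(0))
        assert all(g.alleles() == ("A", "A") for g in genos)

    def test_mendelian_transmission_from_homozygous_parents(self):
        ped = validate_and_sort(
            [
                PedigreeRecord("s", sex="male"),
                PedigreeRecord("d", sex="female"),
                PedigreeRecord("k", "s", "d"),
            ]
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            genos = simulate_genotypes(ped, {"S": 0.5, "M": 0.5}, rng)
            by_id = {g.animal_id: g for g in genos}
            if by_id["s"].alleles() == ("S", "S") and by_id["d"].alleles() == ("M", "M"):
                assert sorted(by_id["k"].alleles()) == ["M", "S"]

    def test_founder_genotypes_at_hwe(self):
        ped = validate_and_sort([PedigreeRecord(f"f{i}") for i in range(10_000)])
        genos = simulate_genotypes(ped, DEFAULT_ALLELE_FREQS, np.random.default_rng(4))
        s = summarize(genos)
        assert s.hwe(method="chi2").p_value > 0.01


class TestSimulatePhenotypes:
    def test_all_incidence_one_maxes_distances(self):
        cfg = small_config(incidences=(1.0,) * 5)
        study = simulate_study(cfg)
        assert all(r.total_distance_km >= 4000 for r in study.distances)

    def test_increasing_incidences_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            small_config(incidences=(0.2, 0.4, 0.1, 0.05, 0.01))

    def test_realized_incidence_within_binomial_bounds(self):
        cfg = SimulationConfig(
            n_founders=10_000, n_generations=0, n_phenotyped=None,
            n_genotyped=None, seed=5,
        )
        study = simulate_study(cfg)
        traits = encode_race_traits(study.distances)
        inc = traits.incidence()
        n = len(study.distances)
        for target, got in zip(cfg.incidences, inc):
            bound = 2.576 * np.sqrt(target * (1 - target) / n)
            assert abs(got - target) < bound + 0.005

    def test_roundtrip_recoding_reproduces_liability_bands(self):
        study = simulate_study(small_config(seed=6))
        traits = encode_race_traits(study.distances)
        n_reached = (traits.Y == 2).sum(axis=1)
        assert np.array_equal(n_reached, study.liabilities["band"].to_numpy())

    def test_cutpoints_monotone(self):
        cut = _liability_cutpoints(small_config())
        assert (np.diff(cut) > 0).all()


class TestSimulateStudy:
    def test_every_phenotyped_and_genotyped_animal_in_pedigree(self):
        study = simulate_study(SimulationConfig(
            n_founders=30, n_generations=2, n_matings=10, offspring_per_mating=4,
            n_phenotyped=50, n_genotyped=20, seed=7,
        ))
        assert all(a in study.pedigree.index for a in study.phenotyped_ids)
        assert set(study.genotyped_ids) <= set(study.phenotyped_ids)
        assert len(study.genotyped_ids) == 20
        assert study.truth["h2"] == pytest.approx(0.30)

    def test_truth_dossier_round_trips_config(self):
        cfg = small_config(beta=0.5, sigma2_u=1.0)
        study = simulate_study(cfg)
        assert study.truth["beta"] == 0.5
        assert study.truth["sigma2_u"] == 1.0
        assert study.truth["h2"] == pytest.approx(0.5)
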