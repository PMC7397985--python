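"""Synthetic population, breeding-value, and trait generators."""

import numpy as np
import pandas as pd
import pytest
from helpers import half_sib_h2_anova

from epoherit.pedigree import Pedigree, additive_relationship_matrix, kinship_summary
from epoherit.simulate import (
    PopulationSimConfig,
    TraitSimConfig,
    simulate_breeding_values,
    simulate_null_trait,
    simulate_population_pedigree,
    simulate_trait,
)


class TestPopulation:
    def test_zero_recruitment_gives_all_founders(self):
        cfg = PopulationSimConfig(n_years=4, pairs_per_year=(30, 40),
                                  recruitment_rate=0.0, rng_seed=1)
        ped, skel = simulate_population_pedigree(cfg)
        assert ped.n_maternities == 0
        assert all(ped.is_founder(i) for i in ped.ids)
        assert len(skel) > 0

    def test_degenerate_config_errors(self):
        with pytest.raises(ValueError):
            PopulationSimConfig(pairs_per_year=(0, 0))
        with pytest.raises(ValueError):
            PopulationSimConfig(recruitment_rate=1.5)

    def test_maternal_sibship_in_study_range_over_seeds(self):
        """The many-small-families regime: mean maternal sibship (recruits
        per mother with >= 1 recruit) in [1.4, 2.1] across seeds."""
        vals = []
        for seed in range(20):
            cfg = PopulationSimConfig(n_years=8, pairs_per_year=(140, 160),
                                      rng_seed=seed)
            ped, _ = simulate_population_pedigree(cfg)
            vals.append(kinship_summary(ped).mean_maternal_sibship)
        assert all(1.4 <= v <= 2.1 for v in vals), vals

    def test_known_parent_fraction_matches_demographic_expectation(self):
        """Steady state: local fraction f* = r / (1 - s) with r the per-capita
        recruit inflow (clutch * recruitment / 2 per breeding slot) and s
        adult survival; phenotyped birds with a known parent are exactly the
        locally born ones."""
        cfg = PopulationSimConfig(rng_seed=5)
        ped, skel = simulate_population_pedigree(cfg)
        local = np.mean([not ped.is_founder(i) for i in skel["individual"]])
        r = cfg.clutch_mean * cfg.recruitment_rate / 2.0
        expected = r / (1.0 - cfg.adult_survival)
        assert abs(local - expected) < 0.08, (local, expected)

    def test_reproducible(self):
        cfg = PopulationSimConfig(n_years=4, pairs_per_year=(30, 40), rng_seed=9)
        p1, s1 = simulate_population_pedigree(cfg)
        p2, s2 = simulate_population_pedigree(cfg)
        assert p1.ids == p2.ids and p1.dam == p2.dam
        pd.testing.assert_frame_equal(s1, s2)


def chain_pedigree(n: int) -> Pedigree:
    return Pedigree.from_records(
        [(f"i{k}", f"i{k-1}" if k else None, None) for k in range(n)]
    )


class TestBreedingValues:
    def test_zero_variance_gives_zeros(self, full_sib_family):
        bv = simulate_breeding_values(full_sib_family, 0.0, seed=1)
        assert (bv == 0).all()

    def test_negative_variance_errors(self, trio):
        with pytest.raises(ValueError):
            simulate_breeding_values(trio, -1.0, seed=1)

    def test_founder_variance(self):
        ped = Pedigree.from_records([(f"f{i}", None, None) for i in range(4000)])
        bv = simulate_breeding_values(ped, 2.0, seed=3)
        n = len(bv)
        se = 2.0 * np.sqrt(2.0 / (n - 1))  # SE of a chi-square sample variance
        assert abs(bv.var() - 2.0) <= 3 * se

    def test_offspring_midparent_regression_slope_one(self):
        records = []
        for k in range(5000):
            records.append((f"o{k}", f"d{k}", f"s{k}"))
        ped = Pedigree.from_records(records)
        bv = simulate_breeding_values(ped, 1.0, seed=11)
        mid = (bv[[f"d{k}" for k in range(5000)]].to_numpy()
               + bv[[f"s{k}" for k in range(5000)]].to_numpy()) / 2.0
        off = bv[[f"o{k}" for k in range(5000)]].to_numpy()
        slope = np.cov(off, mid)[0, 1] / np.var(mid)
        assert abs(slope - 1.0) < 0.05

    def test_replicate_covariance_matches_sigma2A_times_A(self):
        """Empirical covariance of replicated breeding values reproduces
        sigma2_A * A entrywise on a small structured pedigree."""
        ped = Pedigree.from_records(
            [("c1", "m1", "f1"), ("c2", "m1", "f1"), ("c3", "m1", "f2"),
             ("g1", "c1", "f2x"), ("g2", "c3", "f3")],
            sex={"c1": "F", "c3": "F"},
        )
        A = additive_relationship_matrix(ped)
        s2, n_rep = 1.0, 2000
        draws = np.empty((n_rep, len(ped)))
        for r in range(n_rep):
            draws[r] = simulate_breeding_values(
                ped, s2, seed=r, inbreeding=A.inbreeding
            ).loc[A.ids].to_numpy()
        emp = np.cov(draws, rowvar=False)
        target = s2 * A.entries
        # SE of a sample covariance of bivariate normals
        se = np.sqrt((np.outer(np.diag(target), np.diag(target))
                      + target**2) / n_rep)
        assert np.all(np.abs(emp - target) <= 3.5 * se)


class TestTrait:
    def test_pure_poisson_when_all_variances_zero(self, small_population):
        pruned, skel = small_population
        n = 480
        skel = skel.iloc[:n] if len(skel) >= n else skel
        cfg = TraitSimConfig(sigma2_A=0.0, sigma2_R=0.0,
                             intercept_mu=np.log(0.35), rng_seed=1)
        phen = simulate_trait(pruned, skel, cfg)
        m = phen["epo"].mean()
        se = np.sqrt(0.35 / len(phen))
        assert abs(m - 0.35) <= 3 * se
        assert (phen["epo"] >= 0).all()

    def test_overdispersion_from_residual_variance(self):
        """Lognormal-Poisson: empirical variance exceeds the mean in >= 95%
        of replicates once sigma2_R > 0."""
        ped = Pedigree.from_records([(f"f{i}", None, None) for i in range(1000)])
        skel = pd.DataFrame(
            {"individual": ped.ids, "sex": "F", "age_class": "older",
             "site_quality": 0, "site_id": "box0"}
        )
        hits = 0
        for seed in range(100):
            cfg = TraitSimConfig(sigma2_A=0.0, sigma2_R=1.0,
                                 intercept_mu=np.log(0.35), rng_seed=seed)
            phen = simulate_trait(ped, skel, cfg)
            hits += phen["epo"].var() > phen["epo"].mean()
        assert hits >= 95

    def test_gaussian_all_zero_is_constant(self, small_population):
        pruned, skel = small_population
        cfg = TraitSimConfig(sigma2_A=0.0, sigma2_R=0.0, intercept_mu=1.5,
                             family="gaussian-identity", rng_seed=1)
        phen = simulate_trait(pruned, skel, cfg)
        assert (phen["epo"] == 1.5).all()

    def test_unknown_family_errors(self):
        with pytest.raises(ValueError, match="family"):
            TraitSimConfig(family="negative-binomial")

    def test_half_sib_anova_recovers_h2(self):
        """Gaussian trait on a balanced paternal half-sib design: the moment
        estimator lands within 0.1 of the configured heritability."""
        records, sire_of = [], []
        for s in range(2000):
            for d in range(10):
                records.append((f"o{s}_{d}", f"dam{s}_{d}", f"sire{s}"))
                sire_of.append(s)
        ped = Pedigree.from_records(records)
        offspring = [r[0] for r in records]
        skel = pd.DataFrame(
            {"individual": offspring, "sex": "F", "age_class": "older",
             "site_quality": 0, "site_id": "box0"}
        )
        cfg = TraitSimConfig(sigma2_A=0.4, sigma2_R=0.6, intercept_mu=0.0,
                             family="gaussian-identity", rng_seed=21)
        phen = simulate_trait(ped, skel, cfg)
        h2 = half_sib_h2_anova(phen["epo"].to_numpy(), np.array(sire_of))
        assert abs(h2 - 0.4) < 0.1


class TestNullTrait:
    def test_moments_and_support(self, small_population):
        pruned, skel = small_population
        means = []
        for seed in range(20):
            phen = simulate_null_trait(pruned, skel, 0.35, seed=seed)
            assert (phen["epo"] >= 0).all()
            means.append(phen["epo"].mean())
        pooled_se = np.sqrt(0.35 / (20 * len(skel)))
        assert abs(np.mean(means) - 0.35) <= 3 * pooled_se

    def test_parent_offspring_covariance_centred_on_zero(self):
        ped = Pedigree.from_records([(f"o{k}", f"d{k}", None) for k in range(100)])
        ids = ped.ids
        skel = pd.DataFrame(
            {"individual": ids, "sex": "F", "age_class": "older",
             "site_quality": 0, "site_id": "box0"}
        )
        covs = []
        for seed in range(200):
            phen = simulate_null_trait(ped, skel, 0.35, seed=seed)
            x = phen.set_index("individual")["epo"]
            covs.append(np.cov(
                x[[f"d{k}" for k in range(100)]],
                x[[f"o{k}" for k in range(100)]],
            )[0, 1])
        covs = np.array(covs)
        assert abs(covs.mean()) <= 3 * covs.std(ddof=1) / np.sqrt(len(covs))

    def test_invalid_mean_errors(self, trio):
        with pytest.raises(ValueError):
            simulate_null_trait(trio, pd.DataFrame(), 0.0, seed=1)
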