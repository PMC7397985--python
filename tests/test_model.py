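"""Animal-model design construction, MCMC contracts, DIC, diagnostics, and
posterior predictive checks."""

import numpy as np
import pandas as pd
import pytest
from helpers import reml_intercept_animal

from epoherit.model import (
    MCMCConfig,
    ModelSpec,
    PosteriorChain,
    PriorSpec,
    build_design,
    diagnostics,
    dic,
    ess_initial_positive,
    fit_animal_model,
    posterior_predictive_zero_check,
)
from epoherit.pedigree import additive_relationship_matrix
from epoherit.simulate import TraitSimConfig, simulate_trait

FAST = MCMCConfig(nitt=6000, thin=10, burnin=1000, seed=5)


class TestDesign:
    def test_intercept_only_design(self, poisson_dataset):
        ped, phen = poisson_dataset
        d = build_design(phen, ped, ModelSpec())
        assert d.X.shape[1] == 1 and np.all(d.X == 1.0)
        assert d.site_idx is None

    def test_site_factor_structure(self, poisson_dataset):
        ped, phen = poisson_dataset
        phen = phen.copy()
        phen["site_quality"] = phen.index % 3  # 3 levels, both sexes present
        d = build_design(phen, ped, ModelSpec(site_effect=True))
        assert len(d.site_names) == 6
        assert (d.site_group == np.array([0, 0, 0, 1, 1, 1])).all()

    def test_site_regression_reading(self, poisson_dataset):
        ped, phen = poisson_dataset
        d = build_design(phen, ped, ModelSpec(site_effect=True,
                                              site_reading="regression"))
        assert len(d.site_names) == 2
        assert np.allclose(d.site_val, phen["site_quality"].to_numpy(float))

    def test_full_battery_fixed_design_rank_four(self, poisson_dataset):
        ped, phen = poisson_dataset
        spec = ModelSpec(fixed=("age", "sex", "age:sex"))
        d = build_design(phen, ped, spec)
        assert d.X.shape[1] == 4
        assert np.linalg.matrix_rank(d.X) == 4
        # the interaction-without-sex parameterization also spans rank 4
        d4 = build_design(phen, ped, ModelSpec(fixed=("age", "age:sex")))
        assert np.linalg.matrix_rank(d4.X) == 4

    def test_missing_covariates_fatal(self, poisson_dataset):
        ped, phen = poisson_dataset
        broken = phen.copy()
        broken.loc[broken.index[3], "age_class"] = None
        with pytest.raises(ValueError, match="missing covariate"):
            build_design(broken, ped, ModelSpec())


class TestFitContracts:
    def test_fixed_residual_variance_is_exact(self, poisson_dataset):
        ped, phen = poisson_dataset
        chain = fit_animal_model(phen, ped, ModelSpec(), PriorSpec.study_R2(), FAST)
        assert (chain.draws["sigma2_R"] == 1.0).all()

    def test_draw_count_matches_schedule(self, poisson_dataset):
        ped, phen = poisson_dataset
        chain = fit_animal_model(phen, ped, ModelSpec(), PriorSpec.study_R1(), FAST)
        assert len(chain) == FAST.n_draws
        assert (chain.draws["sigma2_A"] > 0).all()
        assert (chain.draws["sigma2_R"] > 0).all()

    def test_bit_identical_reproducibility(self, poisson_dataset):
        ped, phen = poisson_dataset
        cfg = MCMCConfig(nitt=3000, thin=10, burnin=500, seed=17)
        c1 = fit_animal_model(phen, ped, ModelSpec(), PriorSpec.study_R1(), cfg)
        c2 = fit_animal_model(phen, ped, ModelSpec(), PriorSpec.study_R1(), cfg)
        pd.testing.assert_frame_equal(c1.draws, c2.draws)

    def test_gaussian_posterior_matches_reml_oracle(self, gaussian_dataset):
        """Posterior mean of sigma2_A agrees with a direct restricted-likelihood
        maximizer on the same data within Monte-Carlo/prior error."""
        ped, phen = gaussian_dataset
        A = additive_relationship_matrix(ped)
        Ap = A.submatrix(list(phen["individual"]))
        sa_reml, se_reml = reml_intercept_animal(phen["epo"].to_numpy(float), Ap)
        chain = fit_animal_model(
            phen, ped, ModelSpec(family="gaussian-identity"),
            PriorSpec.study_R1(), MCMCConfig(nitt=40000, thin=20, burnin=4000, seed=3),
        )
        assert chain.draws["sigma2_A"].mean() == pytest.approx(sa_reml, abs=0.05)
        assert chain.draws["sigma2_R"].mean() == pytest.approx(se_reml, abs=0.06)

    def test_parameter_expansion_changes_mixing_not_target(self, gaussian_dataset):
        ped, phen = gaussian_dataset
        cfg = MCMCConfig(nitt=40000, thin=20, burnin=4000, seed=9)
        from epoherit.model import GPrior, RPrior

        expanded = PriorSpec.study_R1()
        plain = PriorSpec(
            g_animal=GPrior(V=1.0, nu=1.0),
            g_site=GPrior(V=1.0, nu=1.0),
            r=RPrior(V=1.0, nu=1.0),
        )
        spec = ModelSpec(family="gaussian-identity")
        m1 = fit_animal_model(phen, ped, spec, expanded, cfg).draws["sigma2_A"]
        m2 = fit_animal_model(phen, ped, spec, plain, cfg).draws["sigma2_A"]
        mcse = np.sqrt(
            m1.var() / ess_initial_positive(m1.to_numpy())
            + m2.var() / ess_initial_positive(m2.to_numpy())
        )
        # same well-identified posterior up to MC error and the (weak) prior
        # difference the expansion induces
        assert abs(m1.mean() - m2.mean()) < max(5 * mcse, 0.06)


def manual_chain(draws: pd.DataFrame, y: np.ndarray,
                 family: str = "poisson-log") -> PosteriorChain:
    n = len(y)
    return PosteriorChain(draws=draws, y=y, family=family,
                          eta_mean=np.zeros(n), loc_mean=np.zeros(n))


class TestDIC:
    def test_constant_deviance_gives_pd_zero(self):
        y = np.zeros(5)
        eta = np.full(5, -1.0)
        dev = -2.0 * float(np.sum(y * eta - np.exp(eta)))
        draws = pd.DataFrame({"beta_intercept": np.full(30, -1.0),
                              "sigma2_A": 0.1, "sigma2_R": 1.0,
                              "deviance": dev})
        chain = manual_chain(draws, y)
        chain.eta_mean = eta
        assert dic(chain) == pytest.approx(dev)

    def test_empty_chain_errors(self):
        chain = manual_chain(pd.DataFrame({"deviance": []}), np.zeros(3))
        with pytest.raises(ValueError):
            dic(chain)

    def test_deterministic_across_refits(self, poisson_dataset):
        ped, phen = poisson_dataset
        cfg = MCMCConfig(nitt=3000, thin=10, burnin=500, seed=23)
        d1 = dic(fit_animal_model(phen, ped, ModelSpec(), PriorSpec.study_R1(), cfg))
        d2 = dic(fit_animal_model(phen, ped, ModelSpec(), PriorSpec.study_R1(), cfg))
        assert d1 == d2

    def test_informative_covariate_lowers_dic(self, small_population):
        """DIC prefers the model containing a covariate the data were
        simulated with, in a majority of replicates."""
        ped, skel = small_population
        wins = 0
        n_rep = 20
        cfg = MCMCConfig(nitt=4000, thin=10, burnin=800, seed=1)
        for rep in range(n_rep):
            phen = simulate_trait(
                ped, skel,
                TraitSimConfig(sigma2_A=0.1, sigma2_R=0.4, intercept_mu=0.0,
                               fixed_effects={"age": 1.0},
                               family="gaussian-identity", rng_seed=100 + rep),
            )
            spec0 = ModelSpec(family="gaussian-identity")
            spec1 = ModelSpec(fixed=("age",), family="gaussian-identity")
            d0 = dic(fit_animal_model(phen, ped, spec0, PriorSpec.study_R1(), cfg))
            d1 = dic(fit_animal_model(phen, ped, spec1, PriorSpec.study_R1(), cfg))
            wins += d1 < d0
        assert wins > n_rep / 2


class TestDiagnostics:
    def test_iid_draws_ess_near_n(self, rng):
        x = rng.standard_normal(1000)
        draws = pd.DataFrame({"p": x, "deviance": rng.standard_normal(1000)})
        chain = manual_chain(draws, np.zeros(3))
        d = diagnostics(chain)
        assert 800 <= d.loc["p", "ess"] <= 1200
        assert abs(d.loc["p", "lag1_autocorr"]) < 0.1
        assert not d.loc["p", "flagged"]

    def test_ar1_draws_ess_collapses(self, rng):
        rho, n = 0.9, 4000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for t in range(1, n):
            x[t] = rho * x[t - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
        ess = ess_initial_positive(x)
        theory = n * (1 - rho) / (1 + rho)
        assert ess < 2.5 * theory  # far below n
        assert ess < n / 5

    def test_constant_chain_flagged_degenerate(self):
        draws = pd.DataFrame({"p": np.ones(50), "deviance": np.ones(50)})
        d = diagnostics(manual_chain(draws, np.zeros(3)))
        assert d.loc["p", "degenerate"] and d.loc["p", "flagged"]
        assert np.isnan(d.loc["p", "ess"])

    def test_fixed_residual_not_flagged(self, poisson_dataset):
        ped, phen = poisson_dataset
        chain = fit_animal_model(phen, ped, ModelSpec(), PriorSpec.study_R2(), FAST)
        d = diagnostics(chain)
        assert d.loc["sigma2_R", "degenerate"]
        assert not d.loc["sigma2_R", "flagged"]


class TestPosteriorPredictive:
    def _point_chain(self, mu: float, n_y: int = 480, n_draws: int = 40):
        rng = np.random.default_rng(1)
        y = rng.poisson(0.35, size=n_y).astype(float)
        draws = pd.DataFrame({"beta_intercept": np.full(n_draws, mu),
                              "sigma2_A": 0.0, "sigma2_R": 1e-12,
                              "deviance": 0.0})
        return manual_chain(draws, y)

    def test_zero_fraction_matches_poisson_closed_form(self):
        chain = self._point_chain(np.log(0.35))
        res = posterior_predictive_zero_check(chain, n_draws=400, seed=2)
        frac = res["predicted_zeros"] / len(chain.y)
        assert frac == pytest.approx(np.exp(-0.35), abs=0.01)

    def test_predicted_zeros_decrease_with_mu(self):
        fracs = []
        for mu in (np.log(0.2), np.log(0.5), np.log(1.0)):
            res = posterior_predictive_zero_check(
                self._point_chain(mu), n_draws=300, seed=3
            )
            fracs.append(res["predicted_zeros"])
        assert fracs[0] > fracs[1] > fracs[2]

    def test_self_consistency_on_model_simulated_data(self, poisson_dataset):
        ped, phen = poisson_dataset
        chain = fit_animal_model(
            phen, ped, ModelSpec(), PriorSpec.study_R1(),
            MCMCConfig(nitt=20000, thin=20, burnin=4000, seed=7),
        )
        res = posterior_predictive_zero_check(chain, n_draws=500, seed=4)
        assert res["relative_difference"] < 0.10

    def test_gaussian_family_rejected(self, gaussian_dataset):
        ped, phen = gaussian_dataset
        chain = fit_animal_model(
            phen, ped, ModelSpec(family="gaussian-identity"),
            PriorSpec.study_R1(), FAST,
        )
        with pytest.raises(ValueError, match="Poisson"):
            posterior_predictive_zero_check(chain)


class TestConfigValidation:
    def test_schedule_must_keep_draws(self):
        with pytest.raises(ValueError):
            MCMCConfig(nitt=100, thin=200, burnin=50)

    def test_study_scale_schedule_keeps_1000_draws(self):
        assert MCMCConfig.study_scale().n_draws == 1000

    def test_bad_terms_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(fixed=("weight",))
        with pytest.raises(ValueError):
            ModelSpec(family="binomial")
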