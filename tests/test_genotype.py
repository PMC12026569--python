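"""Binomial-mixture genotype model: formulas, posteriors, FF estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmakit.genotype import (
    FETAL_TAGGING,
    FF_INFORMATIVE,
    UNINFORMATIVE,
    FetalFractionEstimator,
    FetalGenotypeCaller,
    InsufficientDataError,
    SNPSite,
    call_fetal_genotype,
    estimate_fetal_fraction,
    expected_alt_fraction,
    flag_informative_sites,
    genotype_log_likelihood,
    mendelian_prior,
)
from plasmakit.simulate import SimConfig, simulate_plasma_counts, simulate_trio_genotypes

from _oracles import binom_log_pmf, mixture_p, posterior_enumeration


def _site(alt, depth, m, p=None):
    return SNPSite("chr1", 100, "A", "G", alt, depth, m, p)


class TestExpectedAltFraction:
    @pytest.mark.parametrize(
        "m,k,f,eps,expected",
        [
            (0, 1, 0.2, 0.0, 0.10),   # fetal-only het contributes f/2
            (1, 1, 0.37, 0.0, 0.50),  # symmetric het regardless of f
            (1, 1, 0.9, 0.0, 0.50),
            (2, 2, 0.1, 0.0, 1.00),   # all-alt
            (0, 0, 0.1, 0.01, 0.01),  # pure error floor
            (2, 2, 0.1, 0.01, 0.99),
        ],
    )
    def test_formula(self, m, k, f, eps, expected):
        assert expected_alt_fraction(m, k, f, eps) == pytest.approx(expected)

    @given(
        m=st.sampled_from([0, 1, 2]),
        f=st.floats(0.01, 1.0),
        eps=st.floats(0.0, 0.49, exclude_max=True),
    )
    def test_strictly_increasing_in_k(self, m, f, eps):
        values = [expected_alt_fraction(m, k, f, eps) for k in (0, 1, 2)]
        assert values[0] < values[1] < values[2]

    @pytest.mark.parametrize("bad", [{"m": 3}, {"k": -1}, {"f": 1.5}, {"eps": 0.5}])
    def test_invalid_parameters_raise(self, bad):
        kwargs = {"m": 1, "k": 1, "f": 0.1, "eps": 0.0}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            expected_alt_fraction(
                kwargs["m"], kwargs["k"], kwargs["f"], kwargs["eps"]
            )


class TestGenotypeLogLikelihood:
    def test_single_bernoulli(self):
        # depth 1, alt 1, p' = 0.1 (m=0, k=1, f=0.2)
        assert genotype_log_likelihood(1, 1, 0, 1, 0.2) == pytest.approx(math.log(0.1))

    def test_two_reads_het(self):
        # depth 2, alt 1 at p' = 0.5 -> 2 * 0.25
        assert genotype_log_likelihood(1, 2, 1, 1, 0.3) == pytest.approx(math.log(0.5))

    @pytest.mark.parametrize("alt,depth,m,k,f,eps", [
        (10, 100, 0, 1, 0.2, 0.0),
        (110, 200, 1, 2, 0.1, 0.0),
        (3, 30, 0, 0, 0.05, 0.01),
        (25, 30, 2, 1, 0.15, 0.02),
    ])
    def test_matches_comb_oracle(self, alt, depth, m, k, f, eps):
        expected = binom_log_pmf(alt, depth, mixture_p(m, k, f, eps))
        assert genotype_log_likelihood(alt, depth, m, k, f, eps) == pytest.approx(
            expected, abs=1e-9
        )

    def test_requires_depth_and_maternal_genotype(self):
        with pytest.raises(ValueError):
            genotype_log_likelihood(0, 0, 0, 1, 0.1)
        with pytest.raises(ValueError):
            genotype_log_likelihood(1, 10, None, 1, 0.1)


class TestPosterior:
    def test_f_zero_returns_prior(self):
        post = call_fetal_genotype(_site(40, 100, 1), f=0.0)
        assert post.probs == pytest.approx({0: 1 / 3, 1: 1 / 3, 2: 1 / 3})
        assert post.ml_call == 0  # tie breaks to smallest k

    @pytest.mark.parametrize("alt,depth,m,f,eps,expected_call", [
        (10, 100, 0, 0.2, 0.01, 1),   # fetal het over maternal hom-ref
        (110, 200, 1, 0.1, 0.0, 2),   # 0.55 band -> fetal hom-alt
        (1, 200, 0, 0.2, 0.01, 0),
        (198, 200, 2, 0.2, 0.01, 2),
    ])
    def test_ml_call_matches_enumeration(self, alt, depth, m, f, eps, expected_call):
        oracle = posterior_enumeration(alt, depth, m, f, eps)
        assert oracle.index(max(oracle)) == expected_call
        post = call_fetal_genotype(_site(alt, depth, m), f, error_rate=eps)
        assert post.ml_call == expected_call

    def test_matches_enumeration_to_1e9_small_depth(self):
        f, eps = 0.1, 0.01
        for depth in (1, 5, 12, 30):
            for m in (0, 1, 2):
                for alt in range(depth + 1):
                    post = call_fetal_genotype(_site(alt, depth, m), f, error_rate=eps)
                    oracle = posterior_enumeration(alt, depth, m, f, eps)
                    total = sum(post.probs.values())
                    assert total == pytest.approx(1.0, abs=1e-9)
                    for k in (0, 1, 2):
                        assert post.probs[k] == pytest.approx(oracle[k], abs=1e-9)

    def test_deep_site_no_underflow(self):
        post = call_fetal_genotype(_site(5200, 100_000, 0), f=0.1, error_rate=0.001)
        assert sum(post.probs.values()) == pytest.approx(1.0, abs=1e-9)
        assert post.ml_call == 1

    def test_f_one_reduces_to_diploid_likelihood(self):
        # at f = 1 the plasma is pure fetal: the mixture collapses to an
        # ordinary diploid genotype likelihood on the fetal genotype
        eps = 0.01
        site = _site(45, 100, 0)
        post = call_fetal_genotype(site, f=1.0, error_rate=eps)
        for k in (0, 1, 2):
            p = (k / 2) * (1 - 2 * eps) + eps
            assert post.log_likelihoods[k] == pytest.approx(
                binom_log_pmf(45, 100, p), abs=1e-9
            )
        assert post.ml_call == 1

    def test_mendelian_prior(self):
        assert mendelian_prior(1, 1) == pytest.approx({0: 0.25, 1: 0.5, 2: 0.25})
        assert mendelian_prior(0, 2) == pytest.approx({0: 0.0, 1: 1.0, 2: 0.0})

    def test_bad_prior_raises(self):
        with pytest.raises(ValueError):
            call_fetal_genotype(_site(1, 10, 0), 0.1, prior={0: 0.9, 1: 0.9, 2: 0.9})


class TestInformativeSites:
    def test_partition_rules(self):
        sites = pd.DataFrame(
            {
                "maternal_copies": [0, 2, 1, 0, None, 2],
                "paternal_copies": [1, 0, 0, 0, 1, 2],
                "depth": 100,
            }
        )
        flags = flag_informative_sites(sites)
        assert list(flags) == [
            FF_INFORMATIVE,      # m=0, father carries alt
            FETAL_TAGGING,       # m=2: ref reads can only be fetal
            UNINFORMATIVE,       # maternal het
            FETAL_TAGGING,       # m=0, father hom-ref: alt reads tag fetal/de novo
            UNINFORMATIVE,       # unknown maternal genotype
            FETAL_TAGGING,
        ]

    def test_partition_is_exhaustive_and_disjoint(self, small_cohort):
        flags = flag_informative_sites(small_cohort.sites)
        assert flags.isin([FF_INFORMATIVE, FETAL_TAGGING, UNINFORMATIVE]).all()
        assert len(flags) == len(small_cohort.sites)


class TestFetalFractionEstimation:
    def _sites(self, ratios, depth=100, paternal=2):
        return pd.DataFrame(
            {
                "maternal_copies": 0,
                "paternal_copies": paternal,
                "depth": depth,
                "alt_count": [int(round(r * depth)) for r in ratios],
            }
        )

    def test_two_times_mean_alt_fraction(self):
        est = estimate_fetal_fraction(self._sites([0.05] * 10))
        assert est.f == pytest.approx(0.10)
        assert est.n_informative_sites == 10

    def test_zero_alt_reads_gives_zero(self):
        est = estimate_fetal_fraction(self._sites([0.0] * 5))
        assert est.f == 0.0

    def test_error_rate_inversion(self):
        # observed ratio eps-shifted; inversion recovers the clean f
        eps = 0.01
        observed = (0.05 * (1 - 2 * eps)) + eps  # = 0.059, exact at depth 1000
        est = estimate_fetal_fraction(
            self._sites([observed] * 10, depth=1000), error_rate=eps
        )
        assert est.f == pytest.approx(0.10, abs=1e-12)

    def test_no_informative_sites_raises(self):
        sites = self._sites([0.05] * 3, paternal=0)
        with pytest.raises(InsufficientDataError):
            estimate_fetal_fraction(sites)

    def test_recovers_simulated_truth(self):
        errors = []
        for seed in range(3):
            config = SimConfig(n_sites=2000, mean_depth=200, fetal_fraction=0.10, seed=seed)
            rng = config.rng()
            sites = simulate_plasma_counts(
                simulate_trio_genotypes(config, rng), config, rng
            )
            est = estimate_fetal_fraction(sites, error_rate=config.error_rate)
            errors.append(est.f - 0.10)
        assert np.all(np.abs(errors) < 0.01)

    def test_estimator_class_exposes_fitted_attributes(self):
        est = FetalFractionEstimator(error_rate=0.0).fit(self._sites([0.05] * 10))
        assert est.fetal_fraction_ == pytest.approx(0.10)
        assert est.n_informative_sites_ == 10
        assert est.stderr_ == pytest.approx(0.0)


class TestGenotypeCaller:
    def test_predict_on_simulated_sites(self, small_cohort, small_config):
        sites = small_cohort.sites
        caller = FetalGenotypeCaller(
            fetal_fraction=small_config.fetal_fraction,
            error_rate=small_config.error_rate,
        ).fit(sites)
        usable = sites[sites["depth"] > 0]
        calls = caller.predict(usable)
        truth = usable["fetal_copies"].to_numpy()
        accuracy = float((calls == truth).mean())
        assert accuracy > 0.8  # depth 200 at f = 0.10 separates the states well

    def test_posteriors_sum_to_one(self, small_cohort):
        caller = FetalGenotypeCaller(fetal_fraction=0.1).fit(small_cohort.sites)
        proba = caller.predict_proba(small_cohort.sites[small_cohort.sites.depth > 0].head(50))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_get_set_params_roundtrip(self):
        caller = FetalGenotypeCaller(fetal_fraction=0.15, prior="mendelian")
        params = caller.get_params()
        clone = FetalGenotypeCaller(**params)
        assert clone.get_params() == params
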