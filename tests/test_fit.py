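"""Model fitting, LRTs, partition models and pairwise dN/dS."""

import numpy as np
import pytest
from scipy.stats import chi2

from selstruct.codon_evo import (
    fit_M0,
    fit_site_model,
    lrt,
    pairwise_dnds,
    site_posteriors,
)
from selstruct.codon_evo.fit import (
    LRTResult,
    PartitionScheme,
    SiteModelFit,
    fit_fixed_sites,
    fit_lrt_pair,
)
from selstruct.seqdata import CodonAlignment
from selstruct.synthetic_data import SimSpec, simulate_codon_alignment


@pytest.fixture(scope="module")
def purifying_sim():
    return simulate_codon_alignment(
        SimSpec(seed=21, n_codons=300, kappa=2.0, n_taxa=5, depth=0.8,
                site_class_plan=[(0.3, 1.0)])
    )


@pytest.fixture(scope="module")
def m0_fit(purifying_sim):
    return fit_M0(purifying_sim.alignment, purifying_sim.tree)


class TestM0:
    def test_recovers_simulated_omega(self, m0_fit):
        assert abs(m0_fit.omega - 0.3) < 0.1
        assert m0_fit.converged

    def test_identical_sequences_flagged(self):
        aln = CodonAlignment(["a", "b", "c"], ["ATGGCTAAA"] * 3)
        from selstruct.codon_evo.likelihood import ArrayTree

        tree = ArrayTree.from_newick("(a:0.1,(b:0.1,c:0.1):0.1);", ["a", "b", "c"])
        fit = fit_M0(aln, tree)
        assert not fit.converged
        assert np.all(fit.tree.branch_vector() < 1e-4)

    def test_synonymous_only_variation_hits_lower_bound(self):
        sim = simulate_codon_alignment(
            SimSpec(seed=3, n_codons=300, kappa=2.0, n_taxa=5, depth=0.6,
                    site_class_plan=[(0.01, 1.0)])
        )
        fit = fit_M0(sim.alignment, sim.tree)
        assert fit.omega < 0.05


class TestNesting:
    def test_likelihood_ordering(self, purifying_sim, m0_fit):
        aln, tree = purifying_sim.alignment, purifying_sim.tree
        m1 = fit_site_model(aln, tree, "M1", m0_fit=m0_fit)
        m2 = fit_site_model(aln, tree, "M2", m0_fit=m0_fit, warm_start=m1)
        m7 = fit_site_model(aln, tree, "M7", m0_fit=m0_fit)
        m8 = fit_site_model(aln, tree, "M8", m0_fit=m0_fit, warm_start=m7)
        tol = 1e-3
        assert m2.log_likelihood >= m1.log_likelihood - tol
        assert m8.log_likelihood >= m7.log_likelihood - tol
        # M1 contains M0's single-omega fit when omega <= 1
        assert m1.log_likelihood >= m0_fit.log_likelihood - tol - 1e-6 * abs(m0_fit.log_likelihood)

    def test_m7_discretization_used(self, purifying_sim, m0_fit):
        m7 = fit_site_model(
            purifying_sim.alignment, purifying_sim.tree, "M7", m0_fit=m0_fit
        )
        assert m7.mixture.n_classes == 10
        assert np.allclose(m7.mixture.class_weights, 0.1)
        assert np.all(m7.mixture.class_omegas <= 1.0)

    def test_bad_class_count_rejected(self, purifying_sim):
        with pytest.raises(ValueError):
            fit_site_model(purifying_sim.alignment, purifying_sim.tree, "M7",
                           n_beta_classes=1)


class TestLRT:
    def _fake_fit(self, ell, tag="M7", n_params=3):
        return SiteModelFit(
            tag, None, 2.0, None, None, ell, True, n_params, False
        )

    def test_equal_likelihoods_give_p_one(self):
        res = lrt(self._fake_fit(-100.0), self._fake_fit(-100.0, "M8", 5), df=2)
        assert res.stat == 0.0 and res.p_value == 1.0

    def test_chi2_quantile_identity(self):
        res = lrt(self._fake_fit(-100.0), self._fake_fit(-100.0 + 5.991 / 2, "M8", 5), df=2)
        assert abs(res.p_value - 0.05) < 5e-4

    def test_worse_alternative_raises(self):
        with pytest.raises(RuntimeError, match="optimizer failure"):
            lrt(self._fake_fit(-100.0), self._fake_fit(-101.0, "M8", 5), df=2)

    def test_warm_started_pair_never_violates_nesting(self, purifying_sim, m0_fit):
        null, alt, res = fit_lrt_pair(
            purifying_sim.alignment, purifying_sim.tree, "M7", "M8", m0_fit=m0_fit
        )
        assert res.stat >= 0.0 and 0.0 <= res.p_value <= 1.0
        assert res.df == 2


class TestPosteriors:
    def test_m0_posterior_is_degenerate(self, purifying_sim, m0_fit):
        track = site_posteriors(m0_fit, purifying_sim.alignment)
        assert np.allclose(track.post_mean_omega, m0_fit.omega)
        assert np.all(track.prob_positive == float(m0_fit.omega > 1))

    def test_class_posteriors_normalized(self, purifying_sim, m0_fit):
        m8 = fit_site_model(
            purifying_sim.alignment, purifying_sim.tree, "M8", m0_fit=m0_fit
        )
        track = site_posteriors(m8, purifying_sim.alignment)
        assert np.allclose(track.class_posteriors.sum(axis=1), 1.0)
        assert np.all(track.post_mean_omega >= 0)
        assert np.all((track.prob_positive >= 0) & (track.prob_positive <= 1))

    def test_no_positive_mass_without_positive_class(self, purifying_sim, m0_fit):
        m7 = fit_site_model(
            purifying_sim.alignment, purifying_sim.tree, "M7", m0_fit=m0_fit
        )
        track = site_posteriors(m7, purifying_sim.alignment)
        assert np.all(track.prob_positive == 0.0)


class TestFixedSites:
    def test_two_partition_contrast_recovered(self):
        sim = simulate_codon_alignment(
            SimSpec(seed=9, n_codons=300, kappa=2.0, n_taxa=5, depth=0.8,
                    site_class_plan=[(0.1, 0.5), (0.9, 0.5)])
        )
        labels = ["low" if k == 0 else "high" for k in sim.site_labels]
        result = fit_fixed_sites(
            sim.alignment, sim.tree, PartitionScheme(labels)
        )
        assert result.partition_omegas["low"] < result.partition_omegas["high"]
        assert result.lrt.p_value < 0.01
        assert result.lrt.df == 1

    def test_single_partition_rejected(self):
        with pytest.raises(ValueError):
            PartitionScheme(["only"] * 30)

    def test_small_partition_warns(self, purifying_sim):
        labels = ["tiny"] * 5 + ["rest"] * (purifying_sim.alignment.site_count - 5)
        with pytest.warns(UserWarning, match="unstable"):
            fit_fixed_sites(
                purifying_sim.alignment, purifying_sim.tree, PartitionScheme(labels)
            )


class TestPairwise:
    def test_identical_sequences_undefined_ratio(self):
        aln = CodonAlignment(["a", "b"], ["ATGGCTAAAGGG", "ATGGCTAAAGGG"])
        res = pairwise_dnds(aln, "a", "b")
        assert res.dN == 0.0 and res.dS == 0.0
        assert not res.omega_defined

    def test_symmetric_in_argument_order(self, purifying_sim):
        aln = purifying_sim.alignment
        r1 = pairwise_dnds(aln, "t1", "t4")
        r2 = pairwise_dnds(aln, "t4", "t1")
        assert np.isclose(r1.omega, r2.omega, rtol=1e-4)
        assert np.isclose(r1.dN, r2.dN, rtol=1e-4)

    def test_ratio_matches_fitted_omega(self, purifying_sim):
        res = pairwise_dnds(purifying_sim.alignment, "t1", "t5")
        assert res.omega_defined
        assert np.isclose(res.dN / res.dS, res.omega, rtol=1e-6)
        # moderate-divergence estimate lands near the simulated value
        assert 0.1 < res.omega < 0.7

    def test_no_shared_sites_errors(self):
        aln = CodonAlignment(
            ["a", "b", "c"], ["ATG---", "---GCT", "ATGGCT"]
        )
        with pytest.raises(ValueError, match="no shared"):
            pairwise_dnds(aln, "a", "b")
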