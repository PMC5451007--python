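"""Filtering rules, genotype PCA, Nei G_ST, NMDS, pseudo-haploid sampling."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from flightdiff import genomod, popstruct, synthdata
from flightdiff.genomod import AlleleFrequencyPosterior
from tests.conftest import make_rcm


def afp_from_fixed(p_by_pop, n_draws=1):
    """AlleleFrequencyPosterior with constant draws at given frequencies."""
    p = np.asarray(p_by_pop, dtype=float)  # (n_pops, L)
    draws = np.repeat(p[:, :, None], n_draws, axis=2)
    return AlleleFrequencyPosterior(
        draws=draws,
        populations=[f"pop{i}" for i in range(p.shape[0])],
        loci=np.array([f"L{j}" for j in range(p.shape[1])], dtype=object),
    )


class TestFilterDataset:
    def test_site_coverage_rule(self):
        """A site covered in 2 of 10 individuals falls to the 25% rule."""
        ref = np.zeros((10, 2), int)
        ref[:, 1] = 10          # site 1 covered everywhere
        ref[:2, 0] = 10         # site 0 covered in 2/10 = 20%
        rcm = make_rcm(ref, np.zeros_like(ref))
        spec = popstruct.FilterSpec(min_reads_per_population=0)
        filtered, log = popstruct.filter_dataset(rcm, spec)
        assert list(filtered.loci) == ["L1"]
        assert log[log["id"] == "L0"]["rule"].item() == "site_coverage"

    def test_min_reads_per_population_boundary(self):
        """A population totalling 14 reads at a site trips the 15-read rule."""
        ref = np.full((4, 2), 10)
        ref[:2, 0] = 7          # pop a: 14 reads at site 0
        rcm = make_rcm(ref, np.zeros_like(ref), populations=["a", "a", "b", "b"])
        filtered, log = popstruct.filter_dataset(rcm, popstruct.FilterSpec())
        assert "L0" not in set(filtered.loci)
        assert log[log["id"] == "L0"]["rule"].item() == "min_reads_per_population"
        assert "L1" in set(filtered.loci)  # 20 >= 15 in both pops

    def test_multiallelic_rule_uses_allele_counts(self):
        ref = np.full((4, 3), 20)
        rcm = make_rcm(ref, np.zeros_like(ref))
        filtered, log = popstruct.filter_dataset(
            rcm, popstruct.FilterSpec(min_reads_per_population=0),
            allele_count_per_site=np.array([2, 3, 4]),
        )
        assert list(filtered.loci) == ["L0"]
        assert set(log["rule"]) == {"multiallelic"}

    def test_individual_missingness_rule(self):
        ref = np.full((5, 10), 8)
        ref[0, :] = 0  # individual 0 missing everywhere
        rcm = make_rcm(ref, np.zeros_like(ref))
        filtered, log = popstruct.filter_dataset(
            rcm, popstruct.FilterSpec(min_reads_per_population=0)
        )
        assert "ind0" not in set(filtered.individuals)
        assert (log["rule"] == "individual_missingness").sum() == 1

    def test_idempotent_on_simulated_data(self, two_pop_sim):
        rcm, _ = two_pop_sim
        once, _ = popstruct.filter_dataset(rcm, popstruct.FilterSpec())
        twice, log2 = popstruct.filter_dataset(once, popstruct.FilterSpec())
        assert log2.empty
        assert np.array_equal(once.ref, twice.ref)

    def test_empty_result_is_logged_not_silent(self, caplog):
        ref = np.zeros((4, 3), int)
        rcm = make_rcm(ref, ref)
        with caplog.at_level("WARNING"):
            filtered, log = popstruct.filter_dataset(rcm, popstruct.FilterSpec())
        assert filtered.n_loci == 0
        assert len(log) == 3
        assert any("all sites removed" in r.message for r in caplog.records)


class TestGenotypePca:
    def test_identical_individuals_have_zero_variance(self):
        prob = np.tile(np.array([0.2, 0.5, 0.3]), (6, 10, 1))
        gp = genomod.GenotypePosterior(
            prob=prob,
            individuals=np.array([f"i{k}" for k in range(6)], dtype=object),
            loci=np.array([f"L{j}" for j in range(10)], dtype=object),
        )
        r = popstruct.genotype_pca(gp)
        assert np.allclose(r.variance_fraction, 0.0)
        assert np.allclose(r.scores, 0.0)

    def test_two_clusters_separate_on_pc1(self):
        freqs = synthdata.sim_pop_frequencies(400, ["a", "b"], 0.1, seed=41)
        rcm, _ = synthdata.sim_read_counts(
            freqs, 15, coverage=10.0, missing_rate=0.0, seed=42
        )
        _, gp = genomod.gibbs_allele_frequency(
            rcm, steps=1500, burnin=500, seed=43
        )
        r = popstruct.genotype_pca(gp)
        pc1 = r.scores[:, 0]
        a, b = pc1[:15], pc1[15:]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
               max(b.min(), a.min()) > min(b.max(), a.max())  # no overlap
        assert r.variance_fraction[0] > r.variance_fraction[1]

    def test_single_individual_rejected(self):
        gp = genomod.GenotypePosterior(
            prob=np.full((1, 3, 3), 1 / 3),
            individuals=np.array(["i0"], dtype=object),
            loci=np.array(["a", "b", "c"], dtype=object),
        )
        with pytest.raises(ValueError):
            popstruct.genotype_pca(gp)


class TestPairwiseGst:
    def test_equal_frequencies_give_zero(self):
        p = np.random.default_rng(1).random(20)
        g = popstruct.pairwise_gst(afp_from_fixed([p, p]))
        assert g.estimate[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_gives_one(self):
        g = popstruct.pairwise_gst(afp_from_fixed([[1.0], [0.0]]))
        assert g.estimate[0, 1] == pytest.approx(1.0)

    def test_single_locus_hand_value(self):
        """p = (0.2, 0.8): H_S = 0.32, H_T = 0.5, G_ST = 0.36."""
        g = popstruct.pairwise_gst(afp_from_fixed([[0.2], [0.8]]))
        assert g.estimate[0, 1] == pytest.approx(0.36, abs=1e-12)

    def test_bounds_symmetry_and_ci_order(self, small_afp):
        afp, _ = small_afp
        g = popstruct.pairwise_gst(afp)
        i, j = 0, 1
        assert 0.0 <= g.estimate[i, j] <= 1.0
        assert g.estimate[i, j] == g.estimate[j, i]
        assert g.ci_low[i, j] <= g.estimate[i, j] <= g.ci_high[i, j]
        assert g.estimate[i, i] == 0.0

    def test_monomorphic_pair_is_undefined(self):
        g = popstruct.pairwise_gst(afp_from_fixed([[0.0, 1.0], [0.0, 1.0]]))
        assert g.status[0, 1] == "undefined"
        assert np.isnan(g.estimate[0, 1])

    def test_table2_layout(self, small_afp):
        afp, _ = small_afp
        t = popstruct.pairwise_gst(afp).to_table2_frame()
        assert t.iloc[1, 0] != "" and "-" in t.iloc[0, 1]


class TestNmds:
    def test_exact_euclidean_input_reaches_zero_stress(self):
        X = np.random.default_rng(3).normal(size=(5, 3))
        D = squareform(pdist(X))
        r = popstruct.nmds_embed(D, dims=3, restarts=4, seed=4)
        assert r.stress < 1e-3

    def test_equilateral_triangle_in_two_dims(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        r = popstruct.nmds_embed(D, dims=2, restarts=4, seed=5)
        assert r.stress < 1e-3

    def test_unembeddable_one_dim_has_positive_stress(self):
        """A 2-D square's distances cannot be ranked-matched on a line."""
        X = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        D = squareform(pdist(X))
        r = popstruct.nmds_embed(D, dims=1, restarts=8, seed=6)
        assert r.stress > 1e-3
        # brute-force check: no 1-D grid configuration beats the fit badly
        best = np.inf
        rng = np.random.default_rng(7)
        for _ in range(300):
            x = rng.normal(size=(4, 1))
            d = pdist(x)
            order = np.argsort(squareform(D, checks=False), kind="stable")
            from scipy.optimize import isotonic_regression

            dh = np.empty_like(d)
            dh[order] = isotonic_regression(d[order]).x
            dh *= np.sqrt((d**2).sum() / max((dh**2).sum(), 1e-300))
            best = min(best, np.sqrt(((d - dh) ** 2).sum() / (d**2).sum()))
        assert r.stress <= best + 1e-6

    def test_stress_trace_monotone_and_shift_invariant(self):
        D = squareform(pdist(np.random.default_rng(8).normal(size=(7, 4))))
        r = popstruct.nmds_embed(D, dims=2, restarts=3, seed=9)
        assert np.all(np.diff(r.stress_trace) <= 1e-9)
        shifted = D + 0.7
        np.fill_diagonal(shifted, 0.0)
        r2 = popstruct.nmds_embed(shifted, dims=2, restarts=3, seed=9)
        assert np.allclose(r.scores, r2.scores, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0, 1], [2, 0]], float)
        with pytest.raises(ValueError):
            popstruct.nmds_embed(D, dims=1)


class TestPseudoHaploid:
    def test_pure_reference_always_calls_one(self):
        rcm = make_rcm(np.full((3, 4), 10), np.zeros((3, 4), int))
        phm = popstruct.pseudo_haploid_sample(rcm, seed=1)
        assert (phm.calls == 1).all()

    def test_zero_depth_is_missing(self):
        rcm = make_rcm(np.zeros((2, 3), int), np.zeros((2, 3), int))
        phm = popstruct.pseudo_haploid_sample(rcm, seed=2)
        assert (phm.calls == popstruct.MISSING).all()

    def test_balanced_counts_sample_half_and_half(self):
        """(5,5) cells call allele 2 at rate 0.5 ± 0.015 over 10^4 cells."""
        rcm = make_rcm(np.full((100, 100), 5), np.full((100, 100), 5))
        phm = popstruct.pseudo_haploid_sample(rcm, seed=3)
        assert abs((phm.calls == 2).mean() - 0.5) < 0.015

    def test_determinism(self, two_pop_sim):
        rcm, _ = two_pop_sim
        a = popstruct.pseudo_haploid_sample(rcm, seed=4)
        b = popstruct.pseudo_haploid_sample(rcm, seed=4)
        assert np.array_equal(a.calls, b.calls)
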