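import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgdpop import io_formats as io
from wgdpop import popgen
from wgdpop.io_formats import GenotypeMatrix


def make_gm(g, d=None, positions=None):
    g = np.asarray(g, dtype=np.int16)
    n, L = g.shape
    if d is None:
        d = np.full((n, L), 50)
    loci = pd.DataFrame(
        {
            "chromosome": "chr1",
            "position": positions or list(range(10, 10 + 10 * L, 10)),
            "ref": ["A"] * L,
            "alt": ["G"] * L,
        }
    )
    return GenotypeMatrix([f"s{i}" for i in range(n)], loci, g, np.asarray(d))


class TestApplyFilters:
    def test_depth_bounds_mask_calls(self, toy_dir):
        gm = io.read_vcf(toy_dir / "filter_toy.vcf")
        out, report = popgen.apply_filters(gm)
        # sample 1 depths 10/30/250/100/60: calls at 10 and 250 masked
        assert report.n_genotypes_depth_masked == 2
        # locus 1 and locus 3 masked to 10% missing; locus 5 starts at 20%
        assert report.n_after_missingness == 2
        # the single-alt-allele locus (MAF exactly 0.05) is dropped: strict >
        assert report.n_after_maf == 1
        assert out.n_loci == 1
        assert out.loci["position"].tolist() == [200]

    def test_idempotent(self, toy_dir):
        gm = io.read_vcf(toy_dir / "filter_toy.vcf")
        once, _ = popgen.apply_filters(gm)
        twice, rep2 = popgen.apply_filters(once)
        np.testing.assert_array_equal(once.g, twice.g)
        pd.testing.assert_frame_equal(once.loci, twice.loci)
        assert rep2.n_after_maf == once.n_loci

    def test_missing_fraction_boundary(self):
        # 2/10 missing = 20% >= 10% -> dropped; 0/10 kept
        g = np.ones((10, 2))
        g[0, 0] = -1
        g[1, 0] = -1
        _, report = popgen.apply_filters(make_gm(g))
        assert report.n_after_missingness == 1

    def test_all_removed_raises_with_attrition(self):
        g = np.zeros((4, 2))  # monomorphic -> MAF 0
        with pytest.raises(ValueError, match="attrition"):
            popgen.apply_filters(make_gm(g))


class TestRestrictTo4d:
    def test_plus_and_second_position(self, small_wgd_sim):
        """Loci placed at simulated 4D third positions are kept; others dropped."""
        from wgdpop import synthetic_data as sd

        pop = sd.simulate_admixed_genotypes(
            sd.PopSimSpec(n_individuals=(5, 5), n_loci=60, seed=4),
            catalog=small_wgd_sim["catalog"],
            genome=small_wgd_sim["genome"],
            fourfold_locus_fraction=0.5,
        )
        out = popgen.restrict_to_4d_sites(
            pop.gm, small_wgd_sim["catalog"], small_wgd_sim["genome"]
        )
        assert out.n_loci == int(pop.loci_annotations["is_4d"].sum()) == 30

    def test_minus_strand_site_mapping(self, toy_dir):
        """Genomic coordinates of minus-strand 4D third positions verified
        by hand against the spliced fixture."""
        genome = io.read_fasta(toy_dir / "splice_toy.fa")
        cat = io.read_gff3(toy_dir / "splice_toy.gff3", genome)
        sites = popgen.fourfold_positions(cat, genome)
        # CDS (transcription order) genomic positions:
        # 39..31 then 19..11; codons: (39,38,37) (36,35,34) (33,32,31)
        # (19,18,17) (16,15,14) (13,12,11)
        # codon 2 = GCT (Ala, 4D) -> third at genomic 34
        # codon 3 = GCA -> third at 31; codon 4 = GCC -> third at 17
        # codon 5 = GGT (Gly) -> third at 14; ATG and TAA are not 4D
        assert sites == {"chrS": {34, 31, 17, 14}}


class TestLocusStats:
    def test_closed_forms(self):
        # p=(0.5,0.5): GD 0.5, PIC 0.375
        g = np.array([[0], [2], [1], [1]])  # freqs 0.5/0.5
        stats = popgen.locus_stats(make_gm(g))
        assert stats["GD"][0] == pytest.approx(0.5)
        assert stats["PIC"][0] == pytest.approx(0.375)
        # p=(0.95,0.05): GD 0.095, PIC 0.0905
        g = np.zeros((10, 1))
        g[0, 0] = 1
        stats = popgen.locus_stats(make_gm(g))
        assert stats["GD"][0] == pytest.approx(0.095)
        # exact closed form 0.0904875 (rounds to 0.0905)
        assert stats["PIC"][0] == pytest.approx(0.0904875)
        assert stats["MAF"][0] == pytest.approx(0.05)

    def test_ho_with_missing(self):
        g = np.array([[1], [0], [1], [-1]])
        stats = popgen.locus_stats(make_gm(g))
        assert stats["Ho"][0] == pytest.approx(2 / 3)

    def test_zero_call_locus_flagged(self):
        g = np.array([[-1, 0], [-1, 1]])
        stats = popgen.locus_stats(make_gm(g))
        assert bool(stats["flagged"][0]) and not bool(stats["flagged"][1])
        assert np.isnan(stats["GD"][0])

    def test_brute_force_oracle_on_random_loci(self):
        """Vectorized stats equal a per-locus brute-force recomputation on
        1000 random loci with missingness."""
        rng = np.random.default_rng(11)
        g = rng.integers(-1, 3, size=(30, 1000))
        stats = popgen.locus_stats(make_gm(g, positions=list(range(1, 1001))))
        for l in rng.choice(1000, size=120, replace=False):
            calls = [x for x in g[:, l] if x >= 0]
            if not calls:
                assert bool(stats["flagged"][l])
                continue
            p = sum(calls) / (2 * len(calls))
            q = 1 - p
            assert stats["GD"][l] == pytest.approx(1 - p * p - q * q)
            assert stats["PIC"][l] == pytest.approx(1 - p * p - q * q - 2 * p * p * q * q)
            assert stats["Ho"][l] == pytest.approx(sum(1 for x in calls if x == 1) / len(calls))
            assert stats["MAF"][l] == pytest.approx(min(p, q))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_pic_bounded_by_gd_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(-1, 3, size=(12, 20))
        if not ((g >= 0).sum(axis=0) > 0).all():
            g[0] = np.abs(g[0])
        stats = popgen.locus_stats(make_gm(g))
        ok = ~stats["flagged"]
        assert (stats.loc[ok, "PIC"] <= stats.loc[ok, "GD"] + 1e-12).all()
        perm = rng.permutation(g.shape[0])
        stats_p = popgen.locus_stats(make_gm(g[perm]))
        pd.testing.assert_series_equal(stats["GD"], stats_p["GD"])


class TestPca:
    def test_two_samples_pc1_explains_all(self):
        g = np.array([[0, 0, 0, 0], [2, 2, 2, 2]])
        res = popgen.pca_covariance(make_gm(g))
        assert res["proportions"][0] == pytest.approx(1.0)

    def test_duplicated_samples_zero_eigenvalue(self):
        g = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        res = popgen.pca_covariance(make_gm(g))
        assert res["eigenvalues"][-1] == pytest.approx(0.0, abs=1e-10)

    def test_proportions_sum_to_one_and_order_invariance(self, pop_sim):
        gm, _ = popgen.apply_filters(pop_sim.gm)
        res = popgen.pca_covariance(gm)
        assert res["proportions"].sum() == pytest.approx(1.0)
        perm = np.random.default_rng(0).permutation(gm.n_samples)
        gm_p = io.GenotypeMatrix(
            [gm.sample_ids[i] for i in perm], gm.loci, gm.g[perm], gm.d[perm]
        )
        res_p = popgen.pca_covariance(gm_p)
        np.testing.assert_allclose(
            np.abs(res_p["scores"][:, 0]), np.abs(res["scores"][perm, 0]), atol=1e-8
        )

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            popgen.pca_covariance(make_gm(np.array([[0, 1]])))

    def test_pc1_separates_simulated_populations(self):
        from wgdpop import synthetic_data as sd

        pop = sd.simulate_admixed_genotypes(
            sd.PopSimSpec(n_individuals=(30, 30), n_loci=800, fst=0.1, seed=11)
        )
        gm, _ = popgen.apply_filters(pop.gm)
        res = popgen.pca_covariance(gm)
        pc1 = res["scores"][:, 0]
        a, b = pc1[pop.population_of == 0], pc1[pop.population_of == 1]
        assert max(a.max(), b.max()) > min(a.min(), b.min())
        assert a.max() < b.min() or b.max() < a.min()  # no overlap of scores


class TestDistanceMatrix:
    def test_identical_and_opposite(self):
        g = np.array([[0, 0], [0, 0], [2, 2]])
        d = popgen.distance_matrix(make_gm(g))
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0

    def test_hand_worked_three_samples(self):
        g = np.array([[0, 1, 2, -1], [1, 1, 0, 0], [2, -1, 2, 2]])
        d = popgen.distance_matrix(make_gm(g))
        # s0-s1: loci 0,1,2 co-called: (1+0+2)/2 /3 = 0.5
        assert d[0, 1] == pytest.approx(0.5)
        # s0-s2: loci 0,2 co-called: (2+0)/2 /2 = 0.5
        assert d[0, 2] == pytest.approx(0.5)
        # s1-s2: loci 0,2,3: (1+2+2)/2 /3 = 5/6... check: |1-2|+|0-2|+|0-2| = 5 -> /2 /3
        assert d[1, 2] == pytest.approx(5 / 6)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)

    def test_no_cocalled_pair_undefined(self):
        g = np.array([[0, -1], [-1, 2]])
        d = popgen.distance_matrix(make_gm(g))
        assert np.isnan(d[0, 1])


class TestAdmixtureEm:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(20, 50))
        gm = make_gm(g, positions=list(range(1, 51)))
        fit = popgen.admixture_em(gm, K=1, seed=0)
        np.testing.assert_allclose(fit.Q, 1.0)
        np.testing.assert_allclose(fit.P[0], g.mean(axis=0) / 2.0, atol=1e-10)

    def test_loglik_trace_non_decreasing(self, pop_sim):
        gm, _ = popgen.apply_filters(pop_sim.gm)
        sub = gm.subset_loci(np.arange(300))
        for k in (2, 3):
            fit = popgen.admixture_em(sub, K=k, seed=1, max_iter=300)
            diffs = np.diff(fit.loglik_trace)
            assert (diffs >= -1e-6).all()

    def test_k_exceeding_samples_errors(self):
        gm = make_gm(np.ones((3, 4)))
        with pytest.raises(ValueError, match="exceeds"):
            popgen.admixture_em(gm, K=5)

    def test_q_recovery_strong_divergence(self):
        """Fst 0.3 panels: K=2 classification accuracy >= 0.95 after label
        alignment, across 5 seeds."""
        from wgdpop import synthetic_data as sd

        for seed in range(5):
            pop = sd.simulate_admixed_genotypes(
                sd.PopSimSpec(n_individuals=(25, 25), n_loci=500, fst=0.3, seed=seed)
            )
            gm, _ = popgen.apply_filters(pop.gm)
            fit = popgen.admixture_em(gm, K=2, seed=seed, max_iter=500)
            q = popgen.align_cluster_labels(fit.Q, pop.Q_true)
            assigned = q.argmax(axis=1)
            truth = pop.Q_true.argmax(axis=1)
            assert (assigned == truth).mean() >= 0.95


class TestEvannoDeltaK:
    def _fits(self, mean_l, sd=1.0, n=3):
        out = {}
        for k, m in enumerate(mean_l, start=1):
            lls = [m - sd, m, m + sd]  # sample sd == sd
            out[k] = [
                popgen.AdmixtureFit(k, np.ones((2, k)) / k, np.ones((k, 2)) / 2, ll, [ll], 1, 0, True)
                for ll in lls
            ]
        return out

    def test_worked_arithmetic(self):
        """mean L = (-1000, -800, -790, -788), sd 1: delta-K = 190 at K=2,
        8 at K=3; K=2 selected."""
        report = popgen.evanno_delta_k(self._fits([-1000, -800, -790, -788]))
        assert report.delta_k[2] == pytest.approx(190.0)
        assert report.delta_k[3] == pytest.approx(8.0)
        assert report.selected_k == 2

    def test_flat_likelihood_flagged_unreliable(self):
        report = popgen.evanno_delta_k(self._fits([-1000.0, -1000.001, -1000.002, -1000.001]))
        assert not report.reliable

    def test_zero_sd_reported_undefined(self):
        fits = self._fits([-1000, -800, -790, -788], sd=0.0)
        report = popgen.evanno_delta_k(fits)
        assert report.delta_k[2] is None and report.delta_k[3] is None
        assert report.selected_k is None

    def test_requires_three_replicates_and_consecutive_k(self):
        fits = self._fits([-10, -9, -8])
        fits[2] = fits[2][:2]
        with pytest.raises(ValueError):
            popgen.evanno_delta_k(fits)
        with pytest.raises(ValueError):
            popgen.evanno_delta_k({1: [], 3: [], 5: []})
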