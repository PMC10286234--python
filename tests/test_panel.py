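from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from sympy.utilities.iterables import multiset_permutations

from hmkpop import Admixture, genotyping_qc, hwe_exact, individual_pca, ld_test, reduce_panel, wc_fst
from hmkpop.containers import ValidationError
from hmkpop.panel import ld_groups

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# QC


class TestQc:
    def test_low_call_rate_individual_dropped(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(10, 10)).astype(float)
        geno[0, 7:] = np.nan  # 7/10 calls -> rate 0.7 <= 0.8 -> dropped
        # marker rates stay at 9/10, so markers survive the first pass
        rep = genotyping_qc(make_genotypes(geno), threshold=0.8)
        assert rep.dropped_individuals == ["ind0"]
        assert rep.dropped_markers == []

    def test_fully_typed_marker_kept(self):
        geno = np.array([[0, 1], [1, 0], [2, 2.0]])
        rep = genotyping_qc(make_genotypes(geno))
        assert rep.dropped_markers == []

    def test_monomorphic_marker_dropped(self):
        geno = np.array([[0, 1.0], [0, 2], [0, 0]])
        rep = genotyping_qc(make_genotypes(geno))
        assert rep.dropped_markers == ["chr1_1000"]

    def test_replicate_homozygote_conflict_drops_marker(self):
        geno = np.array([[0, 1.0], [2, 1], [1, 0], [0, 2]])
        gm = make_genotypes(geno)
        rep = genotyping_qc(gm, replicate_pairs=[("ind0", "ind1")])
        assert "chr1_1000" in rep.dropped_markers  # 0 vs 2 conflict

    def test_everything_filtered_rejected(self):
        geno = np.full((3, 2), np.nan)
        geno[0] = [0, 1]
        with pytest.raises(ValidationError):
            genotyping_qc(make_genotypes(geno), threshold=0.99)


# ---------------------------------------------------------------------------
# HWE exact test with a full-enumeration oracle


def hwe_oracle(n_aa, n_ab, n_bb):
    """Brute force: enumerate every ordering of the allele multiset into
    ordered gamete pairs, tally the het-count distribution exactly."""
    n = n_aa + n_ab + n_bb
    alleles = [0] * (2 * n_aa + n_ab) + [1] * (2 * n_bb + n_ab)
    tally: dict[int, int] = {}
    total = 0
    for perm in multiset_permutations(alleles):
        h = sum(perm[2 * i] != perm[2 * i + 1] for i in range(n))
        tally[h] = tally.get(h, 0) + 1
        total += 1
    probs = {h: Fraction(c, total) for h, c in tally.items()}
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExact:
    def test_monomorphic_p_one(self):
        assert hwe_exact(10, 0, 0) == 1.0

    def test_het_excess_small(self):
        assert hwe_exact(0, 20, 0) < 0.01

    def test_hwe_proportions_large_p(self):
        assert hwe_exact(25, 50, 25) >= 0.5

    @pytest.mark.parametrize(
        "counts",
        [(1, 2, 1), (3, 0, 3), (0, 4, 0), (2, 3, 1), (4, 1, 0), (1, 1, 4)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-12)

    def test_super_uniform_under_null(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        ps = []
        for _ in range(500):
            f = rng.uniform(0.1, 0.9)
            g = rng.binomial(2, f, size=60)
            ps.append(hwe_exact(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())))
        # one-sided KS against the anti-conservative direction
        assert stats.kstest(ps, "uniform", alternative="greater").pvalue > 0.01
        assert np.mean(np.array(ps) <= 0.05) <= 0.05 + 0.02


# ---------------------------------------------------------------------------
# LD


class TestLd:
    def test_identical_vectors_r2_one(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 40).astype(float)
        r2, p = ld_test(g, g.copy(), n_perm=99, seed=0)
        assert r2 == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_insufficient_overlap_missing(self):
        g1 = np.array([0, 1, 2, 0, 1] + [np.nan] * 10)
        g2 = np.array([np.nan] * 10 + [0, 1, 2, 0, 1.0])
        assert ld_test(g1, g2, n_perm=19, seed=0) is None

    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(1)
        rejections = 0
        for rep in range(200):
            g1 = rng.binomial(2, 0.4, 40).astype(float)
            g2 = rng.binomial(2, 0.4, 40).astype(float)
            res = ld_test(g1, g2, n_perm=99, seed=rep)
            if res is not None and res[1] <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / 200 <= 0.08

    def test_proximity_rule_links_nonsignificant_pair(self):
        rng = np.random.default_rng(2)
        geno = rng.binomial(2, 0.4, size=(30, 3)).astype(float)
        gm = make_genotypes(geno, chrom=["chr5", "chr5", "chr9"], pos=[1000, 6000, 1000])
        groups = ld_groups(gm, n_perm=49, proximity_bp=10_000, seed=0)
        assert [0, 1] in groups  # same chromosome, 5 kb apart


# ---------------------------------------------------------------------------
# Weir-Cockerham FST from genotypes


def wc_oracle_two_pops(geno1, geno2):
    """Independent scalar implementation of the 1984 two-population theta,
    single locus, ratio a / (a + b + c), using exact fractions."""
    pops = [np.asarray(geno1), np.asarray(geno2)]
    r = 2
    ns = [Fraction(len(g)) for g in pops]
    ps = [Fraction(int(g.sum()), 2 * len(g)) for g in pops]
    hs = [Fraction(int((g == 1).sum()), len(g)) for g in pops]
    n_bar = sum(ns) / r
    n_c = (r * n_bar - sum(n * n for n in ns) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(ns, ps)) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(ns, hs)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - Fraction(r - 1, r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - Fraction(r - 1, r) * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return float(a / (a + b + c))


class TestWcFst:
    def test_alternate_fixation_theta_one(self):
        geno = np.array([[0, 0], [0, 0], [2, 2], [2, 2.0]])
        gm = make_genotypes(geno, sites=["P1", "P1", "P2", "P2"])
        out = wc_fst(gm)
        assert out["multi_locus"] == pytest.approx(1.0)

    def test_panmictic_near_zero(self):
        rng = np.random.default_rng(3)
        geno = rng.binomial(2, rng.uniform(0.2, 0.8, 200), size=(60, 200)).astype(float)
        gm = make_genotypes(geno, sites=["P1"] * 30 + ["P2"] * 30)
        out = wc_fst(gm)
        assert abs(out["multi_locus"]) < 0.01

    def test_textbook_toy_matches_independent_oracle(self):
        g1 = np.array([0, 0, 1, 1, 2, 0, 1, 0])
        g2 = np.array([2, 2, 1, 2, 1, 2, 0])
        gm = make_genotypes(
            np.concatenate([g1, g2]).reshape(-1, 1).astype(float),
            sites=["P1"] * 8 + ["P2"] * 7,
        )
        out = wc_fst(gm)
        assert out["per_locus"].iloc[0] == pytest.approx(wc_oracle_two_pops(g1, g2), abs=1e-10)

    def test_single_population_rejected(self):
        gm = make_genotypes([[0, 1.0], [1, 2]], sites=["P1", "P1"])
        with pytest.raises(ValidationError):
            wc_fst(gm)

    def test_pairwise_matrix_symmetric(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(0, 3, size=(30, 20)).astype(float)
        gm = make_genotypes(geno, sites=["P1"] * 10 + ["P2"] * 10 + ["P3"] * 10)
        mat = wc_fst(gm)["pairwise"]
        pd.testing.assert_frame_equal(mat, mat.T)


# ---------------------------------------------------------------------------
# panel reduction


class TestReducePanel:
    def test_singletons_unchanged(self):
        gm = make_genotypes(np.zeros((2, 3)))
        fst = pd.Series([0.1, 0.2, 0.3], index=gm.snp_labels().to_numpy())
        kept = reduce_panel(gm, [[0], [1], [2]], fst)
        assert kept == [0, 1, 2]

    def test_highest_fst_kept(self):
        gm = make_genotypes(np.zeros((2, 2)))
        fst = pd.Series([0.30, 0.10], index=gm.snp_labels().to_numpy())
        assert reduce_panel(gm, [[0, 1]], fst) == [0]

    def test_tie_breaks_leftmost(self):
        gm = make_genotypes(np.zeros((2, 2)), pos=[5000, 2000])
        fst = pd.Series([0.2, 0.2], index=gm.snp_labels().to_numpy())
        assert reduce_panel(gm, [[0, 1]], fst) == [1]  # position 2000

    def test_output_size_equals_group_count(self):
        rng = np.random.default_rng(5)
        gm = make_genotypes(np.zeros((2, 6)))
        fst = pd.Series(rng.uniform(size=6), index=gm.snp_labels().to_numpy())
        groups = [[0, 1], [2], [3, 4, 5]]
        assert len(reduce_panel(gm, groups, fst)) == len(groups)


# ---------------------------------------------------------------------------
# individual PCA and admixture


class TestIndividualPca:
    def test_duplicated_individual_identical_scores(self):
        geno = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1.0]])
        res = individual_pca(make_genotypes(geno))
        np.testing.assert_allclose(
            res.scores.iloc[0].to_numpy(), res.scores.iloc[1].to_numpy(), atol=1e-9
        )

    def test_fixed_difference_populations_separate(self):
        geno = np.vstack([np.zeros((10, 20)), np.full((10, 20), 2.0)])
        res = individual_pca(make_genotypes(geno))
        pc1 = res.scores["PC1"].to_numpy()
        assert max(pc1[:10]) < min(pc1[10:]) or min(pc1[:10]) > max(pc1[10:])


class TestAdmixture:
    def _diverged(self, n=15, m=50):
        geno = np.vstack([np.zeros((n, m)), np.full((n, m), 2.0)])
        return make_genotypes(geno, sites=["A"] * n + ["B"] * n)

    def test_k1_single_ancestry_column(self):
        fit = Admixture(self._diverged()).fit(
            K_range=[1], repetitions=2, iterations=20, seed=0
        )
        np.testing.assert_allclose(fit.Q, 1.0)

    def test_q_rows_on_simplex(self):
        fit = Admixture(self._diverged()).fit(
            K_range=[3], repetitions=2, iterations=30, seed=1
        )
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-6)
        assert (fit.Q >= 0).all() and (fit.G >= 0).all() and (fit.G <= 1).all()

    def test_diverged_populations_resolved_at_k2(self):
        fit = Admixture(self._diverged()).fit(
            K_range=[2], repetitions=3, iterations=60, seed=2
        )
        assert fit.Q.max(axis=1).mean() > 0.95
        lab = fit.Q.argmax(axis=1)
        assert len(set(lab[:15])) == 1 and len(set(lab[15:])) == 1 and lab[0] != lab[-1]

    def test_k_exceeding_individuals_rejected(self):
        gm = self._diverged(n=2, m=10)
        with pytest.raises(ValidationError):
            Admixture(gm).fit(K_range=[10], repetitions=1, iterations=5, seed=0)

    def test_missing_entries_tolerated(self):
        gm = self._diverged()
        geno = gm.geno.copy()
        geno[0, :5] = np.nan
        gm2 = make_genotypes(geno, sites=gm.sites.tolist())
        fit = Admixture(gm2).fit(K_range=[2], repetitions=2, iterations=30, seed=3)
        assert np.isfinite(fit.cross_entropy["cross_entropy"]).all()
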