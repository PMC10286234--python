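import math

import numpy as np
import pandas as pd
import pytest

from hmkpop import (
    block_jackknife_ci,
    great_circle_km,
    group_fst_comparison,
    ibd_test,
    pairwise_fst_matrix,
    pairwise_pool_fst,
    simulate_metapopulation,
)
from hmkpop.containers import PoolCountMatrix, ValidationError
from hmkpop.fst import linearize_fst
from hmkpop.simulate import SimConfig


# ---------------------------------------------------------------------------
# independent brute-force oracle, written before the vectorised estimator


def oracle_pool_fst(rows, n_a, n_b):
    """Per-SNP moment estimator computed with explicit pair counting.

    rows: list of (ref_a, alt_a, ref_b, alt_b). Identity of a read pair is
    counted combinatorially; within-pool identity is deconvolved through the
    probability 1/n that two reads hit the same chromosome.
    """
    num_sum = den_sum = 0.0
    for ref_a, alt_a, ref_b, alt_b in rows:
        ca, cb = ref_a + alt_a, ref_b + alt_b
        if ca < 2 or cb < 2:
            continue
        same_a = (math.comb(alt_a, 2) + math.comb(ref_a, 2)) / math.comb(ca, 2)
        same_b = (math.comb(alt_b, 2) + math.comb(ref_b, 2)) / math.comb(cb, 2)
        q1a = (n_a * same_a - 1) / (n_a - 1)
        q1b = (n_b * same_b - 1) / (n_b - 1)
        q1 = (q1a + q1b) / 2
        q2 = (alt_a / ca) * (alt_b / cb) + (ref_a / ca) * (ref_b / cb)
        num_sum += q1 - q2
        den_sum += 1 - q2
    return num_sum / den_sum


def counts_from_rows(rows, n_ind=(50, 50)):
    snps = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": (np.arange(len(rows)) + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    rows = np.asarray(rows)
    pools = pd.DataFrame(
        {
            "pool_id": ["A", "B"],
            "n_individuals": list(n_ind),
            "latitude": [50, 40],
            "longitude": [0, 0],
            "group_label": ["x", "y"],
        }
    )
    return PoolCountMatrix(
        snps=snps,
        ref_count=rows[:, [0, 2]],
        alt_count=rows[:, [1, 3]],
        pools=pools,
    )


class TestPoolFst:
    def test_five_snp_toy_matches_oracle_exactly(self):
        rows = [
            (30, 10, 12, 8),
            (5, 35, 33, 7),
            (20, 20, 19, 21),
            (40, 0, 0, 40),
            (13, 27, 25, 15),
        ]
        counts = counts_from_rows(rows)
        result = pairwise_pool_fst(counts, "A", "B")
        assert result.fst == pytest.approx(oracle_pool_fst(rows, 100, 100), abs=1e-10)
        assert result.n_snps_used == 5

    def test_alternate_fixation_near_one(self):
        rows = [(200, 0, 0, 200)] * 50
        counts = counts_from_rows(rows)
        assert pairwise_pool_fst(counts, "A", "B").fst >= 0.95

    def test_no_differentiation_within_two_se_of_zero(self):
        truth = simulate_metapopulation(
            SimConfig(
                site_ids=["A", "B"], pool_sizes=[50, 50], latitudes=[50, 40],
                longitudes=[0, 0], group_labels=["a", "b"],
                chrom_lengths={"chr1": 10_000_000}, n_neutral_snps=5000,
                background_fst=0.0, mean_depths=[40, 40], seed=5,
            )
        )
        from hmkpop import pool_and_sequence

        r = pairwise_pool_fst(pool_and_sequence(truth), "A", "B")
        assert abs(r.fst) <= 2 * r.se

    def test_symmetry(self, tiny_counts):
        a = pairwise_pool_fst(tiny_counts, "A", "B")
        b = pairwise_pool_fst(tiny_counts, "B", "A")
        assert a.fst == pytest.approx(b.fst, abs=1e-12)

    def test_depth_zero_snps_excluded(self, tiny_counts):
        r = pairwise_pool_fst(tiny_counts, "A", "B")
        assert r.n_snps_used == 2  # SNP 2 untyped in pool B


class TestBlockJackknife:
    def test_identical_blocks_zero_se(self):
        se, _ = block_jackknife_ci(np.full(10, 2.0), np.full(10, 100.0))
        assert se == pytest.approx(0.0, abs=1e-15)

    def test_two_block_closed_form(self):
        num = np.array([3.0, 5.0])
        den = np.array([100.0, 90.0])
        theta1 = num[1] / den[1]  # delete block 0
        theta2 = num[0] / den[0]
        se, ci = block_jackknife_ci(num, den)
        assert se == pytest.approx(abs(theta1 - theta2) / 2)
        fst = num.sum() / den.sum()
        assert ci == (pytest.approx(fst - 1.96 * se), pytest.approx(fst + 1.96 * se))

    def test_single_block_rejected(self):
        with pytest.raises(ValidationError):
            block_jackknife_ci(np.array([1.0]), np.array([10.0]))

    def test_se_shrinks_with_block_count(self):
        """On homogeneous data SE scales like 1/sqrt(B)."""
        rng = np.random.default_rng(0)
        num = rng.normal(2.0, 0.2, size=40)
        den = np.full(40, 100.0)
        se10, _ = block_jackknife_ci(num[:10], den[:10])
        se40, _ = block_jackknife_ci(num, den)
        assert se40 < se10


class TestGroupComparison:
    def test_identical_sets_p_one(self):
        out = group_fst_comparison({"same": (np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))})
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_exact_rank_sum_enumeration(self):
        out = group_fst_comparison({"sep": (np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))})
        assert out["p_value"].iloc[0] == pytest.approx(0.1)  # 2 / C(6,3)

    def test_holm_adjustment_by_hand(self):
        fake = {
            "a": (np.array([1.0, 2, 3]), np.array([4.0, 5, 6])),
            "b": (np.array([1.0, 2, 3]), np.array([1.0, 2, 3])),
        }
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.5], method="holm")[1]
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.5])
        out = group_fst_comparison(fake)  # surface runs Holm over the family
        assert (out["p_adjusted"] >= out["p_value"]).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            group_fst_comparison({"x": (np.array([]), np.array([1.0]))})


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert great_circle_km((54.42, -10.62), (54.42, -10.62)) == 0.0

    def test_quarter_great_circle(self):
        assert great_circle_km((0, 0), (0, 90)) == pytest.approx(np.pi * 6371 / 2)

    def test_study_pair_matches_independent_haversine(self):
        # independent formula: spherical law of cosines
        lat1, lon1, lat2, lon2 = map(math.radians, (54.42, -10.62, 43.59, -2.78))
        expected = 6371.0 * math.acos(
            math.sin(lat1) * math.sin(lat2)
            + math.cos(lat1) * math.cos(lat2) * math.cos(lon2 - lon1)
        )
        assert great_circle_km((54.42, -10.62), (43.59, -2.78)) == pytest.approx(
            expected, rel=1e-9
        )

    def test_symmetry(self):
        a, b = (54.15, 3.30), (20.20, -17.50)
        assert great_circle_km(a, b) == pytest.approx(great_circle_km(b, a))


class TestIbd:
    def _meta(self, n):
        rng = np.random.default_rng(1)
        return pd.DataFrame(
            {
                "pool_id": [f"p{i}" for i in range(n)],
                "n_individuals": [50] * n,
                "latitude": np.linspace(35, 55, n),
                "longitude": rng.uniform(-15, 0, n),
                "group_label": ["g"] * n,
            }
        )

    def test_linearization(self):
        assert linearize_fst(np.array([0.01]))[0] == pytest.approx(0.01 / 0.99)

    def test_fst_one_rejected(self):
        meta = self._meta(3)
        mat = pd.DataFrame(
            [[0, 1.0, 0.1], [1.0, 0, 0.1], [0.1, 0.1, 0]],
            index=meta["pool_id"], columns=meta["pool_id"],
        )
        with pytest.raises(ValidationError):
            ibd_test(mat, meta, n_perm=19, seed=0)

    def test_perfect_proportionality(self):
        from hmkpop.fst import distance_matrix_km

        meta = self._meta(7)
        km = distance_matrix_km(meta)
        fst_lin = km * 1e-6
        fst = fst_lin / (1 + fst_lin)  # invert the linearization
        res = ibd_test(fst, meta, n_perm=199, seed=0)
        assert res.mantel_r == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.slope == pytest.approx(1e-6, rel=1e-6)

    def test_type_one_error_controlled(self):
        """Shuffled labels on an IBD-free FST matrix reject at ~alpha."""
        meta = self._meta(8)
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            v = rng.uniform(0.001, 0.02, size=(8, 8))
            mat = np.triu(v, 1)
            mat = mat + mat.T
            fst = pd.DataFrame(mat, index=meta["pool_id"], columns=meta["pool_id"])
            res = ibd_test(fst, meta, n_perm=99, seed=rep)
            rejections += res.p_value <= 0.05
        assert rejections / n_rep <= 0.07

    def test_exclusion_of_temporal_replicate(self):
        meta = self._meta(6)
        rng = np.random.default_rng(2)
        v = np.triu(rng.uniform(0.001, 0.02, size=(6, 6)), 1)
        fst = pd.DataFrame(v + v.T, index=meta["pool_id"], columns=meta["pool_id"])
        res = ibd_test(fst, meta, n_perm=49, seed=1, exclude=["p5"])
        assert res.n_permutations == 49


def test_matrix_symmetric(tiny_counts):
    mat = pairwise_fst_matrix(tiny_counts, block_size=2)
    assert mat.loc["A", "B"] == mat.loc["B", "A"]
    assert (np.diag(mat) == 0).all()
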