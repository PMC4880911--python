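import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mut3d import (
    adaptive_pvalue, avg_pairwise_distance_1d, avg_pairwise_distance_3d,
    bh_fdr, call_genes, exact_pvalue, permutation_pvalue,
    select_best_structure,
)
from mut3d.permtest import DistanceObservation, PermutationResult


def brute_force_pvalue(points, n, observed, dim3=True):
    """Independent enumeration oracle over all ordered draws."""
    total, hits = 0, 0
    idx = range(len(points))
    for draw in itertools.product(idx, repeat=n):
        if dim3:
            ds = [math.dist(points[a], points[b])
                  for a, b in itertools.combinations(draw, 2)]
        else:
            ds = [abs(points[a] - points[b])
                  for a, b in itertools.combinations(draw, 2)]
        total += 1
        if sum(ds) / len(ds) <= observed + 1e-12:
            hits += 1
    return hits / total


def result(gene="G", sid="S", n=3, p=0.5, m=9999, dim="3D"):
    obs = DistanceObservation(gene=gene, structure_id=sid, n=n,
                              observed_avg_distance=1.0, dimension=dim)
    k = round(p * (m + 1)) - 1
    return PermutationResult(observation=obs, m=m, k=k,
                             p_value=(k + 1) / (m + 1), seed=0)


class TestAverageDistances:
    @pytest.mark.parametrize("coords,expected", [
        ([(0, 0, 0), (3, 4, 0)], 5.0),
        ([(0, 0, 0), (0, 0, 0), (0, 0, 0)], 0.0),
        ([(0, 0, 0), (1, 0, 0), (2, 0, 0)], 4 / 3),
    ])
    def test_3d_examples(self, coords, expected):
        assert avg_pairwise_distance_3d(coords) == pytest.approx(expected)

    @pytest.mark.parametrize("pos,expected", [
        ([10, 20], 10.0), ([5, 5, 5], 0.0), ([1, 2, 4], 2.0),
    ])
    def test_1d_examples(self, pos, expected):
        assert avg_pairwise_distance_1d(pos) == pytest.approx(expected)

    def test_single_mutation_is_undefined(self):
        with pytest.raises(ValueError, match="undefined statistic"):
            avg_pairwise_distance_3d([(0, 0, 0)])
        with pytest.raises(ValueError, match="undefined statistic"):
            avg_pairwise_distance_1d([7])


class TestExactPvalue:
    def test_coincident_pair_on_collinear_triple(self, collinear3):
        assert exact_pvalue(collinear3, 2, 0.0) == pytest.approx(1 / 3)

    def test_unit_square_side(self, unit_square):
        assert exact_pvalue(unit_square, 2, 1.0) == pytest.approx(0.75)

    def test_observed_at_maximum_gives_one(self, collinear3):
        assert exact_pvalue(collinear3, 2, 2.0) == 1.0

    def test_1d_universe(self):
        # codons 1..3, n=2: same enumeration as three collinear residues
        assert exact_pvalue(3, 2, 0.0, dimension="1D") == pytest.approx(1 / 3)

    def test_explosion_guard(self):
        with pytest.raises(ValueError, match="enumeration"):
            exact_pvalue(np.zeros((50, 3)), 5, 1.0)

    @pytest.mark.parametrize("seed,n", [(0, 2), (1, 2), (2, 3), (3, 3)])
    def test_matches_independent_bruteforce(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(6, 3))
        obs = avg_pairwise_distance_3d(pts[rng.integers(0, 6, size=n)])
        assert exact_pvalue(pts, n, obs) == pytest.approx(
            brute_force_pvalue(pts, n, obs)
        )


class TestPermutationPvalue:
    def test_degenerate_universe_gives_p_one(self):
        pts = np.zeros((5, 3))
        res = permutation_pvalue(pts, 3, 0.0, 1000, seed=1)
        assert res.p_value == 1.0

    def test_collinear_coincident_pair_near_one_third(self, collinear3):
        m = 10_000
        res = permutation_pvalue(collinear3, 2, 0.0, m, seed=11)
        se = math.sqrt((1 / 3) * (2 / 3) / m)
        assert abs(res.p_value - 1 / 3) < 3 * se

    def test_add_one_estimator_form(self, collinear3):
        res = permutation_pvalue(collinear3, 2, 0.0, 999, seed=5)
        assert res.p_value == (res.k + 1) / (res.m + 1)
        assert 0 < res.p_value <= 1

    def test_reproducible_given_seed(self, coil200):
        a = permutation_pvalue(coil200, 4, 20.0, 5000, seed=3)
        b = permutation_pvalue(coil200, 4, 20.0, 5000, seed=3)
        assert a.p_value == b.p_value and a.k == b.k

    def test_universe_too_small_raises(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.zeros((1, 3)), 2, 0.0, 100, seed=0)

    def test_without_replacement_mode(self, collinear3):
        # without replacement a coincident pair can never be simulated:
        # every simulated distance exceeds 0, so p is the minimum (k=0)
        m = 2000
        res = permutation_pvalue(collinear3, 2, 0.0, m, seed=2,
                                 replacement=False)
        assert res.k == 0 and res.p_value == 1 / (m + 1)

    def test_null_pvalues_approximately_uniform(self, coil200):
        """Observed sets drawn from the null itself give p ~ Uniform(0,1]."""
        m, reps, n = 999, 500, 3
        coords = coil200.coordinates()
        rng = np.random.default_rng(77)
        pvals = []
        for i in range(reps):
            obs_pts = coords[rng.integers(0, len(coords), size=n)]
            obs = avg_pairwise_distance_3d(obs_pts)
            pvals.append(permutation_pvalue(coil200, n, obs, m, seed=1000 + i)
                         .p_value)
        d = stats.kstest(pvals, "uniform").statistic
        assert d < 1.63 / math.sqrt(reps)  # 1% critical band


class TestAdaptive:
    def test_large_p_stays_stage_one(self, coil200):
        coords = coil200.coordinates()
        obs = avg_pairwise_distance_3d(coords[::40][:5])  # scattered
        res = adaptive_pvalue(coil200, 5, obs, base_seed=1, m1=2000, m2=20_000)
        assert res.stage == 1 and res.m == 2000 and res.stage1_p is None

    def test_hotspot_escalates_to_stage_two(self, coil200):
        res = adaptive_pvalue(coil200, 3, 0.0, base_seed=1, m1=2000, m2=20_000)
        assert res.stage == 2 and res.m == 20_000
        assert res.stage1_p is not None and res.stage1_p <= 0.01

    def test_boundary_p_exactly_escalation_threshold_escalates(self, coil200):
        # a negative observed value forces k=0, so stage-1 p = 1/(99+1) = 0.01
        res = adaptive_pvalue(coil200, 3, -1.0, base_seed=1, m1=99, m2=5000)
        assert res.stage1_p == pytest.approx(0.01)
        assert res.stage == 2


class TestSelectBestStructure:
    def test_lowest_p_wins(self):
        best = select_best_structure([result(sid="A", p=0.3),
                                      result(sid="B", p=0.002)])
        assert best.observation.structure_id == "B"

    def test_single_structure_identity(self):
        r = result(sid="ONLY")
        assert select_best_structure([r]) is r

    def test_tie_broken_by_larger_n_then_id(self):
        best = select_best_structure([result(sid="A", n=4, p=0.05),
                                      result(sid="B", n=6, p=0.05)])
        assert best.observation.n == 6
        best = select_best_structure([result(sid="B", n=4, p=0.05),
                                      result(sid="A", n=4, p=0.05)])
        assert best.observation.structure_id == "A"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_best_structure([])


def stepup_oracle(p):
    """Hand-rolled BH step-up, independent of the implementation."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        q[i] = prev
    return q


class TestBH:
    def test_hand_examples(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])
        np.testing.assert_allclose(bh_fdr([0.005, 0.5]), [0.01, 0.5])

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40)).tolist()
            np.testing.assert_allclose(bh_fdr(p), stepup_oracle(p),
                                       rtol=1e-12)

    def test_sorted_q_monotone_and_max_equals_max_p_times_one(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1.0, size=25)
        q = bh_fdr(p)
        qs = q[np.argsort(p)]
        assert np.all(np.diff(qs) >= -1e-15)
        assert qs[-1] == pytest.approx(np.sort(p)[-1])


class TestCallGenes:
    def freq(self, **kw):
        return kw

    def test_boundary_semantics(self):
        # two genes so BH is non-trivial but q-values stay interpretable
        results = [result(gene="A", p=0.1), result(gene="B", p=0.1)]
        calls = call_genes(results, {"A": 0.031, "B": 0.03})
        by = {c.gene: c for c in calls}
        assert by["A"].q_value == pytest.approx(0.1)
        assert by["A"].significant          # q == 0.1 inclusive, freq > 3%
        assert not by["B"].significant      # freq not strictly greater

    def test_low_n_gene_rejected(self):
        with pytest.raises(ValueError, match="should not have been tested"):
            call_genes([result(n=2)], {"G": 0.5})

    def test_bh_family_is_tested_set(self):
        ps = [0.001, 0.002, 0.004, 0.8]
        results = [result(gene=f"G{i}", p=p) for i, p in enumerate(ps)]
        calls = call_genes(results, {f"G{i}": 0.5 for i in range(4)})
        assert [c.q_value for c in calls] == pytest.approx(
            stepup_oracle(ps), rel=1e-9
        )


class TestInvariances:
    def test_rigid_motion_preserves_distances_and_pvalue(self, coil200):
        coords = coil200.coordinates()
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q.T + np.array([5.0, 6.0, -7.0])
        mut = [3, 50, 90, 150]
        obs0 = avg_pairwise_distance_3d(coords[mut])
        obs1 = avg_pairwise_distance_3d(moved[mut])
        assert abs(obs0 - obs1) < 1e-9
        r0 = permutation_pvalue(coords, 4, obs0, 5000, seed=9)
        r1 = permutation_pvalue(moved, 4, obs1, 5000, seed=9)
        assert r0.p_value == r1.p_value

    def test_scaling_scales_distance_leaves_p(self, coil200):
        coords = coil200.coordinates()
        c = 2.5
        mut = [3, 50, 90, 150]
        obs = avg_pairwise_distance_3d(coords[mut])
        obs_scaled = avg_pairwise_distance_3d(c * coords[mut])
        assert obs_scaled == pytest.approx(c * obs, rel=1e-12)
        r0 = permutation_pvalue(coords, 4, obs, 5000, seed=13)
        r1 = permutation_pvalue(c * coords, 4, obs_scaled, 5000, seed=13)
        assert r0.p_value == r1.p_value


class TestPower:
    def test_hotspot_attains_minimum_achievable_p(self, coil200):
        m = 10_000
        res = permutation_pvalue(coil200, 4, 0.0, m, seed=21)
        # nothing is below an observed distance of zero except exact ties
        floor = permutation_pvalue(coil200, 4, -1.0, m, seed=21)
        assert res.k >= floor.k
        assert res.p_value <= permutation_pvalue(
            coil200, 4, 5.0, m, seed=21).p_value
        assert res.p_value == (res.k + 1) / (m + 1)

    def test_tighter_clusters_give_smaller_p(self, coil200):
        """Stochastically monotone power as planted radius shrinks."""
        coords = coil200.coordinates()
        rng = np.random.default_rng(4)
        mean_ps = []
        for radius in (4.0, 12.0, 40.0):
            ps = []
            for rep in range(20):
                center = coords[rng.integers(0, len(coords))]
                d = np.linalg.norm(coords - center, axis=1)
                cand = np.where(d <= radius)[0]
                take = rng.choice(cand, size=5, replace=len(cand) < 5)
                obs = avg_pairwise_distance_3d(coords[take])
                ps.append(permutation_pvalue(
                    coil200, 5, obs, 2000, seed=int(rng.integers(2**31))
                ).p_value)
            mean_ps.append(np.mean(ps))
        assert mean_ps[0] < mean_ps[1] < mean_ps[2]
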