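"""Merging, two-point estimation, ordering and positioning."""

import itertools

import numpy as np
import pytest

from synthmap import mapbuild, simfix
from synthmap.mapbuild import (
    compute_positions,
    estimate_two_point,
    merge_matrices,
    order_markers,
    partition_arms,
    two_point_tables,
)
from synthmap.segdata import MISSING, CentromereRange

from conftest import make_matrix


def _sim_merged(seed, n_markers, n_datasets=1, N=100, length=None, **noise):
    length = length or 6.0 * (n_markers - 1) + 20
    tm = simfix.simulate_true_map(n_groups=1, markers_per_group=n_markers,
                                  length_cM=length, seed=seed)
    dss = [simfix.simulate_dh_dataset(tm, N=N, seed=seed * 100 + k,
                                      dataset_id=f"d{k}", **noise)
           for k in range(n_datasets)]
    return tm, merge_matrices(dss, tm.groups[0].name)


class TestMerge:
    def test_union_and_concatenation(self):
        m1 = make_matrix([f"L{i}" for i in range(10)], np.zeros((10, 50)) , dataset_id="a")
        loci2 = [f"L{i}" for i in range(5)] + [f"M{i}" for i in range(7)]
        m2 = make_matrix(loci2, np.ones((12, 50)), dataset_id="b")
        mm = merge_matrices([m1, m2], "LG01")
        assert len(mm.loci) == 17
        assert len(mm.individuals) == 100
        # block structure: locus typed only in dataset a is missing in b's block
        lo, hi = mm.blocks["b"]
        assert (mm.calls[mm.loci.index("L9"), lo:hi] == MISSING).all()
        assert (mm.calls[mm.loci.index("L0"), :50] == 0).all()

    def test_single_dataset_identity(self, tiny_matrix):
        mm = merge_matrices([tiny_matrix], "LG01")
        assert mm.loci == tiny_matrix.loci
        assert np.array_equal(mm.calls, tiny_matrix.calls)

    def test_duplicate_dataset_id_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            merge_matrices([tiny_matrix, tiny_matrix], "LG01")

    def test_disjoint_loci_disconnect_is_detected(self):
        m1 = make_matrix(["A", "B"], [[0, 1, 0], [0, 1, 1]], dataset_id="a")
        m2 = make_matrix(["C", "D"], [[0, 1, 0], [0, 0, 1]], dataset_id="b")
        mm = merge_matrices([m1, m2], "LG01")
        with pytest.raises(ValueError, match="components"):
            order_markers(mm, "exact")


class TestTwoPoint:
    def test_identical_vectors_coupling(self):
        m = merge_matrices([make_matrix(["A", "B"], [[0, 0, 0, 1, 1, 1]] * 2)], "LG01")
        est = estimate_two_point(m, "A", "B")
        assert est.rhat == 0.0 and est.phase == "coupling" and est.n_informative == 6

    def test_complementary_vectors_repulsion(self):
        m = merge_matrices([make_matrix(["A", "B"],
                                        [[0, 0, 0, 1, 1, 1], [1, 1, 1, 0, 0, 0]])], "LG01")
        est = estimate_two_point(m, "A", "B")
        assert est.rhat == 0.0 and est.phase == "repulsion"

    def test_reconstructed_gametes_roundtrip(self):
        from synthmap.reconstruct import RecombinationProfile, gametes_from_profile
        gm = gametes_from_profile(RecombinationProfile("g", ["A", "B"], [0.04], 50))
        m = merge_matrices([gm], "g")
        assert estimate_two_point(m, "A", "B").rhat == pytest.approx(0.04)

    def test_no_shared_meioses_defaults(self):
        m1 = make_matrix(["A"], [[0, 1, MISSING]], dataset_id="a")
        m2 = make_matrix(["B"], [[MISSING, MISSING, 1]], dataset_id="a2")
        mm = merge_matrices([m1, m2], "LG01")
        est = estimate_two_point(mm, "A", "B")
        assert est.rhat == 0.5 and est.n_informative == 0 and est.phase is None

    def test_tables_match_pairwise_estimates(self):
        _, mm = _sim_merged(3, 6, missing_rate=0.2)
        rhat, ninf, _ = two_point_tables(mm.calls)
        for i, j in itertools.combinations(range(len(mm.loci)), 2):
            est = estimate_two_point(mm, mm.loci[i], mm.loci[j])
            assert rhat[i, j] == pytest.approx(est.rhat)
            assert ninf[i, j] == est.n_informative

    def test_rhat_times_n_is_integer(self):
        _, mm = _sim_merged(4, 5, missing_rate=0.3)
        rhat, ninf, _ = two_point_tables(mm.calls)
        prod = rhat * ninf
        assert np.allclose(prod, np.round(prod))


class TestOrdering:
    def brute_force(self, cost, n):
        best, best_obj = None, np.inf
        for perm in itertools.permutations(range(n)):
            if perm[0] > perm[-1]:
                continue  # half the orders: reversal is equivalent
            obj = sum(cost[perm[k], perm[k + 1]] for k in range(n - 1))
            if obj < best_obj:
                best, best_obj = perm, obj
        return best, best_obj

    def test_exact_matches_brute_force_and_truth(self):
        tm, mm = _sim_merged(11, 6, N=100)
        order = order_markers(mm, "exact")
        rhat, ninf, _ = two_point_tables(mm.calls)
        cost = rhat.copy()
        np.fill_diagonal(cost, 0)
        _, bf_obj = self.brute_force(cost, 6)
        idx = [mm.loci.index(l) for l in order]
        assert sum(cost[idx[k], idx[k + 1]] for k in range(5)) == pytest.approx(bf_obj)
        true = tm.groups[0].markers
        assert order == true or order == true[::-1]

    def test_two_loci_trivial(self):
        m = merge_matrices([make_matrix(["B", "A"], [[0, 0, 1, 1], [0, 1, 1, 1]])], "LG01")
        order = order_markers(m, "exact")
        assert sorted(order) == ["A", "B"]

    def test_exact_size_limit(self):
        _, mm = _sim_merged(1, 16)
        with pytest.raises(ValueError, match="15"):
            order_markers(mm, "exact")

    @pytest.mark.parametrize("method", ["annealing", "taboo", "flips"])
    def test_heuristics_match_exact_objective(self, method):
        mism = 0
        for seed in range(25):
            _, mm = _sim_merged(seed + 500, 7, N=100)
            rhat, _, _ = two_point_tables(mm.calls)
            cost = rhat.copy()
            np.fill_diagonal(cost, 0)
            idx = {l: i for i, l in enumerate(mm.loci)}

            def obj(order):
                o = [idx[l] for l in order]
                return sum(cost[o[k], o[k + 1]] for k in range(len(o) - 1))

            if obj(order_markers(mm, method, seed=seed)) > obj(order_markers(mm, "exact")) + 1e-9:
                mism += 1
        assert mism == 0

    def test_heuristic_seed_deterministic(self):
        _, mm = _sim_merged(42, 10)
        a = order_markers(mm, "annealing", seed=3)
        b = order_markers(mm, "annealing", seed=3)
        assert a == b

    def test_canonical_orientation(self):
        _, mm = _sim_merged(9, 8)
        order = order_markers(mm, "exact")
        assert order[0] < order[-1]

    def test_heuristics_never_worsen_greedy_start(self):
        for seed in range(5):
            _, mm = _sim_merged(seed + 60, 9, missing_rate=0.2, error_rate=0.01)
            rhat, ninf, _ = two_point_tables(mm.calls)
            cost = mapbuild._cost_matrix(rhat, ninf)
            greedy = mapbuild._greedy_path(cost)
            g_obj = mapbuild.order_objective(greedy, cost)
            for method in ("annealing", "taboo", "flips"):
                order = order_markers(mm, method, seed=seed)
                o = np.array([mm.loci.index(l) for l in order])
                assert mapbuild.order_objective(o, cost) <= g_obj + 1e-9


class TestPositions:
    def test_cumulative_positions(self):
        from synthmap.reconstruct import RecombinationProfile, gametes_from_profile
        gm = gametes_from_profile(
            RecombinationProfile("g", ["A", "B", "C"], [0.04, 0.10], 50))
        mm = merge_matrices([gm], "g")
        pg = compute_positions(["A", "B", "C"], mm)
        assert pg.positions == pytest.approx([0.0, 4.0, 14.0])
        # interval sum identity
        assert pg.length == pytest.approx(sum(np.diff(pg.positions)))

    def test_all_zero_r(self):
        m = make_matrix(["A", "B", "C"], [[0, 1, 0, 1]] * 3)
        mm = merge_matrices([m], "LG01")
        pg = compute_positions(["A", "B", "C"], mm)
        assert pg.positions == [0.0, 0.0, 0.0]


class TestArms:
    def _group(self, n):
        return mapbuild.PositionedGroup(
            name="RT01", loci=[f"L{i}" for i in range(n)],
            positions=[float(i) for i in range(n)])

    def test_metacentric_partition(self):
        pg = partition_arms(self._group(10), CentromereRange("RT01", "L4", "L5"))
        assert pg.arm_labels.count("p") == 4
        assert pg.arm_labels.count("q") == 4
        assert pg.arm_labels.count("centromeric") == 2
        assert pg.arm_of("L0") == "RT01p" and pg.arm_of("L9") == "RT01q"
        assert pg.arm_of("L4") is None

    def test_acrocentric_single_arm(self):
        pg = partition_arms(self._group(6),
                            CentromereRange("RT01", "L0", "L1", acrocentric=True))
        assert pg.arm_labels == ["centromeric"] * 2 + ["q"] * 4

    def test_centromere_at_start_empty_first_arm(self):
        pg = partition_arms(self._group(5), CentromereRange("RT01", "L0", "L0"))
        assert pg.arm_labels == ["centromeric"] + ["q"] * 4

    def test_missing_centromere_locus_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            partition_arms(self._group(4), CentromereRange("RT01", "L0", "L9"))
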