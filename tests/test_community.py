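from itertools import combinations

import numpy as np
import pytest
from sklearn.metrics import adjusted_mutual_info_score as sk_ami

import iegnet as ig
from iegnet.community import (GammaSelectionError, GammaStabilityProfile,
                              Partition, expected_mutual_information,
                              mean_pairwise_ami, select_stable_plateau)
from oracles import brute_force_modularity, labels_from_blocks, set_partitions


class TestModularity:
    def test_single_module_is_zero(self):
        rng = np.random.default_rng(0)
        W = np.abs(rng.normal(size=(8, 8)))
        W = (W + W.T) / 2
        q = ig.modularity(W, np.zeros(8, dtype=int), gamma=1.0,
                          scheme="positive_only")
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_cliques(self, two_cliques):
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert ig.modularity(two_cliques, labels) == pytest.approx(0.5)

    @pytest.mark.parametrize("scheme", ["positive_only", "negative_asym"])
    def test_matches_double_sum_oracle(self, scheme):
        rng = np.random.default_rng(1)
        for _ in range(5):
            W = rng.normal(size=(6, 6))
            W = (W + W.T) / 2
            labels = rng.integers(0, 3, size=6)
            for gamma in (0.5, 1.0, 1.7):
                assert ig.modularity(W, labels, gamma, scheme) == pytest.approx(
                    brute_force_modularity(W, labels, gamma, scheme), abs=1e-12)

    def test_asymmetric_matrix_rejected(self):
        W = np.arange(16.0).reshape(4, 4)
        with pytest.raises(ValueError, match="symmetric"):
            ig.modularity(W, np.zeros(4, dtype=int))


class TestLouvain:
    def test_two_cliques_recovered_exactly(self, two_cliques):
        p = ig.louvain(two_cliques, gamma=1.0, seed=0)
        mods = sorted(sorted(m) for m in p.modules().values())
        assert mods == [["0", "1", "2"], ["3", "4", "5"]]
        assert p.quality == pytest.approx(0.5)

    def test_matches_brute_force_on_small_graphs(self):
        # Louvain's Q must reach the global optimum on well-structured
        # 6-node instances and never exceed it on any instance
        rng = np.random.default_rng(2)
        for trial in range(4):
            W = rng.normal(size=(6, 6)) * 0.2
            W = (W + W.T) / 2
            W[:3, :3] += 1.0
            W[3:, 3:] += 1.0
            np.fill_diagonal(W, 0.0)
            best_q = max(
                ig.modularity(W, labels_from_blocks(blocks, 6))
                for blocks in set_partitions(list(range(6))))
            p = ig.louvain(W, gamma=1.0, seed=trial)
            assert p.quality <= best_q + 1e-12
            assert p.quality == pytest.approx(best_q, abs=1e-9)

    def test_quality_never_exceeds_brute_force_on_random_8_nodes(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(8, 8))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        best_q = max(
            ig.modularity(W, labels_from_blocks(blocks, 8))
            for blocks in set_partitions(list(range(8))))
        for seed in range(5):
            assert ig.louvain(W, gamma=1.0, seed=seed).quality <= best_q + 1e-12

    def test_planted_block_recovered(self):
        # one 6-region block at r=0.9, background 0: the block must come
        # back as a single module and no single-node move may improve Q
        regions = list(ig.REGIONS)
        block = {"DG", "CA3", "CA1", "PrL", "ACC", "aRC"}
        idx = [i for i, r in enumerate(regions) if r in block]
        W = np.zeros((12, 12))
        for a in idx:
            for b in idx:
                if a != b:
                    W[a, b] = 0.9
        p = ig.louvain(W, regions=regions, gamma=1.0, seed=1)
        assert block in set(p.modules().values()) or \
            frozenset(block) in set(p.modules().values())
        labels = p.labels_for(regions)
        q0 = ig.modularity(W, labels)
        for i in range(12):
            for new in set(labels) | {labels.max() + 1}:
                moved = labels.copy()
                moved[i] = new
                assert ig.modularity(W, moved) <= q0 + 1e-12

    def test_returned_quality_is_recomputable(self, two_cliques):
        p = ig.louvain(two_cliques, gamma=1.3, seed=5)
        labels = p.labels_for([str(i) for i in range(6)])
        assert p.quality == pytest.approx(
            ig.modularity(two_cliques, labels, gamma=1.3), abs=1e-12)

    def test_seed_invariance_on_strong_blocks(self, two_cliques):
        a = ig.louvain(two_cliques, gamma=1.0, seed=1)
        b = ig.louvain(two_cliques, gamma=1.0, seed=99)
        assert ig.ami(a, b) == pytest.approx(1.0)


class TestAMI:
    def test_identity_and_label_permutation(self):
        l1 = np.array([1, 1, 2, 2, 3, 3])
        assert ig.ami(l1, l1) == 1.0
        assert ig.ami(l1, np.array([3, 3, 1, 1, 2, 2])) == 1.0

    def test_partition_interface(self):
        p1 = Partition({r: 1 if i < 6 else 2 for i, r in enumerate(ig.REGIONS)},
                       quality=0.0, gamma=1.0, scheme="negative_asym")
        p2 = Partition({r: 2 if i < 6 else 1 for i, r in enumerate(ig.REGIONS)},
                       quality=0.0, gamma=1.0, scheme="negative_asym")
        assert ig.ami(p1, p2) == 1.0

    def test_fixed_partitions_match_independent_oracle(self):
        l1 = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        l2 = np.array([1, 2, 1, 2, 3, 4, 3, 4])

        # from-scratch oracle: enumerate the contingency table and evaluate
        # the exact hypergeometric E[MI] sum with plain Python floats
        import math
        n = 8
        cont = {}
        for a, b in zip(l1, l2):
            cont[(a, b)] = cont.get((a, b), 0) + 1
        arow = {a: sum(v for (x, _), v in cont.items() if x == a) for a in set(l1)}
        bcol = {b: sum(v for (_, y), v in cont.items() if y == b) for b in set(l2)}
        mi = sum(v / n * math.log(v * n / (arow[a] * bcol[b]))
                 for (a, b), v in cont.items())
        emi = 0.0
        for a in arow.values():
            for b in bcol.values():
                for nij in range(max(1, a + b - n), min(a, b) + 1):
                    hyp = (math.comb(b, nij) * math.comb(n - b, a - nij)
                           / math.comb(n, a))
                    emi += hyp * (nij / n) * math.log(n * nij / (a * b))
        h1 = -sum(v / n * math.log(v / n) for v in arow.values())
        h2 = -sum(v / n * math.log(v / n) for v in bcol.values())
        expect = (mi - emi) / (0.5 * (h1 + h2) - emi)

        assert ig.ami(l1, l2) == pytest.approx(expect, abs=1e-12)
        assert ig.ami(l1, l2) == pytest.approx(sk_ami(l1, l2), abs=1e-10)

    def test_exact_emi_matches_oracle(self):
        import math
        a = np.array([4, 4])
        b = np.array([2, 2, 2, 2])
        n = 8
        emi = 0.0
        for ai in a:
            for bj in b:
                for nij in range(max(1, ai + bj - n), min(ai, bj) + 1):
                    hyp = (math.comb(bj, nij) * math.comb(n - bj, ai - nij)
                           / math.comb(n, ai))
                    emi += hyp * (nij / n) * math.log(n * nij / (ai * bj))
        assert expected_mutual_information(a, b, n) == pytest.approx(emi, abs=1e-13)

    def test_agreement_with_sklearn_on_random_partitions(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            l1 = rng.integers(0, 4, size=12)
            l2 = rng.integers(0, 4, size=12)
            assert ig.ami(l1, l2) == pytest.approx(sk_ami(l1, l2), abs=1e-10)

    def test_symmetry_and_upper_bound(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            l1 = rng.integers(0, 3, size=10)
            l2 = rng.integers(0, 3, size=10)
            assert ig.ami(l1, l2) == pytest.approx(ig.ami(l2, l1), abs=1e-12)
            assert ig.ami(l1, l2) <= 1.0 + 1e-12

    def test_mismatched_label_sets_rejected(self):
        p1 = Partition({r: 1 for r in ig.REGIONS}, 0.0, 1.0, "negative_asym")
        p2 = Partition({"A": 1, "B": 1}, 0.0, 1.0, "negative_asym")
        with pytest.raises(ValueError, match="different label sets"):
            ig.ami(p1, p2)


class TestGammaSweep:
    def test_stable_structure_gives_perfect_band(self, two_cliques):
        prof = ig.gamma_sweep(two_cliques, gamma_min=0.5, gamma_max=1.5,
                              step=0.1, runs=10, base_seed=0)
        assert np.all(prof.mean_ami >= 1.0 - 1e-12)

    def test_mean_pairwise_ami_matches_direct_loop(self):
        rng = np.random.default_rng(6)
        runs = [rng.integers(0, 3, size=10) for _ in range(8)]
        direct = np.mean([ig.ami(a, b) for a, b in combinations(runs, 2)])
        assert mean_pairwise_ami(runs) == pytest.approx(direct, abs=1e-12)

    def test_two_identical_runs(self):
        runs = [np.array([1, 1, 2, 2]), np.array([5, 5, 9, 9])]
        assert mean_pairwise_ami(runs) == 1.0

    def test_seeds_are_logged(self, two_cliques):
        prof = ig.gamma_sweep(two_cliques, gamma_min=1.0, gamma_max=1.0,
                              step=0.5, runs=4, base_seed=100)
        assert prof.seeds == [101, 102, 103, 104]


def _profile(gammas, amis, partitions=None, order=None):
    return GammaStabilityProfile(
        gammas=np.asarray(gammas, dtype=float),
        mean_ami=np.asarray(amis, dtype=float), runs=10,
        modal_partitions=partitions or [], region_order=order or [])


class TestSelectGamma:
    def test_largest_perfect_gamma(self):
        gam = np.round(np.arange(0.5, 1.55, 0.05), 10)
        ami = np.where(gam <= 1.2, 1.0, 0.8)
        assert ig.select_gamma(_profile(gam, ami)) == pytest.approx(1.2)

    def test_all_perfect_returns_gamma_max(self):
        assert ig.select_gamma(_profile([0.5, 1.0, 2.0], [1, 1, 1])) == 2.0

    def test_no_perfect_gamma_errors_with_diagnostic(self):
        with pytest.raises(GammaSelectionError) as exc:
            ig.select_gamma(_profile([0.5, 1.0], [0.7, 0.9]))
        assert exc.value.best_gamma == 1.0
        assert exc.value.best_ami == pytest.approx(0.9)


class TestSelectStablePlateau:
    def test_widest_nontrivial_plateau_wins(self):
        order = ["a", "b", "c", "d"]
        single = (0, 0, 0, 0)
        bipart = (0, 0, 1, 1)
        frag = (0, 1, 2, 3)
        parts = [single] * 3 + [bipart] * 5 + [frag] * 2
        prof = _profile(np.arange(0.1, 1.1, 0.1)[:10], [1.0] * 10,
                        partitions=parts, order=order)
        sel = select_stable_plateau(prof)
        assert sel.assignment == {"a": 1, "b": 1, "c": 2, "d": 2}
        assert sel.gamma_lo == pytest.approx(0.4)
        assert sel.gamma_hi == pytest.approx(0.8)
        # midpoint of the plateau
        assert sel.gamma == pytest.approx(0.6)

    def test_unstable_gap_splits_plateaus(self):
        order = ["a", "b", "c", "d"]
        bipart = (0, 0, 1, 1)
        parts = [bipart] * 6
        prof = _profile(np.arange(0.1, 0.7, 0.1)[:6],
                        [1.0, 1.0, 0.9, 1.0, 1.0, 1.0],
                        partitions=parts, order=order)
        sel = select_stable_plateau(prof)
        assert sel.gamma_lo == pytest.approx(0.4)

    def test_trivial_only_falls_back_to_single_module(self):
        order = ["a", "b"]
        prof = _profile([0.5, 0.6], [1.0, 1.0],
                        partitions=[(0, 0), (0, 0)], order=order)
        sel = select_stable_plateau(prof)
        assert sel.n_modules == 1

    def test_nothing_stable_raises(self):
        prof = _profile([0.5, 0.6], [0.8, 0.9],
                        partitions=[(0, 0), (0, 1)], order=["a", "b"])
        with pytest.raises(GammaSelectionError):
            select_stable_plateau(prof)
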