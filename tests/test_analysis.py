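"""Structure metrics, UPGMA clustering and bond statistics."""

import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from spatialrules import (
    DendrogramNode,
    bond_count_histogram,
    bond_frequency,
    bridge_count,
    distance_matrix,
    local_rmsd,
    paired_rmsd,
    rmsd_positions,
    upgma,
)
from spatialrules.analysis import rosette_bridge_count
from spatialrules.events import BondEvent


def random_rigid_motion(rng):
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-50, 50, size=3)


class TestPositionalRmsd:
    def test_zero_on_identical_structures(self):
        p = np.random.default_rng(0).uniform(-10, 10, size=(6, 3))
        assert rmsd_positions(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_zero_after_translation(self):
        p = np.random.default_rng(1).uniform(-10, 10, size=(5, 3))
        assert rmsd_positions(p, p + [3.0, -7.0, 11.0]) == pytest.approx(0.0, abs=1e-9)

    def test_zero_after_rotation_about_anchor(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(-10, 10, size=(5, 3))
        rot, _ = random_rigid_motion(rng)
        assert rmsd_positions(p, p @ rot.T) == pytest.approx(0.0, abs=1e-9)

    def test_single_displacement_hand_value(self):
        # 4 particles; q differs from p by moving one non-anchor particle 3 Å
        p = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 5]])
        q = p.copy()
        q[3] += [0.0, 0.0, 3.0]
        assert rmsd_positions(p, q) == pytest.approx(math.sqrt(9.0 / 4.0))

    def test_collinear_anchors_rejected(self):
        p = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 1, 0]])
        with pytest.raises(ValueError):
            rmsd_positions(p, p, anchor=(0, 1, 2))


class TestPairedRmsd:
    def test_hand_computed_two_particle_case(self):
        p = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        q = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert paired_rmsd(p, q) == pytest.approx(math.sqrt(2.0 / 6.0), abs=1e-12)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            p = rng.uniform(-30, 30, size=(n, 3))
            q = rng.uniform(-30, 30, size=(n, 3))
            rot, t = random_rigid_motion(rng)
            assert abs(paired_rmsd(p, q @ rot.T + t) - paired_rmsd(p, q)) < 1e-9

    def test_zero_iff_all_pairwise_distances_equal(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(-5, 5, size=(4, 3))
        rot, t = random_rigid_motion(rng)
        assert paired_rmsd(p, p @ rot.T + t) == pytest.approx(0.0, abs=1e-9)
        q = p.copy()
        q[0, 0] += 0.5
        assert paired_rmsd(p, q) > 0

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(-5, 5, size=(5, 3))
        q = rng.uniform(-5, 5, size=(5, 3))
        assert paired_rmsd(p, q) == pytest.approx(paired_rmsd(q, p))
        assert paired_rmsd(p, q) >= 0


class TestLocalRmsd:
    def test_hand_computed_cutoff_case(self):
        p = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        q = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert local_rmsd(p, q, 1.5) == pytest.approx(math.sqrt(2.0 / 6.0 * 0.25), abs=1e-12)

    def test_zero_cutoff_gives_zero(self):
        rng = np.random.default_rng(6)
        p, q = rng.uniform(-9, 9, size=(2, 7, 3))
        assert local_rmsd(p, q, 0.0) == 0.0

    def test_large_cutoff_recovers_paired_rmsd(self):
        rng = np.random.default_rng(7)
        p, q = rng.uniform(-9, 9, size=(2, 7, 3))
        assert local_rmsd(p, q, 1e6) == pytest.approx(paired_rmsd(p, q))

    def test_nondecreasing_in_cutoff(self):
        rng = np.random.default_rng(8)
        p, q = rng.uniform(-9, 9, size=(2, 6, 3))
        values = [local_rmsd(p, q, c) for c in np.linspace(0, 40, 30)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestDistanceMatrix:
    def test_identical_snapshots_give_zero_matrix(self):
        p = np.random.default_rng(9).uniform(-5, 5, size=(4, 3))
        dm = distance_matrix([p, p.copy()])
        assert np.allclose(dm.matrix, 0.0)

    def test_entries_equal_pairwise_metric_calls(self):
        rng = np.random.default_rng(10)
        snaps = [rng.uniform(-5, 5, size=(5, 3)) for _ in range(3)]
        dm = distance_matrix(snaps, metric="paired")
        for i in range(3):
            for j in range(3):
                expect = 0.0 if i == j else paired_rmsd(snaps[i], snaps[j])
                assert dm.matrix[i, j] == pytest.approx(expect)

    def test_inconsistent_particle_sets_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix([np.zeros((3, 3)), np.zeros((4, 3))])


class TestUpgma:
    def test_two_leaves_merge_at_their_distance(self):
        tree = upgma(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert tree.height == pytest.approx(3.0)
        assert sorted(tree.leaves()) == [0, 1]

    def test_hand_run_three_leaf_case(self):
        m = np.array([[0.0, 2, 8], [2, 0, 8], [8, 8, 0.0]])
        tree = upgma(m)
        assert tree.height == pytest.approx(8.0)
        heights = sorted(c.height for c in tree.children)
        assert heights[0] == pytest.approx(0.0)  # leaf C
        assert heights[1] == pytest.approx(2.0)  # {A,B} merged first

    def test_all_zero_matrix_gives_zero_heights(self):
        tree = upgma(np.zeros((4, 4)))
        coph = tree.cophenetic()
        assert all(h == 0.0 for h in coph.values())

    def test_matches_independent_average_linkage_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            d = rng.uniform(0.5, 10.0, size=(6, 6))
            d = (d + d.T) / 2.0
            np.fill_diagonal(d, 0.0)
            tree = upgma(d)
            coph = tree.cophenetic()
            ref = squareform(cophenet(linkage(squareform(d, checks=False), "average")))
            for i in range(6):
                for j in range(i + 1, 6):
                    assert coph[frozenset((i, j))] == pytest.approx(ref[i, j]), (i, j)

    def test_ultrametric_heights_nondecreasing(self):
        rng = np.random.default_rng(12)
        d = rng.uniform(1, 9, size=(7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(upgma(d))

    def test_newick_export_is_parseable(self):
        tree = upgma(np.array([[0.0, 2, 8], [2, 0, 8], [8, 8, 0.0]]))
        text = tree.to_newick()
        assert text.endswith(";") and text.count("(") == text.count(")")
        import io

        from Bio import Phylo

        t = Phylo.read(io.StringIO(text), "newick")
        assert t.count_terminals() == 3


def _ev(rule, n, action="formed"):
    return [BondEvent(0, rule, 2 * i, 0, 2 * i + 1, 0, action) for i in range(n)]


class TestBondStatistics:
    def _model(self):
        from spatialrules import parse_model

        return parse_model(
            "begin molecule types\nX(y)\nY(x)\nend molecule types\n"
            "begin reaction rules\nXY: X(y) + Y(x) -> X(y!1).Y(x!1) 1\nend reaction rules\n"
        )

    def test_all_bonds_realized_is_100_percent(self):
        model = self._model()
        logs = [_ev("XY", 6), _ev("XY", 6)]
        freq = bond_frequency(logs, model, {"X": 6, "Y": 6})
        assert freq["XY"] == pytest.approx(100.0)

    def test_no_bonds_is_0_percent(self):
        model = self._model()
        freq = bond_frequency([[], []], model, {"X": 6, "Y": 6})
        assert freq["XY"] == 0.0

    def test_partial_counts(self):
        model = self._model()
        freq = bond_frequency([_ev("XY", 3), _ev("XY", 3)], model, {"X": 6, "Y": 6})
        assert freq["XY"] == pytest.approx(50.0)

    def test_broken_bonds_reduce_final_count(self):
        model = self._model()
        log = _ev("XY", 4) + _ev("XY", 1, "broken")
        freq = bond_frequency([log], model, {"X": 6, "Y": 6})
        assert freq["XY"] == pytest.approx(50.0)

    def test_capacity_uses_smaller_partner(self):
        model = self._model()
        freq = bond_frequency([_ev("XY", 1)], model, {"X": 1, "Y": 6})
        assert freq["XY"] == pytest.approx(100.0)

    def test_unknown_rule_in_log_raises(self):
        model = self._model()
        with pytest.raises(KeyError):
            bond_frequency([_ev("nope", 1)], model, {"X": 6, "Y": 6})

    def test_histogram_tallies_and_sums_to_one(self):
        h = bond_count_histogram([0, 0, 0, 6], 6)
        assert h[0] == 0.75 and h[6] == 0.25
        assert sum(h.values()) == pytest.approx(1.0)
        rng = np.random.default_rng(13)
        counts = rng.integers(0, 7, size=200)
        h = bond_count_histogram(counts, 6)
        for k in range(7):
            assert h[k] == pytest.approx(np.mean(counts == k))

    def test_histogram_rejects_count_above_max(self):
        with pytest.raises(ValueError):
            bond_count_histogram([7], 6)

    def test_time_resolved_frequency_final_point_matches_static(self):
        from spatialrules.analysis import bond_frequency_over_time

        model = self._model()
        logs = [
            [BondEvent(10, "XY", 0, 0, 1, 0, "formed"),
             BondEvent(50, "XY", 2, 0, 3, 0, "formed"),
             BondEvent(80, "XY", 0, 0, 1, 0, "broken")],
            [BondEvent(30, "XY", 0, 0, 1, 0, "formed")],
        ]
        copies = {"X": 6, "Y": 6}
        tr = bond_frequency_over_time(logs, model, copies, steps=[0, 20, 60, 100])
        static = bond_frequency(logs, model, copies)
        assert tr["XY"][-1] == pytest.approx(static["XY"])
        # intermediate points follow the cumulative net counts
        assert tr["XY"][0] == 0.0
        assert tr["XY"][1] == pytest.approx(100.0 * 1 / 12)
        assert tr["XY"][2] == pytest.approx(100.0 * 3 / 12)


class TestBridges:
    def test_unbonded_world_has_no_bridges(self):
        count, conn = bridge_count([], [{0}, {1}, {2}])
        assert count == 0 and not any(conn.values())

    def test_chain_through_linkers_connects_one_pair(self):
        # anchors {0} and {3}; path 0-1-2-3 through non-anchor particles
        bonds = [(0, 1), (1, 2), (2, 3)]
        count, conn = bridge_count(bonds, [{0}, {3}, {9}])
        assert count == 1
        assert conn[frozenset((0, 1))] is True

    def test_path_through_other_anchor_does_not_count(self):
        # 0 -- 5(anchor B) -- 9: A and C only connect through anchor B
        bonds = [(0, 5), (5, 9)]
        count, conn = bridge_count(bonds, [{0}, {5}, {9}])
        assert conn[frozenset((0, 2))] is False
        assert count == 2  # A-B and B-C are directly bonded

    def test_agrees_with_breadth_first_search_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            n = 30
            groups = [set(rng.choice(n, size=3, replace=False).tolist()) for _ in range(3)]
            while groups[0] & groups[1] or groups[0] & groups[2] or groups[1] & groups[2]:
                groups = [set(rng.choice(n, size=3, replace=False).tolist()) for _ in range(3)]
            bonds = [tuple(rng.choice(n, size=2, replace=False).tolist()) for _ in range(25)]
            count, conn = bridge_count(bonds, groups)

            # oracle: BFS on the explicit adjacency with other anchors removed
            def oracle(gi, gj):
                blocked = set().union(*(groups[k] for k in range(3) if k not in (gi, gj)))
                adj = {}
                for a, b in bonds:
                    if a in blocked or b in blocked:
                        continue
                    adj.setdefault(a, []).append(b)
                    adj.setdefault(b, []).append(a)
                frontier = list(groups[gi])
                seen = set(frontier)
                while frontier:
                    u = frontier.pop()
                    if u in groups[gj]:
                        return True
                    for v in adj.get(u, []):
                        if v not in seen:
                            seen.add(v)
                            frontier.append(v)
                return False

            for gi in range(3):
                for gj in range(gi + 1, 3):
                    assert conn[frozenset((gi, gj))] == oracle(gi, gj)

    def test_rosette_bridge_count_is_spanning_count(self):
        groups = [{0}, {1}, {2}, {3}]
        # 0-1 joined directly, 2 joined via linker 10, 3 isolated
        bonds = [(0, 1), (1, 10), (10, 2)]
        assert rosette_bridge_count(bonds, groups) == 2
        bonds.append((2, 3))
        assert rosette_bridge_count(bonds, groups) == 3
        # extra cross-links do not add bridges
        bonds += [(0, 11), (11, 2), (1, 12), (12, 3)]
        assert rosette_bridge_count(bonds, groups) == 3
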