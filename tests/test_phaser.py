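"""Contact counting and the greedy-flip phasing optimizer."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from diphase.model import Block
from diphase.phaser import (ContactMatrix, cluster_contigs, contig_contacts,
                            count_contacts, dismiss_same_phase_switches,
                            objective, optimize, phase_groups, RefIndex)
from diphase.model import PhaseAssignment


def two_block_matrix(w_ab=5, w_a1b1=5, w_ab1=0, w_a1b=0):
    cm = ContactMatrix()
    cm.add("a", 0, "b", 0, w_ab)
    cm.add("a", 1, "b", 1, w_a1b1)
    cm.add("a", 0, "b", 1, w_ab1)
    cm.add("a", 1, "b", 0, w_a1b)
    return cm


def random_matrix(rng, n):
    cm = ContactMatrix()
    units = [f"u{i}" for i in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        for si, sj in itertools.product((0, 1), (0, 1)):
            cm.add(units[i], si, units[j], sj, int(rng.integers(0, 20)))
    return cm, units


def exhaustive_optimum(cm, units):
    best = None
    for assign in itertools.product((1, -1), repeat=len(units)):
        theta = dict(zip(units, assign))
        f = objective(theta, cm)
        best = f if best is None else max(best, f)
    return best


class TestObjective:
    def test_same_phase_scores_net_contacts(self):
        assert objective({"a": 1, "b": 1}, two_block_matrix()) == 10

    def test_opposite_phase_flips_sign(self):
        assert objective({"a": 1, "b": -1}, two_block_matrix()) == -10

    def test_global_flip_invariance(self):
        rng = np.random.default_rng(0)
        cm, units = random_matrix(rng, 6)
        theta = {u: int(rng.choice([1, -1])) for u in units}
        flipped = {u: -t for u, t in theta.items()}
        assert objective(theta, cm) == objective(flipped, cm)

    def test_missing_phase_raises(self):
        with pytest.raises(KeyError):
            objective({"a": 1}, two_block_matrix())


class TestOptimize:
    def test_single_unit_trivial(self):
        res = optimize(ContactMatrix(), seed=0, units=["a"])
        assert res.theta == {"a": 1} and res.objective == 0

    def test_cis_dominant_pair_gets_equal_phase(self):
        res = optimize(two_block_matrix(8, 7, 1, 2), seed=0)
        assert res.theta["a"] == res.theta["b"]

    def test_trans_dominant_pair_gets_opposite_phase(self):
        res = optimize(two_block_matrix(1, 2, 8, 7), seed=0)
        assert res.theta["a"] == -res.theta["b"]

    @pytest.mark.parametrize("seed", range(30))
    def test_attains_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        cm, units = random_matrix(rng, int(rng.integers(3, 11)))
        res = optimize(cm, seed=seed)
        assert res.objective == exhaustive_optimum(cm, units)
        assert res.objective == objective(res.theta, cm)  # recomputable

    def test_beats_random_assignments(self):
        rng = np.random.default_rng(42)
        cm, units = random_matrix(rng, 12)
        res = optimize(cm, seed=1)
        for _ in range(200):
            theta = {u: int(rng.choice([1, -1])) for u in units}
            assert objective(theta, cm) <= res.objective

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        cm, _ = random_matrix(rng, 10)
        assert optimize(cm, seed=5).theta == optimize(cm, seed=5).theta

    def test_parameter_recovery_cis_trans(self):
        """Planted +-1 vector recovered from Poisson contacts at 4:1 ratio."""
        recovered = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 20
            units = [f"u{i}" for i in range(n)]
            truth = rng.choice([1, -1], size=n)
            cm = ContactMatrix()
            for i, j in itertools.combinations(range(n), 2):
                same = truth[i] == truth[j]
                for si, sj in itertools.product((0, 1), (0, 1)):
                    lam = 30.0 if (si == sj) == same else 7.5
                    cm.add(units[i], si, units[j], sj, int(rng.poisson(lam)))
            res = optimize(cm, seed=seed + 100)
            got = np.array([res.theta[u] for u in units])
            if abs(int(np.sum(got * truth))) == n:
                recovered += 1
        assert recovered >= n_rep - 1

    def test_zero_contact_unit_flagged_and_positive(self):
        cm = two_block_matrix()
        res = optimize(cm, seed=0, units=["a", "b", "lonely"])
        assert "lonely" in res.flagged and res.theta["lonely"] == 1


def simple_blocks():
    blocks = [
        Block("c:0-100", "c", 0, 100, "collapsed", None, "c"),
        Block("c:100-200", "c", 100, 200, "hap2", "x:0-100", "c"),
        Block("x:0-100", "c", 100, 200, "hap1", "c:100-200", "x", 0, 100),
        Block("c:200-300", "c", 200, 300, "hap2", "y:0-100", "c"),
        Block("y:0-100", "c", 200, 300, "hap1", "c:200-300", "y", 0, 100),
    ]
    pairing = {"x:0-100": "c:100-200", "c:100-200": "x:0-100",
               "y:0-100": "c:200-300", "c:200-300": "y:0-100"}
    return blocks, pairing


class TestCountContacts:
    def test_hap1_to_partner_hap2_counts_cross_type(self):
        blocks, pairing = simple_blocks()
        pairs = [("r", "x:0-100", 10, 60, "c:200-300", 20, 70)]
        cm, _, stats = count_contacts(pairs, blocks, pairing)
        assert stats["counted"] == 1
        assert cm.w[("c:100-200", "c:200-300")][0, 1] == 1

    def test_same_block_pair_excluded(self):
        blocks, pairing = simple_blocks()
        pairs = [("r", "x:0-100", 10, 60, "c:100-200", 20, 70)]
        cm, _, stats = count_contacts(pairs, blocks, pairing)
        assert stats["same_unit"] == 1 and not cm.w

    def test_collapsed_touch_excluded(self):
        blocks, pairing = simple_blocks()
        pairs = [("r", "c:0-100", 10, 60, "c:100-200", 20, 70)]
        cm, _, stats = count_contacts(pairs, blocks, pairing)
        assert stats["collapsed_skipped"] == 1 and not cm.w

    def test_matches_naive_recount(self):
        rng = np.random.default_rng(8)
        blocks, pairing = simple_blocks()
        refs = ["x:0-100", "y:0-100", "c:100-200", "c:200-300"]
        unit_of = {"x:0-100": ("c:100-200", 0), "y:0-100": ("c:200-300", 0),
                   "c:100-200": ("c:100-200", 1), "c:200-300": ("c:200-300", 1)}
        pairs = []
        for i in range(200):
            r1, r2 = rng.choice(refs, size=2)
            pairs.append((f"r{i}", str(r1), 10, 50, str(r2), 20, 60))
        cm, _, _ = count_contacts(pairs, blocks, pairing)
        expect = np.zeros((2, 2), dtype=int)
        for _, r1, _, _, r2, _, _ in pairs:
            (u1, s1), (u2, s2) = unit_of[r1], unit_of[r2]
            if u1 == u2:
                continue
            if u1 > u2:
                u1, u2, s1, s2 = u2, u1, s2, s1
            expect[s1, s2] += 1
        got = cm.w.get(("c:100-200", "c:200-300"), np.zeros((2, 2), int))
        assert got.tolist() == expect.tolist()

    def test_group_order_invariance(self):
        """Reversing block order leaves the per-group optimum unchanged."""
        rng = np.random.default_rng(9)
        cm, units = random_matrix(rng, 8)
        fwd = optimize(cm, seed=3, units=units)
        rev = optimize(cm, seed=3, units=list(reversed(units)))
        assert fwd.objective == rev.objective


class TestDismissSwitches:
    def split_setup(self, t_left, t_right):
        blocks = [
            Block("c:0-50", "c", 0, 50, "hap2", "x:0-50", "c", parent_id="c:0-100"),
            Block("x:0-50", "c", 0, 50, "hap1", "c:0-50", "x", 0, 50,
                  parent_id="x:0-100"),
            Block("c:50-100", "c", 50, 100, "hap2", "x:50-100", "c",
                  parent_id="c:0-100"),
            Block("x:50-100", "c", 50, 100, "hap1", "c:50-100", "x", 50, 100,
                  parent_id="x:0-100"),
        ]
        pairing = {"c:0-50": "x:0-50", "x:0-50": "c:0-50",
                   "c:50-100": "x:50-100", "x:50-100": "c:50-100"}
        assignment = PhaseAssignment(theta={"c:0-50": t_left, "c:50-100": t_right},
                                     objective=0, seed=0, rounds=0)
        return assignment, blocks, pairing

    def test_same_phase_sub_blocks_remerge(self):
        assignment, blocks, pairing = self.split_setup(1, 1)
        nb, npair, theta, dismissed = dismiss_same_phase_switches(
            assignment, blocks, pairing)
        assert "c:0-100" in dismissed
        ids = {b.block_id for b in nb}
        assert ids == {"c:0-100", "x:0-100"}
        assert theta == {"c:0-100": 1}
        assert npair["c:0-100"] == "x:0-100"

    def test_opposite_phase_split_stands(self):
        assignment, blocks, pairing = self.split_setup(1, -1)
        nb, _, theta, dismissed = dismiss_same_phase_switches(
            assignment, blocks, pairing)
        assert dismissed == []
        assert len(nb) == 4 and theta == assignment.theta

    def test_unsplit_blocks_untouched(self):
        blocks, pairing = simple_blocks()
        assignment = PhaseAssignment(theta={"c:100-200": 1, "c:200-300": -1},
                                     objective=0, seed=0, rounds=0)
        nb, _, theta, dismissed = dismiss_same_phase_switches(
            assignment, blocks, pairing)
        assert dismissed == [] and len(nb) == len(blocks)


class TestClusterContigs:
    def test_cis_linked_contigs_share_group(self):
        cc = ContactMatrix()
        cc.add("ctg1", 0, "ctg2", 0, 30)
        cc.add("ctg1", 1, "ctg2", 1, 30)
        cc.add("ctg1", 0, "ctg2", 1, 5)
        groups, flagged = cluster_contigs(cc, ["ctg1", "ctg2"], seed=0)
        assert groups["ctg1"] == groups["ctg2"] and not flagged

    def test_unlinked_contig_flagged(self):
        cc = ContactMatrix()
        cc.add("ctg1", 0, "ctg2", 0, 30)
        groups, flagged = cluster_contigs(cc, ["ctg1", "ctg2", "ctg3"], seed=0)
        assert flagged == ["ctg3"] and groups["ctg3"] == "H1"

    @pytest.mark.parametrize("seed", range(10))
    def test_grouping_matches_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        cm, units = random_matrix(rng, 6)
        res = optimize(cm, seed=seed, units=units)
        assert res.objective == exhaustive_optimum(cm, units)
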