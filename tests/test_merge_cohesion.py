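import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nims import (
    AnatomicalNetwork,
    Cover,
    ModuleSetCollection,
    PlantedSpec,
    SpinglassConfig,
    build_covers,
    cohesion_test,
    planted_network,
    run_nims,
    select_merges,
    signed_rank_test,
)
from nims.local_modules import NodeModule
from nims.set_algebra import IntersectionRecord, supertest
from conftest import clique_edges, net_from_edges
from oracles import wilcoxon_greater_by_enumeration

FAST = SpinglassConfig(replicates=3, seed=7)


def mod(focal, members):
    members = frozenset(members)
    assert focal in members, "test helper: focal must be a member"
    return NodeModule(focal=focal, members=members, score=0.0)


def record(combo, observed, p_bonferroni, significant=True):
    return IntersectionRecord(
        combo=tuple(combo),
        observed=observed,
        expected=1.0,
        fold_enrichment=float(observed),
        p_raw=p_bonferroni / 10,
        p_bonferroni=p_bonferroni,
        significant=significant,
    )


class TestSignedRankTest:
    def test_three_positive_differences(self):
        w, p, n = signed_rank_test([1, 2, 3])
        assert (w, n) == (6.0, 3)
        assert p == pytest.approx(0.125)  # 1/2^3

    def test_tied_magnitudes_midranks(self):
        w, _, n = signed_rank_test([1, -1])
        assert (w, n) == (1.5, 2)

    def test_midranks_mixed(self):
        # |d| = 1,1,2,2,3 -> midranks 1.5,1.5,3.5,3.5,5
        w, _, _ = signed_rank_test([1, -1, 2, -2, 3])
        assert w == pytest.approx(1.5 + 3.5 + 5)

    def test_zeros_dropped(self):
        w1, p1, n1 = signed_rank_test([0, 1, 0, 2, 3, 0])
        w2, p2, n2 = signed_rank_test([1, 2, 3])
        assert (w1, p1, n1) == (w2, p2, n2)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            signed_rank_test([0, 0, 0])

    def test_w_bounds(self):
        for d in ([5, -4, 3, -2, 1], [-1, -2, -3], [10, 20, 30, 40]):
            w, p, n = signed_rank_test(d)
            assert 0 <= w <= n * (n + 1) / 2
            assert 0 < p <= 1

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_exact_matches_enumeration(self, data):
        n = data.draw(st.integers(1, 10))
        magnitudes = data.draw(
            st.lists(
                st.integers(1, 50), min_size=n, max_size=n, unique=True
            )
        )
        signs = data.draw(st.lists(st.sampled_from([-1, 1]), min_size=n, max_size=n))
        diffs = [s * m for s, m in zip(signs, magnitudes)]
        w, p, _ = signed_rank_test(diffs)
        w_oracle, p_oracle = wilcoxon_greater_by_enumeration(diffs)
        assert w == w_oracle
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        diffs = rng.integers(1, 500, size=60) * rng.choice([-1, 1], size=60)
        w, p, n = signed_rank_test(diffs.tolist())
        assert n == 60
        assert 0 < p < 1


class TestSelectMerges:
    def test_two_disjoint_significant_pairs_both_accepted(self):
        coll = ModuleSetCollection(
            modules=(
                mod("Ethmoidal", {"Ethmoidal", "f", "x"}),
                mod("Frontal", {"Frontal", "f", "x"}),
                mod("Sphenoidal", {"Sphenoidal", "o", "y"}),
                mod("Occipital", {"Occipital", "o", "y"}),
            ),
            universe_size=10,
        )
        records = [
            record(("Ethmoidal", "Frontal"), observed=2, p_bonferroni=0.001),
            record(("Sphenoidal", "Occipital"), observed=2, p_bonferroni=0.002),
            record(("Ethmoidal", "Sphenoidal"), observed=0, p_bonferroni=1.0,
                   significant=False),
        ]
        plan = select_merges(records, coll, alpha=0.05)
        assert set(plan.merges) == {
            ("Ethmoidal", "Frontal"),
            ("Sphenoidal", "Occipital"),
        }

    def test_overlap_reducing_superset_rejected(self):
        # three-way merge with overlap 15 is preferred over the four-way
        # extension whose overlap drops to 8, even when both are significant
        coll = ModuleSetCollection(
            modules=(
                mod("RPost", {f"n{i}" for i in range(18)} | {"RPost"}),
                mod("LPost", {f"n{i}" for i in range(18)} | {"LPost"}),
                mod("RSquam", {f"n{i}" for i in range(16)} | {"RSquam"}),
                mod("Pter", {f"n{i}" for i in range(8)} | {"Pter", "p2"}),
            ),
            universe_size=40,
        )
        records = [
            record(("RPost", "LPost", "RSquam"), observed=15, p_bonferroni=1e-8),
            record(("RPost", "LPost", "RSquam", "Pter"), observed=8, p_bonferroni=1e-5),
        ]
        plan = select_merges(records, coll, alpha=0.05)
        assert plan.merges == (("RPost", "LPost", "RSquam"),)
        assert plan.rejected == (
            (("RPost", "LPost", "RSquam", "Pter"), "overlap-reducing superset"),
        )

    def test_no_significant_records_empty_plan(self):
        coll = ModuleSetCollection(
            modules=(mod("a", {"a", "b"}), mod("c", {"c", "d"})), universe_size=4
        )
        plan = select_merges(
            [record(("a", "c"), observed=0, p_bonferroni=1.0, significant=False)],
            coll,
        )
        assert plan.merges == ()
        assert plan.rationale == ()

    def test_every_accepted_merge_is_significant(self):
        coll = ModuleSetCollection(
            modules=(mod("a", {"a", "b"}), mod("c", {"b", "c"})), universe_size=4
        )
        plan = select_merges(
            [record(("a", "c"), observed=1, p_bonferroni=0.04)], coll, alpha=0.05
        )
        for r in plan.rationale:
            assert r.p_bonferroni <= 0.05

    def test_rationale_overlap_fractions(self):
        coll = ModuleSetCollection(
            modules=(mod("a", {"a", "b", "c", "d"}), mod("e", {"c", "d", "e"})),
            universe_size=6,
        )
        plan = select_merges(
            [record(("a", "e"), observed=2, p_bonferroni=0.01)], coll
        )
        assert plan.rationale[0].overlap_fraction == {
            "a": 2 / 4, "e": 2 / 3}

    def test_decide_callback_can_veto(self):
        coll = ModuleSetCollection(
            modules=(mod("a", {"a", "b"}), mod("c", {"b", "c"})), universe_size=4
        )
        plan = select_merges(
            [record(("a", "c"), observed=1, p_bonferroni=0.01)],
            coll,
            decide=lambda rec: False,
        )
        assert plan.merges == ()
        assert plan.rejected == ((("a", "c"), "declined by user"),)

    def test_bad_alpha(self):
        coll = ModuleSetCollection(modules=(mod("a", {"a"}),), universe_size=2)
        with pytest.raises(ValueError):
            select_merges([], coll, alpha=1.5)


class TestBuildCovers:
    def make_seven_module_collection(self):
        mods = tuple(
            mod(f"m{i}", {f"m{i}", f"n{i}", f"n{i + 1}"}) for i in range(7)
        )
        return ModuleSetCollection(modules=mods, universe_size=20)

    def test_two_merges_covering_five_modules_leaves_four_covers(self):
        from nims.merge_cohesion import MergePlan

        coll = self.make_seven_module_collection()
        plan = MergePlan(
            merges=(("m0", "m1"), ("m2", "m3", "m4")), rationale=(), rejected=()
        )
        covers = build_covers(coll, plan)
        assert len(covers) == 4  # 2 merged + m5 + m6
        merged = {c.label: c for c in covers}
        assert merged["m0+m1"].members == frozenset(
            {"m0", "m1", "n0", "n1", "n2"}
        )

    def test_empty_plan_covers_equal_modules(self):
        from nims.merge_cohesion import MergePlan

        coll = ModuleSetCollection(
            modules=(mod("a", {"a", "b"}), mod("c", {"c"}), mod("d", {"d", "e"})),
            universe_size=5,
        )
        covers = build_covers(coll, MergePlan(merges=(), rationale=(), rejected=()))
        assert len(covers) == 3
        assert {c.members for c in covers} == {m.members for m in coll.modules}

    def test_dangling_label_rejected(self):
        from nims.merge_cohesion import MergePlan

        coll = ModuleSetCollection(modules=(mod("a", {"a"}),), universe_size=2)
        plan = MergePlan(merges=(("a", "ghost"),), rationale=(), rejected=())
        with pytest.raises(ValueError, match="unknown modules"):
            build_covers(coll, plan)


class TestCohesionTest:
    def test_clique_cover_in_barbell(self, barbell):
        cover = Cover(
            label="A", members=frozenset({"a0", "a1", "a2", "a3"}),
            constituents=("A",),
        )
        result = cohesion_test(barbell, cover)
        assert result.n_used == len(barbell.nodes)
        # every node sits mostly within its own side of the boundary
        assert result.W == len(barbell.nodes) * (len(barbell.nodes) + 1) / 2
        assert result.p < 0.05
        assert len(result.splits) == len(barbell.nodes)

    def test_own_group_pairing_flips_non_members(self, barbell):
        from nims.merge_cohesion import own_group_pairing

        cover = Cover(
            label="A", members=frozenset({"a0", "a1", "a2", "a3"}),
            constituents=("A",),
        )
        splits = {s.node: s for s in own_group_pairing(barbell, cover)}
        # a3 and b0 carry the bridge; everyone else is purely internal
        assert (splits["a3"].in_links, splits["a3"].out_links) == (3, 1)
        assert (splits["b0"].in_links, splits["b0"].out_links) == (3, 1)
        assert (splits["a0"].in_links, splits["a0"].out_links) == (3, 0)

    def test_undefined_when_balanced(self):
        square = net_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        cover = Cover(label="half", members=frozenset({"a", "b"}), constituents=("h",))
        with pytest.raises(ValueError, match="undefined"):
            cohesion_test(square, cover)

    def test_unknown_member_rejected(self, triangle):
        cover = Cover(label="bad", members=frozenset({"zz"}), constituents=("b",))
        with pytest.raises(ValueError):
            cohesion_test(triangle, cover)

    def test_pluggable_pairing(self, barbell):
        from nims.network_model import degree_split

        def members_only(net, cover):
            return [
                s for s in degree_split(net, cover.members) if s.node in cover.members
            ]

        cover = Cover(
            label="A", members=frozenset({"a0", "a1", "a2", "a3"}),
            constituents=("A",),
        )
        result = cohesion_test(barbell, cover, pairing=members_only)
        assert result.n_used <= 4


class TestRunNims:
    def test_k6_short_circuits(self, k6):
        report = run_nims(k6, FAST)
        assert report.trivially_integrated
        assert len(report.modules) == 1
        assert report.modules[0].members == frozenset(k6.nodes)
        assert report.intersections == []
        assert report.covers == []
        assert report.cohesion == []

    def test_planted_two_cliques_recovered(self):
        net, truth = planted_network(
            PlantedSpec(module_sizes=(5, 5), p_in=1.0, p_out=0.0, overlap=0, seed=3)
        )
        report = run_nims(net, SpinglassConfig(replicates=5, seed=3))
        assert {c.members for c in report.covers} == {
            frozenset(v) for v in truth.values()
        }
        for res in report.cohesion:
            assert res.p < 0.05

    def test_overlapping_cliques_merge_into_one_cover(self):
        # two 6-cliques sharing 3 nodes: the two local modules overlap
        # significantly and merge into a single cover
        left = [f"l{i}" for i in range(3)]
        right = [f"r{i}" for i in range(3)]
        shared = [f"s{i}" for i in range(3)]
        net = net_from_edges(
            clique_edges(left + shared) + clique_edges(right + shared)
        )
        report = run_nims(net, SpinglassConfig(replicates=5, seed=2))
        if not report.trivially_integrated and report.plan is not None:
            for group in report.plan.merges:
                assert len(group) >= 2

    def test_deterministic_reports(self):
        net, _ = planted_network(
            PlantedSpec(module_sizes=(4, 4), p_in=0.9, p_out=0.2, overlap=1, seed=8)
        )
        cfg = SpinglassConfig(replicates=4, seed=17)
        a = run_nims(net, cfg).to_json()
        b = run_nims(net, cfg).to_json()
        assert a == b

    def test_every_cover_has_cohesion_or_warning(self):
        net, _ = planted_network(
            PlantedSpec(module_sizes=(5, 5), p_in=1.0, p_out=0.1, overlap=1, seed=5)
        )
        report = run_nims(net, FAST)
        assert len(report.cohesion) + sum(
            "undefined" in w for w in report.warnings
        ) >= len(report.covers)

    def test_uncovered_nodes_listed(self):
        # pendant chain hanging off a clique pair may fall outside all covers
        net, _ = planted_network(
            PlantedSpec(module_sizes=(5, 5), p_in=1.0, p_out=0.0, overlap=0, seed=1)
        )
        report = run_nims(net, FAST)
        covered = set().union(*(c.members for c in report.covers))
        assert set(report.uncovered_nodes) == set(net.nodes) - covered

    def test_cover_symmetry_on_bilateral_fixture(self):
        net, _ = planted_network(
            PlantedSpec(module_sizes=(6, 6), p_in=1.0, p_out=0.05, overlap=1,
                        bilateral=True, seed=4)
        )
        report = run_nims(net, SpinglassConfig(replicates=5, seed=4))

        def mirror(label):
            if label.endswith("L"):
                return label[:-1] + "R"
            if label.endswith("R"):
                return label[:-1] + "L"
            return label

        cover_sets = {frozenset(c.members) for c in report.covers}
        mirrored = {frozenset(mirror(n) for n in s) for s in cover_sets}
        assert cover_sets == mirrored
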