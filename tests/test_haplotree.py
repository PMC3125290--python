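"""Tree building, distance profiles, ancestral-sequence scoring."""

import numpy as np
import pytest

from mitoclock import (
    BranchEvent,
    MutationClass,
    Node,
    HaplotypeTree,
    Substitution,
    as_lifespan,
    build_tree,
    distance_profile,
    find_ancestral_sequences,
    induced_subtree,
    root_to_tip_distances,
)

from conftest import make_caterpillar, star_clade


class TestBuildTree:
    def test_single_tip_distance(self):
        tree = build_tree([("tip", "root", "A100G;C200T")])
        for ev in tree.node("tip").events:
            ev.mutation_class = MutationClass.SYNONYMOUS
        prof = distance_profile(tree, "root", "all")
        assert prof.counts == {"tip": 2}

    def test_round_trip_through_tsv(self, tmp_path):
        tree = make_caterpillar([2, 0, 3])
        path = tmp_path / "branches.tsv"
        tree.to_tsv(path)
        from mitoclock import read_tree_tsv

        back = read_tree_tsv(path)
        assert {n.node_id for n in back.preorder()} == {
            n.node_id for n in tree.preorder()
        }
        p1 = distance_profile(tree, tree.root.node_id, "synonymous")
        p2 = distance_profile(back, back.root.node_id, "synonymous")
        assert p1.counts == p2.counts

    def test_duplicate_tip_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_tree([("a", "root", ""), ("a", "root", "")])

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            build_tree([("a", "b", ""), ("b", "a", "")])

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            build_tree([("a", "r1", ""), ("b", "r2", "")])

    def test_random_tree_path_counts_match_bfs_oracle(self, rng):
        # random 50-tip topology; compare path counts against an
        # independent breadth-first search over a parent adjacency map
        n_tips = 50
        rows, parents = [], {}
        node_names = ["root"]
        pos = 10
        for i in range(n_tips):
            parent = str(rng.choice(node_names))
            child = f"x{i}"
            k = int(rng.integers(4))
            subs = ";".join(f"A{pos + 3 * j}G" for j in range(k))
            pos += 3 * k + 3
            rows.append((child, parent, subs))
            parents[child] = (parent, k)
            node_names.append(child)
        tree = build_tree(rows)
        prof = distance_profile(tree, "root", "all")
        for tip in tree.tips:
            d, cur = 0, tip.node_id
            while cur != "root":
                cur, k = parents[cur][0], parents[cur][1]
                d += k
                # oracle walks the adjacency map, not the Node objects
            assert prof.counts[tip.node_id] == d


class TestDistanceProfile:
    def test_zero_mutation_path(self):
        tree = build_tree([("tip", "root", "")])
        assert distance_profile(tree, "root", "all").counts == {"tip": 0}

    def test_additivity_along_root_path(self):
        tree = make_caterpillar([1, 2, 3, 4])
        full = distance_profile(tree, "root", "synonymous")
        mid = tree.node("i1")
        below = distance_profile(tree, mid, "synonymous",
                                 tips=tree.tips_below(mid))
        above = tree.path_count(mid, tree.root, tree_filter("synonymous"))
        for tip_id, d in below.counts.items():
            assert full.counts[tip_id] == d + above

    def test_depth_one_clade_composes_with_subclade_distance(self):
        # a clade whose MRCA is one synonymous step below the root: each
        # tip's root distance is 1 + its distance to the clade MRCA
        root = Node("root")
        mrca = Node("R0", parent=root)
        mrca.events.append(
            BranchEvent(Substitution(50, "A", "G"), MutationClass.SYNONYMOUS)
        )
        root.children.append(mrca)
        star_clade(mrca, [2, 3, 4, 2], "t")
        tree = HaplotypeTree(root)
        to_root = distance_profile(tree, "root", "synonymous")
        to_mrca = distance_profile(tree, "R0", "synonymous",
                                   tips=tree.tips_below(mrca))
        for tid in to_mrca.counts:
            assert to_root.counts[tid] == 1 + to_mrca.counts[tid]

    def test_nondescendant_tips_excluded(self):
        tree = build_tree([("a", "root", ""), ("b", "root", ""), ("c", "a", "")])
        prof = distance_profile(tree, "a")
        assert set(prof.counts) == {"c"}

    def test_filter_separates_classes(self):
        tree = build_tree([("tip", "root", "A100G;A200G;A300G")])
        classes = [
            MutationClass.SYNONYMOUS,
            MutationClass.NONSYNONYMOUS,
            MutationClass.NONSYNONYMOUS,
        ]
        for ev, c in zip(tree.node("tip").events, classes):
            ev.mutation_class = c
        assert distance_profile(tree, "root", "synonymous").counts["tip"] == 1
        assert distance_profile(tree, "root", "all_coding").counts["tip"] == 3


def tree_filter(name):
    from mitoclock.haplotree import FILTERS

    return FILTERS[name]


class TestAncestralSequences:
    def test_star_tree_carrier_at_root(self):
        root = Node("root")
        carrier = Node("carrier", parent=root)
        root.children.append(carrier)
        star_clade(root, [2, 3, 4], "sib")
        tree = HaplotypeTree(root)
        recs = find_ancestral_sequences(tree)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.carrier_tips == ["carrier"]
        assert rec.db == 0
        assert rec.da == pytest.approx(3.0)
        assert rec.lifespan == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "db,da,expected_pct",
        [(6, 3.70, 38.14), (3, 2.75, 47.83), (2, 2.00, 50.00)],
    )
    def test_lifespan_formula(self, db, da, expected_pct):
        assert 100 * as_lifespan(da, db) == pytest.approx(expected_pct, abs=0.005)

    def test_lifespan_symmetric_at_equal_distances(self):
        assert as_lifespan(3.3, 3.3) == pytest.approx(0.5)

    def test_lifespan_undefined_at_zero(self):
        with pytest.raises(ValueError):
            as_lifespan(0, 0)

    def test_lifespan_monotonicity(self):
        assert as_lifespan(4.0, 5) > as_lifespan(3.0, 5)
        assert as_lifespan(3.0, 6) < as_lifespan(3.0, 5)

    def test_published_u_clade_row(self):
        # ancestor 6 synonymous steps below the super-MRCA; 10 diverged
        # relatives averaging 3.70 -> lifespan 38.14%
        root = Node("MRCA_R")
        chain_pos = [10]

        def syn_branch(parent, child_id, k):
            node = Node(child_id, parent=parent)
            parent.children.append(node)
            for _ in range(k):
                node.events.append(
                    BranchEvent(
                        Substitution(chain_pos[0], "A", "G"),
                        MutationClass.SYNONYMOUS,
                    )
                )
                chain_pos[0] += 1
            return node

        as_node = syn_branch(root, "AS_U", 6)
        carrier = Node("S23", parent=as_node)
        as_node.children.append(carrier)
        star_clade(as_node, [2, 3, 3, 3, 4, 4, 4, 4, 5, 5], "rel", 500)
        tree = HaplotypeTree(root)
        recs = find_ancestral_sequences(tree, "MRCA_R")
        rec = next(r for r in recs if r.node_id == "AS_U")
        assert rec.db == 6
        assert rec.da == pytest.approx(3.70)
        assert 100 * rec.lifespan == pytest.approx(38.14, abs=0.005)

    def test_carriers_have_zero_distance_invariant(self):
        tree = make_caterpillar([0, 2, 0, 3])
        for rec in find_ancestral_sequences(tree):
            node = tree.node(rec.node_id)
            for tid in rec.carrier_tips:
                assert tree.path_count(
                    tree.node(tid), node, tree_filter("all_coding")
                ) == 0

    def test_nested_candidates_report_highest_node(self):
        # carrier hangs below two nested zero-mutation internal nodes; only
        # the closest-to-root one is reported for that carrier set
        root = Node("root")
        a = Node("a", parent=root)
        a.events.append(
            BranchEvent(Substitution(50, "A", "G"), MutationClass.SYNONYMOUS)
        )
        root.children.append(a)
        b = Node("b", parent=a)
        a.children.append(b)
        carrier = Node("carrier", parent=b)
        b.children.append(carrier)
        star_clade(b, [2], "relb", 100)
        star_clade(a, [3], "rela", 200)
        tree = HaplotypeTree(root)
        recs = find_ancestral_sequences(tree)
        by_carrier = [r for r in recs if r.carrier_tips == ["carrier"]]
        assert len(by_carrier) == 1
        assert by_carrier[0].node_id == "a"


class TestRootToTip:
    def test_ultrametric_groups_equal(self):
        nwk = "[&R] ((a:1,b:1):1,(c:1,d:1):1);"
        out = root_to_tip_distances(
            nwk, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        )
        means = dict(zip(out["group"], out["mean_distance"]))
        assert means["g1"] == pytest.approx(means["g2"]) == pytest.approx(2.0)

    def test_halved_clade_halves_mean(self):
        nwk = "[&R] ((a:1,b:1):1,(c:0.5,d:0.5):0.5);"
        out = root_to_tip_distances(
            nwk, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        )
        means = dict(zip(out["group"], out["mean_distance"]))
        assert means["g2"] == pytest.approx(means["g1"] / 2)

    def test_two_tree_sample_averages(self):
        t1 = "[&R] (a:1,b:3);"
        t2 = "[&R] (a:2,b:5);"
        out = root_to_tip_distances([t1, t2], {"a": "A", "b": "B"})
        means = dict(zip(out["group"], out["mean_distance"]))
        assert means["A"] == pytest.approx(1.5)
        assert means["B"] == pytest.approx(4.0)

    def test_unrooted_rejected(self):
        with pytest.raises(ValueError, match="unrooted|root"):
            root_to_tip_distances("[&U] (a:1,b:1,c:1);", {"a": "g", "b": "g", "c": "g"})

    def test_unassigned_tip_rejected(self):
        with pytest.raises(ValueError, match="group"):
            root_to_tip_distances("[&R] (a:1,b:1);", {"a": "g"})


class TestInducedSubtree:
    def test_events_conserved_on_paths(self):
        tree = make_caterpillar([1, 2, 3, 4, 5])
        keep = ["tip0", "tip2", "tip4"]
        sub = induced_subtree(tree, keep)
        full = distance_profile(tree, tree.root.node_id, "synonymous")
        reduced = distance_profile(sub, sub.root.node_id, "synonymous")
        assert {t: reduced.counts[t] for t in keep} == {
            t: full.counts[t] for t in keep
        }

    def test_unknown_tip_rejected(self):
        tree = make_caterpillar([1])
        with pytest.raises(ValueError):
            induced_subtree(tree, ["nope"])
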